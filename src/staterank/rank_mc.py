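"""Monte Carlo rank uncertainty for state prevalence estimates.

League tables of geographic units hide large sampling uncertainty in the
ranks themselves. The engine here quantifies it directly: each state's
prevalence is treated as an independent draw around its point estimate
with its reported standard error; every simulation row jointly re-draws
all states, ranks them (rank 1 = highest prevalence), and the per-state
rank distribution across rows yields a median rank and a 95% rank
confidence interval.

Two CI modes are available:

``individual``
    per-state 2.5th/97.5th order statistics of the rank distribution;
``simultaneous``
    per-state intervals jointly widened until at least the nominal
    fraction of simulation rows has *every* state inside its interval.

Median and CI endpoints are order statistics of integer ranks (no
interpolation), so all reported quantities are integers and the median
always lies inside its CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import stats

from .estimates_io import (
    EstimateTable,
    RankSummary,
    RankTable,
    ValidationError,
)

DISTRIBUTIONS = ("normal", "truncated_normal", "binomial", "lognormal")
MODES = ("individual", "simultaneous")


class CoverageWarning(UserWarning):
    """Simulation-count or joint-coverage caveats."""


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one Monte Carlo ranking run.

    n_sims
        number of joint simulation rows (default 100,000, the published
        convention; fewer than 1,000 triggers a warning because the CI
        order statistics become unstable).
    distribution
        sampling law per state: ``normal`` (default), ``truncated_normal``
        (normal truncated to [0, 100]), ``binomial`` (draws on the
        effective-sample-size grid), or ``lognormal`` (moment-matched).
    ci_level
        CI level in (0, 1); default 0.95.
    mode
        ``individual`` or ``simultaneous`` rank CIs.
    seed
        one seed governs the entire replicate matrix through a single
        generator stream, so runs are exactly reproducible.

    Rank direction is fixed: rank 1 is always the highest prevalence.
    """

    n_sims: int = 100_000
    distribution: str = "normal"
    ci_level: float = 0.95
    mode: str = "individual"
    seed: int = 0

    rank_direction: str = field(default="descending", init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValidationError(f"n_sims must be positive, got {self.n_sims}")
        if self.distribution not in DISTRIBUTIONS:
            raise ValidationError(
                f"unknown distribution {self.distribution!r}; expected one of {DISTRIBUTIONS}"
            )
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError(f"ci_level must be in (0, 1), got {self.ci_level}")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from a key: value text file (YAML subset)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {"n_sims", "distribution", "ci_level", "mode", "seed"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class RankMatrix:
    """Integer ranks for every simulation row; each row is a permutation."""

    ranks: np.ndarray  # (n_sims, n_states) int
    state_order: tuple[str, ...]

    @property
    def n_sims(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_states(self) -> int:
        return self.ranks.shape[1]


def effective_sample_size(prevalence: float, se: float) -> float:
    """Binomial sample size whose sampling SE matches the reported SE.

    On the proportion scale, a simple random sample of size n has
    SE = sqrt(p(1-p)/n); inverting gives n = p(1-p)/SE^2. Inputs are on
    the percent scale as stored.
    """
    if not 0.0 < prevalence < 100.0:
        raise ValidationError(
            f"effective sample size undefined at boundary prevalence {prevalence}"
        )
    if se <= 0.0:
        raise ValidationError(f"effective sample size requires SE > 0, got {se}")
    p = prevalence / 100.0
    return p * (1.0 - p) / (se / 100.0) ** 2


def draw_replicates(table: EstimateTable, config: SimulationConfig) -> np.ndarray:
    """Simulate an (n_sims, n_states) matrix of prevalence replicates.

    Column j is drawn independently with location p_j and spread SE_j
    under ``config.distribution``. States with SE = 0 produce constant
    columns under every distribution.
    """
    rng = np.random.default_rng(config.seed)
    p = table.prevalences
    se = table.ses
    n = config.n_sims
    k = table.n_states
    dist = config.distribution

    if dist == "normal":
        return p + se * rng.standard_normal((n, k))

    if dist == "truncated_normal":
        # inverse-CDF on the truncated law; exact, no rejection loop
        u = rng.random((n, k))
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(se > 0, (0.0 - p) / np.where(se > 0, se, 1.0), -np.inf)
            b = np.where(se > 0, (100.0 - p) / np.where(se > 0, se, 1.0), np.inf)
        out = stats.truncnorm.ppf(u, a, b, loc=p, scale=np.where(se > 0, se, 1.0))
        return np.where(se > 0, out, p)

    if dist == "binomial":
        out = np.empty((n, k))
        for j in range(k):
            if se[j] == 0.0:
                out[:, j] = p[j]
                continue
            if p[j] in (0.0, 100.0):
                raise ValidationError(
                    f"{table.states[j]}: binomial draws undefined at boundary "
                    f"prevalence {p[j]} with SE {se[j]} > 0"
                )
            n_eff = max(1, round(effective_sample_size(p[j], se[j])))
            out[:, j] = 100.0 * rng.binomial(n_eff, p[j] / 100.0, size=n) / n_eff
        return out

    # lognormal: solve for (mu, sigma) so the draw has mean p and SD se
    out = np.empty((n, k))
    for j in range(k):
        if se[j] == 0.0:
            out[:, j] = p[j]
            continue
        if p[j] <= 0.0:
            raise ValidationError(
                f"{table.states[j]}: lognormal draws require prevalence > 0"
            )
        sigma2 = np.log1p((se[j] / p[j]) ** 2)
        mu = np.log(p[j]) - sigma2 / 2.0
        out[:, j] = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    return out


def rank_replicates(replicates: np.ndarray) -> "RankMatrix":
    """Rank every simulation row, rank 1 = largest simulated prevalence.

    Exact ties within a row (possible under the binomial law) are broken
    by input column order, so every row is a permutation of 1..n_states.
    """
    replicates = np.asarray(replicates, dtype=float)
    if not np.all(np.isfinite(replicates)):
        raise ValidationError("replicate matrix contains non-finite values")
    n, k = replicates.shape
    order = np.argsort(-replicates, axis=1, kind="stable")
    ranks = np.empty((n, k), dtype=np.int32)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(1, k + 1, dtype=np.int32), (n, k)), axis=1)
    return RankMatrix(ranks=ranks, state_order=())


def _order_stat_index(q: float, n: int) -> int:
    """0-based index of the ceil(q*n)-th order statistic, clipped to [0, n-1]."""
    return min(max(int(np.ceil(q * n)), 1), n) - 1


def summarize_ranks(
    rank_matrix: RankMatrix,
    config: SimulationConfig,
    estimates: EstimateTable | None = None,
) -> RankTable:
    """Median rank and CI per state from a simulated rank matrix.

    The median is the lower median (the ceil(n/2)-th order statistic), so
    it is always an integer attained in the simulation and always lies
    inside the CI. Individual-mode CI endpoints are the 2.5th/97.5th
    (for ci_level 0.95) order statistics of each state's rank
    distribution; simultaneous mode calls :func:`simultaneous_adjust`.
    """
    ranks = rank_matrix.ranks
    if ranks.size == 0:
        raise ValidationError("empty rank matrix")
    n, k = ranks.shape
    if n < 1000:
        warnings.warn(
            f"only {n} simulations; rank CI order statistics are unstable below 1000",
            CoverageWarning,
            stacklevel=2,
        )
    states = rank_matrix.state_order or (
        estimates.states if estimates is not None else tuple(f"col{j}" for j in range(k))
    )

    sorted_ranks = np.sort(ranks, axis=0)
    med = sorted_ranks[_order_stat_index(0.5, n), :]
    alpha = 1.0 - config.ci_level
    if config.mode == "simultaneous":
        lo, hi = simultaneous_adjust(rank_matrix, config.ci_level)
    else:
        lo = sorted_ranks[_order_stat_index(alpha / 2.0, n), :]
        hi = sorted_ranks[_order_stat_index(1.0 - alpha / 2.0, n), :]

    summaries = []
    for j in range(k):
        counts = np.bincount(ranks[:, j], minlength=k + 1)[1:]
        summaries.append(
            RankSummary(
                state=states[j],
                median_rank=int(med[j]),
                ci_low=int(lo[j]),
                ci_high=int(hi[j]),
                rank_counts=counts,
            )
        )
    return RankTable(summaries=tuple(summaries), provenance=config, estimates=estimates)


def simultaneous_adjust(
    rank_matrix: RankMatrix, ci_level: float = 0.95, grid_size: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly calibrated per-state rank intervals.

    Searches a grid of per-state tail probabilities gamma from the nominal
    (1 - ci_level) downward for the largest gamma whose product set of
    per-state order-statistic intervals [Q_j(gamma/2), Q_j(1 - gamma/2)]
    contains every state's rank simultaneously in at least ``ci_level``
    of simulation rows. Joint row coverage is monotone as gamma shrinks,
    so the grid is bisected. The result is a superset of the individual
    interval for every state.
    """
    ranks = rank_matrix.ranks
    n, k = ranks.shape
    if n < 1000:
        warnings.warn(
            f"only {n} simulations; simultaneous calibration is unstable below 1000",
            CoverageWarning,
            stacklevel=2,
        )
    sorted_ranks = np.sort(ranks, axis=0)
    alpha = 1.0 - ci_level
    gammas = np.linspace(alpha, 0.0, grid_size + 1)  # nominal downward to full range

    def intervals(gamma: float) -> tuple[np.ndarray, np.ndarray]:
        lo = sorted_ranks[_order_stat_index(gamma / 2.0, n), :]
        hi = sorted_ranks[_order_stat_index(1.0 - gamma / 2.0, n), :]
        return lo, hi

    def joint_coverage(lo: np.ndarray, hi: np.ndarray) -> float:
        inside = (ranks >= lo) & (ranks <= hi)
        return float(np.mean(inside.all(axis=1)))

    lo, hi = intervals(gammas[0])
    if joint_coverage(lo, hi) >= ci_level:
        return lo, hi

    # bisect for the smallest grid index whose coverage reaches ci_level
    left, right = 0, len(gammas) - 1  # left fails, right (gamma=0) always covers
    while right - left > 1:
        mid = (left + right) // 2
        lo, hi = intervals(gammas[mid])
        if joint_coverage(lo, hi) >= ci_level:
            right = mid
        else:
            left = mid
    lo, hi = intervals(gammas[right])
    if joint_coverage(lo, hi) < ci_level:  # pragma: no cover - gamma=0 spans all rows
        warnings.warn(
            "grid exhausted without reaching joint coverage; returning full-range intervals",
            CoverageWarning,
            stacklevel=2,
        )
        return np.ones(k, dtype=int), np.full(k, k, dtype=int)
    return lo, hi


def simulate_ranks(table: EstimateTable, config: SimulationConfig | None = None) -> RankTable:
    """Draw replicates, rank them, and summarize — the full engine in one call."""
    config = config or SimulationConfig()
    replicates = draw_replicates(table, config)
    matrix = RankMatrix(ranks=rank_replicates(replicates).ranks, state_order=table.states)
    return summarize_ranks(matrix, config, estimates=table)
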