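"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here with its truth
attached: estimate tables with known true prevalences and ranks (for
rank-CI coverage experiments), stratified-cluster microdata with known
true prevalence and intra-cluster correlation (for design-based variance
checks), and a full two-survey, three-behavior "world" for end-to-end
rehearsal of the analysis.

True state prevalences are drawn uniformly over a configurable range —
deliberately not normal, so the ranking engine's coverage is not assessed
only under its own sampling assumption. Observed estimates add normal
noise at the state's SE, truncated to [0, 100]. Clustered microdata uses
PSU-level random intercepts on the logit scale, which keeps prevalences
in range at any clustering strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .estimates_io import EstimateTable, StateEstimate, ValidationError
from .survey_estimation import SurveyMicrodata


@dataclass(frozen=True)
class TruthTable:
    """Known truth per state: prevalence, SE, and rank (1 = highest)."""

    states: tuple[str, ...]
    true_prevalence: np.ndarray
    true_se: np.ndarray
    true_rank: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.states)
        if sorted(self.true_rank.tolist()) != list(range(1, n + 1)):
            raise ValidationError("true ranks must be a permutation of 1..n_states")

    def rank_of(self, state: str) -> int:
        return int(self.true_rank[self.states.index(state)])


def _true_ranks(states: Sequence[str], prevalence: np.ndarray) -> np.ndarray:
    """Descending ranks of true prevalence, ties broken alphabetically."""
    order = sorted(range(len(states)), key=lambda j: (-prevalence[j], states[j]))
    ranks = np.empty(len(states), dtype=int)
    ranks[order] = np.arange(1, len(states) + 1)
    return ranks


def generate_estimate_table(
    n_states: int = 51,
    prevalence_low: float = 4.5,
    prevalence_high: float = 14.3,
    se_low: float = 0.4,
    se_high: float = 1.4,
    seed: int = 0,
    survey: str = "synthetic",
    behavior: str = "synthetic",
) -> tuple[EstimateTable, TruthTable]:
    """Estimate table with known truth.

    Defaults mirror the marginal structure of published state tables of
    adolescent substance use (prevalences roughly 4-15%, SEs 0.4-1.4%).
    True prevalences are uniform on [low, high]; SEs uniform on
    [se_low, se_high]; observed prevalence is normal around truth with
    that SE, truncated to [0, 100].
    """
    if not (0.0 <= prevalence_low < prevalence_high <= 100.0):
        raise ValidationError("need 0 <= prevalence_low < prevalence_high <= 100")
    if not (0.0 <= se_low < se_high):
        raise ValidationError("need 0 <= se_low < se_high")
    if n_states < 2:
        raise ValidationError("need n_states >= 2")
    rng = np.random.default_rng(seed)
    states = tuple(f"S{j:02d}" for j in range(1, n_states + 1))
    truth = rng.uniform(prevalence_low, prevalence_high, n_states)
    ses = rng.uniform(se_low, se_high, n_states)
    a = (0.0 - truth) / ses
    b = (100.0 - truth) / ses
    observed = stats.truncnorm.ppf(rng.random(n_states), a, b, loc=truth, scale=ses)
    table = EstimateTable(
        entries=tuple(
            StateEstimate(state=s, prevalence=float(observed[j]), se=float(ses[j]),
                          survey=survey, behavior=behavior)
            for j, s in enumerate(states)
        ),
        survey=survey,
        behavior=behavior,
    )
    truth_table = TruthTable(
        states=states,
        true_prevalence=truth,
        true_se=ses,
        true_rank=_true_ranks(states, truth),
    )
    return table, truth_table


def generate_microdata(
    n_states: int = 3,
    strata_per_state: int = 10,
    psus_per_stratum: int = 2,
    respondents_per_psu: int = 30,
    true_prevalence: Sequence[float] | float = 10.0,
    icc: float = 0.05,
    weight_cv: float = 0.5,
    seed: int = 0,
) -> tuple[SurveyMicrodata, TruthTable]:
    """Stratified-cluster microdata with known truth.

    PSU random intercepts live on the logit scale with variance
    sigma^2 = icc * (pi^2/3) / (1 - icc), the latent-threshold
    calibration for a target intra-cluster correlation. Weights are
    lognormal with coefficient of variation ``weight_cv``, normalized to
    mean 1 within state. ``true_prevalence`` (percent) may be a scalar or
    one value per state; a state at 0 (or 100) yields all-0 (all-1)
    outcomes.
    """
    if not 0.0 <= icc < 1.0:
        raise ValidationError(f"icc must be in [0, 1), got {icc}")
    if psus_per_stratum < 2:
        raise ValidationError("need >= 2 PSUs per stratum for variance estimation")
    if weight_cv < 0:
        raise ValidationError("weight_cv must be nonnegative")
    prev = np.broadcast_to(np.asarray(true_prevalence, dtype=float), (n_states,)).copy()
    if np.any((prev < 0) | (prev > 100)):
        raise ValidationError("true_prevalence must lie in [0, 100]")

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(icc * (np.pi**2 / 3.0) / (1.0 - icc)) if icc > 0 else 0.0
    states = tuple(f"S{j:02d}" for j in range(1, n_states + 1))
    rows = []
    for j, state in enumerate(states):
        p = prev[j] / 100.0
        for h in range(strata_per_state):
            for c in range(psus_per_stratum):
                u = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                if p in (0.0, 1.0):
                    p_psu = p
                else:
                    p_psu = float(expit(logit(p) + u))
                y = rng.binomial(1, p_psu, size=respondents_per_psu)
                w = _lognormal_weights(rng, respondents_per_psu, weight_cv)
                for i in range(respondents_per_psu):
                    rows.append((state, f"h{h:02d}", f"h{h:02d}p{c:02d}", w[i], int(y[i])))
    frame = pd.DataFrame(rows, columns=["state", "stratum", "psu", "weight", "outcome"])
    # normalize weights to mean 1 within state
    frame["weight"] = frame["weight"] / frame.groupby("state")["weight"].transform("mean")
    truth = TruthTable(
        states=states,
        true_prevalence=prev,
        true_se=np.zeros(n_states),
        true_rank=_true_ranks(states, prev),
    )
    return SurveyMicrodata(records=frame), truth


def _lognormal_weights(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


# Ranges emulating the published tables: (prevalence_low, prevalence_high,
# se_low, se_high) per behavior, for the in-home-style survey A and the
# school-based-style survey B (systematically higher levels).
_WORLD_RANGES = {
    "cigarette": {"A": (4.5, 14.3, 0.4, 1.4), "B": (4.7, 18.5, 0.4, 1.6)},
    "binge_alcohol": {"A": (5.9, 14.3, 0.5, 1.5), "B": (7.1, 21.7, 0.4, 2.4)},
    "marijuana": {"A": (6.3, 18.7, 0.5, 1.6), "B": (8.2, 27.1, 0.5, 2.0)},
}
_DROPPED_FROM_B = ("S08", "S21", "S33", "S46")  # survey B misses 4 states


@dataclass(frozen=True)
class TwoSurveyWorld:
    """Two surveys x three behaviors with correlated true prevalences."""

    tables: dict[tuple[str, str], EstimateTable]
    truths: dict[tuple[str, str], TruthTable]
    truth_correlation: float
    seed: int


def make_two_survey_world(
    seed: int = 0, truth_correlation: float = 0.9, n_states: int = 51
) -> TwoSurveyWorld:
    """A full synthetic study: surveys A (all states) and B (4 dropped),
    three behaviors each, with cross-survey true-prevalence correlation
    ``truth_correlation`` imposed through a Gaussian copula.
    """
    if not -1.0 <= truth_correlation <= 1.0:
        raise ValidationError("truth_correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    states = tuple(f"S{j:02d}" for j in range(1, n_states + 1))
    b_states = tuple(s for s in states if s not in _DROPPED_FROM_B)

    tables: dict[tuple[str, str], EstimateTable] = {}
    truths: dict[tuple[str, str], TruthTable] = {}
    for behavior, ranges in _WORLD_RANGES.items():
        za = rng.standard_normal(n_states)
        zb = truth_correlation * za + np.sqrt(1.0 - truth_correlation**2) * rng.standard_normal(n_states)
        for survey, z in (("A", za), ("B", zb)):
            lo, hi, se_lo, se_hi = ranges[survey]
            keep = states if survey == "A" else b_states
            idx = [states.index(s) for s in keep]
            truth = lo + (hi - lo) * stats.norm.cdf(z[idx])
            ses = rng.uniform(se_lo, se_hi, len(keep))
            a = (0.0 - truth) / ses
            b = (100.0 - truth) / ses
            observed = stats.truncnorm.ppf(rng.random(len(keep)), a, b, loc=truth, scale=ses)
            tables[(survey, behavior)] = EstimateTable(
                entries=tuple(
                    StateEstimate(state=s, prevalence=float(observed[k]), se=float(ses[k]),
                                  survey=survey, behavior=behavior)
                    for k, s in enumerate(keep)
                ),
                survey=survey,
                behavior=behavior,
            )
            truths[(survey, behavior)] = TruthTable(
                states=tuple(keep),
                true_prevalence=truth,
                true_se=ses,
                true_rank=_true_ranks(keep, truth),
            )
    return TwoSurveyWorld(
        tables=tables, truths=truths, truth_correlation=truth_correlation, seed=seed
    )
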