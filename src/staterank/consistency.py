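"""Rank-consistency and paired-comparison analysis across surveys/behaviors.

Spearman rank correlations (midrank tie correction, t-approximation
p-values) quantify how consistently two rankings order the same states;
paired t-tests with Bonferroni adjustment compare prevalence levels
between surveys. Both operate on the states common to the two inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimates_io import EstimateTable, RankTable, ValidationError


@dataclass(frozen=True)
class AlignedPair:
    """State-matched value vectors from two tables (alphabetical order)."""

    states: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    dropped_from_a: tuple[str, ...]
    dropped_from_b: tuple[str, ...]

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class ConsistencyResult:
    """Tie-corrected Spearman correlation between two rank vectors."""

    rho: float
    p_value: float
    n_states: int
    method_note: str = "midrank tie correction; two-sided t approximation on n-2 df"


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test of b - a with Bonferroni-adjusted p-value."""

    mean_diff: float
    t_stat: float
    df: int
    p_raw: float
    p_adjusted: float
    m_comparisons: int


def _as_series(table) -> pd.Series:
    """State-indexed values: median ranks from a RankTable, prevalences
    from an EstimateTable; a state-indexed Series passes through."""
    if isinstance(table, RankTable):
        return table.median_ranks()
    if isinstance(table, EstimateTable):
        return pd.Series(
            {e.state: e.prevalence for e in table.entries}, name="prevalence_pct"
        )
    if isinstance(table, pd.Series):
        return table
    raise TypeError(f"cannot align object of type {type(table).__name__}")


def align_states(a, b) -> AlignedPair:
    """Inner-join two state-keyed tables; stable alphabetical order.

    Accepts RankTable (aligned on median rank), EstimateTable (aligned on
    prevalence), or a state-indexed pandas Series. States absent from
    either side are dropped and reported.
    """
    sa, sb = _as_series(a), _as_series(b)
    shared = sorted(set(sa.index) & set(sb.index))
    if not shared:
        raise ValidationError("no states in common between the two tables")
    return AlignedPair(
        states=tuple(shared),
        x=sa.loc[shared].to_numpy(dtype=float),
        y=sb.loc[shared].to_numpy(dtype=float),
        dropped_from_a=tuple(sorted(set(sa.index) - set(shared))),
        dropped_from_b=tuple(sorted(set(sb.index) - set(shared))),
    )


def spearman_ranks(x: Sequence[float], y: Sequence[float]) -> ConsistencyResult:
    """Spearman rank correlation with midrank ties and t-approximate p.

    rho is the Pearson correlation of midranks; the two-sided p-value uses
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom. Published
    median ranks carry many ties, which midranks handle correctly (the
    classical 6*sum(d^2) formula would not).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 pairs, got {x.size}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("zero variance in a rank vector; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return ConsistencyResult(rho=float(rho), p_value=float(p), n_states=int(x.size))


def paired_t(a: Sequence[float], b: Sequence[float], m_comparisons: int = 3) -> PairedComparison:
    """Paired t-test of d = b - a with Bonferroni adjustment.

    ``m_comparisons`` defaults to 3, one per behavior when comparing two
    surveys across cigarette, binge-alcohol and marijuana outcomes.
    Degenerate differences are handled explicitly: constant nonzero
    difference gives p -> 0; identically zero difference gives t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValidationError(f"need at least 2 pairs, got {a.size}")
    if m_comparisons < 1:
        raise ValidationError("m_comparisons must be >= 1")
    d = b - a
    n = d.size
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.sign(mean)) * np.inf
        p = 1.0 if mean == 0.0 else 0.0
    else:
        res = stats.ttest_rel(b, a)
        t, p = float(res.statistic), float(res.pvalue)
    return PairedComparison(
        mean_diff=mean,
        t_stat=t,
        df=n - 1,
        p_raw=p,
        p_adjusted=min(1.0, m_comparisons * p),
        m_comparisons=m_comparisons,
    )


def consistency_matrix(
    tables: Mapping[str, object],
    pairs: Iterable[tuple[str, str]],
    shared_states_with: Mapping[str, str] | None = None,
) -> dict[tuple[str, str], ConsistencyResult]:
    """Spearman consistency for each requested pair of rank tables.

    ``tables`` maps labels to RankTable / state-indexed Series. Each pair
    is correlated on the intersection of its two state sets (all available
    states). To restrict a label to the states it shares with some other
    table — e.g. within-survey correlations confined to the cross-survey
    state set — pass ``shared_states_with={label: other_label}``.
    """
    if len(tables) < 2:
        raise ValidationError("need at least 2 tables")
    shared_states_with = shared_states_with or {}
    out: dict[tuple[str, str], ConsistencyResult] = {}
    for la, lb in pairs:
        sa, sb = _as_series(tables[la]), _as_series(tables[lb])
        keep = set(sa.index) & set(sb.index)
        for lbl in (la, lb):
            other = shared_states_with.get(lbl)
            if other is not None:
                keep &= set(_as_series(tables[other]).index)
        if not keep:
            raise ValidationError(f"no states in common for pair ({la}, {lb})")
        states = sorted(keep)
        out[(la, lb)] = spearman_ranks(
            sa.loc[states].to_numpy(dtype=float), sb.loc[states].to_numpy(dtype=float)
        )
    return out


def consistency_frame(results: Mapping[tuple[str, str], ConsistencyResult]) -> pd.DataFrame:
    """Delimited-text-ready view: pair_label, n_states, rho, p_value."""
    return pd.DataFrame(
        {
            "pair_label": [f"{a}|{b}" for a, b in results],
            "n_states": [r.n_states for r in results.values()],
            "rho": [r.rho for r in results.values()],
            "p_value": [r.p_value for r in results.values()],
        }
    )
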