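"""Domain types and delimited-text I/O for state-level prevalence estimates.

The central object is the :class:`EstimateTable`: one row per state with a
survey-weighted prevalence (percent) and its standard error (percent) for a
single survey and behavior. Six tables transcribed from published
state-level estimates of adolescent substance use (NSDUH and YRBSS,
2011-2015; past-month cigarette smoking, binge alcohol drinking, and
marijuana use) ship as packaged fixtures, including the published median
Monte Carlo rank for each state.

Prevalences and SEs are stored on the percent scale exactly as printed
(one decimal); nothing in this package rescales them to proportions except
internally where a formula requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

SURVEYS = ("nsduh", "yrbss")
BEHAVIORS = ("cigarette", "binge_alcohol", "marijuana")

#: YRBSS state counts differ by behavior (Hawaii lacks marijuana data).
REQUIRED_COLUMNS = ("state", "prevalence_pct", "se_pct")


class ValidationError(ValueError):
    """Raised when an input table or record violates its contract."""


@dataclass(frozen=True)
class StateEstimate:
    """Survey-weighted prevalence (percent) and SE (percent) for one state."""

    state: str
    prevalence: float
    se: float
    survey: str = ""
    behavior: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 100.0:
            raise ValidationError(
                f"{self.state}: prevalence {self.prevalence} outside [0, 100]"
            )
        if self.se < 0.0:
            raise ValidationError(f"{self.state}: negative SE {self.se}")


@dataclass(frozen=True)
class EstimateTable:
    """Ordered collection of :class:`StateEstimate` for one survey x behavior.

    State identifiers must be unique and at least two states are required
    (a single state cannot be ranked against anything).
    """

    entries: tuple[StateEstimate, ...]
    survey: str = ""
    behavior: str = ""

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValidationError(
                f"need at least 2 states to rank, got {self.n_states}"
            )
        seen: set[str] = set()
        for e in self.entries:
            if e.state in seen:
                raise ValidationError(f"duplicate state: {e.state!r}")
            seen.add(e.state)

    @property
    def n_states(self) -> int:
        return len(self.entries)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(e.state for e in self.entries)

    @property
    def prevalences(self) -> np.ndarray:
        return np.array([e.prevalence for e in self.entries], dtype=float)

    @property
    def ses(self) -> np.ndarray:
        return np.array([e.se for e in self.entries], dtype=float)

    def __iter__(self) -> Iterator[StateEstimate]:
        return iter(self.entries)

    def __getitem__(self, state: str) -> StateEstimate:
        for e in self.entries:
            if e.state == state:
                return e
        raise KeyError(state)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.states,
                "prevalence_pct": self.prevalences,
                "se_pct": self.ses,
            }
        )


@dataclass(frozen=True)
class RankSummary:
    """Median Monte Carlo rank and 95% rank CI for one state.

    ``rank_counts[r - 1]`` is the number of simulation rows in which the
    state held rank ``r``; the counts sum to the number of simulations.
    """

    state: str
    median_rank: int
    ci_low: int
    ci_high: int
    rank_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median_rank <= self.ci_high:
            raise ValidationError(
                f"{self.state}: median rank {self.median_rank} outside "
                f"CI [{self.ci_low}, {self.ci_high}]"
            )
        if self.ci_low < 1:
            raise ValidationError(f"{self.state}: ci_low {self.ci_low} < 1")


@dataclass(frozen=True)
class RankTable:
    """One :class:`RankSummary` per state, with provenance.

    Median ranks need not form a permutation of 1..n_states: ties and
    surveys with missing states both break the pattern.
    """

    summaries: tuple[RankSummary, ...]
    provenance: object = None  # the SimulationConfig used, when available
    estimates: EstimateTable | None = None

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(s.state for s in self.summaries)

    def __getitem__(self, state: str) -> RankSummary:
        for s in self.summaries:
            if s.state == state:
                return s
        raise KeyError(state)

    def median_ranks(self) -> pd.Series:
        """Median rank per state, indexed by state identifier."""
        return pd.Series(
            {s.state: s.median_rank for s in self.summaries}, name="median_rank"
        )

    def to_frame(self) -> pd.DataFrame:
        """Rank table ordered by median rank, ties broken alphabetically."""
        rows = sorted(self.summaries, key=lambda s: (s.median_rank, s.state))
        frame = pd.DataFrame(
            {
                "state": [s.state for s in rows],
                "median_rank": [s.median_rank for s in rows],
                "ci_low": [s.ci_low for s in rows],
                "ci_high": [s.ci_high for s in rows],
            }
        )
        if self.estimates is not None:
            est = self.estimates.to_frame().set_index("state")
            frame.insert(1, "prevalence_pct", est.loc[frame["state"], "prevalence_pct"].to_numpy())
            frame.insert(2, "se_pct", est.loc[frame["state"], "se_pct"].to_numpy())
        return frame


def read_estimate_table(path: str | Path, survey: str = "", behavior: str = "") -> EstimateTable:
    """Read a delimited estimate table (columns state, prevalence_pct, se_pct).

    Row order is preserved. Rows failing validation (prevalence outside
    [0, 100], non-positive SE, duplicate state) raise
    :class:`ValidationError` naming the offending row.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    entries = []
    for _, row in frame.iterrows():
        se = float(row["se_pct"])
        if se <= 0.0:
            raise ValidationError(f"{path}: state {row['state']!r} has non-positive SE {se}")
        entries.append(
            StateEstimate(
                state=str(row["state"]),
                prevalence=float(row["prevalence_pct"]),
                se=se,
                survey=survey,
                behavior=behavior,
            )
        )
    return EstimateTable(entries=tuple(entries), survey=survey, behavior=behavior)


def write_estimate_table(table: EstimateTable, path: str | Path) -> None:
    """Write an estimate table; ``read_estimate_table`` round-trips it."""
    table.to_frame().to_csv(path, index=False)


def _fixture_name(survey: str, behavior: str) -> str:
    survey = survey.strip().lower()
    behavior = behavior.strip().lower()
    if survey not in SURVEYS:
        raise ValidationError(f"unknown survey {survey!r}; expected one of {SURVEYS}")
    if behavior not in BEHAVIORS:
        raise ValidationError(f"unknown behavior {behavior!r}; expected one of {BEHAVIORS}")
    return f"{survey}_{behavior}.csv"


def load_packaged_table(survey: str, behavior: str) -> EstimateTable:
    """Load a packaged published estimate table.

    ``survey`` is ``nsduh`` or ``yrbss``; ``behavior`` is ``cigarette``,
    ``binge_alcohol`` or ``marijuana`` (case-insensitive). NSDUH tables
    carry 51 states (50 states plus the District of Columbia); YRBSS
    carries 47 (46 for marijuana, where Hawaii has no data).
    """
    name = _fixture_name(survey, behavior)
    with resources.as_file(resources.files("staterank.data") / name) as path:
        return read_estimate_table(path, survey=survey.lower(), behavior=behavior.lower())


def load_published_ranks(survey: str, behavior: str) -> pd.Series:
    """Published median Monte Carlo ranks, indexed by state.

    These are the rank columns printed alongside the prevalence estimates;
    they include ties, so they are not a permutation.
    """
    name = _fixture_name(survey, behavior)
    with resources.as_file(resources.files("staterank.data") / name) as path:
        frame = pd.read_csv(path)
    return frame.set_index("state")["published_rank"]


def write_rank_table(table: RankTable, path: str | Path) -> None:
    """Write a rank table ordered by median rank (ties alphabetical)."""
    if not str(path):
        raise ValidationError("empty output path")
    table.to_frame().to_csv(path, index=False)
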