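"""Design-based prevalence estimation from complex survey microdata.

Implements the weighted ratio estimator of a binary outcome's prevalence
and its Taylor-series-linearization standard error for a stratified,
clustered, weighted sample, under the with-replacement first-stage
approximation (no finite-population correction) that is standard for
public-use analyses of national surveillance surveys.

For a state with respondents i, weights w_i, binary outcomes y_i:

    p = sum(w_i y_i) / sum(w_i)                       (proportion scale)

The linearized residual of the ratio is z_i = w_i (y_i - p) / W with
W = sum(w_i). Aggregating z to PSU totals z_hc within design strata h,

    Var(p) = sum_h n_h / (n_h - 1) * sum_c (z_hc - zbar_h)^2

where n_h is the number of PSUs in stratum h. Every stratum contributing
to the variance must have at least two PSUs; singleton strata raise an
error rather than being silently collapsed.

Estimation is per state, independently; strata are nested within state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimates_io import EstimateTable, StateEstimate, ValidationError

MICRODATA_COLUMNS = ("state", "stratum", "psu", "weight", "outcome")


class SingletonStratumError(ValidationError):
    """A variance stratum with a single PSU cannot contribute a variance."""


@dataclass(frozen=True)
class SurveyMicrodata:
    """Respondent-level records: state, stratum, psu, weight, outcome."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MICRODATA_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"microdata missing column(s) {missing}")
        w = self.records["weight"].to_numpy(dtype=float)
        if not np.all(w > 0):
            bad = self.records.index[w <= 0][:5].tolist()
            raise ValidationError(f"non-positive weights at rows {bad}")
        y = self.records["outcome"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("outcome must be binary 0/1")

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(sorted(self.records["state"].unique()))

    def for_state(self, state: str) -> pd.DataFrame:
        sub = self.records[self.records["state"] == state]
        if sub.empty:
            raise ValidationError(f"state {state!r} not present in microdata")
        return sub


def read_microdata(path: str | Path) -> SurveyMicrodata:
    """Read respondent-level microdata from delimited text."""
    return SurveyMicrodata(records=pd.read_csv(path))


def write_microdata(data: SurveyMicrodata, path: str | Path) -> None:
    data.records.to_csv(path, index=False)


def weighted_prevalence(data: SurveyMicrodata, state: str) -> float:
    """Weighted prevalence (percent) of the outcome in one state."""
    sub = data.for_state(state)
    w = sub["weight"].to_numpy(dtype=float)
    y = sub["outcome"].to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValidationError(f"state {state!r}: zero total weight")
    return 100.0 * float(w @ y) / float(total)


def taylor_se(data: SurveyMicrodata, state: str) -> float:
    """Taylor-linearization SE (percent) of the weighted prevalence."""
    sub = data.for_state(state)
    w = sub["weight"].to_numpy(dtype=float)
    y = sub["outcome"].to_numpy(dtype=float)
    total = w.sum()
    p = float(w @ y) / float(total)
    z = w * (y - p) / total

    variance = 0.0
    for stratum, grp in sub.assign(_z=z).groupby("stratum", sort=False):
        psu_totals = grp.groupby("psu", sort=False)["_z"].sum().to_numpy()
        n_h = psu_totals.size
        if n_h < 2:
            raise SingletonStratumError(
                f"state {state!r}, stratum {stratum!r}: only {n_h} PSU; "
                "variance estimation needs >= 2 PSUs per stratum"
            )
        variance += n_h / (n_h - 1) * float(((psu_totals - psu_totals.mean()) ** 2).sum())
    return 100.0 * float(np.sqrt(variance))


def estimate_table_from_microdata(
    data: SurveyMicrodata, survey: str = "", behavior: str = ""
) -> EstimateTable:
    """One design-based StateEstimate per state (alphabetical order)."""
    entries = tuple(
        StateEstimate(
            state=s,
            prevalence=weighted_prevalence(data, s),
            se=taylor_se(data, s),
            survey=survey,
            behavior=behavior,
        )
        for s in data.states
    )
    return EstimateTable(entries=entries, survey=survey, behavior=behavior)
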