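"""One-invocation reproduction of the full ranking analysis.

`run_rank` ranks a single estimate table; `run_published_analysis` runs the whole
published analysis from the packaged fixtures: six Monte Carlo rank
tables (two surveys x three behaviors), cross-survey and within-survey
Spearman consistency, three Bonferroni-adjusted paired t-tests, and
figure-data files (state, median, ci_low, ci_high per survey, ordered by
the in-home survey's median rank). Every run writes a manifest with the
config echo, input digests, seed, version, per-stage timings, and output
paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .consistency import (
    align_states,
    consistency_frame,
    consistency_matrix,
    paired_t,
)
from .estimates_io import (
    BEHAVIORS,
    EstimateTable,
    RankTable,
    load_packaged_table,
    read_estimate_table,
    write_rank_table,
)
from .rank_mc import SimulationConfig, simulate_ranks

log = logging.getLogger("staterank")


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline output."""

    command: str
    config: dict
    seed: int
    version: str = __version__
    inputs: dict = field(default_factory=dict)   # path/label -> sha256
    outputs: list = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)

    def add_input(self, label: str, payload: bytes) -> None:
        self.inputs[label] = hashlib.sha256(payload).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _digest_table(table: EstimateTable) -> bytes:
    return table.to_frame().to_csv(index=False).encode()


def run_rank(
    table: EstimateTable | str | Path,
    config: SimulationConfig,
    out_dir: str | Path,
    name: str | None = None,
) -> tuple[RankTable, RunManifest]:
    """Rank one estimate table and write the rank table plus manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(table, EstimateTable):
        table = read_estimate_table(table)
    name = name or f"{table.survey or 'table'}_{table.behavior or 'ranks'}"

    manifest = RunManifest(command="rank", config=asdict(config), seed=config.seed)
    manifest.add_input(name, _digest_table(table))
    t0 = time.perf_counter()
    ranked = simulate_ranks(table, config)
    manifest.timings_s["simulate"] = round(time.perf_counter() - t0, 3)

    rank_path = out / f"{name}_ranks.csv"
    write_rank_table(ranked, rank_path)
    manifest.outputs.append(str(rank_path))
    manifest.write(out / f"{name}_manifest.json")
    manifest.outputs.append(str(out / f"{name}_manifest.json"))
    log.info("wrote %s (%d states, %d sims)", rank_path, table.n_states, config.n_sims)
    return ranked, manifest


_PAIRED_T_M = 3  # Bonferroni across the three behaviors


def run_published_analysis(out_dir: str | Path, config: SimulationConfig | None = None) -> RunManifest:
    """Reproduce the full analysis from the packaged fixtures.

    Writes six rank tables, figure-data files ordered by NSDUH median
    rank, cross-survey and within-survey consistency tables (within-survey
    both on all available states and restricted to the cross-survey
    shared set), three paired t-tests, and a manifest.
    """
    config = config or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command="published", config=asdict(config), seed=config.seed)

    tables: dict[tuple[str, str], EstimateTable] = {}
    ranked: dict[tuple[str, str], RankTable] = {}
    t0 = time.perf_counter()
    for survey in ("nsduh", "yrbss"):
        for behavior in BEHAVIORS:
            table = load_packaged_table(survey, behavior)
            tables[(survey, behavior)] = table
            manifest.add_input(f"{survey}_{behavior}", _digest_table(table))
            ranked[(survey, behavior)] = simulate_ranks(table, config)
            path = out / f"{survey}_{behavior}_ranks.csv"
            write_rank_table(ranked[(survey, behavior)], path)
            manifest.outputs.append(str(path))
    manifest.timings_s["rank_tables"] = round(time.perf_counter() - t0, 3)

    # figure data: per behavior, both surveys ordered by NSDUH median rank
    t0 = time.perf_counter()
    for behavior in BEHAVIORS:
        rows = []
        nsduh = ranked[("nsduh", behavior)]
        yrbss = ranked[("yrbss", behavior)]
        order = sorted(nsduh.summaries, key=lambda s: (s.median_rank, s.state))
        for s in order:
            rows.append((s.state, s.median_rank, s.ci_low, s.ci_high, "nsduh"))
        for s in order:
            try:
                y = yrbss[s.state]
            except KeyError:
                continue
            rows.append((y.state, y.median_rank, y.ci_low, y.ci_high, "yrbss"))
        frame = pd.DataFrame(rows, columns=["state", "median_rank", "ci_low", "ci_high", "survey"])
        path = out / f"figure_{behavior}.csv"
        frame.to_csv(path, index=False)
        manifest.outputs.append(str(path))
    manifest.timings_s["figure_data"] = round(time.perf_counter() - t0, 3)

    # consistency: cross-survey per behavior; within-survey cross-behavior
    t0 = time.perf_counter()
    labeled = {f"{s}_{b}": r for (s, b), r in ranked.items()}
    cross = [(f"nsduh_{b}", f"yrbss_{b}") for b in BEHAVIORS]
    within = [
        (f"{s}_cigarette", f"{s}_binge_alcohol") for s in ("nsduh", "yrbss")
    ] + [
        (f"{s}_cigarette", f"{s}_marijuana") for s in ("nsduh", "yrbss")
    ] + [
        (f"{s}_binge_alcohol", f"{s}_marijuana") for s in ("nsduh", "yrbss")
    ]
    results = consistency_matrix(labeled, cross + within)
    path = out / "consistency.csv"
    consistency_frame(results).to_csv(path, index=False)
    manifest.outputs.append(str(path))

    # within-survey correlations restricted to the cross-survey shared set
    shared = {f"nsduh_{b}": f"yrbss_{b}" for b in BEHAVIORS}
    results_shared = consistency_matrix(labeled, within, shared_states_with=shared)
    path = out / "consistency_shared_states.csv"
    consistency_frame(results_shared).to_csv(path, index=False)
    manifest.outputs.append(str(path))

    # paired t-tests: YRBSS minus NSDUH prevalence, Bonferroni m=3
    rows = []
    for behavior in BEHAVIORS:
        pair = align_states(tables[("nsduh", behavior)], tables[("yrbss", behavior)])
        res = paired_t(pair.x, pair.y, m_comparisons=_PAIRED_T_M)
        rows.append(
            (f"yrbss_vs_nsduh_{behavior}", pair.n_states, res.mean_diff,
             res.t_stat, res.p_raw, res.p_adjusted)
        )
    frame = pd.DataFrame(
        rows, columns=["comparison", "n_pairs", "mean_diff", "t", "p_raw", "p_adjusted"]
    )
    path = out / "paired_tests.csv"
    frame.to_csv(path, index=False)
    manifest.outputs.append(str(path))
    manifest.timings_s["consistency"] = round(time.perf_counter() - t0, 3)

    manifest.write(out / "manifest.json")
    manifest.outputs.append(str(out / "manifest.json"))
    for p in manifest.outputs:
        assert Path(p).exists()
    log.info("published-analysis run complete: %d outputs in %s", len(manifest.outputs), out)
    return manifest
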