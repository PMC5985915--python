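import warnings

import numpy as np
import pytest

from staterank import (
    EstimateTable,
    StateEstimate,
    SimulationConfig,
    ValidationError,
    draw_replicates,
    effective_sample_size,
    rank_replicates,
    simulate_ranks,
    simultaneous_adjust,
    summarize_ranks,
)
from staterank.rank_mc import CoverageWarning, RankMatrix


class TestSimulationConfig:
    def test_defaults_match_published_convention(self):
        cfg = SimulationConfig()
        assert cfg.n_sims == 100_000
        assert cfg.distribution == "normal"
        assert cfg.ci_level == 0.95
        assert cfg.mode == "individual"
        assert cfg.rank_direction == "descending"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sims": 0},
            {"distribution": "cauchy"},
            {"mode": "bonferroni"},
            {"ci_level": 1.0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SimulationConfig(**kwargs)

    def test_from_key_value_file(self, tmp_path):
        path = tmp_path / "config.yml"
        path.write_text("n_sims: 5000\ndistribution: lognormal\nseed: 7\n")
        cfg = SimulationConfig.from_file(path)
        assert (cfg.n_sims, cfg.distribution, cfg.seed) == (5000, "lognormal", 7)
        path.write_text("n_sims: 5000\nbogus: 1\n")
        with pytest.raises(ValidationError, match="bogus"):
            SimulationConfig.from_file(path)


class TestEffectiveSampleSize:
    def test_known_values(self):
        assert effective_sample_size(50.0, 5.0) == pytest.approx(100.0)
        assert effective_sample_size(20.0, 2.0) == pytest.approx(400.0)

    def test_boundary_prevalence_rejected(self):
        for p in (0.0, 100.0):
            with pytest.raises(ValidationError):
                effective_sample_size(p, 1.0)

    def test_binomial_draws_reproduce_the_input_se(self, tiny_table):
        cfg = SimulationConfig(n_sims=100_000, distribution="binomial", seed=11)
        reps = draw_replicates(tiny_table, cfg)
        np.testing.assert_allclose(reps.std(axis=0, ddof=1), tiny_table.ses, rtol=0.05)


class TestDrawReplicates:
    def test_fixed_seed_is_reproducible(self, tiny_table):
        cfg = SimulationConfig(n_sims=500, seed=3)
        np.testing.assert_array_equal(
            draw_replicates(tiny_table, cfg), draw_replicates(tiny_table, cfg)
        )

    @pytest.mark.parametrize("dist", ["normal", "truncated_normal", "binomial", "lognormal"])
    def test_zero_se_gives_constant_columns(self, degenerate_table, dist):
        cfg = SimulationConfig(n_sims=200, distribution=dist, seed=1)
        reps = draw_replicates(degenerate_table, cfg)
        np.testing.assert_array_equal(reps, np.tile(degenerate_table.prevalences, (200, 1)))

    def test_normal_moments_within_sampling_error(self):
        table = EstimateTable(
            entries=(
                StateEstimate(state="A", prevalence=10.0, se=1.0),
                StateEstimate(state="B", prevalence=50.0, se=2.0),
            )
        )
        cfg = SimulationConfig(n_sims=100_000, seed=5)
        reps = draw_replicates(table, cfg)
        # 4 sigma / sqrt(n) band on the mean; 2% on the SD
        assert abs(reps[:, 0].mean() - 10.0) < 4 * 1.0 / np.sqrt(cfg.n_sims)
        assert reps[:, 0].std(ddof=1) == pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("dist", ["truncated_normal", "binomial", "lognormal"])
    def test_alternative_laws_are_moment_matched(self, dist):
        # far from the [0, 100] boundary all three should match mean and SD
        table = EstimateTable(
            entries=(
                StateEstimate(state="A", prevalence=30.0, se=1.5),
                StateEstimate(state="B", prevalence=10.0, se=1.0),
            )
        )
        cfg = SimulationConfig(n_sims=100_000, distribution=dist, seed=6)
        reps = draw_replicates(table, cfg)
        np.testing.assert_allclose(reps.mean(axis=0), table.prevalences, rtol=0.01)
        np.testing.assert_allclose(reps.std(axis=0, ddof=1), table.ses, rtol=0.05)

    def test_binomial_boundary_prevalence_rejected(self):
        table = EstimateTable(
            entries=(
                StateEstimate(state="A", prevalence=0.0, se=1.0),
                StateEstimate(state="B", prevalence=10.0, se=1.0),
            )
        )
        with pytest.raises(ValidationError, match="boundary"):
            draw_replicates(table, SimulationConfig(n_sims=10, distribution="binomial"))


class TestRankReplicates:
    def test_single_row_forced_ordering(self):
        rm = rank_replicates(np.array([[10.0, 5.0, 1.0]]))
        np.testing.assert_array_equal(rm.ranks, [[1, 2, 3]])

    def test_ties_break_by_column_order(self):
        rm = rank_replicates(np.array([[5.0, 5.0, 7.0]]))
        np.testing.assert_array_equal(rm.ranks, [[2, 3, 1]])

    def test_rows_are_permutations(self, rng):
        x = rng.normal(size=(300, 8))
        ranks = rank_replicates(x).ranks
        expected = np.arange(1, 9)
        for row in np.sort(ranks, axis=1):
            np.testing.assert_array_equal(row, expected)

    def test_matches_pairwise_comparison_oracle(self, rng):
        x = rng.normal(size=(1000, 3))
        ranks = rank_replicates(x).ranks
        # rank_i = 1 + #{j: x_j > x_i}  (no ties under continuous draws)
        oracle = 1 + (x[:, None, :] > x[:, :, None]).sum(axis=2)
        np.testing.assert_array_equal(ranks, oracle)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            rank_replicates(np.array([[1.0, np.nan]]))


class TestSummarizeRanks:
    def test_zero_se_recovers_deterministic_ranks_with_degenerate_cis(self, degenerate_table):
        rt = simulate_ranks(degenerate_table, SimulationConfig(n_sims=2000, seed=1))
        expected = {"Alpha": 1, "Gamma": 2, "Beta": 3, "Delta": 4}
        for state, rank in expected.items():
            s = rt[state]
            assert (s.median_rank, s.ci_low, s.ci_high) == (rank, rank, rank)

    def test_rank_counts_sum_to_n_sims(self, tiny_table):
        cfg = SimulationConfig(n_sims=3000, seed=2)
        rt = simulate_ranks(tiny_table, cfg)
        for s in rt.summaries:
            assert s.rank_counts.sum() == cfg.n_sims

    def test_lower_median_is_integer_inside_ci(self, rng):
        table = EstimateTable(
            entries=tuple(
                StateEstimate(state=f"S{j}", prevalence=10.0 + 0.1 * j, se=2.0)
                for j in range(10)
            )
        )
        rt = simulate_ranks(table, SimulationConfig(n_sims=5000, seed=4))
        for s in rt.summaries:
            assert isinstance(s.median_rank, int)
            assert s.ci_low <= s.median_rank <= s.ci_high

    def test_warns_below_1000_sims(self, tiny_table):
        with pytest.warns(CoverageWarning):
            simulate_ranks(tiny_table, SimulationConfig(n_sims=100, seed=1))

    def test_empty_matrix_rejected(self):
        rm = RankMatrix(ranks=np.empty((0, 3), dtype=int), state_order=("a", "b", "c"))
        with pytest.raises(ValidationError, match="empty"):
            summarize_ranks(rm, SimulationConfig(n_sims=1000))

    def test_monotonicity_with_equal_ses(self):
        # larger point estimate => median rank no worse, at equal SEs
        prevs = [14.0, 12.5, 11.0, 9.5, 8.0, 6.5]
        table = EstimateTable(
            entries=tuple(
                StateEstimate(state=f"S{j}", prevalence=p, se=1.0)
                for j, p in enumerate(prevs)
            )
        )
        rt = simulate_ranks(table, SimulationConfig(n_sims=10_000, seed=8))
        medians = [rt[f"S{j}"].median_rank for j in range(len(prevs))]
        assert medians == sorted(medians)


class TestSimultaneousAdjust:
    def test_single_state_interval_is_degenerate(self):
        rm = RankMatrix(ranks=np.ones((2000, 1), dtype=int), state_order=("only",))
        lo, hi = simultaneous_adjust(rm, 0.95)
        assert (lo[0], hi[0]) == (1, 1)

    def test_superset_of_individual_intervals(self):
        table = EstimateTable(
            entries=tuple(
                StateEstimate(state=f"S{j:02d}", prevalence=8.0 + 0.3 * j, se=1.0)
                for j in range(20)
            )
        )
        cfg = SimulationConfig(n_sims=20_000, seed=9)
        reps = draw_replicates(table, cfg)
        rm = RankMatrix(ranks=rank_replicates(reps).ranks, state_order=table.states)
        lo, hi = simultaneous_adjust(rm, 0.95)
        individual = summarize_ranks(rm, cfg, estimates=table)
        for j, s in enumerate(individual.summaries):
            assert lo[j] <= s.ci_low
            assert hi[j] >= s.ci_high
        # and the calibration target is met on the simulation rows
        joint = np.mean(((rm.ranks >= lo) & (rm.ranks <= hi)).all(axis=1))
        assert joint >= 0.95

    def test_well_separated_states_need_no_adjustment(self, tiny_table):
        # gaps of 10 percentage points vs SE 0.5: both modes are degenerate
        for mode in ("individual", "simultaneous"):
            cfg = SimulationConfig(n_sims=5000, seed=10, mode=mode)
            rt = simulate_ranks(tiny_table, cfg)
            for rank, state in enumerate(("Alpha", "Beta", "Gamma"), start=1):
                s = rt[state]
                assert (s.median_rank, s.ci_low, s.ci_high) == (rank, rank, rank)
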