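# staterank

**Monte Carlo rank uncertainty for state-level survey prevalence estimates.**

League tables that rank states (or hospitals, counties, schools) on a
survey-estimated indicator routinely present the ranks as if they were
exact. They are not: each underlying estimate carries sampling error, and
rank is a highly unstable function of many noisy estimates. `staterank`
quantifies that instability for state rankings of adolescent substance-use
prevalence (past-month cigarette smoking, binge alcohol drinking, and
marijuana use, from the NSDUH in-home survey and the YRBSS school survey,
2011–2015), and is reusable for any table of unit-level estimates with
standard errors.

## The method

Given estimates p̂₁…p̂ₖ (percent) with standard errors SE₁…SEₖ, the engine
draws `n_sims` (default 100,000) joint replicates

    p*ᵢⱼ ~ N(p̂ⱼ, SEⱼ²)   independently across states j,

ranks every replicate row (rank 1 = highest prevalence; truncated-normal,
binomial and lognormal sampling laws are available as robustness checks),
and summarizes each state's simulated rank distribution by its **lower
median rank** and a **95% rank CI** from the 2.5th/97.5th order statistics.
A *simultaneous* mode widens all intervals jointly until ≥95% of simulation
rows have every state inside its interval at once. Around the engine sit:

- **Design-based estimation** — weighted prevalence with Taylor-series
  linearization SEs from stratified, clustered, weighted microdata
  (with-replacement first-stage approximation);
- **Consistency analysis** — Spearman rank correlations (midrank ties,
  t-approximation p-values) across surveys and behaviors, and paired
  t-tests with Bonferroni adjustment;
- **Synthetic data** — generators for estimate tables and cluster
  microdata with known truth, used for coverage and recovery experiments.

The six published state tables ship as packaged fixtures
(`load_packaged_table("nsduh", "cigarette")`, …), including the published
median ranks (`load_published_ranks`).

## Worked example

```python
from staterank import SimulationConfig, load_packaged_table, simulate_ranks

table = load_packaged_table("nsduh", "cigarette")          # 51 states
ranked = simulate_ranks(table, SimulationConfig(n_sims=100_000, seed=1))
for state in ("Wyoming", "Georgia", "Utah"):
    s = ranked[state]
    print(state, s.median_rank, (s.ci_low, s.ci_high))
```

prints

```
Wyoming 1 (1, 7)
Georgia 26 (11, 41)
Utah 51 (47, 51)
```

Wyoming has the highest estimated adolescent smoking prevalence (14.3%)
and is securely in the top handful of ranks; Utah (4.5%) is securely last.
Georgia's point rank of 26 is close to meaningless — its 95% CI spans
thirty ranks — which is exactly why league tables need error bars.
Each `examples/*.py` script is a self-contained narrative like this
(ranking the published tables, cross-survey consistency, microdata
estimation, and a CI-coverage experiment).

The command line mirrors the library:

```bash
staterank rank --fixture nsduh_cigarette --n-sims 100000 --seed 1 --out-dir out/
staterank published --out-dir out/   # full six-table analysis + consistency
```

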