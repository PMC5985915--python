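"""Design-based estimation from stratified-cluster survey microdata.

Generates synthetic weighted microdata for five states with known true
prevalences (a stratified two-stage cluster design with intra-cluster
correlation 0.05), estimates each state's prevalence with its
Taylor-linearization SE, and ranks the states with the Monte Carlo
engine. The printed table shows estimate +/- SE against the truth.
"""

from staterank import (
    SimulationConfig,
    estimate_table_from_microdata,
    generate_microdata,
    simulate_ranks,
)

truth_prevalences = [6.0, 9.0, 12.0, 15.0, 18.0]
data, truth = generate_microdata(
    n_states=5, strata_per_state=15, psus_per_stratum=2, respondents_per_psu=40,
    true_prevalence=truth_prevalences, icc=0.05, weight_cv=0.5, seed=11,
)
table = estimate_table_from_microdata(data, survey="synthetic", behavior="synthetic")
ranked = simulate_ranks(table, SimulationConfig(n_sims=10_000, seed=1))

print(f"{'state':<6}{'truth %':>8}{'estimate %':>12}{'SE %':>7}  median rank (95% CI)")
for entry, true_p in zip(table.entries, truth.true_prevalence):
    s = ranked[entry.state]
    print(
        f"{entry.state:<6}{true_p:>8.1f}{entry.prevalence:>12.2f}{entry.se:>7.2f}  "
        f"{s.median_rank} ({s.ci_low}, {s.ci_high})"
    )
print(
    "\nEstimates sit within a couple of SEs of truth; with only five states\n"
    "and well-separated prevalences the rank CIs are narrow."
)
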