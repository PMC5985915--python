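# Methods

## Model and procedure

The package treats a table of state-level prevalence estimates p̂ⱼ (percent)
with standard errors SEⱼ as the sufficient summary of each state's survey
sample. Estimates are independent across states (each state is sampled
separately; no covariance is published or modeled). Rank uncertainty is
propagated by parametric simulation: draw a joint replicate of all states,
rank it descending (rank 1 = highest prevalence), repeat `n_sims` times,
and read rank point estimates and intervals off the per-state rank
distributions.

Sampling laws, all located at p̂ⱼ with spread SEⱼ:

- **normal** (default): N(p̂ⱼ, SEⱼ²). The working assumption for the
  published tables.
- **truncated normal**: the same law truncated to [0, 100], drawn by
  inverse CDF; relevant when p̂ is within a few SEs of a boundary.
- **binomial**: 100·X/ñⱼ with X ~ Bin(ñⱼ, p̂ⱼ/100) and
  ñⱼ = round(p(1−p)/SE²) on the proportion scale, floored at 1 — the
  effective sample size whose simple-random-sampling SE matches the
  reported SE. Undefined at p̂ ∈ {0, 100} with SE > 0 (hard error).
- **lognormal**: parameters solved so the draw's mean is p̂ⱼ and SD SEⱼ
  (σ² = ln(1 + SE²/p̂²), μ = ln p̂ − σ²/2). Requires p̂ > 0.

States with SE = 0 produce constant columns under every law; zero SEs are
admitted only for synthetic/degenerate inputs, never by the table readers.

**Ranking.** Within a replicate row, rank 1 goes to the largest value;
exact ties (possible only under the binomial law, which lives on a grid)
break by input column order via a stable sort. Every row is therefore a
permutation of 1..k. The direction is fixed, not configurable: every
published table ranks highest prevalence first.

**Summaries.** The reported rank is the **lower median** — the
⌈n/2⌉-th order statistic of the state's simulated ranks. It is always an
integer actually attained in the simulation and always lies inside the CI,
which is why it is reported instead of the raw point-estimate rank.
Individual 95% CIs are the ⌈0.025n⌉-th and ⌈0.975n⌉-th order statistics;
no interpolation is used anywhere, because interpolated non-integer ranks
would be artifacts.

**Simultaneous intervals.** Individual intervals cover each state's rank
marginally; simultaneous mode asks for joint coverage. The per-state tail
probability γ is shrunk from the nominal 0.05 over a 201-point grid until
the product set of per-state order-statistic intervals
[Qⱼ(γ/2), Qⱼ(1−γ/2)] contains *all* states' ranks in ≥95% of simulation
rows. Joint row coverage is monotone in γ, so the grid is bisected
(identical result to a linear scan, ~8 coverage evaluations). The output
is a superset of the individual intervals by construction; γ = 0 (the
observed min/max per state) always attains full row coverage, so the
fallback full-range-with-warning branch is unreachable in practice.
"Joint coverage" here is defined on simulation rows — the quantity the
calibration controls; coverage of *true* ranks is an empirical property
checked separately on synthetic worlds.

## Design-based estimation

For microdata rows (state, stratum, PSU, weight w, binary outcome y), the
prevalence is the ratio estimator p = Σwy/Σw, and its variance is the
Taylor-linearization / with-replacement form: linearized residuals
zᵢ = wᵢ(yᵢ − p)/W are summed to PSU totals within strata, and
Var(p) = Σₕ nₕ/(nₕ−1) Σ_c (z_hc − z̄ₕ)². No finite-population correction is
applied (standard for public-use analyses of the national surveillance
surveys this emulates, which are drawn with small sampling fractions).
Strata are nested within state and each state is estimated independently —
the pipeline ranks direct estimates, with no pooling or small-area
smoothing. A stratum with a single PSU is a hard error: silently centering
it at the grand mean (a common software fallback) would mask generator
bugs, and the synthetic designs always provide ≥2 PSUs. In the
single-stratum, one-respondent-per-PSU, equal-weight limit the formula
reduces exactly to p(1−p)/(n−1), the closed-form binomial variance with
the with-replacement df correction — one of the test oracles; the other is
a delete-one-PSU stratified jackknife.

## Consistency analysis

Spearman rank correlation uses midranks (average rank across ties) and the
two-sided t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df. Midranks matter:
published median-rank columns contain many ties (three states share rank 6
in the cigarette table), where the classical 1 − 6Σd²/(n(n²−1)) formula is
invalid; on tie-free data the two agree exactly (tested exhaustively to
n = 6). Implementation is `scipy.stats.spearmanr`, which computes exactly
this; the classical formula lives in the tests as the independent oracle.
Paired t-tests compare the two surveys' prevalence vectors state by state,
with Bonferroni m = 3 by default (three behaviors per survey comparison).
Degenerate difference vectors are resolved explicitly: identically zero →
t = 0, p = 1; constant nonzero → p = 0.

Cross-survey correlations use the states present in both surveys (47; 46
for marijuana). Within-survey cross-behavior correlations default to **all
states available in that survey**: recomputing both variants against the
published correlation values shows the full-set values match them
(e.g. 0.243 vs the published 0.24 on 51 states, against 0.256 for the
shared 47-state set), so that is the default, with
`shared_states_with` available to restrict.

## Synthetic data

`generate_estimate_table` draws true prevalences **uniformly** over a
configurable range (default 4.5–14.3%, SEs 0.4–1.4% — the marginal
structure of the published cigarette table). Uniform truth is deliberate:
coverage of the rank CIs should not be certified only under the engine's
own normal sampling assumption. Observed estimates add truncated-normal
noise at the state's SE. True ranks break ties alphabetically, matching
the rank-table writer.

`generate_microdata` builds a stratified two-stage cluster design with
PSU-level random intercepts on the logit scale, σ² = ICC·(π²/3)/(1−ICC) —
the latent-threshold calibration, which keeps probabilities in range at
any clustering strength. Weights are lognormal with a requested
coefficient of variation, normalized to mean 1 within state. The marginal
prevalence under logit-normal mixing differs slightly from the nominal
value (Jensen's inequality); recovery tests therefore compare estimates to
truth through the estimated SEs rather than asserting exact unbiasedness.

`make_two_survey_world` assembles two surveys × three behaviors with a
Gaussian-copula cross-survey correlation on the true prevalences, survey B
shifted to higher ranges and missing four states — an end-to-end rehearsal
of the published design (51 vs 47 states). What these generators do *not*
emulate: real sampling frames, nonresponse and post-stratification
weighting, school- vs household-mode effects, or reporting bias. Passing
tests certify the statistical machinery, not the surveys' data quality.

## Numerical and design choices

- One `numpy` Generator seeded once per run drives the whole replicate
  matrix; identical seeds give byte-identical outputs.
- Default CI mode is **individual** percentile intervals. The published
  analysis calls its intervals simultaneous but cites an external method
  without parameters; the extreme-rank results reproduce under both modes
  (extremes are where the modes agree), so the simpler mode is the
  default and the choice is surfaced as a flag rather than hidden.
- Rank-table output is sorted by median rank with alphabetical
  tie-breaks; fixtures store values exactly as printed (one decimal), with
  no attempt to reconstruct unrounded estimates.
- A known consequence of printed rounding: the median of the rounded
  NSDUH cigarette prevalence column is 9.2%, while the publication
  reports 9.3% — the original analysis used unrounded estimates. Column
  medians are therefore documented, not reproduction targets.
- The published figure listing and results text disagree on Wyoming's
  upper cigarette CI bound (7 vs 8); at 100,000 draws this engine gets 7
  for most seeds, and no test pins that endpoint.

## Problem sizes in tests

The acceptance-grade checks run the published tables at the full 100,000
simulations. Method-property experiments use smaller, adequate sizes
chosen for stable statistics: coverage uses 200 worlds × 2,000 simulations
(order-statistic CIs at 2,000 draws are accurate to ±1 rank);
recovery/null-calibration worlds use 1,000 simulations; microdata checks
use designs with ≥20 variance degrees of freedom (and ~75 for the 3·SE
recovery bound, where the SE estimate's own noise would otherwise widen
the effective tail probability).

## Limitations

Independence across states is assumed, as in the source analysis; shared
survey-design effects would induce rank correlations this engine cannot
see. The binomial effective-sample-size rounding makes that law slightly
coarse for very small SEs. P-values for Spearman are asymptotic (n ≈ 50);
exact permutation p-values are out of scope. Sex-stratified published
estimates are not included (they were never printed), though the
consistency operations accept any pair of rank tables, so subgroup
analyses run unchanged on user-supplied data.
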