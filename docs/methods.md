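# Methods

This note records the statistical model behind `mdisw`, the choices made
where the methodology left room, and what the simulation-based checks do and
do not demonstrate.

## The design problem

A standards-based audit (S-BA) is a three-month quality-improvement cycle for
one care standard at one health facility: assess compliance for a sample of
clients (control month), review findings and act (transition month, no data),
re-assess (intervention month).  Run in a single facility this is an
uncontrolled before-after comparison, confounded with secular trend.  The
multi-dimensional incomplete stepped-wedge cluster-randomised trial
(M-DISW-CRT) embeds many such cycles, for several standards, across many
facilities, with randomised timing, so that the effect of introducing the
audit process can be estimated free of secular-trend confounding.  Each
standard traces its own incomplete stepped-wedge pattern within the same set
of facilities — hence *multi-dimensional* — and most facility-month-standard
cells collect no data — hence *incomplete*.

Two variants are implemented.

**Variant A** — each facility audits two self-selected standards in
consecutive non-overlapping three-month phases.  Facilities are randomised
to three start-month strata (months 1, 2, 3); without this staggering the
step would be perfectly confounded with the intervention, and
`gls_effect_variance` raises an explicit error for such designs.  Baseline
and endline months add one extra assessment each (the second standard at
control in the first month, the first standard at intervention in the last),
so every audited standard has exactly three collection months, each facility
completes six collection events in a six-month window, and the trial spans
eight months.

**Variant B** — each of 18 facilities audits all six standards in
overlapping phases (the intervention month of one cycle is the control month
of the next), in an order given by a row of a Latin square, with two
start-month strata.  A baseline month assesses all six standards at control
before the first cycle; the endline month re-assesses every standard at
intervention.  Standards audited in phases 1–5 therefore have four
collection months, the final-phase standard three, and a facility completes
23 collection events.

### Month indexing

Months are abstract 1-based integers.  For variant B the baseline month of a
stratum-s facility is month s, so phases occupy months s+1..s+3, …,
s+11..s+13 and the two-stratum trial spans months 1–15.  Because the
analysis treats month as categorical, the labels are arbitrary; fixing
baseline = stratum keeps all months positive and makes the stratum-2
schedule an exact +1 shift of stratum 1.

### Randomisation

*Phase-order balance (variant A).*  Facilities choose their pair of
standards; randomisation decides which member of the pair is audited first.
For each pair {x, y} with c facilities, k audit x first.  The split vector
minimises the maximum over standards of |phase-1 total − phase-2 total|.
The optimiser is an exact branch-and-bound (iterative deepening on the
bound, with per-standard pruning), with a three-stage tie-break: smallest
sorted imbalance vector, then most even per-pair splits (so pairs chosen by
six or more facilities can occupy all six of their sequences), then a seeded
uniform draw.  A concrete objective had to be fixed to make "balance is
optimised" testable; the min-max objective with these tie-breaks reproduces
the published 40-facility worked example exactly (margins 14/11/8/7 by
14/10/9/7, maximum imbalance 1).

*Latin squares (variant B).*  "Completely balanced" is implemented as
row-complete (Williams) squares: every standard once per row and column and
every ordered pair of distinct standards horizontally adjacent exactly once,
which neutralises first-order carry-over between consecutively audited
standards.  Squares are generated from the Williams base square of order 6
(first row 1, 2, 6, 3, 5, 4; subsequent rows +1 cyclically) under seeded
random symbol relabelling and row permutation, both of which preserve the
Latin and row-complete properties.  Three squares cover 18 facilities: one
whole square per stratum, the third split 3/3 at random, which guarantees
every standard is audited once or twice per phase in each stratum and
exactly three times per phase overall (verified over 100 seeds).

## Power

Power uses the cluster-period-mean GLS formulation classical for
stepped-wedge designs (Hussey–Hughes, extended to incomplete layouts).  Each
facility × standard pseudo-cluster contributes one row per collection month;
fixed effects are intercept, month indicators and the treatment indicator;
the variance of the treatment estimator is the treatment entry of
(X′V⁻¹X)⁻¹.  Treating standards within a facility as distinct clusters is
the same expansion used for sample-size work with standard stepped-wedge
software: F facilities × C cycles spread over S sequences gives F·C/S
clusters per sequence (9 = 18×6/12 for variant B).  This ignores the fixed
standard effect assumed at analysis but accounts for the differing baseline
compliance between standards better than inflating replication counts.

The within-cluster covariance supports discrete-time decay: cluster-period
means have variance σ²(1+(m−1)ρ)/m and covariance σ²ρr^{|j−k|} for months j,
k, with ρ the within-period ICC and r the cluster autocorrelation; r = 1 is
the exchangeable structure.  The equivalence of this cluster-period
formulation with full client-level GLS is exact and is property-tested to
1e-8 on randomised small designs.

Numerical choices:

* Binary outcomes are approximated on the proportion scale with working
  variance σ² = [p₀(1−p₀) + p₁(1−p₁)]/2 (symmetric between arms, nearly
  flat around p = 0.5).  `control` (p₀(1−p₀)) and `pooled` conventions are
  selectable.
* Power = Φ(|δ|/se − z₀.₉₇₅), a normal rather than t approximation; with the
  recommended minimum of 18 clusters the difference is small.
* `detectable_difference` inverts the power function by Brent root-finding
  on (0, 1−p₀) to 1e-6.
* Month effects use reference coding; the treatment variance is invariant to
  the coding.  Estimability is checked through the Schur complement of the
  treatment entry in the information matrix (relative threshold 1e-10).
* When F·C does not divide S, the remainder is spread one per sequence in
  seeded random order.

ρ and r have no empirical estimates for this design; power should be
reported over a plausible grid.  Defaults (ρ = 0.05, r = 0.8 in examples)
are illustrative.

## Simulation

`simulate_trial` draws client-level outcomes from the same model family the
analysis assumes:

logit p = μ + month_effect + standard_effect + θ·x + λ·lag·x + u_f + w_{f,t} + b_{f,s}

with u (facility), w (facility × month) and b (facility × standard)
independent centred normals, and m independent Bernoulli clients per
collection event (cross-sectional sampling; clients are never followed, and
standards collected in the same month are sampled independently since
compliance attaches to the care process, not the client).  Using the
analysis model as generator makes parameter recovery the natural correctness
check.  `w` is i.i.d. across months by default; an optional AR(1) decay
(`w_decay`) matches the discrete-time-decay correlation of the power module.
The lag covariate (months since the cycle's closing assessment, 0 at that
assessment) lets effect attenuation be generated and estimated; the
reference analysis assumes no attenuation.

Default SDs (σ_u = 0.3, σ_w = 0.2) are illustrative magnitudes for
moderately heterogeneous facilities — no variance-component estimates exist
for real M-DISW-CRT trials — and every simulation study in the tests states
its parameters explicitly.

`simulate_marginal_trial` generates instead from the proportion-scale model
that the power calculation assumes (Gaussian pseudo-cluster effects with
exactly the σ²ρr^{|Δ|} covariance, probabilities clipped to [0, 1]); it
exists so the Monte-Carlo check of analytic power is a like-for-like
comparison.  Clipping is negligible for moderate ICC (ρσ² ≈ 0.012 at
ρ = 0.05, p ≈ 0.5).

What these generators do not emulate: client covariates, varying cluster
sizes, missing data/dropout, order effects beyond the lag term, and any
facility behaviour change triggered by seeing baseline data.  Passing tests
demonstrate internal consistency of design, power and analysis under the
stated model — not robustness to those real-world features.

## Estimation

The reference analysis is a logistic GLMM on cluster-period binomial counts:
fixed intercept, month, standard and intervention; random facility intercept
and facility × month interaction.  Aggregating clients to counts is
likelihood-equivalent for this model since covariates are constant within a
cell.

No maximum-likelihood fitter for binomial GLMMs with these crossed/nested
random terms is available in the scientific Python stack, so the package
implements penalised quasi-likelihood (Breslow–Clayton): iterate a working
linear mixed model on the adjusted dependent variate, with variance
components re-estimated by REML at each step.  All random terms are indexed
within facility, so the working covariance is block-diagonal by facility and
each REML evaluation costs only small per-facility Cholesky factorisations;
variance components are optimised on the log scale by L-BFGS-B.  PQL's
well-known small-denominator bias is immaterial here because every
cluster-period is a binomial with m = 25 by design; agreement with an
independent Laplace fit (lme4::glmer on identical aggregated data) is tested
at |Δθ| < 0.05 and 10% relative on the SE.  Operating characteristics under
the generative model (type-I error ≈ 5%, bias < 0.01 on log-OR scale, CI
coverage ≈ 95–96%) are verified by simulation in the acceptance tests.

Additional choices:

* Wald (z) 95% CIs on the log-odds scale, matching the OR-with-CI reporting
  convention; no small-sample df correction (Kenward–Roger etc. are out of
  scope).
* Reference-level coding, earliest month / lexicographically first standard
  as reference; redundant columns (e.g. empty month × standard cells) are
  dropped by a QR screen that protects the intercept and intervention
  columns, and confounding of the intervention term is a hard error, never a
  silent drop.
* A fit is declared non-convergent when the PQL iterations fail to
  stabilise, the REML criterion is non-finite, or an interior variance
  component shows no curvature (profile flat ⇒ unidentified).  Variance
  components shrunk to the zero boundary are legitimate fits, not failures.
* Fallback ladder on non-convergence, each step recorded in
  `fallback_applied`: (1) drop the facility × month random term; (2) for
  specifications with a facility × standard random term, drop the month
  fixed effect and the facility random intercept; (3) report failure with
  NaN estimates rather than a silently altered model.  Under the simulated
  study conditions in the tests the sensitivity fits converge without
  fallback — the ladder exists for sparser data, and its ordering is tested
  directly.
* Per-standard fits are available as a secondary analysis only and emit a
  warning: single-standard data are sparse and design-imbalance-prone.

`gls_wald` provides the separate Gaussian GLS route on cluster-period
proportions with known correlation parameters; it exists to cross-check the
power module and is not the reference analysis.

## Problem sizes used in the checks

The test-suite simulations use the reference study conditions: 18 facilities
for variant B (40 for the bias/coverage study, approximating a larger
multi-country trial), 40 facilities for variant A, m = 25 clients per
collection event, 2000 replicates for the power-calibration check, 500 for
type-I error and 200 for bias/coverage.  `scripts/acceptance.py` re-runs the
same pipeline at 400/200/100 replicates, sizes chosen to keep Monte-Carlo
error well inside the tolerances being checked.

## Known limitations

* PQL is an approximation; with small cluster-period denominators (m ≪ 10)
  its bias would matter and a Laplace/AGQ fitter should be preferred.
* The power module assumes a common m across all cluster-periods, per the
  fixed 25-clients-per-month sampling rule; unequal cluster sizes are not
  supported.
* Order effects between standards are controlled by design (row-complete
  squares) but not modelled in the analysis.
* The detectable-difference figure for a single facility is reported by the
  tooling only as an order-of-magnitude cross-check against the closed-form
  two-proportion calculation; a single facility cannot support the full
  month-adjusted model.
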