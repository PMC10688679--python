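# mdisw

Design, power, simulation and analysis for **multi-dimensional incomplete
stepped-wedge cluster-randomised trials (M-DISW-CRT)** of standards-based
clinical audit.

## The problem

A standards-based audit (S-BA) is a low-cost quality-improvement cycle for a
care standard at a health facility: assess compliance with the standard for
a sample of clients, act on the deficiencies found, re-assess.  On its own
it is an uncontrolled before-after comparison.  The M-DISW-CRT embeds many
audit cycles — several standards per facility, many facilities, randomised
timing — so that the benefit of introducing the audit *process* can be
estimated while adjusting for secular trend.  Each standard traces its own
incomplete stepped-wedge pattern (most facility-month-standard cells collect
no data), and every facility ends in the intervention state for the
standards it audits.

The package is aimed at trial statisticians planning or analysing such
trials: it builds and validates the schedules, randomises the allocation,
computes analytic power, simulates client-level compliance data, and
estimates the intervention odds ratio.

Two variants are supported:

* **A** — each facility audits 2 self-chosen standards in consecutive
  non-overlapping 3-month phases, with 3 start-month strata (needed to break
  the step/intervention confounding); 6 collection events per facility in a
  6-month window, 8-month trial.
* **B** — each facility audits all 6 standards in overlapping phases ordered
  by rows of row-complete (Williams) Latin squares, with 2 strata, plus
  baseline and endline assessment months; 23 collection events per facility.

## The statistics

*Power.*  Cluster-period-mean GLS in the Hussey–Hughes tradition: with
fixed month effects and treatment indicator, Var(θ̂) is the treatment entry
of (X′V⁻¹X)⁻¹, where each facility × standard pseudo-cluster contributes a
block with Cov(ȳⱼ, ȳₖ) = σ²ρr^{|j−k|} and Var(ȳⱼ) = σ²[1+(m−1)ρ]/m — ρ the
within-period ICC, r the cluster autocorrelation (r = 1 ⇒ exchangeable).
Power = Φ(|δ|/se − z₀.₉₇₅) for a difference in proportions δ at baseline
compliance p₀.

*Analysis.*  Logistic GLMM on the client-level outcome (aggregated to
binomial counts): logit p = μ + monthₜ + standardₛ + θ·x with random
facility intercepts and facility × month effects; θ is reported as an odds
ratio with a Wald 95% CI.  Fitting is penalised quasi-likelihood with REML
variance components (cross-checked against `lme4::glmer`); sensitivity
models add intervention × standard, month × standard, a lag covariate, or a
facility × standard random term, with a documented fallback ladder on
non-convergence.

See `docs/methods.md` for assumptions, parameter conventions and
limitations.

## Worked example

```python
import numpy as np
from mdisw import (
    CorrelationModel, GenerativeParams, PowerSpec,
    assign_rows_B, build_schedule_B, complete_latin_squares,
    design_matrix, fit_primary, power, pseudo_cluster_expansion,
    simulate_trial,
)

standards = ["Sa", "Sb", "Sc", "Sd", "Se", "Sf"]
squares = complete_latin_squares(standards, 3, seed=1)
rows = assign_rows_B(squares, [f"f{i:02d}" for i in range(18)], seed=1)
schedules = build_schedule_B(rows)

dm = design_matrix(schedules, "Sa")
dm.clusters_per_sequence = pseudo_cluster_expansion(18, 6, 12)
spec = PowerSpec(design=dm, m=25, p0=0.5, delta=0.1,
                 corr=CorrelationModel(icc=0.05, cac=0.8))
print(f"sequences: {dm.n_sequences}, power: {power(spec).power:.4f}")

params = GenerativeParams(mu=0.0, theta=np.log(2), sigma_u=0.3, sigma_w=0.2)
records = simulate_trial(schedules, params, seed=5)
fit = fit_primary(records)
print(f"records: {len(records)}, OR = {fit.or_hat:.2f} "
      f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f})")
```

Output:

```
sequences: 12, power: 0.9998
records: 10350, OR = 2.00 (95% CI 1.77-2.25)
```

The 18-facility, 6-standard trial yields 12 sequences of 9 pseudo-clusters
each; a 10-percentage-point improvement from 50% baseline compliance is
detected with near-certain power at ρ = 0.05, r = 0.8.  The simulated trial
(10,350 client records, true odds ratio 2) is analysed with the reference
GLMM; the estimate 2.00 with CI (1.77, 2.25) recovers the generating effect.

The same workflow is scriptable from the shell:

```bash
mdisw run --config config.yaml --seed 3 --out results/
```

which writes schedules, the allocation, a power report, simulated records, a
fit and a reproducibility manifest (`mdisw design|power|simulate|analyze`
run the stages individually).

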