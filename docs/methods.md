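# Methods

This note records the statistical conventions, the synthetic-data design
and the numerical choices behind `ftdnorm`, in the order the pipeline runs.

## Normative model and w-scores

Per (ROI, modality) an OLS regression of the control measure on age (years),
sex (female = 0, male = 1), TIV (mm³) and scanner type is fitted with
statsmodels. Scanner type enters as a 5-level factor (the five 3T systems a
multi-site study of this kind uses: Siemens Trio/Skyra/Prisma, Philips
Achieva, GE Discovery MR750); the reference level is the most frequent
category among controls, ties broken lexicographically. An alternative
3-level manufacturer coding can be achieved by recoding the scanner column
upstream; the model itself is agnostic to the label set.

The residual SD uses the regression convention σ² = RSS/(n − p) by default;
`sigma_df="n-1"` switches to RSS/(n − 1) since the convention is a genuine
ambiguity in this literature. At n = 240 and p = 8 the two differ by 1.5%.
A model whose residual SD is numerically zero (relative floor 1e-10 of the
mean absolute value) is flagged degenerate and never scores; ROIs with no
usable control values are skipped and logged. Missing data are handled
complete-case per ROI, with counts logged — no imputation.

w-scores are (observed − predicted)/σ. Because the intercept is included,
in-sample control w-scores have mean exactly 0 (to ~1e-11 with double
precision) and SD √((n−p)/(n−1)) ≈ 0.985 at n = 240. w-scores are invariant
(to ~1e-9) under unit changes of the raw measure and under constant shifts
of a covariate; both invariances are tested. Scoring a participant whose
scanner category was absent from the control fit raises an error rather
than silently falling back to the reference level.

Percentile conversion is exact: percentile = 100·Φ(w), cut point =
Φ⁻¹(p). The conventional cut constants −1.960/−1.645/−1.282/−0.675 are the
3-decimal roundings of the corresponding normal quantiles.

## Abnormality calls and group maps

The default cut is the control 10th percentile (|w| = 1.282), configurable
in (0, 50). Direction is modality-aware: volumes and FA flag the lower
tail, MD the upper tail. A w-score exactly at the cut is *normal* — the
rule is strictly beyond the cut.

Group maps report, per (gene × stage, ROI, modality): n, mean w, a seeded
percentile bootstrap 95% CI of the mean (B = 1000 resamples; lo/hi are the
2.5th/97.5th percentiles of the replicate means), a two-sided one-sample
t-test against 0, and a percentile band. The band uses the disease-tail
probability of the mean w at thresholds {0.025, 0.05, 0.10, 0.25}; it is
one-sided because the map colours only the abnormal direction. Significance
is flagged when the bootstrap CI excludes 0 (primary criterion); the
t-test p-value is reported alongside because both rules are defensible and
users can apply either. No multiple-testing correction is applied across
ROIs by default; `fdr=True` adds Benjamini–Hochberg q-values.

## Exact Wilcoxon signed-rank test

Zero differences are dropped before ranking (classical exact-test
convention); `n_used` is reported so the choice is auditable. Ties in |Δ|
receive midranks. For n ≤ 20 the p-value is exact: the null distribution of
the positive-rank sum W⁺ is built over all 2ⁿ sign assignments of the
observed rank vector — implemented as an iterative convolution over the
doubled (hence integer, even with midranks) ranks, which is mathematically
identical to enumerating the 2ⁿ assignments but runs in O(n·Σr). The
two-sided p doubles the smaller of P(W⁺ ≥ w) and P(W⁺ ≤ w), capped at 1.
Beyond n = 20 (cutoff configurable) a tie-corrected normal approximation
without continuity correction is used. The exact path is verified against
a brute-force 2ⁿ enumeration oracle (ties and zeros included) and against
scipy's exact method on untied data.

The smallest attainable two-sided exact p with n untied pairs is 2/2ⁿ:
0.0625 at n = 5, 0.03125 at n = 6. Hence the progression rules: strata
with fewer than 3 pairs are excluded from testing entirely, and
non-significant results with 3–5 pairs are flagged `caution_lt6` because
significance is unattainable there by construction.

## Staging and stratification

Stage derives from the CDR®+NACC-FTLD global score: 0/0.5 presymptomatic,
1–3 fully symptomatic; any other value is a validation error. Progression
strata are restricted to presymptomatic carriers of the requested gene —
staging is recomputed from the clinical score at analysis time, so a
symptomatic carrier can never enter a stratum even if a cohort label says
otherwise. Visits are matched by label (baseline/month12), not by date
arithmetic; a real 12-month window rule would be applied upstream.

## Synthetic cohort generator

The generator exists so every stage is testable end-to-end. Its defaults
encode the cohort structure of the study population it emulates: 240
controls (age 44.8 ± 12.2 y, 42.9% male) and carrier groups *C9orf72*
113/47, *MAPT* 52/15, *GRN* 130/30 (presymptomatic/symptomatic) with their
published age and sex distributions. TIV is N(1,450,000, 130,000²) mm³ —
a field-plausible head-size distribution, shared across groups. Scanners
are i.i.d. categorical over the five types (probabilities 0.25/0.20/0.20/
0.20/0.15) with small nonzero additive offsets (±0.1–0.2 σ) so the scanner
adjustment is genuinely exercised.

Control measures follow the same linear model the normative fit assumes:
plausible per-structure volume intercepts (e.g. hippocampus 7,400 mm³,
thalamus 14,500 mm³), ageing slopes of ~0.3%/year for volumes, FA
intercept 0.48 (σ = 0.025), MD intercept 7.8e-4 mm²/s (σ = 3e-5). Carrier
abnormality is injected as `effect · σ_ROI` added to the control-model
mean, so the population mean w-score of a generated group equals the
configured effect by construction — the basis of the parameter-recovery
tests. Values are clamped to physical ranges (volumes ≥ 0, FA ∈ [0, 1],
MD > 0) with a logged warning; at the default parameters clamping never
triggers.

Follow-up clinical scores move by an additive Gaussian change whose mean
and SD depend on (gene, scale, baseline abnormality status), floored at 0
(CBI-R also capped at 180); availability of the month-12 visit is
Bernoulli (default 0.8). The default change magnitudes (+2 to +3 CDR-SB
points and +8 to +11 CBI-R points in abnormal strata; +0.3/+0.5 in normal
strata) are of the order reported for such cohorts; no generative model for
clinical change is published, so this additive structure is the minimal one
supporting recovery tests.

What the generator does **not** model: spatial structure, intra-participant
correlation between ROI residuals beyond the shared covariates, correlation
between clinical scales, conversion between stages, scanner-by-region
interactions, and non-Gaussian residuals. Passing tests therefore
demonstrate that the pipeline recovers what it assumes — correctly wired
estimation and inference — not that real cohorts satisfy those assumptions.

## Problem sizes used in tests

The default test suite fits models on 240 simulated controls, uses a
two-to-three-ROI generative model for repeated simulations, 2,000-draw
construction-correctness checks, 1,000-simulation bootstrap-coverage runs
at n = 100 with B = 1,000, and one full-cohort end-to-end run (627
participants, 84 models, B = 200); the complete suite runs in well under a
minute. The acceptance script enumerates exact-test attainability for
n = 1..10 and averages 25 replicates of a fit-on-240 / classify-10,000
held-out calibration experiment (a single replicate varies by ~2 percentage
points because σ̂ is estimated from 240 controls; averaging reduces the
standard error to ~0.4 points without changing the estimand).

## Known limitations

* Linear normative curves only; no spline/GAM age trajectories and no
  site-harmonisation beyond the additive scanner term.
* The exact-test conventions (zeros dropped, midranks, doubled tail) match
  common exact implementations but are not guaranteed identical to every
  legacy statistical package.
* Percentile bands describe the *group mean* w-score, not individual
  prevalence of abnormality.
* The synthetic generator's effect sizes and progression magnitudes are
  illustrative; recovering them validates the machinery, not any clinical
  effect estimate.
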