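# Methods

## Tilt-test phenotyping

A tilt test contributes supine readings at 0/5/10/15/20 min and tilted
readings at 0/3/5/10/15/20 min. The supine average uses the 5/10/15/20-min
readings only; the 0-min supine reading is an accommodation artifact and is
discarded. Orthostatic changes are computed per channel as
`delta = supine average − tilted value` (positive = drop), with the minimum
pool restricted to the 3/5-min readings (the "within 5 minutes" OH
constraint is structural) and the maximum pool spanning 3–20 min; the
tilted 0-min reading belongs to neither pool. Systolic and diastolic
extrema are selected independently, so the two channels' minima may come
from different time points — this matches the disjunctive "≥ 20/10"
threshold notation, which treats the channels separately.

Thresholds (all inclusive, all configurable on `TiltProfiler`): SH at
average supine BP ≥ 140/90; OH at Δmin ≥ 20/10, raised to 30/15 under SH;
OHT at Δmax ≤ −20/−10, with the additional tilted-BP ≥ 140/90 arm applying
only to patients without SH. The "and/or" in the non-SH OHT criterion is
read as a disjunction (SBP ≥ 140 **or** DBP ≥ 90), consistent with how the
same notation is used in every other criterion. OH and OHT are not mutually
exclusive. Missing required supine time points are hard errors; incomplete
tilted pools operate on the available points (≥ 1) with a warning.

## MIBG metrics

H/M = heart ROI uptake / mediastinum ROI uptake; the cohort table may carry
ratios directly (the usual reporting granularity) or per-phase ROI count
pairs. Washout rate is `100·(early − delayed)/early` percent, negative when
delayed uptake exceeds early uptake (typical of preserved innervation); no
decay correction is applied since none is part of the definition used.
Denervation is delayed H/M strictly below the site-calibrated reference
limit, default 1.78.

## Composite scores

Instrument totals are standardized to cohort z-scores with the sample SD
(n − 1); composites are unweighted means of component z's. "Scaled" is
interpreted as plain cohort standardization — no 0–100 pre-scaling is
applied because none is defined. The global composite defaults to ten
instruments (UPDRS II/III, NMSS, MADRS, ESS, PDSS-2, RBDSQ, SCOPA-AUT,
OHQ I, OHQ II); UPDRS I, H&Y, MMSE and CDR are excluded because they never
enter any composite in this analysis family. Membership is configurable and
logged. The OHQ contributes its two parts as separate z's by default (they
are summed separately by design); `ohq_combined=True` collapses them. The
SCOPA-AUT total is expected to exclude the sexual-dysfunction items. A
patient's composite is the mean of available component z's when at least
half are observed, else missing — a pragmatic rule; no published
missing-data rule exists beyond the SCOPA-AUT omission.

## Mediation model

Two linear equations estimated by OLS on complete cases (listwise deletion
before centering; `n_used_` recorded):

    M1: b = i₁ + α·a + γ₁'·cov + e₁
    M2: c = i₂ + τ'·a + β_b·b + γ₂'·cov + e₂

Predictor, mediator and covariates are mean-centered first
(multicollinearity hygiene); estimates, SEs, βs and bootstrap CIs are
provably invariant to this, and a test asserts it. In linear models the
decomposition is exact: the coefficient of `a` in the auxiliary regression
`c ~ a + cov` equals τ' + α·β_b to machine precision, which is asserted on
random data. The total effect's SE is taken from that auxiliary regression.

Coefficient SEs use the maximum-likelihood residual variance (SSR/n), the
path-analysis convention; SSR/(n − p) is available via
`ml_variance=False` and changes SEs only. The indirect effect's SE is the
first-order delta method (Sobel), `sqrt(β_b²·se_α² + α²·se_β²)`; the exact
SE convention of the original software is not documented, and the reported
SE there (0.040 for the ΔSBP model) sits close to but above the Sobel value
from the same coefficients (0.035) — percentile bootstrap, not the normal
theory, is the inferential authority in both that analysis and this
package. z = estimate/SE and two-sided normal p-values accompany every
effect, matching the reporting convention.

Completely standardized effects: β(a→b) = α·SD(a)/SD(b),
β(b→c) = β_b·SD(b)/SD(c), β(direct) = τ'·SD(a)/SD(c), with the indirect and
total βs by the product/sum identities. Covariates are centered but never
standardized.

**Bootstrap.** Cases (rows) are resampled jointly with replacement, n rows
per resample, preserving the covariate association; all five effects are
recomputed per resample and the CI is the empirical (α/2, 1 − α/2)
percentile interval. Resample index streams are counter-based
(`default_rng([seed, i, attempt])`), so results are reproducible and
independent of execution order or chunking (asserted in tests). A resample
with a singular design is redrawn up to `max_retries` times, then a hard
error. The batched normal-equations solver handles 1000 resamples of a
5000-row model in ~2 s on one CPU.

## Synthetic cohort generator

The generator emulates the cross-sectional statistical shape the analysis
assumes; defaults are the study conditions (n = 227, 69.6% abnormal MIBG,
H/M components 1.34 ± 0.18 / 2.04 ± 0.16, age 69.6 ± 9.2 y, duration
1.1 ± 1.0 y truncated at 0.1, paths α = −11.665 (SBP) / −5.270 (DBP) mmHg
per H/M unit, β_b = 0.002 z/mmHg, τ' = −0.441 z per H/M unit).

Residual SDs are not published; they are fixed once so marginal SDs match
the cohort description after the structural contributions: ΔSBP_min
residual 12.0 (marginal SD ≈ 13.3), ΔDBP_min residual 7.3 (≈ 7.8), latent
burden residual 0.65 (SD ≈ 0.7). Systolic/diastolic mediator residuals
share a latent orthostatic factor (r = 0.6, configurable). Covariates enter
both the mediator and burden equations (small effects: 0.10 mmHg/y and
0.5 mmHg/y on ΔSBP_min; 0.005 z/y and 0.05 z/y on burden) so covariate
adjustment is non-trivially exercised. Δmax targets are Δmin minus a
non-negative gap (|N(9.7, 6)| systolic, |N(7.1, 5)| diastolic, means taken
from the reported Δmin/Δmax differences), which enforces the subset-pool
ordering by construction.

The latent burden `L` is the structural outcome and is emitted as the
`latent_burden` column; questionnaire totals are clamped, rounded affine
functions of standardized `L` (loading 0.6, instrument means/SDs/ranges per
scale; clamping is counted and logged). Parameter-recovery checks therefore
regress on `latent_burden`: the questionnaire-derived `global_z` is by
construction an attenuated proxy of `L` (measurement noise plus clamping),
so structural coefficients are recoverable from `L` but attenuated through
`global_z` — end-to-end checks on `global_z` assert signs and CI behavior,
not coefficient values.

BP targets are rounded to integer mmHg before series construction, making
the classifier round-trip exact: four supine readings averaging exactly to
the target, the 3-min tilted reading carrying both channel minima, the
20-min reading both maxima, interior readings strictly between. Rare
infeasible tails (implied BP outside (0, 300) or diastolic reaching
systolic) are clamp-repaired and counted. Group labels for analysis are
always re-derived from the sampled delayed H/M via the 1.78 cutoff, never
taken from the mixture component: components overlap, and the cutoff
classification is the operational truth (mixture weight 0.696 maps to a
classified proportion of ≈ 0.707).

What the generator does **not** emulate: beat-to-beat hemodynamics,
longitudinal progression, diagnostic misclassification, floor-heavy
questionnaire distributions (totals are clamped Gaussians, not zero-inflated
counts), or the unknown joint distribution of ΔBP and H/M beyond the stated
marginal and path structure. Passing tests demonstrate correctness of the
pipeline's arithmetic and calibration of its inference under this
structural model — not fidelity of any conclusion on real patients.

## Group statistics

Pooled t (accepting raw values or (n, mean, SD) summaries, so published
tables are directly checkable), Welch t with Satterthwaite df, Fisher's
exact test with the probability-at-most-observed two-sided rule (documented
because two-sided Fisher conventions differ), and Mann-Whitney U from
midranks — exact enumeration over rank assignments for n₁ + n₂ ≤ 12 (ties
allowed), tie-corrected normal approximation with continuity correction
otherwise (correction switchable). The t-vs-Mann-Whitney routing is left to
the caller; a Shapiro-Wilk helper exists but is never auto-invoked, since
no normality-test protocol is defined.

## Numerical and design notes

- OLS rank deficiency raises "collinear design" naming the offending
  columns (identified by R² ≈ 1 against the remaining columns).
- Mediation requires ≥ 10 complete cases and non-degenerate variance in
  every model variable.
- Report files round percentages to 1 decimal and effects to 3 decimals;
  nothing is rounded inside computations.
- All pipeline randomness derives from one seed; per-model substreams come
  from `SeedSequence([seed, model_index])`.
- Problem sizes used by the verification scripts — n = 5000 for path
  recovery, 500 replicates of n = 200 with 1000 resamples for coverage,
  n = 10,000 for the classifier round-trip — were chosen to give
  Monte-Carlo error comfortably below the tolerances being checked.

## Known limitations

- The percentile bootstrap mildly undercovers the indirect effect when the
  b→c path is near zero at n = 200 (measured ≈ 93% for a nominal 95%) — a
  known property of percentile intervals for product coefficients, not an
  implementation artifact; coverage improves with n.
- The Sobel SE is first-order and understates the indirect effect's
  sampling variability for small n; it is reported for comparability, with
  the bootstrap CI authoritative.
- Emergent phenotype prevalences in the simulator (OH ≈ 35%, SH ≈ 13%) are
  somewhat above the reported 22.9% / 8.8%: the generator calibrates
  marginal means/SDs and structural paths, and prevalence is whatever the
  thresholds then imply under Gaussian tails.
- The exact Mann-Whitney branch enumerates C(n₁+n₂, n₁) splits and is
  restricted to n₁ + n₂ ≤ 12 by default.
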