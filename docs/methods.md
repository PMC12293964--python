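# Methods

This note documents the models and procedures `strokeconn` implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Connectivity features

ROI time series are the unweighted voxel means of a 4-D volume over an
integer-labeled atlas. Optional temporal filtering is a zero-phase
Butterworth band-pass (order 4 per direction, applied forward and backward
with `scipy.signal.sosfiltfilt`) over 0.01–0.1 Hz, the standard
low-frequency window for resting-state BOLD fluctuations; band edges must
lie below the Nyquist frequency 1/(2·TR).

Connectivity between two regions is the Pearson correlation of their
series, variance-stabilized by the Fisher transform z = arctanh r. |r| is
clipped at 1 − 10⁻⁷ so degenerate inputs stay finite; magnitudes beyond
1 + 10⁻¹² are rejected as errors rather than clipped.

A **network registry** names networks as sets of base regions, each
resolving to a left and a right node. The default registry contains four
motor networks (primary sensorimotor; premotor/prefrontal; insular–
cingulate; basal ganglia), the default mode network and the frontoparietal
network. Networks deliberately share regions (e.g. the medial superior
frontal gyrus belongs to both a motor network and the DMN). Crossing
networks with hemisphere scopes {left, right, both} yields 18
configurations; the "both" scope keeps left and right nodes separate, so
interhemispheric homologue pairs contribute to intra-network averages.

Features are unweighted means of z over pair sets, in a fixed canonical
order (networks in registry order, scopes left/right/both, inter pairs in
lexicographic configuration order): 18 intra features (all unordered pairs
within a configuration) and 153 inter features (all cross pairs between two
configurations). Because configurations can share regions, a cross pair of
a region with itself (r = 1, z infinite) can occur; such self-pairs are
excluded from inter averages — the only reading that keeps every feature
finite. Overlapping-but-distinct pairs are kept.

## Lesion volumetrics

Volume is foreground voxel count times voxel volume, in mm³. Voxel
dimensions are read from the NIfTI header; a mismatch with caller
expectations is an error, not a warning. Masks must be exactly binary;
interpolation residue in [0, 1] is accepted only with an explicit
threshold (0.5 by convention).

## Regression engine

All models are OLS with intercept. AIC and BIC are computed from the full
Gaussian log-likelihood (constants included) with the error variance
counted as a parameter: a model with k slopes has k + 2 parameters. The
convention matters only up to a constant shared by all models fit to the
same data; differences (ΔAIC) and the identity
χ² = ΔAIC(nested − full) + 2·df are convention-invariant and are covered by
tests.

Forward selection adds, at each step, the candidate with the largest
increase in training R² whose inclusion keeps every VIF below 2, stopping
at five predictors or when no admissible candidate improves the fit. The
cap reflects the 10–15 observations-per-predictor rule at n = 44; the VIF
gate is enforced *during* selection, which is the only way to guarantee
the bound holds in the final model. Selection uses training R² (not CV R²)
as the criterion; per-step CV is available for reporting. Ties are broken
by canonical feature order so runs are reproducible.

Cross-validation partitions subjects into K = 5 random folds (sizes
differing by at most one, seeded permutation). Fold R² is 1 − SSE/SST with
SST about the held-out fold's own mean — stricter than pooled prediction
R², and possibly negative. CV R² and CV MSE are unweighted means over
folds. One partition (one seed) is shared by every model in a suite so
per-fold scores are paired.

The fold-paired t-test on per-fold R² differences has K − 1 = 4 degrees of
freedom and correlated folds; p-values are descriptive, and a
Nadeau–Bengio variance correction (inflating the variance by
1/K + n_test/n_train) is available as an option. The likelihood-ratio test
for nested OLS fits uses χ² = 2 Δlog L = n ln(RSS_nested/RSS_full) with
df = added predictors; it is asymptotic, and at n = 44 its null
distribution matches χ²(df) closely only for small df (the calibration
test uses df = 1, where the Kolmogorov–Smirnov distance to χ²(1) is about
0.03 over 2000 null cohorts; at df = 4 it is about 0.07).

## The model suite

Seven models are fit to each cohort with shared folds: lesion volume only;
the single best connectivity predictor; greedy selection over all 171
features without lesion volume; greedy selection seeded with lesion
volume; and greedy selection restricted to pure-left, pure-right, or all
(bilateral) candidate sets. The bilateral candidate set defaults to *all*
features — the natural contrast with single-hemisphere restriction — with
a strict both-scope-only variant behind a flag. Reported comparisons:
left vs right and left vs bilateral (ΔAIC and fold-paired t), and a
likelihood-ratio test extending a primary-motor-only baseline (default
`intra|MotorI:both`, configurable) with left-hemisphere incremental
predictors.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, not
realistic physiology:

- **Time series**: stationary zero-mean multivariate normal, T = 260
  volumes at TR = 1.78 s. The correlation matrix places within-network
  correlation 0.4 on every pair of regions sharing a network and 0.2
  elsewhere; pairs claimed by several networks take the strongest claim.
  These defaults leave a comfortable positive-definiteness margin —
  because the networks overlap, a larger within/between gap (e.g. 0.5 over
  0.1) makes the implied matrix non-PD, and such configurations are
  rejected with a diagnostic. An optional AR(1) coefficient adds temporal
  autocorrelation (innovations scaled so marginal correlations are
  unchanged) so the band-pass filter can be exercised on temporally
  structured input; there is no hemodynamic convolution, motion, or
  physiological noise.
- **Lesions**: volumes uniform on 0.1–20 cm³ (subcortical range), rounded
  to whole mm³; masks are single 6-connected components grown voxel by
  voxel to the exact target count.
- **Lesion → connectivity coupling**: damage is confined to *affected
  networks* (default: the primary sensorimotor and basal ganglia motor
  networks, matching a subcortical motor stroke). Each affected network's
  within-correlations are attenuated by slope × impact, where the impact
  score mixes lesion volume (weight 0.4) with an independent per-network
  severity draw — equally sized lesions can damage networks to different
  degrees, which both reflects the motivation for connectivity analysis
  (volume alone does not determine deficit) and keeps lesion volume and
  connectivity features only moderately collinear (VIF < 2). Damage is
  lateralized: each subject has a stroke side (left with probability
  0.57), and attenuation falls 75–100% on that hemisphere's
  within-hemisphere pairs, with a quarter-strength effect on
  interhemispheric pairs. The default slope (1.5 × 10⁻⁵ per mm³) caps
  attenuation at 30% of the within-network correlation.
- **Outcome**: NIHSS = intercept + β·predictors + ε, ε ~ N(0, σ²), linear
  in named pipeline predictors. The default truth uses lesion volume plus
  left- and right-hemisphere motor coherence with a heavier left weight
  (left-hemisphere dominance in skilled movement), giving means and
  spreads in the observed mild-to-moderate range (≈ 4–5 ± 3 points).
  Outcomes are continuous by default — the analysis fits linear models to
  NIHSS without a transform — with opt-in integer rounding clipped to
  [0, 14]. σ can be given directly or calibrated so the design
  (population) R² on the realized predictors equals a target; the truth
  object stores coefficients, σ and the design R², and reproduces every
  outcome exactly when σ = 0.
- **Seeding**: one master seed; per-subject streams are derived through
  `SeedSequence` spawn keys, so enlarging the cohort never reshuffles
  earlier subjects, and every generator is a pure function of
  (config, seed).
- **Toy volumetric rendering**: each region's series is copied into a
  disjoint voxel block (optional i.i.d. voxel noise), with a matching
  label volume, as a round-trip fixture for the extraction code.

## What the synthetic tests do and do not show

Problem sizes mirror the study design (44 subjects, 171 predictors, 5
folds); multi-seed checks use 25–200 replicate cohorts, and calibration
checks 2000 lightweight replicates. On cohorts generated at design
R² = 0.70, the combined (lesion-seeded) model's mean cross-validated R²
over 50 seeds lands within ±0.10 of 0.70 — forward selection at n = 44
overfits mildly, and the strict per-fold R² definition absorbs the rest.
On null cohorts (all outcome slopes zero) every suite model's mean CV R²
is negative over 200 seeds: selection-induced optimism does not survive
cross-validation.

Exact predictor identity is *not* recoverable at this sample size: scope
variants of one network's features average overlapping pair sets and are
near-proxies of one another, so with 171 candidates the greedy step often
selects a proxy of a true predictor rather than the predictor itself
(hit rates ~40–50% even at partial R² > 0.2). What is recoverable — and
tested — is the signal-bearing network family: the selected model contains
an affected-network feature in ≥ 80% of seeds. Substantive conclusions
from such analyses should therefore be drawn at the network level, not the
level of individual selected features.

Passing these tests shows the pipeline's arithmetic, ordering, seeding and
statistical calibration are correct under the generator's assumptions
(Gaussian, stationary, linear coupling). It does not validate hemodynamic
preprocessing choices, nuisance-regression strategies, or robustness to
motion and physiological artifacts, none of which the generator emulates.

## Numerical choices and degenerate inputs

- Fisher clipping at |r| = 1 − 10⁻⁷; zero-variance regions are errors
  naming the region.
- R² ties in selection broken by canonical feature order; improvement
  threshold 10⁻¹² guards machine-precision ties.
- Perfect collinearity reports VIF = ∞ (sentinel) in `compute_vif`, but a
  rank-deficient chosen design is an error naming the collinear columns.
- A CV fold with zero outcome variance raises an error prompting a
  re-seed rather than returning an undefined fold R².
- Identical per-fold scores give t = 0, p = 1; nonzero constant
  differences are a degenerate-input error.
- Lesion masks with unachievable target volumes report the nearest
  achievable volume.
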