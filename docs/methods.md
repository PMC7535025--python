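# Methods

## The problem

Surveys of anemia in women of reproductive age in high-infection-burden
settings face a measurement problem: the iron biomarkers that would explain
the anemia (ferritin, soluble transferrin receptor) are themselves distorted
by inflammation. `anemiascope` implements the full analysis chain such a
survey needs — inflammation adjustment, status classification at standard
cutoffs, socio-economic scoring, and determinant modeling — together with a
calibrated synthetic cohort generator so the entire chain is testable
end-to-end without access to any participant-level data.

## Synthetic cohort generator

### Quantile-anchored marginals

Each biomarker's marginal distribution is specified non-parametrically by
monotone (probability, value) anchor pairs and sampled by inverse transform.
Anchors come from two kinds of published summary:

* median and interquartile range → anchors at p = 0.25, 0.5, 0.75;
* prevalence thresholds → an anchor at (cutoff value, cumulative
  probability), e.g. 19.1% of women below the 120 g/L anemia cutoff gives
  the anchor (0.191, 120).

Between anchors the quantile function is piecewise linear — on the natural
log of the value for the right-skewed biomarkers (ferritin, TfR, hepcidin,
CRP, AGP, plasma iron), linear for hemoglobin, zinc and selenium. Beyond the
extreme anchors the outermost segment's slope is continued, capped at 5× the
outermost anchor value to avoid absurd extremes, and floored at a small
positive epsilon. Selenium is additionally truncated to (2.0, 5.0) µmol/L,
the range observed in the study population.

Prevalence-threshold anchors take precedence: when a rounded IQR anchor
contradicts a threshold anchor (the zinc upper quartile of 11 µmol/L is
incompatible with 78% of women below 10.7), the IQR anchor is dropped with a
warning. The classification cutoffs are the testable core of the pipeline,
so the prevalences they imply must be exact; the IQR is a rounded summary.

A useful consequence of this construction: because the anemia-cutoff anchors
are placed at (0.066, 110) and (0.191, 120) and the lower tail extrapolation
bottoms out near 105 g/L, the generated severity distribution is exactly the
published one — 12.5% mild, 6.6% moderate, 0% severe — up to Monte-Carlo
error.

### Gaussian copula and calibration

The joint distribution couples the nine biomarker marginals through a latent
multivariate normal. Published pairwise Pearson correlations (reported on
the analysis scale — log-transformed for the skewed biomarkers) are imposed
by calibrating each constrained pair's latent correlation with a stochastic
secant root-find: using a fixed matrix of standard-normal draws (common
random numbers, 10⁵ per pair), the latent ρ is adjusted until the empirical
correlation of the transformed margins is within 0.005 of the target.
Unconstrained pairs stay at latent zero. The assembled matrix is repaired to
positive definiteness by eigenvalue clipping (floor 10⁻⁶) and
renormalization to unit diagonal; the default target set needs no repair.
Because each margin is a deterministic monotone transform of its latent
normal, the copula preserves the marginals exactly regardless of the
correlation structure.

### Socio-demographic fields

Education (61.8% illiterate), the four-level food-insecurity category
(52.6/12.5/23.0/11.8, renormalized to sum exactly to 1), and eight binary
asset indicators are drawn independently of the biomarkers. HFIAS item
responses are generated backwards from the sampled category: one item is
forced to a condition whose severity code equals the category and the
remaining items draw admissible lower-severity frequencies, so the
categorization round-trips exactly. Age, household size, number of children,
MUAC and BMI are (truncated) normals at the published mean/SD pairs;
gravidity is the number of children plus an occasional extra pregnancy,
clipped to 1–8. Altitude is a constant 1700 m, typical of the highland
setting modeled.

By default the socio-demographic block is independent of the biomarkers — a
deliberate simplification (the published summaries do not constrain the
joint distribution). An optional *effects hook* subtracts 6 g/L of
hemoglobin for MUAC < 22 cm and 4 g/L for illiteracy, giving the logistic
modeling stage recoverable signal; effect sizes were chosen once so the
multivariate odds ratios for both risk factors exceed 1 comfortably at
n = 2000. The hook is off by default because it perturbs the hemoglobin
marginal.

### Determinism

A single top-level seed feeds named substreams (latent biomarkers,
demographics, anthropometry, categorical fields, HFIAS items, assets, and
one per copula calibration pair), so adding a stage never perturbs earlier
streams and identical spec + seed reproduces a cohort byte-for-byte through
CSV round-trips.

### What the generator does and does not emulate

It reproduces: the printed medians/IQRs, every printed prevalence threshold,
the printed pairwise correlations on the analysis scale, and the category
frequencies. It does not attempt: household clustering, missing data,
assay noise or digit preference, the joint distribution of socio-economic
variables with biomarkers (beyond the hook), or the three-way and higher
dependence structure, which a Gaussian copula with pairwise targets cannot
pin down. Consequently *emergent* joint quantities are only approximately
reproduced: iron deficiency lands near the published 31% and iron overload
near 2% (both effectively anchored through the raw ferritin quantile
function), while tissue iron deficiency (body iron < 0) comes out near 9%
against a published 16% — the body-iron index lives in the TfR–ferritin
joint tail, which the single published r = −0.24 underdetermines. Passing
calibration tests therefore demonstrates the pipeline's correctness on
realistic marginals and pairwise structure, not distributional fidelity of
every derived index.

## Inflammation adjustment

For each of ferritin and TfR, the slopes β₁, β₂ of ln(biomarker) on ln CRP
and ln AGP (jointly, with intercept) are estimated by OLS on the sample
itself (n ≥ 20 enforced), and each record is corrected as

    adjusted = exp( ln v − β₁·max(0, ln CRP − ref_CRP) − β₂·max(0, ln AGP − ref_AGP) )

where each reference is the maximum observed ln value within the lowest
decile of the sorted sample (floor(n/10) observations, ties included). The
max(0, ·) clamp leaves records at or below reference untouched; it can be
disabled for sensitivity analysis. A negative fitted slope disables its term
by default (`positive_betas_only`) so the correction never inflates a
biomarker. Both CRP and AGP terms apply to both biomarkers, exactly as the
single published formula states; adjusting TfR with AGP only (a variant some
surveys use) is possible by zeroing the other slope.

The altitude correction term −0.32x + 0.22x² (g/dL, x = altitude·0.0033) is
implemented with configurable coefficients because the printed values are
tenfold the widely used CDC/WHO coefficients (−0.032, 0.022) and imply a
~51 g/L correction at 1700 m; both scales are provided
(`AltitudeCorrection()`, `CDC_SCALE_ALTITUDE`) and neither is asserted as
correct. The generator emits hemoglobin on the altitude-adjusted scale
(the published summaries are adjusted), so the correction runs only when a
cohort is flagged as pre-adjustment.

Cook's body iron index is −(log₁₀(ratio) − 2.8229)/0.1207 mg/kg with
ratio = sTfR(µg/L)/ferritin(µg/L); TfR assayed in mg/L is multiplied by
1000 first. The zero crossing (ratio 10^2.8229 ≈ 665) separates positive
stores from tissue iron deficiency.

## Status classification

All cutoffs live in one table (`status_classification.CUTOFFS`) so the
boundary audit enumerates them mechanically. Severity bands are closed below
and open above (Hb 110.0 is mild, 120.0 is not anemic), matching the integer
resolution of field hemoglobinometers; ferritin cutoffs are strict
(15.0 is not deficient, 150.0 is not overload); the TfR cutoff is inclusive
(8.3 is a functional deficit). The acute CRP cutoff is strict > 5 by
default with an inclusive variant behind a flag, because the source
definitions disagree between first mention and later prose. Iron overload is
evaluated on adjusted ferritin, consistent with deficiency.

## Socio-economic scores

The HFIAS score is the sum of the nine frequency codes (0–27). The
four-level category applies the FANTA v3 most-severe-condition rule via a
packaged decision table (27 rows: item × frequency → severity code), rather
than hard-coded nested conditionals, so tests are table-driven and the
monotonicity property (raising any item's frequency never lowers the
category) is verified by exhaustive enumeration of all 4⁹ response patterns.

The wealth index standardizes asset indicators to zero mean/unit variance
(zero-variance indicators dropped with a warning), projects on the first
principal component (numpy SVD), orients the sign so the largest-|loading|
indicator loads positively (the PC sign is otherwise arbitrary), and cuts
quintiles at the 20/40/60/80 rank percentiles with average-rank ties —
group sizes then differ by at most one.

Model covariates are dichotomized exactly at the published cuts: MUAC < 22
cm, age ≤ 21 years, gravidity 1–3 (reference 4–8), illiterate vs literate,
zinc < 10.7 µmol/L, TfR < 8.3 mg/L (reference ≥ 8.3), AGP ≤ 1 g/L
(reference > 1).

## Determinant models

Hemoglobin model: predictors are log₁₀-transformed (values ≤ 0.01 unit are
rejected, not floored — silent flooring would distort the fits), screened by
iterative VIF (threshold 2.5; worst offender dropped and VIFs recomputed
each round; a perfectly collinear predictor reports infinite VIF), then fit
by OLS. Each predictor's squared semipartial correlation is computed by
explicit nested refit, R²(full) − R²(full − j), with a partial-F p-value;
the test suite checks this against the independent algebraic identity
sr²_j = t_j²(1 − R²)/(n − p − 1) to 10⁻¹⁰. Adjusted R² is reported as a
percentage. Note the natural log is used inside the inflammation-adjustment
fit while log₁₀ is used for model predictors; the two bases are deliberately
not unified, matching the conventions of each procedure.

Anemia model: a bivariate logistic screen per candidate factor retains those
with Wald p < 0.05; retained factors enter a multivariate maximum-likelihood
logistic fit reporting OR = exp(β) with 95% Wald intervals
exp(β ± 1.96·SE). Wald rather than profile-likelihood intervals are the
default to match common epidemiological practice. A 2×2 screen table with a
zero cell falls back to the continuity-corrected (add 0.5) estimate with a
Woolf SE; quasi-separation in the multivariate fit triggers a warning and a
ridge-penalized fallback (GLM, α = 10⁻³) whose estimates are flagged as
unstable. Fewer than 10 events draws a small-sample warning.

## Problem sizes

Default test and calibration sizes were chosen to give each check resolving
power at interactive cost: copula calibration at 10⁵ draws per pair (secant,
3–6 iterations), generator calibration checks on a 50,000-record cohort
(Monte-Carlo SE ≈ 0.2 pp on a 19% prevalence), the correlation check at
10⁵ records (SE ≈ 0.003), confidence-interval coverage over 500 replicates
of n = 2000, and parameter-recovery simulations at n = 5000 with residual
SDs set so the estimator's standard error sits well below the recovery
bound being asserted.

## Known limitations

* Socio-demographic/biomarker independence (absent the effects hook) means
  the logistic stage's null behavior, not the study's actual effect sizes,
  is what the default cohort exercises.
* The published regression tables cannot be reproduced numerically without
  the raw data; the modeling stages are validated by parameter recovery,
  algebraic identities and coverage simulations instead.
* Tissue-iron-deficiency prevalence is underdetermined by the published
  pairwise correlations (see above).
* Whether the study clamped the inflammation adjustment at the reference
  decile, and which altitude coefficient scale it used, cannot be resolved
  from the text; both choices are configurable and the defaults follow
  standard practice.
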