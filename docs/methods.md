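# Methods

## The measurement model

`choriflow` quantifies choriocapillaris perfusion on a single grayscale
en-face OCTA slab, treated as a 2-D intensity field in [0, 1] sampled on a
square isotropic grid (default 512 px over a nominal 3.0 × 3.0 mm scan,
5.86 µm/px). Three assumptions are built in:

1. **Bright = flow.** Decorrelation signal is monotone in flow, so after
   local-contrast normalization a brighter-than-local-threshold pixel is
   flow. Polarity is fixed; a dark-vessel flag exists only in the
   superficial-plexus segmenter.
2. **Local thresholding is required.** The slab has low global contrast
   and slow illumination drifts, so a pixel is compared with the
   Phansalkar threshold `T = m(1 + p·e^{−q·m} + k(s/R − 1))` computed in
   its own window rather than with a global cut. Defaults
   (`p=2, q=10, k=0.25, R=0.5`, window radius 4 px ≈ 23 µm half-width)
   follow the method's published values for unit-range images; all are in
   `PhansalkarParams` because the literature varies and results are not
   comparable across parameter sets. Windows are reflect-padded, which
   avoids the dark-border bias zero padding would cause.
3. **Heterogeneity is a tile statistic.** The binarized 2.7 mm area is
   split into an 18 × 18 grid (~150 µm tiles, bracketing the 200–250 µm
   lobule scale), and the CV of per-tile flow fractions summarizes how
   unevenly flow deficits are distributed. The sample (n−1) SD is used;
   with 324 tiles the choice is nearly immaterial but must be fixed for
   reproducibility. When the mask side is not a grid multiple the mask is
   center-trimmed and the trim recorded; an all-void mask yields an
   explicit `zero_mean_flow` non-value rather than NaN.

Magnification correction uses the Littmann–Bennett relation. Against the
device's assumed axial length the `0.01306` constant cancels, leaving the
ratio `(AL − 1.82)/(AL_assumed − 1.82)`; the assumed length defaults to
24.46 mm and is configurable since devices differ. Correction is a
*metadata* rescale — the pixel grid is never resampled, because area
ratios are scale-free and interpolation would perturb the binarization —
followed by a centered crop to 2.7 × 2.7 mm, floored to whole pixels with
the exact achieved size recorded. A corrected scan narrower than the crop
(AL below ≈ 22.2 mm at the defaults) excludes the eye with a reason code,
as does a quality index not strictly greater than 7.

Vessel length density (VLD) on the superficial slab is
segment-skeletonize-sum: background-flattened Otsu segmentation, speck
removal (< 3 px), morphological thinning, then length as 1 per orthogonal
and √2 per diagonal skeleton adjacency, each pair counted once (raw pixel
counting would understate diagonal vessels by up to 41 %). VLD is
measured on the nominal scan area without axial-length correction,
matching how device software reports it.

The impaired-flow rule is the conjunction CCFA < 65.9 % and CV ≥ 0.140,
inequalities exactly as stated; both cutoffs are configurable.

## The synthetic scene model

The generator's purpose is end-to-end verifiability: every rendered slab
carries exact ground truth.

**Choriocapillaris slab.** A bright baseline texture (intensity 0.80) is
organized by a jittered hexagonal lattice of ~225 µm lobules with a
slight darkening (12 %) along lobule borders. Flow voids are unions of
random ellipses with full axes 10–45 µm placed by a spatially modulated
point process; placement continues until the void mask reaches a target
coverage fraction, so `void_param` *is* the coverage and
`true_flow_fraction = 1 − void_param` to within one small ellipse. Void
centers are drawn proportionally to a log-Gaussian rate field (white
noise smoothed at 300 µm, exponentiated, normalized to mean 1) whose
amplitude `heterogeneity_param` controls clustering — and therefore the
tile CV — without changing total coverage. Speckle is multiplicative
log-normal, mean-preserving before clipping (σ = 0.15 by default).
The ellipse-size range was set below the tile scale so that the tile CV
of a homogeneous (`heterogeneity_param = 0`) slab sits near 0.09 at
typical coverages, beneath the lowest group target (0.124); larger voids
put the spatial-sampling floor of the 18 × 18 grid above the control
target and make it uncalibratable.

**Superficial slab.** Vessel centerlines grow as a branching random walk
(10 tips, 14 px steps, angular jitter SD 0.25 rad, branch probability
0.14 per step; tips leaving the field are replaced) until total
centerline length per area reaches the target VLD, the final segment
being trimmed so the recorded ground-truth density is exact. Centerlines
are dilated to ~3 px calibre and rendered bright on a dark background
with the same speckle model. The growth parameters were chosen to make a
plausibly dense, tortuous plexus on which the skeleton estimator is
nearly unbiased: chain-code overcounting of oblique segments (~+5 % for
straight lines under the 1/√2 step weights) is largely offset by thinning
losses at branch tips and crossings, leaving ~+1 % net at study-range
densities.

**What the generator does not emulate:** projection artifacts, B-scan
geometry, pulsatility, segmentation errors of real devices, inter-eye
correlation within a patient, and the device's proprietary VLD algorithm.
Passing recovery tests therefore demonstrates internal consistency of the
measurement chain, not agreement with any particular scanner.

## Cohort model

Each synthetic eye draws a latent severity `z ~ N(0,1)`; every continuous
channel (CCFA target, CV target, VLD target, PROS length, RPE volume) is
`μ_g + σ_g(λ_ch z + √(1−λ_ch²) ε)`, so within-group correlations are
products of loadings. Loadings are solved in closed form so that the
*pooled* cohort correlations — which include the between-group mean
structure — match configured targets (CCFA–VLD 0.572 anchors the scale;
CCFA–PROS 0.395, CCFA–RPE −0.445, CV–VLD −0.578 then fix the remaining
signs and magnitudes). Group presets carry the published means/SDs; the
diabetic-without-retinopathy RPE volume has no published value and is
set midway between its neighbours (0.39 ± 0.025). Continuous
draws are truncated to physical ranges by resampling; inclusion rules
(BCVA < 0.05 logMAR, AL < 27 mm, positive labs) can therefore never be
violated by an emitted eye. Axial length is N(24.2, 0.8²) truncated to
[22.3, 26.9] mm — a realistic adult range that also keeps corrected scans
wide enough for the 2.7 mm crop. Sex uses the published per-group male
fractions (2/12, 8/15, 15/18); age uses the published group means/SDs
truncated to the published ranges. Per-eye seeds are `base_seed + index`,
making tables byte-identical across runs; experiments that average over
repeated cohorts space the base seeds (1000 apart) so eye streams do not
overlap.

Systemic labs are generated conditionally on impaired-flow status:
each exposure's binary exceedance indicator follows
`logit P = logit(base) + ln(OR)·impaired + 0.03(age − 50)` with the
published age-adjusted ORs as generative defaults (HbA1c ≥ 7 %: 4.992;
systolic BP ≥ 135: 5.572; …), and the continuous value is drawn
half-normally on the indicator's side of the cutoff. Because a 2 × 2 odds
ratio is symmetric within each age stratum, regressing impaired status on
the indicator plus age recovers the generative OR. Total cholesterol and
the composite indices are derived from the panel (TC = LDL + HDL + TG/5)
rather than given independent generative ORs — enforcing all nine
published ORs on one consistent panel would be over-constrained, so the
composite associations are emergent. The HbA1c cutoff is taken in percent
units (≥ 7.0 %).

## Calibration

Simulator controls are not set by hand. `calibrate_preset` bisects
`void_param` on [0, 1] until the mean *measured* CCFA ratio of ≥ 20
simulated eyes (common random seeds, so the score is deterministic and
monotone) is within `tol` (default 0.5 points) of the group target, then
bisects `heterogeneity_param` for the CV (tolerance 0.01). A target
outside the bracket — e.g. a CV below the tile grid's sampling floor —
raises a calibration error rather than returning the nearest endpoint.
Around the operating point a finite-difference 2 × 2 Jacobian
(∂CCFA/∂v, ∂CCFA/∂h; ∂CV/∂v, ∂CV/∂h) is estimated; per-eye targets map to
per-eye controls by inverting it, which matters because void coverage
itself raises the tile CV (∂CV/∂v ≈ 0.45–0.55 at study operating points)
and a one-axis mapping would inflate group-mean CVs by ~0.015.

## Statistical conventions

Two-sided tests throughout, α = 0.05, no multiple-testing correction.
Kruskal–Wallis (tie-corrected) across groups; pairwise Mann–Whitney U
with exact enumeration when both n ≤ 8 and no ties, otherwise the
continuity/tie-corrected normal approximation. Pearson r with the
t-transform p (n−2 df); zero-variance input returns an explicit
non-value. AUC is computed through the Mann–Whitney identity (average
ranks give ties ½ credit); the Youden cutoff scans observed values, ties
breaking toward the less extreme threshold. The 2 × 2 odds ratio uses
Woolf's log-SE interval, Haldane–Anscombe +0.5 on a zero cell (flagged),
Pearson chi-square without continuity correction or Fisher's exact test
when an expected cell is below 5. Logistic models are fitted by ML
(Newton/IRLS, statsmodels) with Wald 95 % CIs; |coef| > 15 or
non-convergence flags separation and suppresses the CI. Each systemic
exposure is fitted in its own age-adjusted model — a single model with
nine collinear lipid covariates at n = 45 would be unstable, and the
one-at-a-time layout mirrors how such tables are reported. The
two-threshold rule's cutoffs are each derived from their own marginal ROC
curve and then evaluated as a conjunction; the joint derivation is an
interpretation, flagged as such.

## Problem sizes and numerical choices

Validation experiments run at the study's group sizes (12/15/18) over 10
independently seeded cohorts, with n = 450 for the pooled correlation,
n = 5000 per dataset (five replicate datasets, geometric-mean OR) for
logistic recovery, and 2 × 20 000 normal draws for the preset AUC; these
sizes keep every quantity's Monte-Carlo error well inside its comparison
band. Unit tests use a 256 px canvas (half scale) where only invariants,
not absolute targets, are checked. Degenerate inputs have defined
behaviour rather than exceptions wherever a value can be meaningfully
flagged: blank images segment to empty masks, all-false masks yield
`zero_mean_flow`, all-impaired cohorts flag separation downstream.

## Known limitations

- Phansalkar parameters and window radius are field conventions, not
  device truths; absolute CCFA levels shift with them (hence calibration).
- The void process is phenomenological (elliptical blobs), not a vascular
  dropout model; only its controllable statistics are claimed.
- The skeleton VLD estimator's near-zero bias is a property of the
  default growth geometry; strongly parallel or merging vasculature would
  bias it low.
- Pooled measured correlations are slightly diluted (<0.02) relative to
  the wired target-channel correlations by measurement noise.
- One eye per subject; no longitudinal structure; no treatment effects.
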