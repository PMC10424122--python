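# Methods

This note documents the models, parameter choices and numerical behavior
of `couplemap`: what each stage computes, why the defaults are what they
are, what the synthetic cohorts do and do not emulate, and where the
statistical machinery is known to be approximate.

## Pipeline overview

Stages run in a fixed, logged order per subject — discard initial
volumes → joint detrend + nuisance regression → ideal band-pass →
within-tissue smoothing → ALFF → coupling ratio — followed by group mask
construction and group inference. Re-running any configuration
(including the seed) is bit-identical; the run report carries content
hashes of every table and map.

## Preprocessing

**Volume discard.** The first 5 volumes are dropped (scanner
equilibration; configurable).

**Framewise displacement.** FD is the Power form: the sum of absolute
backward differences of the three translations (mm) plus the three
rotations (rad) converted to arc length on a 50 mm sphere. The radius is
configurable; 50 mm is the convention of the DPARSF/DPABI ecosystem.
Frames with FD > 1 mm are flagged.

**Nuisance regression.** One OLS per voxel against a design with an
intercept, a linear trend, the 24-parameter motion model (6 rigid-body
parameters, the same 6 lagged one frame with zero in the first row, and
the squares of all 12), the mean CSF signal (voxels with CSF probability
> 0.5 in the subject's segmentation), and one one-hot column per flagged
frame — 27 + n_flagged columns. Folding the trend into this regression
is algebraically identical to a separate detrend pass and saves a data
copy. Spike frames are regressed, not deleted: the one-hot columns force
exactly zero residual at those frames while leaving the rest of the
series untouched. Near-singular designs are solved by pseudoinverse and
logged; residuals are orthogonal to every design column by construction
(verified to < 1e-8 relative in the tests).

**Band-pass.** An ideal frequency-domain filter retains DFT bins with
0.01 ≤ f ≤ 0.1 Hz (inclusive edges; DC always removed). An ideal filter
rather than an IIR design because the downstream statistic (ALFF) is
itself defined on the DFT spectrum: in-band content is preserved exactly
and out-of-band content removed exactly at bin frequencies. The filter
runs before smoothing; the order is configurable in principle but the
two operations act on orthogonal axes, so only boundary effects of the
mask interact with it.

**Within-tissue smoothing.** Gaussian smoothing (default 4 mm FWHM,
σ = FWHM/2.3548) restricted to a mask, computed as
smooth(data·mask)/smooth(mask) inside the mask and zero outside. This
boundary normalization prevents edge attenuation and guarantees zero
leakage across the WM/GM boundary — the reason the source analysis
smooths the two tissues separately. Constants are preserved exactly up
to the mask edge. The in-mask *mean* of a general field is not exactly
preserved by the normalized kernel (measured shift ≈ 0.1–0.2 % of the
field SD); only constants are.

## ALFF

ALFF at a voxel is the mean over in-band DFT bins of the amplitude
spectrum 2|X(f)|/t (the square root of the power spectrum under the
one-sided amplitude convention). The normalization is a free choice —
only group contrasts matter — and is fixed so that a unit sinusoid at a
bin frequency has unit amplitude, which makes the synthetic generator's
calibration exact: a series built from unit-amplitude sinusoids at every
in-band bin has ALFF equal to that amplitude. "Mean" (not sum) over bins
and inclusive band edges are deliberate; no taper is applied. An
optional standardization (divide by the in-mask mean) is provided but
off by default, since raw ALFF enters the coupling ratio.

## Tissue masks

Subject masks assign each voxel to the tissue with the strictly greatest
probability; exact ties break by a fixed GM > WM > CSF priority, and
voxels with all three probabilities below 0.05 are background (both
rules are unspecified upstream conventions, made explicit and
configurable here). Group masks require an anatomical consensus
fraction strictly greater than 0.60 (WM) or 0.20 (GM) of subjects *and*
functional coverage strictly greater than 0.80 — a subject covers a
voxel iff its preprocessed series has positive temporal SD — and, for
WM, exclusion of a subcortical mask supplied as a generic binary image.
Strict inequalities follow the "more than X%" wording of the protocol.

## Coupling

The coupling map is ALFF divided by the tissue-density (VBM) value,
voxel-wise, on a shared grid (a same-grid contract replaces
co-registration; affines must agree to 1e-4). Densities below a floor
of 0.1 are removed from the coupling mask and counted, rather than
producing unbounded ratios that would dominate the group statistics.
Group analysis of coupling is restricted to voxels where *every*
subject clears the floor, so the same voxel set enters all subjects'
statistics.

## Group inference

**ANCOVA.** The voxel statistic is the partial F for the group factor
given age, gender and education: full model (intercept, 2 group dummies,
3 centered covariates) vs reduced (covariates only), df = (2, n − 6).
Residuals of the full model feed the smoothness estimator.

**Smoothness.** Residuals are normalized to unit sum of squares across
images per voxel; for each axis the mean squared forward difference of
the normalized residuals estimates the derivative variance Λ of the
unit-variance component field, and FWHM = √(4 ln 2 / Λ) voxels. RESELs =
mask voxels / ∏FWHM. The simple gradient form (no Gaussian-ACF
inversion) is used deliberately: it recovers applied smoothing within
~10 % at 2-voxel FWHM and degrades gracefully to ≈ 1.18 voxels on white
noise, whereas an exact ACF inversion is undefined there.

**Cluster correction.** The F map is thresholded at the F quantile of
voxel p < 0.001; connected components use 26-connectivity (configurable
6/18). Each cluster's family-wise p uses the unified RFT formulation:
expected cluster count m = RESELs × ρ₃(u) with ρ₃ the 3-D
Euler-characteristic density *of an F field* with the map's degrees of
freedom (verified against the Gaussian limit F(1,∞) = Z²); expected
suprathreshold volume S·P(F > u); extent distribution
P(extent ≥ k resels) = exp(−βk^{2/3}) with β = (Γ(5/2)·m/E[N])^{2/3};
corrected p = 1 − exp(−m·P(extent ≥ k)). Only the 3-D EC term is used
(boundary terms omitted — exact for the periodic fields of the
calibration studies, a small approximation for real masks). An earlier
formulation that Gaussianized the F values and applied the Gaussian EC
density was rejected because the permutation oracle showed it ~10×
conservative for marginal clusters.

**Permutation oracle.** Freedman–Lane: fit the covariates-only model
once, permute its residuals, add back the reduced fit, recompute the F
map, and build the null distribution of the maximum suprathreshold
cluster size; corrected p = (1 + #{perm max ≥ observed})/(n_perm + 1).
This is the distribution-free arbiter for the RFT p-values.

**Post-hoc contrasts.** For each significant cluster, all three group
pairs are tested two ways on the per-subject cluster means: a
covariate-adjusted t (the group-indicator coefficient in an OLS with
centered covariates; constant covariates are dropped, so with no
covariate variation this reduces exactly to the two-sample t) and a
Mann–Whitney U. The U statistic reports the min(U, n₁n₂−U) convention;
p-values use exact enumeration up to group size 20 without ties and the
tie-corrected normal approximation otherwise. Mann–Whitney is the
default for the cluster table (the nonparametric route matches the
U-statistic style of the published cluster report; the parametric route
is also reported). The primary p is Bonferroni-corrected by the number
of significant clusters in the omnibus map, with significance at
0.05/n.

**Clinical correlations.** Pearson r between cluster means and MMSE
within each patient group, with the exact conversion
t = r√((n−2)/(1−r²)), p two-tailed on n−2 df. This closed form
reproduces all four published r→p pairs to the printed precision.

## Synthetic cohorts

The generator produces what the analysis consumes, with known ground
truth, directly on the 3 mm analysis grid (simulating native-space EPI
plus normalization would add nothing to correctness testing):

- **Anatomy**: a concentric "head" — CSF core, WM band, GM shell,
  background — via radial Gaussian profiles perturbed by a per-subject
  smooth random field (SD 0.05), probabilities capped to sum ≤ 0.98,
  plus a fixed "subcortical" blob for exclusion-mask testing. Anatomy
  realism is irrelevant to correctness; topology (disjoint ribbons,
  partial-volume boundaries) is what the mask logic needs.
- **BOLD**: per voxel, a sum of randomized-phase sinusoids at every DFT
  bin in 0.01–0.1 Hz with amplitude = tissue baseline (GM 1.0, WM 0.6,
  CSF 0.3) × a per-subject factor (1 + N(0, 0.1)), plus white noise
  (SD 0.2). TR 2.2 s, 164 time points, matching the acquisition the
  analysis targets. Because every in-band bin carries the same
  amplitude, noiseless ALFF equals the configured amplitude exactly.
- **Motion**: random-walk jitter (0.01 mm translations; rotations
  scaled by 1/50 so their FD contribution matches) plus persistent
  translation steps of 2 mm at spike frames (rate 0.02/frame), which
  the FD > 1 mm rule flags at exactly the stepped frame. Flagged frames
  also get a global intensity offset, which the spike regressors remove
  exactly.
- **Effects**: spherical regions with per-group deltas — "alff" and
  "coupling" effects add the delta to the band amplitude (coupling
  moves because density does not), "vbm" effects subtract it from
  tissue density (atrophy).
- **Phenotype**: ages ≈ N(74–76, 8²) per group, binary gender,
  education ≈ N(14.5, 2.5²) truncated at 8 years, CDR 0/0.5/1, MMSE =
  group baseline (28.9/26.0/22.1) + slope × (latent regional coupling −
  cohort mean) + N(0, residual SD), clipped to [0, 30]. The latent
  coupling is the generative amplitude/density ratio, so the configured
  link survives estimation noise at realistic settings.
- **Reproducibility**: subject k draws from `default_rng([seed, k])`, so
  any subject regenerates in isolation; MMSE is assigned after the
  cohort exists (it needs the cohort-mean coupling) from noise drawn
  inside each subject's stream.

What the generator does **not** emulate: scanner artifacts, slice
timing, susceptibility distortion, spatial autocorrelation of the BOLD
noise (voxel phases are independent; spatial smoothness enters through
the pipeline's own smoothing), physiological noise spectra, real
anatomy or atlases. Passing tests therefore demonstrate correctness of
the computations and calibration of the inference under the stated
model — not robustness to real-data artifacts.

## Study sizes in the validation suite

The calibration and recovery studies (shared by the test suite and
`scripts/acceptance.py`) use: 100 random series (t = 159, TR 2.2) for
the ALFF–DFT comparison; 500 null simulations on a 40³ periodic grid at
8 mm FWHM (3 mm voxels) with per-simulation smoothness estimated from a
12-field companion stack for the family-wise error rate; one
30-subject dataset with a strong (1.8 SD, radius-5) ordered regional
effect and 1000 permutations for the RFT-vs-permutation comparison —
evaluated at decisively significant clusters, because a
1000-permutation p has resolution ≈ 0.001 and Monte-Carlo SD ≈ 0.005,
so sub-0.01 agreement is only meaningful away from borderline p; and 20
replicate cohorts (30/group, 16³ grid) for end-to-end recovery of a
d = 1.5 coupling increase. The effect region there is a radius-3-voxel
sphere in the WM band: large enough that its interior retains the
nominal effect under 4 mm within-mask smoothing, and yielding detected
cluster extents (≈ 7–56 voxels) bracketing the mid-size clusters of the
published report. The d = 1.5 shift is standardized by the generator's
between-subject regional-amplitude SD, which slightly understates total
between-subject coupling variability — the realized standardized effect
is conservative.

## Known limitations

- **Cluster-level RFT is conservative at low smoothness.** On ideal
  null lattices at FWHM ≈ 2.7 voxels the EC density overpredicts
  cluster counts (≈ 28.5 vs ≈ 19.7 observed; lattice discretization and
  26-connectivity merging) and the exponential extent tail is ≈ 2.5×
  heavy near 2 RESELs, so the true family-wise rate at nominal 0.01 is
  ≈ 0.004. This matches the literature on the extent approximation and
  persists at finer voxel sampling; the permutation route is exact by
  construction and is the recommended arbiter when calibration matters.
- The smoothness estimator omits the small-sample residual-dof
  correction; with ≥ 10 images the bias is within the tolerances the
  recovery studies verify.
- Post-hoc contrasts and correlations use cluster means selected by the
  omnibus map on the same data (circularity inherited from the source
  design); they describe, not confirm.
- The coupling denominator floor (0.1) and the background floor (0.05)
  are conventions; results near partial-volume boundaries depend on
  them, which is why both are configurable and logged.
- MMSE is generated (and analyzed) as a continuous score; real MMSE is
  an integer scale with ceiling effects that the clip at 30 only
  partially mimics.
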