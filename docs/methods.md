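# Methods

## Overview

`longvbm` implements a two-timepoint longitudinal voxel-based morphometry
(VBM) pipeline and exercises it end to end on synthetic brain phantoms with
known atrophy ground truth.  The package has three layers: a cohort
generator (`phantom`), the image-processing chain
(`registration`, `segmentation`, `morphometry`, orchestrated by
`pipeline`), and the cohort statistics (`cohort_stats`).

## The phantom generator

### Geometry

The template brain is an asymmetric ellipsoid (per-axis radii 0.80, 0.70
and 0.76 of the half field of view; 48³ voxels at 1 mm isotropic by
default) built from concentric shells: a CSF rim (normalized radius
0.84–1.0), a cortical GM ribbon (0.60–0.84), a WM core, and a central
ventricular CSF cavity (inside 0.30) that provides a pure-CSF reservoir —
without it every CSF voxel is partial volume and no intensity model can be
anchored.  Two spherical deep-GM blobs embedded in the WM carry the
reserved hippocampus labels.  Shell boundaries are sigmoids of the signed
distance (half-width 0.3 mm), normalized by |∇ρ| so the edge has the same
physical width everywhere; with this construction the soft GM prior
integrates to the hard-geometry volume to better than 0.5%.  The distinct
ellipsoid radii matter: a spherical brain makes rotations unidentifiable
for registration, and radii are kept below 0.8 of the field of view so a
±3 mm session offset cannot push the head outside the acquisition grid.

The cortical ribbon is split into angular sectors (10 by default, 5
azimuthal × 2 hemispheres), labels 1..10, with the hippocampi as labels
101/102.  Parcels cover voxels with GM prior > 0.25: the faint sigmoid
tails are excluded so that the atrophy process (applied parcelwise, see
below) does not touch voxels bordering the longitudinally stable CSF rim
on which the session-bias estimate relies.

### Atrophy model

Atrophy is probability-mass transfer from GM to CSF in template space,
before any rigid offset, so ground-truth volumes are exact and the
per-voxel tissue total — hence total intracranial volume — is conserved by
construction.  The applied rate for parcel *p* in %/yr is

    r_p = base_p · (sex multiplier if female) + accel_p · (age − 65)
          + shared subject jitter + parcel jitter,   clipped at 0

Defaults are the study conditions of a large community aging cohort:
cortical base rates spanning −0.2 to −1.1 %/yr, hippocampal base
−0.67 %/yr, female multiplier 1.4, hippocampal age acceleration
−0.03 %/yr per year of age (global acceleration 0), a +0.14 %/yr slower
loss in HRT-treated women, shared subject jitter 0.5 %/yr and parcel
jitter 0.1 %/yr.  With the cohort's covariate
distributions these yield a cohort-mean global rate near −0.84 %/yr and a
hippocampal rate near −1.05 %/yr, and a women:men rate ratio near 1.4.

### Covariates and acquisition nuisances

Covariates follow the study-entry table of the emulated cohort: 742/1172
women, age 72 ± 4 years truncated to [65, 82] (per-sex means 72.0/72.3),
hypertension 83.8% (men) / 69.5% (women), HRT in 166/491 women, education
10.7 ± 4.6 (men) / 9.2 ± 4.0 (women) years rounded and clipped to [0, 17],
follow-up interval truncated-normal (3.6 ± 0.3 years in [3.0, 4.5]) with
actual scan dates written so intervals are computed at 365.25 days/year.

Each scan sees the anatomy through its own head position: the follow-up
session carries the full rigid offset (|rotation| ≤ 3°, |translation| ≤
3 mm, uniform) and the baseline a sub-voxel jitter.  This symmetry is
deliberate: a baseline sampled exactly on the template grid would be
artificially sharper than the resampled follow-up and the interpolation
asymmetry alone biases longitudinal differences.  Intensities are composed
from a tissue-contrast table (T1: WM 1.0 > GM 0.7 > CSF 0.25; T2: CSF
1.0 > GM 0.55 > WM 0.4; background 0.02 — chosen so that GM and CSF have
equal T1+T2 sums, which makes the TIV-conservation invariant directly
testable on the images), multiplied by a session-specific bias field
exp(quadratic polynomial, coefficients N(0, 0.05²)), plus Gaussian noise
with σ = 2% of the channel's brightest tissue mean.

The rate-level generator (`simulate_rate_table`) reproduces the same
atrophy model without imaging, including log-normal head-size variation
(5% CV) and the cross-sectional imprint of aging: baseline volumes carry
the rate model integrated from age 65 to the baseline age (linear in age
for constant rates, quadratic where the rate accelerates), anchored at the
cohort mean age.  This gives the generator the paper-like cross-sectional
behaviour — a slightly attenuated OLS age slope relative to the
longitudinal rate, a noisier shifting-window estimate, and a
quadratic-in-age signature that appears in hippocampal but not global
volumes.

## The measurement chain

Per subject: (1) rigid alignment of the follow-up T1 to the baseline T1;
(2) session-bias matching; (3) nonlinear normalization of the baseline GM
map to the GM prior; (4) reapplication of the single warp (composed with
the rigid for the follow-up) to all four images in one interpolation pass;
(5) tissue-fraction estimation per session; (6) the common intracranial
intersection and optimized CSF; (7) Jacobian modulation; (8) volume and
rate integration.  Within-session T2→T1 alignment is available (normalized
mutual information) but skipped by default for phantom data synthesized on
a shared per-session grid.

### Rigid registration

Same-contrast alignment is Levenberg–Marquardt on the intensity residuals
with an analytic Jacobian, multi-resolution (2 levels, stride-2 fine
sampling), with cubic (pre-filtered B-spline) interpolation inside the
residuals — trilinear interpolation smooths one side of the comparison
only and displaces weakly identifiable modes by ~0.1°.  A quadratic
log-intensity-ratio nuisance field is estimated jointly with the six rigid
parameters: session-specific bias otherwise displaces the SSD optimum by
degrees.  The nuisance field is discarded; only the transform is kept.
Cross-contrast alignment uses Powell descent on 32-bin normalized mutual
information.  Capture range is a few degrees and millimetres, which
covers the generator; translations recover to ~0.01 mm and rotations to
~0.15° on noise-free textured phantoms (the pure z-rotation of the smooth
ellipsoid is the weakest mode).

### Nonlinear normalization and Jacobians

The warp is an affine followed by a displacement field in a separable
DCT-II basis written in normalized grid coordinates, so coefficients
transfer unchanged across resolutions; K = 8 gives the classic 8×8×8
basis with 1,536 parameters.  The affine stage is a bounded trust-region
least-squares fit (rotations ±0.1 rad, log-scales ±5%, shears ±5%,
translations ±10 mm): smooth ellipsoidal brains are nearly
rotation-symmetric and an unbounded fit occasionally wanders to a rotated
or rescaled near-symmetry that destroys downstream ROI volumes.  The DCT
stage minimizes SSD plus a bending-energy penalty — diagonal in the DCT
basis, since second derivatives of cosines are cosines — by L-BFGS with
the analytic gradient, coarse-to-fine, on images pre-smoothed 8 mm (fit
only).  The pipeline default regularization (1e6) keeps the warp near the
affine for template-born phantoms; the known-warp recovery test uses a
lighter penalty.  Jacobian determinants use the analytic DCT derivatives;
they agree with central finite differences of the closed-form field to
<1e-3 and integrate to mapped-region volumes to <1%.  The normalization
source is the baseline GM *fraction* map, whose partial-volume profile
matches the soft prior (a saturated EM posterior does not).

### Tissue quantification: why unmixing instead of classification

The generator's atrophy is uniform probability scaling within parcels, so
a pure-GM voxel's intensity changes by only (rate·Δt)·(μ_GM−μ_CSF) ≈ 1–2%
— far inside the flat part of any classification posterior.  EM
classification both saturates (posterior ≈ 1 regardless of a 3% mixture
shift) and absorbs the shift into its refitted class means; measured rates
were ≈ 0.  The pipeline therefore estimates per-voxel tissue volume
fractions by exact linear unmixing: with two channels plus the sum-to-one
constraint, exactly three classes are identifiable per voxel, and the
3×3 system is solved in closed form.  Per-voxel class support admits
GM/WM/CSF wherever the background prior is < 0.01 (atrophy can create CSF
anywhere inside the brain, so CSF must never be dropped there) and
GM/CSF/background at the brain edge (WM never borders the skull).  The
support rule matters: selecting the smallest-prior class instead silently
erased longitudinal signal, and admitting tissue where background is
present fabricates GM at ~10× amplification — the 2-channel 3-class
inverse has determinant ≈ 0.07 and is proportionally ill-conditioned.
Fractions are returned unclipped so integrals stay mean-unbiased under
noise; masks and labels clip or argmax them.

The class means are calibrated once per subject by regressing the baseline
intensities on the prior tissue fractions (`fit_intensity_model`) — exact
when the priors describe the session's anatomy, and robust for thin
structures where no pure voxel exists — and held fixed for both sessions
so longitudinal change cannot be absorbed into the means.  EM
classification (`segment_tissues`) remains the mask path: the
multi-spectral posteriors define the per-session intracranial masks, whose
voxelwise intersection is the common intracranial space (TIV assumed
constant), and the optimized CSF is that space minus GM and WM.  Tissue
volumes are integrated within the common mask — identical for both
sessions, so masking cannot bias rates.  Passing `class_params` to
`segment_tissues` computes the one-shot Bayes posterior under the
calibrated model, the preferred classification (free EM lets the CSF mean
drift into rim partial volume).

### Session-bias matching

Scanner bias differs between sessions and the unmixing amplifies a
percent-level differential into tens of percent of regional volume.  The
two sessions are compared in the halfway frame (each resampled once
through a half-magnitude transform, so interpolation smoothing is
symmetric — resampling one side only dims the thin CSF rim on that side
and masquerades as a bias gradient).  The log intensity ratio is
aggregated over 6³-voxel blocks of longitudinally stable voxels (deep WM,
CSF rim; block sums are effectively noise-free, killing the Jensen bias of
per-voxel log ratios), fitted as a quadratic polynomial — the generating
family — and divided out of the follow-up in its own frame.  The
baseline's own bias, then shared by both sessions, cancels in the rate
difference.  One fixed-point refinement pass subtracts the anatomical
intensity change implied by first-pass parcel rates from the fitted ratio,
removing the residual leak of true atrophy into the stable set to second
order.  A dense per-session bias removal (fitting the whole brain against
the model prediction) was evaluated and rejected: it distorts
deep-structure volumes whenever priors and anatomy disagree locally.

### ROI integration

Parcel volumes integrate the modulated GM map against Gaussian-softened
(1.5 mm FWHM) label indicators rather than hard masks: the resampling
chain spreads roughly a voxel of tissue mass across label borders, and a
hard boundary systematically loses the displaced mass of small structures
such as the hippocampus.  Softening preserves each indicator's own
integral, so large-parcel volumes are essentially unchanged.

## The statistical layer

* `fit_rate_ancova` — OLS with sum-to-zero sex coding, age centered at 65,
  sex×age interaction, covariates education/hypertension/TIV; type-III
  partial F tests.  Coefficients equal normal-equation solutions exactly.
* `fit_quadratic_age` — the same design with and without (age−65)²; the
  quadratic coefficient is tested against zero.
* `voxelwise_glm_fwe` — per-voxel GLM contrast with max-|t| permutation
  (Freedman–Lane residual permutation; sign-flipping for one-sample
  designs; corrected p = rank in the max-null) or Bonferroni.  Calibration
  at the nominal 5% familywise level is regression-tested on 200 null
  replicates.
* `shifting_window_slope` — mean volume per 1-year age bin, slope = mean of
  adjacent-bin differences (gap-scaled over empty interior bins), with the
  OLS slope alongside for the attenuation comparison.
* `matched_subsample_compare` — greedy nearest-neighbour caliper matching
  (0.25 SD per standardized variable, up to 2:1) with a post-match
  standardized-mean-difference gate (< 0.1) and a Welch test on the
  matched groups.

Permutation (seeded) rather than random-field theory provides the FWE
control; Bonferroni is the deterministic cross-check.  For pattern
analyses on the rate-level generator, percent rates are the response of
choice: absolute cm³/yr rates additionally carry the age trend of the
shrinking baseline volumes, which is real but not part of the planted
rate process.

## Problem sizes and numerical choices

Default phantoms are 48³ at 1 mm (not acquisition-sized grids) so a full
cohort runs in minutes; the acceptance script uses a 48-subject imaging
cohort and the full 1,172-subject rate-level cohort for statistics.
Tolerances: rigid LM xtol/ftol 1e-10; DCT stage L-BFGS ftol 1e-5 (1e-9 in
recovery tests), 24 iterations per level in the pipeline; EM convergence
1e-6 relative log-likelihood over ≤50 iterations with a variance floor of
1e-6 of the data variance and quantile re-initialization when flat priors
leave all class means equal (a symmetric EM fixed point).  Intracranial
masks binarize at 0.5.  All randomness flows from explicit integer seeds;
per-subject seeds derive from the master seed by `SeedSequence` spawning
and stay below 2³¹.

## What passing tests do and do not show

The generator emulates contrast, noise, smooth bias, head repositioning
and region-specific atrophy with exact ground truth, but not MR physics
(no k-space artefacts, motion ghosting, distortion), no white-matter
hyperintensities or lesions, no anatomy beyond the shell geometry, and no
inter-subject anatomical variability (all subjects share the template
anatomy, so nonlinear normalization is exercised only near the identity).
Recovery results therefore demonstrate the internal consistency and
calibration of the measurement and inference chain under controlled
conditions, not performance on real scans.

## Known limitations

* The design is baseline-anchored (one warp fitted at baseline, follow-up
  resampled once more than baseline), which is asymmetry-bias-prone; the
  generator's symmetric session jitter and the halfway-frame bias matching
  mitigate but do not remove this.
* Regional rate recovery carries residual parcel-specific systematic
  errors up to ~1 %/yr at the default noise/bias levels, from the
  interaction of session-bias matching, interpolation point-spread and the
  sector geometry; the global rate is recovered with |bias| < 0.1 %/yr.
  The regional errors are documented honestly by the rate-recovery
  acceptance test rather than hidden by looser tolerances.
* Fraction unmixing needs both channels; a T1-only pipeline cannot
  separate GM loss from WM change at partial-volume voxels.
* The hippocampal stand-ins are ~0.1 cm³ blobs; their percent rates are
  the noisiest outputs (≈2 %/yr per-subject scatter at default noise).
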