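# Methods note

This note records the model, the numerical choices, and the limits of the
synthetic validation study implemented by `tenoquant`. It states what the
code computes and why; every empirical claim here is one the test suite or
the `scripts/acceptance.py` run actually computes.

## Problem and measurement model

Tenosynovitis — inflammation of the synovial sheath around a tendon — appears
on fat-saturated T1-weighted gadolinium-enhanced (T1-Gd) wrist MRI as bright
enhancing tissue wrapped around dark tendons. The clinical reference standard
is a semi-quantitative visual grade per tendon compartment (0–3, by maximum
sheath thickness: 0 none, grade 1 below 2 mm, grade 2 from 2 to 5 mm, grade 3
at 5 mm and above). The package replaces the visual grade with a continuous
measurement: the fraction of voxels in a peritendinous measurement region
whose soft membership in the enhancing-tissue intensity cluster falls inside
a calibrated window.

The pipeline has five stages:

1. **Super-resolution reconstruction (SRR).** Two anisotropic scans are
   acquired: axial (3 mm slices, 0.3 mm gap, so 3.3 mm through-plane
   sampling along z) and coronal (2 mm slices, 0.2 mm gap, 2.2 mm along y).
   The forward model `A_k` for scan `k` is separable per axis: through-slice,
   each output sample is the box average of the high-resolution volume over
   the slice-thickness window (the gap contributes to no slice); in-plane,
   the window is the voxel extent. The isotropic volume `x` minimizes

       sum_k ||A_k x - y_k||^2 + lambda ||L x||^2,   lambda = 0.05,

   where `L` is the 6-neighbor graph Laplacian. The normal equations are
   solved by conjugate gradients starting from the mean of the linearly
   upsampled inputs.

2. **Multi-atlas landmarking.** Each atlas case (image plus reference label
   map: 10 tendon compartments, carpal mass, hamate, radius, ulna) is
   affinely registered to the reconstructed volume (mean-squared-difference
   metric, multi-resolution, full deterministic sampling); its labels are
   carried over by nearest-neighbor resampling, and the per-case candidates
   are fused by per-voxel plurality vote with ties — including ties with
   background — resolving to background. Left wrists are handled by
   mirroring the right-wrist atlas. A registration that cannot improve on
   the identity transform falls back to identity rather than dropping the
   case.

3. **Watershed tendon refinement.** Atlas labels are landmarks, not
   boundaries. Markers are the fused tendon labels eroded by 0.4 mm
   (physical distance, via the Euclidean distance transform); the outside
   marker is the complement of the 1.0 mm dilation of the tendon union. The
   Gaussian gradient magnitude (sigma 0.3 mm) is flooded from these markers.
   A resulting region is rejected if its mean intensity exceeds 75 (tendons
   are dark on T1-Gd) or its volume is below 0.01 ml.

4. **Measurement ROI.** The ROI is every voxel within Euclidean distance
   D of a segmented tendon (inclusive), excluding all labeled structures,
   restricted to the skin-bounded hand extent (corner-seeded background
   growing, largest foreground component) and to the axial slice range
   between the slice where radius and ulna are closest in-plane (ties to
   the most distal slice) and the slice with the most hamate voxels (the
   hook of the hamate; ties to the most distal slice).

5. **Quantification.** A two-cluster fuzzy C-means (fuzziness m = 2) is
   fitted to all voxel intensities of the reconstructed volume. With C2 the
   higher-center cluster, the one-sided C2 map keeps the C2 membership where
   intensity is at or above the C2 center and is zero below it. The
   measurement is the fraction of ROI voxels with `T_L <= p_C2 < T_H`
   (half-open window). The upper bound matters: fully-enhancing voxels with
   membership near 1 are vessels and effusions, not sheath inflammation,
   which sits at intermediate memberships.

Free parameters (D, T_L, T_H) are calibrated by exhaustive grid search —
D over {1,…,6} mm, thresholds on a 0.01 grid with `T_L < T_H` — maximizing
the Pearson correlation between the measurement and the total visual score
over a stratified training set (patients binned by their maximum per-region
grade V_max: 0, (0,1], (1,3]; equal counts drawn per bin). The defaults are
D = 3 mm and (T_L, T_H) = (0.82, 0.94). Locked parameters are then evaluated
on the held-out patients.

## Synthetic phantom and study design

No imaging data ships with the package; validation runs on a parametric
wrist phantom:

- Ten tendons (six extensor compartments dorsally, four flexors volarly) as
  tubes with a gentle sinusoidal in-plane meander along z (amplitude 2.5% of
  the field, period twice the field, staggered phases), so the anatomy is
  genuinely three-dimensional and through-plane resolution matters.
- An ellipsoidal carpal mass with a hamate, and converging radius/ulna tubes,
  giving the boundary rules real targets.
- Tenosynovitis as an annular sheath of nominal thickness w around selected
  tendons, painted at enhancing-synovium intensity; w maps to the visual
  grade through the same thickness bands the readers use.
- Bright vessel-like tubes near tendons (the main source of false
  enhancement), a hand ellipse of intermediate tissue, air background.
- Gaussian edge smoothing (0.4 mm) band-limits the piecewise-constant
  geometry before noise is added. This is deliberate: ideal step edges have
  unbounded high-frequency content that no 0.05-regularized reconstruction
  should be expected to reproduce, and real anatomy is band-limited by the
  scanner's point-spread function anyway. Zero-mean Gaussian noise (sd 5)
  is added and intensities are clipped at zero.
- Per-patient pose jitter (translation up to 1.5 mm, scale 0.96–1.04) so
  registration does real work.

Visual scores are derived from the nominal sheath thicknesses; an optional
two-reader noise model perturbs each grade by ±1 with probability 0.1 per
reader and averages, landing scores on the half-grid as averaged human
scores do.

A study cohort (default 30 phantoms, seed-determined) spans the three
severity categories in equal proportion; three clean phantoms form the
atlas. Generator defaults are the study conditions — they are not tuned
per run.

## Numerical choices

- Forward operators are sparse per-axis averaging matrices with rows
  normalized to one, so constants are preserved exactly; the adjoint is the
  product of transposes. A scan sample at the grid border whose window
  misses every target cell (possible because the target extent is truncated
  to whole cells) replicates the nearest target sample instead of erroring.
- The graph Laplacian uses the negative-sign convention with replicate
  boundaries; it is symmetric, so the regularizer's normal-equation term is
  `lambda L^2`.
- CG tolerance is on the relative residual of the normal equations (1e-6);
  the objective is tracked every iteration and is non-increasing.
- FCM initializes centers at the 25th/75th intensity percentiles, making the
  fit deterministic; equivalence with a 100-restart brute-force fixed-point
  oracle is part of the acceptance suite.
- The threshold sweep uses per-patient membership histograms binned at the
  threshold step (values on a bin edge land in the upper bin), so every
  window fraction is an exact count ratio and the 5 050-window sweep is
  independent of image size. Grid-search ties resolve to the
  lexicographically smallest (D, T_L, T_H).
- All randomness flows from a single seed through named sub-seeds; pipeline
  outputs carry no timestamps, so reruns are byte-identical.

## Limitations

- The phantom is a geometric caricature: no bone marrow texture, no motion,
  no bias field, no partial-volume model beyond box averaging, and its
  intensity classes are cleanly separated. Correlations achieved on it are
  upper bounds, not estimates of clinical performance.
- Affine registration suffices for a rigid phantom with pose jitter; real
  wrists need deformable refinement.
- The z-elongated tube geometry leaves the registration's z-scale weakly
  determined; the watershed refinement absorbs the resulting 1-voxel-scale
  landmark error.
- Visual-score simulation reads the nominal sheath thickness, not a
  measured one, so reader behavior (anchoring, compartment confusion) is
  modeled only by the optional ±1 noise.
- The calibrated window is specific to the phantom's intensity
  configuration; on clinical data it must be re-calibrated against visual
  scores, exactly as the grid search implements.
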