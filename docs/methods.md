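# Methods

## The two-stage multivariate linear method

The package implements a design-constrained eigen-decomposition for
two-group discrimination from multimodal MRI. Stage 1 operates per
modality on a subjects × voxels feature matrix `Y`:

1. residualize `Y` and the ±1 group code `g` on the nuisance block
   `X_n = [1, age_z, sex_01, tiv_z]` (ordinary least squares);
2. project the adjusted data onto the adjusted group direction
   (`Ŷ = P_{g_adj} Y_adj`) — this is the subspace an F test of the group
   difference constrains the solution to;
3. take the SVD of `Ŷ`. With a two-level group factor the projection has
   rank one, so exactly one component can be informative: its right
   singular vector is the modality's eigen-image (unit Euclidean norm),
   the squared singular value its eigenvalue, and the predicted/empirical
   subject scores are the left-singular and data-side projections.

For balanced groups without covariates the eigen-image reduces in closed
form to the normalized difference of the group mean maps; this closed form
is used as an oracle in the tests. The sign of each component is fixed so
the first group's mean predicted score is non-negative, which makes
results reproducible across platforms; a fully null component is stored as
a zero row rather than an arbitrary unit vector.

Stage 2 stacks the per-modality unit-norm signatures into an M × V matrix
and decomposes it by SVD. The group contrast is *not* re-applied: the
signatures already live in the group-difference space, and stage 2
partitions their shared and unique structure, which is what allows up to
M = 3 informative components despite the rank-1 two-group contrast.
Signatures are unit-normalized so no modality dominates through scale.
Contributions are reported signed (columns of the left singular matrix,
sign fixed so the largest-magnitude entry per component is positive) and
as squared shares, which form a probability vector per component.
A modality whose stage-1 result is null enters as a zero row with a
warning and the fusion proceeds on the remaining rank.

**Duality.** The voxel space and the component/load space are two
coordinate systems of one decomposition: the load-space route
(`fit(method="scores")`) eigendecomposes the M × M Gram matrix of the
signatures and maps back to voxel space by the dual transform
`w_k = Aᵀ u_k / s_k`, expressing fused subject loads through the stage-1
subject scores. Its eigenvalue spectrum is identical to the image-space
route by construction; contributions and eigen-images agree up to
per-component sign, and only inside exactly degenerate eigenspaces are
components defined merely up to rotation. A naive SVD of the raw empirical
score matrix would *not* reproduce the image-space result (on noise-free
data every modality's empirical score vector is proportional to the
adjusted group indicator, collapsing the score matrix to rank one), which
is why the dual-transform formulation is used.

**Informative components.** An eigenvalue counts as non-null when it
exceeds `1e-6` times the largest (with an absolute floor of `1e-12` on the
largest). The relative tolerance sits well above float64 rounding noise
and well below any genuine component produced by the generator; note that
under measurement noise three signatures are never exactly collinear, so
identical *planted* patterns still yield three non-null (if very unequal)
eigenvalues — exact rank collapse occurs only for exactly identical
signature inputs.

## First-level features

* **Task fMRI.** OLS GLM with one boxcar-convolved regressor per condition
  (canonical double-gamma HRF: gamma shapes 6 and 16, unit dispersions,
  undershoot ratio 6, 32 s kernel — the de-facto standard; sampled from
  the closed form so kernels at different TRs agree at shared times), six
  motion covariates and an intercept. The subject feature is the omnibus F
  over all conditions, orthogonal to the motion effect: the tested
  design-space directions are the condition columns with their
  nuisance projection removed, and the statistic is computed as the
  extra sum of squares through an orthonormal basis of those directions —
  algebraically the classical contrast quadratic form, but stable when
  regressor scales differ by orders of magnitude. An `effects` mode
  returning the per-condition effect maps is available because either
  image type can reasonably feed the stage-1 decomposition.
  No autocorrelation whitening, drift model or slice-timing correction is
  applied; series are assumed realigned, normalized and dummy-trimmed, and
  a length/paradigm mismatch is a hard error rather than a silent trim.
* **Resting fMRI.** Residual mean square (RSS/dof) after a nuisance-only
  fit (intercept + optional motion). There are no events to convolve, so
  no HRF enters the resting model.
* **Structure.** Gray-matter maps smoothed with an 8 mm FWHM Gaussian
  (sigma = FWHM/2√(2 ln 2) per axis in mm, reflected boundaries — this
  preserves constants and total mass on small grids). TIV in ml is the
  voxel volume times the summed GM+WM+CSF maps when tissue maps are
  supplied, otherwise it comes from the subject table.

## The synthetic study

The generator emulates the data shape the pipeline assumes, not MRI
physics. Defaults define the study conditions:

* two groups of 19 and 25 subjects; ages uniform 25–60 y, sex
  balanced-random, TIV ~ N(1500, 120) ml;
* one shared 24³ grid of 3 mm voxels; a feathered spherical brain template
  (amplitude 5 arbitrary GM units);
* one planted pattern per modality: spherical blobs (7.5 mm core,
  2.4 mm Gaussian feather truncated at 2.5 sigma) placed 120° apart well
  inside the brain, so at overlap 0 their supports are disjoint; the
  `overlap` knob linearly interpolates all patterns toward one shared
  central blob (identical at overlap 1);
* structural maps: template + 0.5·group·amplitude·pattern + age/sex
  effects on a separate nuisance blob + N(0, 1) noise, floored at zero
  (GM maps are non-negative; at the default template amplitude the floor
  is almost never reached);
* task series: 312 volumes at TR 2 s — four cycles of 32 s
  DS/DN/PS blocks each followed by 20 s rest — with activation amplitude
  `1.0 + 0.5·group·amplitude` on the task pattern and unit noise. The
  printed acquisition length of the emulated protocol (256 volumes) is
  inconsistent with twelve full 32 s + 20 s blocks; the paradigm
  structure was kept and the volume count made self-consistent;
* resting series: 187 volumes of pure noise whose standard deviation is
  `1 ± 0.25·effect·pattern` by group, so the residual-mean-square feature
  carries the group signal exactly on the resting pattern's support;
* motion: six lightly smoothed random-walk traces (they enter the designs
  but no motion artifact is injected into the series);
* atlas: nearest-seed-point tessellation into 114 contiguous regions.

One master seed drives named independent substreams per subject and
modality, so adding a subject never perturbs existing data and any volume
can be regenerated in isolation.

What the generator does *not* emulate — spatial autocorrelation of scanner
noise, physiological fluctuations, registration error, anatomical
variability — means passing tests demonstrate the estimator's algebra,
calibration and recovery behavior under the assumed model, not performance
on real scanner data.

Expected recovery under the defaults follows
`|r| ≈ sqrt(S / (S + N))` with `S` the pattern energy and `N` the
accumulated per-voxel noise of the adjusted group difference; the default
geometry puts all three modalities at `|r| ≈ 0.9–0.97` for 20 subjects per
group, which is what the recovery tests check (≥ 0.8 in ≥ 18/20 seeds).

## Pipeline and numerical choices

* All modalities must share one grid; a mismatch is a hard error —
  resampling is deliberately out of scope.
* The analysis mask is the structural mean above 20% of the template
  amplitude, intersected with finite-and-varying voxels of every modality's
  features. Masks index voxels 0-based in row-major order, making
  matrix/volume round trips bit-exact.
* Covariates: continuous ones are z-scored (population sd), sex is coded
  0/1 by first appearance, the group ±1 by a deterministic group order;
  missing values are an error naming the subject, never imputed.
* Voxel-wise standardization of `Y` before the decomposition is available
  (`standardize=True`) but off by default.
* Region means are computed over the intersection of each atlas region
  with the analysis mask; regions entirely outside the mask are flagged
  (zero count, NaN mean), not dropped. Ranking is by absolute mean with
  sign retained and stable region-id tie-break.
* Pipeline outputs are deterministic given config + seed; the summary JSON
  is byte-identical across reruns.

## Problem sizes used in the checks

Study-scale checks run the complete pipeline at the default 24³ grid with
19 + 25 (or 20 + 20) subjects. The multi-seed component-count ceiling is
exercised on a reduced profile — 16³ grid, 5 + 6 subjects, two paradigm
cycles, 5 mm blobs — chosen so twenty full end-to-end simulations remain
quick while preserving the study's structure; the ceiling is a rank bound
and does not depend on grid size.

## Known limitations

* Exactly two diagnostic groups; no repeated measures, no more than one
  retained component per modality at stage 1 (the two-group contrast caps
  the rank).
* No permutation-based significance for eigenvalues.
* The resting model is intercept + motion only; any structured resting
  design would need to be added by the user.
* Tied singular values leave the affected subspace defined only up to
  rotation; the sign convention resolves orientation but not rotation
  within exact ties.
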