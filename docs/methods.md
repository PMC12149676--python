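# Methods

## The problem and the models

During adaptive radiotherapy (ART) for head-and-neck cancer, a mid-treatment
CT must be re-contoured while the patient's *pre-treatment* CT and approved
contours are already on file. `adaptseg` implements four ways of producing
the mid-treatment structure set and the protocol for comparing them:

* **RM** (reference model): a 3D U-Net that sees only the mid-treatment
  image. The baseline every adaptive method must beat.
* **PSM** (patient-specific model): the same image-only network, but the
  test patients' pre-treatment images are pooled into its training set
  (with the total sample count matched to RM by removing an equal number of
  other samples at random). Prior knowledge enters at *training* time, so a
  new model is needed per patient cohort.
* **GAM** (general adaptive model): prior knowledge enters at *inference*
  time. The network input stacks the mid-treatment image, the rigidly
  aligned pre-treatment image, and one channel per aligned pre-treatment
  structure mask (C = 2 + S input channels; 19 for the clinical 17-structure
  set). Training pairs are also used time-reversed (predict pre from mid),
  doubling the sample count and exposing every label at both input and
  output.
* **RIR** (rigid image registration): no learning — the pre-treatment
  contours are propagated through a rigid transform estimated by maximizing
  mutual information between the two images.

All networks share one architecture: a 3D U-Net with four down/up-sampling
levels, two convolution blocks per level (3×3×3 convolution, stride 1,
padding 1 → instance normalization → ReLU), 2×2×2 max-pooling on the way
down, 2×2×2 transposed convolutions with skip concatenation on the way up,
and a final 1×1×1 convolution to S logit channels. Outputs are independent
per-channel sigmoids: structures may overlap anatomically and any structure
may be missing from a given case, so a softmax's mutual exclusivity would be
wrong. Binarization threshold for evaluation is 0.5.

The network and its training loop are implemented directly in
numpy + numba (hand-derived backward passes; the 3×3×3 convolutions are
JIT-compiled kernels on large grids and BLAS shift-gemms on the small deep
grids). Correctness of every gradient is pinned by a float64
finite-difference test.

## Loss and weighting

Training minimizes a hybrid loss, `L = λ_d · L_dice + λ_f · L_focal` with
λ_d = λ_f = 1 (the conventional equal mix for this loss family; both
exposed in `LossConfig`).

* Soft dice per structure: `1 − 2Σpt / (Σp + Σt + ε)`, ε = 1e-6.
* Focal per structure: voxel mean of `−(1−p_t)^γ log p_t` with γ = 2 (the
  focal-loss default), where `p_t` is the predicted probability of the true
  class; γ = 0 recovers binary cross-entropy.

Each structure's terms are weighted by two factors, both normalized to mean
one over the structures:

* **Class weights** `w_s ∝ 1 / presence-frequency` over the training
  samples ("frequency" is per-sample label presence, matching how label
  imbalance is counted in this setting, not voxel frequency).
* **Volume weights** `u_s ∝ 1 / mean structure volume (cm³)` over the
  training labels, applied **only for the first T epochs**
  (`volume_weight_epochs`): long enough to pull small structures to a
  non-zero validation DSC, short enough not to penalize large structures
  for the whole run. At clinical scale T = 200 of 1000 epochs; the
  desk-scale study keeps the same fraction (12 of 60).

Structures absent from a sample contribute nothing to either term and
receive exactly zero gradient; a structure with no labels anywhere in the
training set is excluded with a warning.

Optimization is Adam at learning rate 0.001, batch size 1 (full volumes),
fixed epoch count, no early stopping; the weights of the epoch with the
best mean validation DSC are kept. Augmentation samples one spatial
transform per sample per epoch — translation, rotation (±5°), isotropic
scale (0.8–1.2) — applied identically to every channel (linear for images,
nearest for labels). The translation default is ±50 mm on a clinical
330–500 mm field of view; the desk-scale study uses ±12 mm, the same
~12% of its 96 mm field.

### Training-set bookkeeping

With 110 patients in five folds: each run has 22 test, 18 validation and 70
training patients. RM uses both images of every non-test patient
(176 samples); PSM adds the 22 test pre-treatment images and drops 22
randomly chosen non-test samples (seeded) to match; GAM builds 88 forward
+ 88 time-reversed pairs. The published sample count (176 = 88 × 2) implies
that validation patients' images participate in training and are used for
*model selection* only; that is the package default, and
`strict_split=True` restricts training to the 70 training patients proper
(140 samples). No regime ever sees a test patient's mid-treatment data;
this invariant is asserted on every constructed sample list and raising is
a hard error.

## Rigid registration

Pre-treatment images are aligned to mid-treatment images with a
multi-resolution rigid registration: Mattes mutual information (50 bins),
image pyramid downsampled by 4, 2, 1 (smoothing σ = 2, 1, 0 voxels),
learning rate 1, random metric sampling (fraction 0.5, seeded — the
registration is deterministic given its seed). The optimizer is
regular-step gradient descent (relaxation 0.8, minimum step 1e-5, up to
400 iterations per level) with parameter scales estimated from physical
shift; in development, plain gradient descent at this field of view stalled
within ~10 iterations and left 2–4° rotation errors, while the regular-step
variant recovers poses of ≤10 mm / ≤5° to within 1 mm / 1° in ≥90% of
cases. All knobs live in `RegistrationSettings`. Label maps are always
resampled nearest-neighbour so they remain strictly binary; images are
linearly interpolated with the image minimum (an air analog) as fill.

The estimated `RigidTransform` maps fixed-frame (mid) points to
moving-frame (pre) points — simultaneously the resampling convention and
the phantom's ground-truth convention, so recovered and true transforms
compare directly. Euler angles follow SimpleITK's Z·X·Y composition.

## Label preprocessing

Before any geometry standardization, each present structure mask is
cleaned: interior gaps of up to 5 consecutive empty axial slices are filled
by shape-based interpolation (linear interpolation of the flanking slices'
signed-distance maps, so the midpoint of two identical cross-sections is
that cross-section), then all but the largest 26-connected component is
removed (ties broken toward the lowest label). The gap bound exists because
unbounded interpolation across distant fragments is unsafe; larger gaps are
left and reported. Cleanup precedes resampling so that interpolation
operates on the acquisition's native slices. The full chain —
cleanup → optional rigid resampling of pre onto the mid grid → resample to
target spacing → crop to a fixed physical extent — is idempotent on its own
output, and the clinical defaults are 1×1×2 mm spacing with a
330×400×500 mm crop (which is exactly 330×400×250 voxels).

Cropping fills out-of-field image voxels with the input minimum (CT air
analog) and mask voxels with 0. Crop centers come from configuration or
phantom metadata; automatic anatomical localization is out of scope.

## Evaluation

* **DSC** `2|A∩B|/(|A|+|B|)`; both-empty is defined as 1 (correct
  prediction of absence) and flagged.
* **MSD**: symmetric mean surface distance in mm — the average over both
  directions of the mean nearest-boundary distance, with boundaries defined
  as foreground voxels having a face-adjacent background neighbour and
  distances measured between voxel centers in physical units. An empty mask
  makes MSD undefined; such records are excluded from means and counted,
  rather than assigned an arbitrary penalty distance.
* Predictions are resampled (nearest-neighbour) to the reference image's
  original grid before scoring, and only structures present in the
  reference are scored.
* **Convergence audit**: a structure "converged" in a run if its
  per-epoch validation DSC ever exceeded τ = 0.01 (an operationalization of
  "non-zero validation DSC"; any-epoch max, configurable).
* **Corrected resampled t-test** on per-fold mean score differences:
  `t = d̄ / sqrt((1/k + n₂/n₁) s_d²)` with k−1 degrees of freedom, n₂ test
  and n₁ training patients per run. The correction inflates the naive
  variance `s_d²/k` to account for the overlap of training sets across
  folds, which makes the naive paired test anti-conservative. Two-sided
  p-values; following the comparison-table convention, no multiplicity
  correction across structures. Zero-variance differences are degenerate
  and flagged (p = 1 if d̄ = 0, else 0). Calibration is verified by
  simulation under an equicorrelated null with fold correlation
  ρ = n₂/(n₁+n₂) — the value for which the correction factor is exact.

## The phantom generator

No clinical data ships with the package; every experiment runs on synthetic
paired-timepoint cohorts that copy the *statistical structure* of an ART
replanning dataset:

* a smooth triaxial "head" (air −1000 / tissue 40 a.u.) with three
  unlabeled high-contrast bony nodules. The triaxial radii and asymmetric
  nodules are deliberate: a rotationally symmetric phantom would make the
  inter-timepoint rotation unidentifiable to intensity-based registration,
  which no real head is;
* labeled ellipsoidal structures with per-patient jitter in position and
  radius, spanning the contrasts and failure modes that drive the
  comparison: a high-contrast **bone** (+800, mandible/spinal-cord analog)
  and a low-contrast **plexus** (+60, brachial-plexus analog), both
  displaced between timepoints by a smooth random displacement field
  (band-limited: cubic interpolation of a 3³ control grid, amplitude 7 mm —
  the local, non-rigid motion that defeats rigid propagation but not
  image-driven segmentation), and a **tumor** (+25, barely above the σ = 15
  noise) with large inter-patient position variability (σ = 7 mm) that
  follows only the rigid pose offset and shrinks between timepoints by a
  volume factor drawn from (0.5, 0.8);
* a global rigid pose offset between timepoints (±6 mm, ±3° by default),
  applied analytically: every scene is an implicit-function evaluation, so
  the mid-treatment image *is* the pre-treatment scene composed with the
  stored transform, giving registration an exact ground truth;
* independent voxel noise per timepoint and per-structure missing labels
  (default 5% per structure per timepoint, tumor never missing).

What the phantom does **not** emulate: anatomical shape realism, CT
artifacts, contrast agent, organ-specific volume change other than tumor
shrinkage, and deformations that violate the piecewise-smooth displacement
model. Passing the desk-scale study therefore demonstrates that the
pipeline's machinery — conditioning, registration, losses, bookkeeping,
statistics — behaves as designed, not that clinical-scale accuracy numbers
transfer.

## Desk-scale study sizes and numerical choices

The shipped study (`experiment.run_study`) uses a 10-patient, 32³-voxel
(3 mm isotropic) cohort, two folds, base width 8, 60 epochs, 2 validation
patients per run — sizes chosen so the whole cross-validated comparison
(RM, GAM, RIR) trains in minutes on one CPU core. 32³ is the smallest grid
divisible by 2⁴ with room for the three structures. Registration fixtures
use 56³ at 2 mm, where the nearest-neighbour voxelization ceiling of thin
structures stays above DSC 0.9. The expected direction of results —
GAM ≫ RM on the tumor (an image-only model cannot find a low-contrast,
positionally variable target; the prior makes it nearly trivial), GAM > RIR
on the high-contrast deformed structure (image contrast beats a rigid
prior under local motion), RIR ≈ its shrinkage-bound ceiling 2f/(1+f) on
the tumor — is robust to these sizes; the magnitudes are not
clinical-scale.

Other fixed numerical choices: float32 training precision (float64
available for verification); He-normal weight init, zeros for biases,
seeded; instance-norm ε = 1e-5; focal-loss probability clip 1e-7; CT
intensities clipped to [−1024, 3071] and scaled to [0, 1] before stacking;
binarization of label files at 0.5 on load (tolerates interpolated label
values); pooling-tie gradients routed to the first maximum.

## Known limitations

* Deformable registration is intentionally absent (the comparison's point
  is what rigid alignment plus learning achieves).
* The numpy/numba U-Net targets desk-scale problems; clinical-resolution
  training (width 32, 1000 epochs, ~10⁷ voxel volumes) would require a GPU
  framework behind the same module surface.
* Augmentation treats voxel rotations as rigid, exact only for isotropic
  spacing (the desk phantom is isotropic; anisotropic grids get an
  approximation).
* `comparison_report` markers inherit the no-multiplicity-correction
  convention; with many structures some markers are expected by chance.
* Time-reversed GAM samples reuse the forward pair's rigid alignment
  through its inverse rather than re-registering mid→pre.
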