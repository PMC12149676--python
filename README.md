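# adaptseg

Prior-conditioned auto-segmentation for adaptive head-and-neck
radiotherapy, with its comparator baselines and the full cross-validated
evaluation protocol — runnable end-to-end on synthetic phantom cohorts, so
no clinical data is required.

## The problem

When a head-and-neck cancer patient is re-planned mid-course (adaptive
radiotherapy), the tumor (GTVp) and organs-at-risk must be re-contoured on
a new CT — and the patient's *pre-treatment* CT and approved contours are
always available. This package implements and compares four ways of using
(or not using) that prior:

| Method | Prior enters at | Input channels |
| --- | --- | --- |
| RM (reference model) | never | mid-treatment CT (C = 1) |
| PSM (patient-specific model) | training (pooled) | mid-treatment CT (C = 1) |
| GAM (general adaptive model) | **inference** | mid CT + aligned pre CT + S pre-label masks (C = 2 + S) |
| RIR (rigid registration) | inference | — (label propagation) |

All learned regimes share one 3D U-Net (four down/up-sampling levels,
instance norm, ReLU, per-channel sigmoid outputs), trained with a hybrid
soft-dice + focal loss whose per-structure terms carry inverse
presence-frequency class weights and, for the first part of training,
inverse-volume weights:

```
L = λ_d Σ_s w_s u_s(e) (1 − 2Σpt/(Σp+Σt+ε)) + λ_f Σ_s w_s u_s(e) E_v[−(1−p_t)^γ log p_t]
```

Cross-validated model comparison uses the corrected resampled t-test on
per-fold mean DSC/MSD differences, `t = d̄ / √((1/k + n₂/n₁) s_d²)`, which
corrects the naive paired test's anti-conservatism under training-set
overlap.

The network and its training loop are a compact numpy + numba
implementation (hand-derived backward passes, verified against finite
differences), sized for desk-scale experiments on one CPU core. Rigid
registration is multi-resolution Mattes mutual information via SimpleITK.
See `docs/methods.md` for the full model, parameter and phantom
documentation.

## Worked example

Generate a ten-patient paired-timepoint phantom cohort and run the
cross-validated comparison (two folds; reference model, general adaptive
model, rigid propagation):

```python
from adaptseg.experiment import StudyConfig, run_study

result = run_study(StudyConfig(seed=0))
print(result.report[["structure", "RM_mean", "GAM_mean", "RIR_mean"]].round(2))
for structure in ("tumor", "bone", "plexus"):
    for method in ("RM", "GAM", "RIR"):
        print(structure, method, round(result.mean_dsc(method, structure), 2))
```

With the default seed this prints, for the variable low-contrast tumor,
mean test DSC 0.14 for the image-only reference model (it cannot localize
a structure that is barely above the noise and moves between patients),
0.68 for the prior-conditioned model, and 0.81 for rigid propagation
(its shrinkage-bound ceiling). On the high-contrast locally-deformed
"bone" the learned models (RM 0.89, GAM 0.89) clearly beat rigid
propagation (0.66), which cannot follow non-rigid motion. `result.records` holds the
per-patient DSC/MSD table and `result.report` the per-structure
mean ± sd over folds with corrected-t-test significance markers.

A command-line interface wraps the same pipeline for shell use:

```bash
adaptseg phantom generate --out cohort/ --patients 10
adaptseg preprocess --in cohort/ --out std/ --spacing 3 3 3 --extent 96 96 96
adaptseg register --fixed mid.nii.gz --moving pre.nii.gz --out transform.json
adaptseg study --patients 10 --epochs 60 --out results/
```

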