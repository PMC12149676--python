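"""Training regimes, losses, augmentation, and the cross-validation harness.

Three regimes share one U-Net architecture and differ only in how the
patient's pre-treatment data enters:

* ``RM`` (reference): image-only; trained on every pre- and mid-treatment
  image of the non-test patients.
* ``PSM`` (patient-specific): image-only, but the *test* patients'
  pre-treatment images are pooled into training (sample count matched to RM
  by removing an equal number of other samples at random).
* ``GAM`` (general adaptive): the prior is an inference-time input — each
  sample stacks the mid-treatment image with the rigidly aligned
  pre-treatment image and label channels; the time order is also reversed to
  double the sample count.

No regime ever sees a test patient's mid-treatment data; this invariant is
asserted on every sample list.

The loss is a hybrid of soft-dice and focal terms, each aggregated over the
present structures with per-structure weights: inverse presence-frequency
class weights (always) times inverse-mean-volume weights (first
``volume_weight_epochs`` epochs only, to push small structures to converge
without penalising large ones for the whole run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform
from sklearn.base import BaseEstimator

from .evaluate import dsc
from .imaging import PatientCase, Timepoint
from .model import ModelSpec, UNet3D, sigmoid

__all__ = [
    "FoldPlan",
    "make_fold_plan",
    "Sample",
    "build_training_samples",
    "assert_no_leakage",
    "LeakageError",
    "LossConfig",
    "AugmentConfig",
    "dice_loss",
    "focal_loss",
    "class_weights",
    "volume_weights",
    "volume_weight_schedule",
    "augment_arrays",
    "materialize_sample",
    "UNetSegmenter",
    "train_model",
]

# CT intensity window mapped linearly onto [0, 1] before stacking
HU_CLIP = (-1024.0, 3071.0)


def normalize_image(voxels: np.ndarray) -> np.ndarray:
    lo, hi = HU_CLIP
    return ((np.clip(voxels, lo, hi) - lo) / (hi - lo)).astype(np.float32)


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Patient-level k-fold partition with per-run validation subsets."""

    k: int
    folds: list[list[str]]
    validation: list[list[str]]  # per run, drawn from the non-test patients
    seed: int

    def test_ids(self, run: int) -> list[str]:
        return list(self.folds[run])

    def validation_ids(self, run: int) -> list[str]:
        return list(self.validation[run])

    def train_ids(self, run: int) -> list[str]:
        """Non-test patients excluding the validation subset."""
        test = set(self.folds[run])
        val = set(self.validation[run])
        return [p for fold in self.folds for p in fold if p not in test and p not in val]

    def nontest_ids(self, run: int) -> list[str]:
        test = set(self.folds[run])
        return [p for fold in self.folds for p in fold if p not in test]


def make_fold_plan(
    patient_ids: list[str], k: int, val_fraction: float = 18 / 110, seed: int = 0
) -> FoldPlan:
    """Deterministic patient-level k-fold plan.

    Folds are equally sized (±1) and disjoint, covering the cohort; the test
    fold rotates across runs and each run's validation patients are drawn
    from the remaining patients. With 110 patients, k=5 and the default
    validation fraction this yields the 70/18/22 train/validation/test split.
    """
    ids = list(patient_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds cohort size {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    folds = [sorted(shuffled[j::k]) for j in range(k)]
    n_val = int(round(val_fraction * len(ids)))
    validation = []
    for run in range(k):
        pool = [p for j, fold in enumerate(folds) if j != run for p in fold]
        pick = rng.choice(len(pool), size=min(n_val, len(pool)), replace=False)
        validation.append(sorted(pool[i] for i in pick))
    return FoldPlan(k, folds, validation, seed)


# ---------------------------------------------------------------------------
# Training-set construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    """One training sample descriptor.

    ``kind`` is ``"pre"``/``"mid"`` for single-image regimes (segment that
    image), or ``"forward"``/``"reversed"`` for the paired prior-conditioned
    regime (``forward``: predict mid labels from mid image + aligned pre
    prior; ``reversed``: the time-mirrored twin).
    """

    patient_id: str
    kind: str

    @property
    def target_timepoint(self) -> str:
        return {"pre": "pre", "mid": "mid", "forward": "mid", "reversed": "pre"}[self.kind]


class LeakageError(RuntimeError):
    """A training sample would expose test-patient mid-treatment data."""


def assert_no_leakage(samples: list[Sample], test_ids: list[str]) -> None:
    test = set(test_ids)
    bad = [s for s in samples if s.patient_id in test and s.target_timepoint == "mid"]
    bad += [s for s in samples if s.patient_id in test and s.kind in ("forward", "reversed")]
    if bad:
        raise LeakageError(f"test-patient mid-treatment data in training set: {bad[:3]}")


def build_training_samples(
    cohort, plan: FoldPlan, run: int, regime: str, strict_split: bool = False
) -> list[Sample]:
    """Training sample list for one cross-validation run of one regime.

    ``cohort`` may be a list of patient ids or of objects with a
    ``patient_id``. By default all non-test patients contribute samples and
    the validation patients are used for model selection only (this is what
    reproduces the 176-sample bookkeeping of a 110-patient, k=5 cohort);
    ``strict_split=True`` restricts samples to the train split proper.
    """
    ids = [c if isinstance(c, str) else c.patient_id for c in cohort]
    plan_ids = {p for fold in plan.folds for p in fold}
    if set(ids) != plan_ids:
        raise ValueError("cohort and fold plan disagree on patient ids")
    test = plan.test_ids(run)
    source = plan.train_ids(run) if strict_split else plan.nontest_ids(run)
    source = [p for p in ids if p in set(source)]  # keep cohort order

    regime = regime.upper()
    if regime == "RM":
        samples = [Sample(p, "pre") for p in source] + [Sample(p, "mid") for p in source]
    elif regime == "PSM":
        base = [Sample(p, "pre") for p in source] + [Sample(p, "mid") for p in source]
        extra = [Sample(p, "pre") for p in test]
        # count-match with RM: remove as many non-test samples, seeded
        rng = np.random.default_rng(plan.seed + 1000 + run)
        drop = set(rng.choice(len(base), size=min(len(extra), len(base)), replace=False))
        samples = [s for i, s in enumerate(base) if i not in drop] + extra
    elif regime == "GAM":
        samples = [Sample(p, "forward") for p in source] + [Sample(p, "reversed") for p in source]
    else:
        raise ValueError(f"unknown regime {regime!r}")
    assert_no_leakage(samples, test)
    return samples


# ---------------------------------------------------------------------------
# Losses and weights
# ---------------------------------------------------------------------------

@dataclass
class LossConfig:
    """Hybrid dice + focal loss configuration.

    ``volume_weight_epochs`` bounds the epochs during which inverse-volume
    weights apply (200 of the full-scale 1000-epoch schedule).
    """

    dice_weight: float = 1.0
    focal_weight: float = 1.0
    gamma: float = 2.0
    volume_weight_epochs: int = 200
    epochs: int = 1000
    learning_rate: float = 1e-3
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.dice_weight, self.focal_weight, self.gamma) < 0:
            raise ValueError("loss weights and gamma must be >= 0")
        if self.volume_weight_epochs > self.epochs:
            raise ValueError("volume_weight_epochs must not exceed epochs")


@dataclass
class AugmentConfig:
    """Random spatial augmentation ranges (one transform per sample, applied
    identically to every channel: linear for images, nearest for labels)."""

    translation_mm: float = 50.0
    rotation_deg: float = 5.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0


def dice_loss(pred, target, present, weights=None, eps: float = 1e-6,
              with_grad: bool = False):
    """Soft-dice loss over present structure channels.

    ``pred`` are per-channel probabilities (S, ...); per present structure
    ``1 - 2*sum(p*t) / (sum(p) + sum(t) + eps)``, aggregated as a weighted
    mean; absent structures contribute nothing (and receive zero gradient).
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    present = np.asarray(present, dtype=bool)
    S = pred.shape[0]
    w = np.ones(S) if weights is None else np.asarray(weights, dtype=float)
    wsum = w[present].sum()
    loss = 0.0
    grad = np.zeros_like(pred) if with_grad else None
    for s in range(S):
        if not present[s]:
            continue
        p = pred[s]
        t = target[s]
        inter = float((p * t).sum())
        denom = float(p.sum() + t.sum()) + eps
        loss += w[s] * (1.0 - 2.0 * inter / denom)
        if with_grad:
            grad[s] = w[s] * (-2.0 * t / denom + 2.0 * inter / denom ** 2)
    if wsum > 0:
        loss /= wsum
        if with_grad:
            grad /= wsum
    return (loss, grad) if with_grad else loss


def focal_loss(pred, target, gamma: float = 2.0, present=None, weights=None,
               with_grad: bool = False):
    """Focal loss, mean over voxels per structure, weighted mean over structures.

    ``-(1 - p_t)^gamma * log(p_t)`` with ``p_t = p`` where the target is 1
    and ``1 - p`` elsewhere; ``gamma = 0`` reduces to binary cross-entropy.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    S = pred.shape[0]
    present = np.ones(S, bool) if present is None else np.asarray(present, dtype=bool)
    w = np.ones(S) if weights is None else np.asarray(weights, dtype=float)
    wsum = w[present].sum()
    tiny = 1e-7
    loss = 0.0
    grad = np.zeros_like(pred) if with_grad else None
    for s in range(S):
        if not present[s]:
            continue
        p = np.clip(pred[s], tiny, 1.0 - tiny)
        t = target[s]
        q = np.where(t > 0.5, p, 1.0 - p)
        one_m = 1.0 - q
        n = q.size
        loss += w[s] * float((-(one_m ** gamma) * np.log(q)).mean())
        if with_grad:
            if gamma == 0:
                dq = -1.0 / q
            else:
                dq = gamma * one_m ** (gamma - 1.0) * np.log(q) - one_m ** gamma / q
            grad[s] = w[s] * np.where(t > 0.5, dq, -dq) / n
    if wsum > 0:
        loss /= wsum
        if with_grad:
            grad /= wsum
    return (loss, grad) if with_grad else loss


def class_weights(presence: dict[str, list[bool]]) -> dict[str, float]:
    """Inverse presence-frequency class weights, normalized to mean 1.

    ``presence`` maps structure name to its per-training-sample presence
    flags. A structure present in half the samples gets twice the weight of
    one present in all (before normalization); a structure present in none
    is excluded with a warning (it cannot be trained).
    """
    freqs = {}
    for name, flags in presence.items():
        f = float(np.mean(flags)) if len(flags) else 0.0
        if f == 0.0:
            warnings.warn(f"structure {name!r} has no labels in the training set; excluded",
                          stacklevel=2)
            continue
        freqs[name] = f
    if not freqs:
        raise ValueError("no structure has any training label")
    raw = {n: 1.0 / f for n, f in freqs.items()}
    mean = np.mean(list(raw.values()))
    return {n: v / mean for n, v in raw.items()}


def volume_weights(volumes_cm3: dict[str, list[float]]) -> dict[str, float]:
    """Inverse mean-volume weights (normalized mean 1) from per-sample volumes."""
    raw = {}
    for name, vols in volumes_cm3.items():
        if len(vols) == 0:
            continue
        mv = float(np.mean(vols))
        raw[name] = 1.0 / max(mv, 1e-9)
    mean = np.mean(list(raw.values()))
    return {n: v / mean for n, v in raw.items()}


def volume_weight_schedule(epoch: int, u: np.ndarray, t_bound: int) -> np.ndarray:
    """Inverse-volume multipliers while ``epoch < t_bound``, all-ones after."""
    u = np.asarray(u, dtype=float)
    return u if epoch < t_bound else np.ones_like(u)


# ---------------------------------------------------------------------------
# Augmentation and sample materialization
# ---------------------------------------------------------------------------

def augment_arrays(
    images: list[np.ndarray],
    labels: list[np.ndarray],
    spacing,
    cfg: AugmentConfig,
    rng: np.random.Generator,
):
    """Apply one random rigid+scale transform to all channels of a sample.

    The transform (translation, rotation about the volume center, isotropic
    scale) is sampled once and applied identically to every channel — linear
    interpolation and edge-value fill for image channels, nearest-neighbour
    and zero fill for label channels. Returns (images, labels).
    """
    from .phantom import _rotation_matrix  # same Euler convention as elsewhere

    spacing = np.asarray(spacing, dtype=float)
    t_mm = rng.uniform(-cfg.translation_mm, cfg.translation_mm, 3)
    ang = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg, 3)
    scale = rng.uniform(*cfg.scale_range)
    if not np.any(t_mm) and not np.any(ang) and scale == 1.0:
        return [im.copy() for im in images], [lb.copy() for lb in labels]

    shape = np.asarray(images[0].shape if images else labels[0].shape, dtype=float)
    center = (shape - 1) / 2.0
    rot = _rotation_matrix(ang)
    # output voxel x maps to input voxel A @ x + o with A = (R * s)^-1
    forward = rot * scale
    inv = np.linalg.inv(forward)
    t_vox = t_mm / spacing
    offset = center - inv @ (center + t_vox)

    out_images = [
        affine_transform(im, inv, offset=offset, order=1, mode="constant",
                         cval=float(im.min())).astype(np.float32)
        for im in images
    ]
    out_labels = [
        affine_transform(lb.astype(np.float32), inv, offset=offset, order=0,
                         mode="constant", cval=0.0) > 0.5
        for lb in labels
    ]
    return out_images, out_labels


def materialize_sample(
    sample: Sample,
    cases: dict[str, PatientCase],
    structure_names: list[str],
    aligned: dict[str, dict[str, Timepoint]] | None = None,
):
    """Build (input channels, target channels, present flags) for one sample.

    Single-image kinds stack one normalized image channel; paired kinds
    stack [target-time image, aligned other-time image, S aligned prior
    label channels] — channel order is fixed and identical for every sample.
    ``aligned`` maps patient id to rigidly resampled timepoints
    (``"pre_in_mid"``, ``"mid_in_pre"``), required for paired kinds.
    """
    case = cases[sample.patient_id]
    if sample.kind in ("pre", "mid"):
        tp: Timepoint = getattr(case, sample.kind)
        x = normalize_image(tp.image.voxels)[None]
    elif sample.kind in ("forward", "reversed"):
        if aligned is None or sample.patient_id not in aligned:
            raise ValueError("paired samples need rigidly aligned timepoints")
        if sample.kind == "forward":
            tp = case.mid
            prior = aligned[sample.patient_id]["pre_in_mid"]
        else:
            tp = case.pre
            prior = aligned[sample.patient_id]["mid_in_pre"]
        chans = [normalize_image(tp.image.voxels), normalize_image(prior.image.voxels)]
        for name in structure_names:
            chans.append(prior.structures.masks[name].astype(np.float32))
        x = np.stack(chans)
    else:
        raise ValueError(f"unknown sample kind {sample.kind!r}")
    target = np.stack([tp.structures.masks[n] for n in structure_names])
    present = np.array([tp.structures.present[n] for n in structure_names])
    return x.astype(np.float32), target, present


# ---------------------------------------------------------------------------
# The segmenter estimator and the training loop
# ---------------------------------------------------------------------------

class UNetSegmenter(BaseEstimator):
    """Multi-structure 3D U-Net segmenter with a scikit-learn-style API.

    ``fit(samples, val_samples)`` trains on materialized samples — tuples of
    ``(input channels, target channels, present flags)`` — for a fixed
    number of epochs with Adam, tracking per-structure validation DSC every
    epoch; the weights of the epoch with the best mean validation DSC are
    kept. ``predict(x)`` returns per-structure probabilities,
    ``predict_masks(x)`` binarized masks.

    Parameters mirror the training protocol: hybrid dice+focal loss with
    inverse-frequency class weights throughout and inverse-volume weights
    for the first ``loss_config.volume_weight_epochs`` epochs, random
    rigid+scale augmentation, learning rate 0.001.
    """

    def __init__(
        self,
        structure_names: list[str] | None = None,
        in_channels: int = 1,
        base_width: int = 8,
        loss_config: LossConfig | None = None,
        augment_config: AugmentConfig | None = None,
        spacing=(1.0, 1.0, 2.0),
        seed: int = 0,
        verbose: bool = False,
    ):
        self.structure_names = structure_names
        self.in_channels = in_channels
        self.base_width = base_width
        self.loss_config = loss_config
        self.augment_config = augment_config
        self.spacing = spacing
        self.seed = seed
        self.verbose = verbose

    # -- internals ---------------------------------------------------------
    def _loss_and_grad(self, logits, target, present, weights):
        cfg = self._loss_cfg
        p = sigmoid(logits)
        ld, gd = dice_loss(p, target, present, weights, eps=cfg.eps, with_grad=True)
        lf, gf = focal_loss(p, target, cfg.gamma, present, weights, with_grad=True)
        loss = cfg.dice_weight * ld + cfg.focal_weight * lf
        dldp = cfg.dice_weight * gd + cfg.focal_weight * gf
        dldz = (dldp * p * (1.0 - p)).astype(np.float32)
        return float(loss), dldz

    def _validation_dsc(self, val_samples) -> np.ndarray:
        S = len(self.structure_names_)
        acc = np.zeros(S)
        cnt = np.zeros(S)
        for x, t, present in val_samples:
            pred = self.net_.predict_proba(x) >= 0.5
            for s in range(S):
                if present[s]:
                    acc[s] += dsc(pred[s], t[s])
                    cnt[s] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)

    # -- API ---------------------------------------------------------------
    def fit(self, samples, val_samples=None):
        if not samples:
            raise ValueError("no training samples")
        S = samples[0][1].shape[0]
        names = self.structure_names or [f"s{i}" for i in range(S)]
        if len(names) != S:
            raise ValueError("structure_names length does not match target channels")
        self.structure_names_ = list(names)
        self._loss_cfg = self.loss_config or LossConfig()
        cfg = self._loss_cfg

        presence = {n: [bool(p[s]) for _, _, p in samples] for s, n in enumerate(names)}
        cw = class_weights(presence)
        self.class_weights_ = np.array([cw.get(n, 0.0) for n in names])
        voxel_cm3 = float(np.prod(self.spacing)) / 1000.0
        vols = {
            n: [float(t[s].sum()) * voxel_cm3 for _, t, p in samples if p[s]]
            for s, n in enumerate(names)
        }
        vw = volume_weights({n: v for n, v in vols.items() if v})
        self.volume_weights_ = np.array([vw.get(n, 1.0) for n in names])

        self.net_ = UNet3D(
            ModelSpec(self.in_channels, S, base_width=self.base_width), seed=self.seed
        )
        self.n_parameters_ = self.net_.parameter_count()
        from .unet_ops import Adam

        opt = Adam(self.net_.layers(), lr=cfg.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        aug_rng = np.random.default_rng(
            (self.augment_config.seed if self.augment_config else 0) + self.seed
        )
        history = []
        best = (-np.inf, None)
        for epoch in range(cfg.epochs):
            w_epoch = self.class_weights_ * volume_weight_schedule(
                epoch, self.volume_weights_, cfg.volume_weight_epochs
            )
            order = rng.permutation(len(samples))
            epoch_loss = 0.0
            for i in order:
                x, t, present = samples[i]
                if self.augment_config is not None:
                    n_img = x.shape[0] - len(names) if x.shape[0] > 1 else 1
                    n_prior = x.shape[0] - n_img
                    imgs, lbls = augment_arrays(
                        list(x[:n_img]),
                        [c > 0.5 for c in x[n_img:]] + [c > 0.5 for c in t],
                        self.spacing, self.augment_config, aug_rng,
                    )
                    prior = [np.asarray(l, np.float32) for l in lbls[:n_prior]]
                    x = np.stack(imgs + prior)
                    t = np.stack(lbls[n_prior:])
                logits = self.net_.forward(x)
                loss, dldz = self._loss_and_grad(logits, t, present, w_epoch)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {loss}"
                    )
                epoch_loss += loss
                opt.zero_grad()
                self.net_.backward(dldz)
                opt.step()
            row = {"epoch": epoch, "loss": epoch_loss / len(samples)}
            if val_samples:
                vd = self._validation_dsc(val_samples)
                for s, n in enumerate(names):
                    row[f"val_dsc_{n}"] = vd[s]
                mean_vd = np.nanmean(vd)
                row["val_dsc_mean"] = mean_vd
                if mean_vd > best[0]:
                    best = (mean_vd, [p.copy() for p in self.net_.state_arrays()])
                    self.best_epoch_ = epoch
            history.append(row)
            if self.verbose:
                print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
        if best[1] is not None:
            for dst, src in zip(self.net_.state_arrays(), best[1]):
                dst[...] = src
        self.history_ = pd.DataFrame(history)
        return self

    def validation_traces(self) -> dict[str, list[float]]:
        """Per-structure validation DSC trace (for the convergence audit)."""
        return {
            n: self.history_[f"val_dsc_{n}"].tolist()
            for n in self.structure_names_
            if f"val_dsc_{n}" in self.history_
        }

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.net_.predict_proba(x)

    def predict_masks(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return self.predict(x) >= threshold


def train_model(
    samples,
    val_samples=None,
    structure_names=None,
    in_channels: int = 1,
    base_width: int = 8,
    loss_config: LossConfig | None = None,
    augment_config: AugmentConfig | None = None,
    spacing=(1.0, 1.0, 2.0),
    seed: int = 0,
) -> UNetSegmenter:
    """Functional wrapper: fit a :class:`UNetSegmenter` on materialized samples."""
    seg = UNetSegmenter(
        structure_names=structure_names,
        in_channels=in_channels,
        base_width=base_width,
        loss_config=loss_config,
        augment_config=augment_config,
        spacing=spacing,
        seed=seed,
    )
    return seg.fit(samples, val_samples)
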