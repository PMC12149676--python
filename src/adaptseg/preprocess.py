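"""Label cleanup and geometric standardization applied before training/evaluation.

The chain is: interpolate missing axial label slices (shape-based, bounded
gap), remove disconnected foreground components, optionally resample the
pre-treatment timepoint onto the mid-treatment grid through a rigid
alignment, then resample both timepoints to a common spacing and crop to a
fixed physical extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import PatientCase, StructureSet, Timepoint, crop_to_region, resample

__all__ = [
    "PreprocessReport",
    "interpolate_missing_slices",
    "remove_disconnected",
    "standardize_case",
]

#: Largest interior run of empty axial slices that is filled by interpolation.
#: Larger gaps are left unfilled (bridging distant fragments is unsafe).
MAX_FILL_GAP = 5


@dataclass
class PreprocessReport:
    """Per-structure cleanup counts plus the geometry applied to the case."""

    rows: list[dict] = field(default_factory=list)
    spacing: tuple | None = None
    crop_extent: tuple | None = None
    crop_center: tuple | None = None

    def add(self, patient_id: str, timepoint: str, structure: str,
            slices_interpolated: int, voxels_removed: int) -> None:
        if slices_interpolated < 0 or voxels_removed < 0:
            raise ValueError("report counts must be >= 0")
        self.rows.append(
            {
                "patient_id": patient_id,
                "timepoint": timepoint,
                "structure": structure,
                "slices_interpolated": slices_interpolated,
                "voxels_removed": voxels_removed,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["patient_id", "timepoint", "structure",
                     "slices_interpolated", "voxels_removed"],
        )


def _signed_distance(slice2d: np.ndarray) -> np.ndarray:
    """Signed distance of a binary 2D shape: positive inside, negative outside."""
    inside = ndimage.distance_transform_edt(slice2d)
    outside = ndimage.distance_transform_edt(~slice2d)
    return inside - outside


def interpolate_missing_slices(
    mask: np.ndarray, max_gap: int = MAX_FILL_GAP, axis: int = 2
) -> tuple[np.ndarray, int]:
    """Fill interior gaps of empty axial slices by shape-based interpolation.

    For each run of at most ``max_gap`` consecutive empty slices flanked by
    non-empty slices, the fill is the positive region of the linear
    interpolation between the flanking slices' signed distance maps (so the
    midpoint of two identical shapes is that shape). Slices outside the
    structure's axial extent are untouched. Returns ``(mask, n_filled)``;
    never removes foreground.
    """
    mask = np.asarray(mask).astype(bool)
    moved = np.moveaxis(mask, axis, 0)
    occupied = np.flatnonzero(moved.reshape(moved.shape[0], -1).any(axis=1))
    if occupied.size < 2:
        return mask, 0
    out = moved.copy()
    n_filled = 0
    for lo, hi in zip(occupied[:-1], occupied[1:]):
        gap = hi - lo - 1
        if gap == 0 or gap > max_gap:
            continue
        sd_lo = _signed_distance(moved[lo])
        sd_hi = _signed_distance(moved[hi])
        for z in range(lo + 1, hi):
            t = (z - lo) / (hi - lo)
            out[z] = ((1 - t) * sd_lo + t * sd_hi) > 0
            n_filled += 1
    return np.moveaxis(out, 0, axis), n_filled


def remove_disconnected(mask: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Keep only the largest foreground connected component.

    26-connectivity by default (``connectivity`` in {6, 18, 26}); ties are
    broken by the lowest component label. Returns ``(mask, voxels_removed)``.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return mask, 0
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity must be one of {sorted(order)}")
    structure = ndimage.generate_binary_structure(3, order[connectivity])
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask, 0
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1  # argmax returns the first (lowest) maximum
    out = labels == keep
    return out, int(mask.sum() - out.sum())


def _clean_structures(
    ss: StructureSet, report: PreprocessReport, patient_id: str, tp_name: str,
    max_gap: int,
) -> StructureSet:
    masks = {}
    for name in ss.names:
        if not ss.present[name]:
            masks[name] = ss.masks[name]
            report.add(patient_id, tp_name, name, 0, 0)
            continue
        m, n_filled = interpolate_missing_slices(ss.masks[name], max_gap=max_gap)
        m, n_removed = remove_disconnected(m)
        masks[name] = m
        report.add(patient_id, tp_name, name, n_filled, n_removed)
    return StructureSet(ss.shape, ss.spacing, ss.origin, masks, dict(ss.present))


def standardize_case(
    case: PatientCase,
    spacing,
    crop_extent,
    crop_center=None,
    pre_to_mid=None,
    max_gap: int = MAX_FILL_GAP,
) -> tuple[PatientCase, PreprocessReport]:
    """Apply the full cleanup + standardization chain to one case.

    Order: label-slice interpolation, connected-component filtering, optional
    rigid resampling of the pre-treatment timepoint onto the mid grid
    (``pre_to_mid``: a :class:`~adaptseg.register.RigidTransform` mapping mid
    points to pre points, as returned by registration), grid resampling to
    ``spacing``, crop to ``crop_extent`` around ``crop_center`` (default: the
    mid volume's physical center). Both timepoints end on the identical grid;
    the operation is idempotent on its own output.
    """
    from .register import warp  # local import; register depends on imaging only

    spacing = np.asarray(spacing, dtype=float)
    crop_extent = np.asarray(crop_extent, dtype=float)
    report = PreprocessReport(
        spacing=tuple(spacing), crop_extent=tuple(crop_extent)
    )

    cleaned = {}
    for tp_name in ("pre", "mid"):
        tp: Timepoint = getattr(case, tp_name)
        cleaned[tp_name] = Timepoint(
            tp.image, _clean_structures(tp.structures, report, case.patient_id, tp_name, max_gap)
        )

    if pre_to_mid is not None:
        pre = cleaned["pre"]
        mid_img = cleaned["mid"].image
        cleaned["pre"] = Timepoint(
            warp(pre.image, pre_to_mid, target_grid=mid_img),
            warp(pre.structures, pre_to_mid, target_grid=mid_img),
        )

    if crop_center is None:
        mid_img = cleaned["mid"].image
        crop_center = mid_img.origin - mid_img.spacing / 2 + mid_img.extent_mm / 2
    crop_center = np.asarray(crop_center, dtype=float)
    report.crop_center = tuple(crop_center)

    out = {}
    for tp_name in ("pre", "mid"):
        tp = cleaned[tp_name]
        img = crop_to_region(resample(tp.image, spacing), crop_center, crop_extent)
        ss = crop_to_region(resample(tp.structures, spacing), crop_center, crop_extent)
        out[tp_name] = Timepoint(img, ss)

    if not out["pre"].image.same_grid(out["mid"].image):
        raise AssertionError("standardization failed to unify pre/mid grids")
    return PatientCase(case.patient_id, out["pre"], out["mid"], case.interval_days), report
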