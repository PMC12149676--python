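"""Core spatial data types, resampling/cropping geometry, and NIfTI I/O.

Conventions used throughout the package:

* Arrays are indexed ``(x, y, z)`` with z the axial (slice) axis, matching
  the canonical RAS+ data layout that :mod:`nibabel` produces.
* Voxel indexing is 0-based and world coordinates are voxel-center based:
  the world position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
* All volumes are reoriented to canonical RAS+ on load; mixed orientations
  silently corrupt registration, so a single fixed right-handed convention
  is enforced at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "StructureSet",
    "Timepoint",
    "PatientCase",
    "resample",
    "crop_to_region",
    "read_case",
    "write_case",
    "read_cohort",
    "write_cohort",
]

#: Threshold used to binarize label files on load (tolerates interpolated labels).
BINARIZE_THRESHOLD = 0.5


class GeometryError(ValueError):
    """Raised when image/mask geometries are inconsistent or a region is invalid."""


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid with physical spacing and origin.

    Parameters
    ----------
    voxels
        3D array of intensities (HU-like arbitrary units), indexed (x, y, z).
    spacing
        Physical voxel spacing in mm, one value per axis, all > 0.
    origin
        World position (mm) of the *center* of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise GeometryError(f"expected a 3D volume, got shape {self.voxels.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical extent spanned by the grid (edge to edge of boundary voxels)."""
        return np.asarray(self.shape) * self.spacing

    def same_grid(self, other: "ImageVolume | StructureSet", atol: float = 1e-3) -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    # -- SimpleITK interop -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.transpose(2, 1, 0)))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(arr, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


@dataclass
class StructureSet:
    """Named per-structure binary masks sharing one grid.

    Structure ordering is fixed (dict insertion order) and must be identical
    across all cases of a cohort; a structure with ``present[name] == False``
    has an all-zero mask and is excluded from losses and metrics.
    """

    shape: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    present: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        for name in list(self.masks):
            m = np.asarray(self.masks[name])
            if m.shape != self.shape:
                raise GeometryError(
                    f"mask {name!r} shape {m.shape} != grid shape {self.shape}"
                )
            if m.dtype != bool:
                vals = np.unique(m)
                if not np.all(np.isin(vals, (0, 1))):
                    raise ValueError(f"mask {name!r} is not binary (values {vals[:5]}...)")
                m = m.astype(bool)
            self.masks[name] = m
            self.present.setdefault(name, bool(m.any()))
        for name, ok in self.present.items():
            if name not in self.masks:
                raise GeometryError(f"presence flag for unknown structure {name!r}")
            if not ok and self.masks[name].any():
                raise ValueError(f"structure {name!r} flagged absent but has foreground")

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def mask_volume_cm3(self, name: str) -> float:
        """Structure volume in cm^3 (voxel count x voxel volume)."""
        return float(self.masks[name].sum()) * float(np.prod(self.spacing)) / 1000.0

    @classmethod
    def empty_like(cls, image: ImageVolume, names: list[str]) -> "StructureSet":
        return cls(
            image.shape,
            image.spacing.copy(),
            image.origin.copy(),
            {n: np.zeros(image.shape, dtype=bool) for n in names},
            {n: False for n in names},
        )


@dataclass
class Timepoint:
    """One imaging session: a volume plus its structure set on the same grid."""

    image: ImageVolume
    structures: StructureSet

    def __post_init__(self) -> None:
        if not self.image.same_grid(self.structures):
            raise GeometryError("image and structure set are on different grids")


@dataclass
class PatientCase:
    """Paired pre-treatment and mid-treatment data for one patient."""

    patient_id: str
    pre: Timepoint
    mid: Timepoint
    interval_days: int = 0

    def __post_init__(self) -> None:
        if self.interval_days < 0:
            raise ValueError("interval_days must be >= 0")


# ---------------------------------------------------------------------------
# Geometry operations
# ---------------------------------------------------------------------------

def _resample_sitk(
    img: sitk.Image,
    out_spacing: np.ndarray,
    out_origin: np.ndarray,
    out_size: np.ndarray,
    interp: int,
    default: float,
    transform: sitk.Transform | None = None,
) -> sitk.Image:
    return sitk.Resample(
        img,
        [int(s) for s in out_size],
        transform or sitk.Transform(),
        interp,
        tuple(float(v) for v in out_origin),
        tuple(float(v) for v in out_spacing),
        (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        float(default),
        sitk.sitkFloat32,
    )


def resample(v, target_spacing, mode: str | None = None):
    """Resample an :class:`ImageVolume` or :class:`StructureSet` to a new spacing.

    The output grid spans the same physical extent as the input (to within one
    voxel). Images use linear interpolation, masks nearest-neighbour, unless
    ``mode`` overrides the default for images.
    """
    target_spacing = np.asarray(target_spacing, dtype=float).reshape(3)
    if np.any(target_spacing <= 0):
        raise GeometryError(f"target spacing must be positive, got {target_spacing}")

    if isinstance(v, StructureSet):
        ref = ImageVolume(np.zeros(v.shape, np.float32), v.spacing, v.origin)
        out_ref = resample(ref, target_spacing, mode="nearest")
        masks = {}
        for name, m in v.masks.items():
            mv = ImageVolume(m.astype(np.float32), v.spacing, v.origin)
            masks[name] = resample(mv, target_spacing, mode="nearest").voxels > 0.5
        return StructureSet(out_ref.shape, out_ref.spacing, out_ref.origin, masks, dict(v.present))

    extent = v.extent_mm
    out_size = np.maximum(1, np.round(extent / target_spacing)).astype(int)
    # voxel-center convention: keep the physical edge of the field fixed
    out_origin = v.origin - v.spacing / 2 + target_spacing / 2
    interp = sitk.sitkNearestNeighbor if mode == "nearest" else sitk.sitkLinear
    out = _resample_sitk(
        v.to_sitk(), target_spacing, out_origin, out_size, interp, float(v.voxels.min())
    )
    return ImageVolume.from_sitk(out)


def crop_to_region(v, center_mm, extent_mm, background: float | None = None):
    """Crop (or pad) to a physical region of the given extent centred at ``center_mm``.

    Out-of-field voxels are filled with ``background`` (default: minimum
    intensity for images — a CT air analog — and 0 for masks).
    """
    center_mm = np.asarray(center_mm, dtype=float).reshape(3)
    extent_mm = np.asarray(extent_mm, dtype=float).reshape(3)
    if np.any(extent_mm <= 0):
        raise GeometryError("crop extent must be positive")

    if isinstance(v, StructureSet):
        ref = ImageVolume(np.zeros(v.shape, np.float32), v.spacing, v.origin)
        out_ref = crop_to_region(ref, center_mm, extent_mm, background=0.0)
        masks = {}
        for name, m in v.masks.items():
            mv = ImageVolume(m.astype(np.float32), v.spacing, v.origin)
            masks[name] = (
                crop_to_region(mv, center_mm, extent_mm, background=0.0).voxels > 0.5
            )
        return StructureSet(out_ref.shape, out_ref.spacing, out_ref.origin, masks, dict(v.present))

    out_size = np.maximum(1, np.round(extent_mm / v.spacing)).astype(int)
    out_origin = center_mm - extent_mm / 2 + v.spacing / 2
    # zero-overlap check against the input's physical bounds
    lo = v.origin - v.spacing / 2
    hi = v.origin + (np.asarray(v.shape) - 0.5) * v.spacing
    out_lo = out_origin - v.spacing / 2
    out_hi = out_origin + (out_size - 0.5) * v.spacing
    if np.any(out_hi <= lo) or np.any(out_lo >= hi):
        raise GeometryError("requested crop region does not overlap the volume")
    fill = float(v.voxels.min()) if background is None else float(background)
    out = _resample_sitk(
        v.to_sitk(), v.spacing, out_origin, out_size, sitk.sitkNearestNeighbor, fill
    )
    return ImageVolume.from_sitk(out)


# ---------------------------------------------------------------------------
# NIfTI I/O and the cohort manifest
# ---------------------------------------------------------------------------

def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _save_nifti(path: Path, voxels: np.ndarray, spacing, origin) -> None:
    img = nib.Nifti1Image(np.asarray(voxels, dtype=np.float32), _affine(np.asarray(spacing), np.asarray(origin)))
    nib.save(img, str(path))


def _load_nifti(path: Path) -> ImageVolume:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    aff = img.affine
    rot = aff[:3, :3]
    spacing = np.sqrt((rot ** 2).sum(axis=0))
    if not np.allclose(rot, np.diag(spacing), atol=1e-3):
        raise GeometryError(f"{path}: oblique orientation not supported after canonical reorientation")
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ImageVolume(data, spacing, aff[:3, 3])


def write_case(case: PatientCase, out_dir: str | Path) -> dict:
    """Write one case as NIfTI files; returns its manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entry: dict = {"id": case.patient_id, "interval_days": case.interval_days}
    for tp_name in ("pre", "mid"):
        tp: Timepoint = getattr(case, tp_name)
        img_path = out_dir / f"{tp_name}_image.nii.gz"
        _save_nifti(img_path, tp.image.voxels, tp.image.spacing, tp.image.origin)
        labels = {}
        for name in tp.structures.names:
            if not tp.structures.present[name]:
                continue
            lbl_path = out_dir / f"{tp_name}_label_{name}.nii.gz"
            _save_nifti(
                lbl_path,
                tp.structures.masks[name].astype(np.float32),
                tp.image.spacing,
                tp.image.origin,
            )
            labels[name] = lbl_path.name
        entry[tp_name] = {"image": img_path.name, "labels": labels}
    return entry


def read_case(entry: dict, structure_names: list[str], root: str | Path) -> PatientCase:
    """Read one case from a manifest entry.

    Label voxel data is binarized at 0.5; structures without a label file are
    flagged absent with an all-zero mask. A mask whose grid disagrees with its
    image raises :class:`GeometryError`.
    """
    root = Path(root)
    tps = {}
    for tp_name in ("pre", "mid"):
        image = _load_nifti(root / entry[tp_name]["image"])
        ss = StructureSet.empty_like(image, structure_names)
        for name in structure_names:
            rel = entry[tp_name]["labels"].get(name)
            if rel is None:
                continue
            lbl = _load_nifti(root / rel)
            if not image.same_grid(lbl):
                raise GeometryError(
                    f"{entry['id']}/{tp_name}: label {name!r} grid differs from image grid"
                )
            ss.masks[name] = lbl.voxels > BINARIZE_THRESHOLD
            ss.present[name] = True
        tps[tp_name] = Timepoint(image, ss)
    return PatientCase(entry["id"], tps["pre"], tps["mid"], int(entry.get("interval_days", 0)))


def write_cohort(cases: list[PatientCase], out_dir: str | Path, extra: dict | None = None) -> dict:
    """Write a cohort directory with a JSON manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = cases[0].pre.structures.names if cases else []
    manifest = {"structures": names, "patients": []}
    if extra:
        manifest.update(extra)
    for case in cases:
        entry = write_case(case, out_dir / case.patient_id)
        entry["pre"]["image"] = f"{case.patient_id}/{entry['pre']['image']}"
        entry["pre"]["labels"] = {k: f"{case.patient_id}/{v}" for k, v in entry["pre"]["labels"].items()}
        entry["mid"]["image"] = f"{case.patient_id}/{entry['mid']['image']}"
        entry["mid"]["labels"] = {k: f"{case.patient_id}/{v}" for k, v in entry["mid"]["labels"].items()}
        manifest["patients"].append(entry)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(cohort_dir: str | Path) -> tuple[list[PatientCase], dict]:
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    cases = [read_case(e, manifest["structures"], cohort_dir) for e in manifest["patients"]]
    return cases, manifest
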