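"""Synthetic paired pre-/mid-treatment phantom cohorts.

The generator emulates the statistical structure of an adaptive head-and-neck
replanning dataset without any clinical data: a smooth "head" background with
ellipsoidal structures of strongly imbalanced volume and contrast, a
high-variability low-contrast "tumor" that shrinks between timepoints, a
global rigid pose offset plus a smooth local deformation between timepoints,
and per-structure missing labels.

Every scene is *analytic* (implicit ellipsoids evaluated at voxel centers),
so the mid-treatment timepoint is exactly the pre-treatment scene composed
with the sampled rigid transform (and, for deformable structures, with a
band-limited displacement field). The sampled ground-truth transform is
stored in the manifest, which gives registration tests an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .imaging import ImageVolume, PatientCase, StructureSet, Timepoint

__all__ = [
    "StructureSpec",
    "PhantomConfig",
    "desk_profile",
    "generate_cohort",
    "cohort_summary",
]

AIR_HU = -1000.0
HEAD_HU = 40.0
BONE_HU = 900.0

#: Unlabeled high-contrast bony landmarks (skull-base analogs) rendered into
#: the background anatomy. Their asymmetric placement breaks the rotational
#: near-symmetry of the ellipsoidal head, as real bony anatomy does, which
#: makes the inter-timepoint pose observable to intensity-based registration.
#: (center offset as fraction of the field extent, radius mm)
MARKER_NODULES = (
    ((0.20, -0.12, 0.16), 7.0),
    ((-0.16, 0.18, -0.14), 6.0),
    ((0.10, 0.22, 0.20), 5.0),
)


@dataclass
class StructureSpec:
    """Generative parameters for one phantom structure.

    ``rigidity == "rigid"`` structures follow only the global rigid offset
    between timepoints; ``"deformable"`` ones are additionally displaced by
    the local deformation field. ``contrast`` is the intensity offset (a.u.)
    over the head background — low values make a structure hard to segment
    from the image alone, mimicking low-contrast soft-tissue anatomy.
    """

    name: str
    radii_mm: tuple[float, float, float]
    contrast: float
    center_frac: tuple[float, float, float]
    position_sd_mm: float = 2.0
    radius_jitter: float = 0.1
    volume_scale: float = 1.0
    role: str = "organ"  # "organ" | "tumor"
    rigidity: str = "rigid"  # "rigid" | "deformable"
    missing_label_prob: float = 0.0

    def __post_init__(self) -> None:
        if min(self.radii_mm) <= 0:
            raise ValueError(f"{self.name}: radii must be positive")
        if not np.isfinite(self.contrast):
            raise ValueError(f"{self.name}: contrast must be finite")
        if not 0.0 <= self.missing_label_prob <= 1.0:
            raise ValueError(f"{self.name}: missing_label_prob must be in [0, 1]")
        if self.role not in ("organ", "tumor"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if self.rigidity not in ("rigid", "deformable"):
            raise ValueError(f"{self.name}: unknown rigidity {self.rigidity!r}")


@dataclass
class PhantomConfig:
    """Full description of a phantom cohort.

    Inter-timepoint change is controlled by the rigid offset ranges
    (``translation_mm``, ``rotation_deg``, both symmetric around zero), the
    local deformation amplitude, and the tumor shrinkage fraction range
    (volume ratio mid/pre, in (0, 1]).
    """

    n_patients: int = 20
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    structures: list[StructureSpec] = field(default_factory=list)
    translation_mm: float = 6.0
    rotation_deg: float = 3.0
    deform_amplitude_mm: float = 7.0
    deform_grid: int = 3
    shrink_range: tuple[float, float] = (0.5, 0.8)
    noise_sd: float = 15.0
    smooth_sigma_vox: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.shrink_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("shrinkage fractions must lie in (0, 1]")
        if self.structures and not any(s.role == "tumor" for s in self.structures):
            raise ValueError("at least one structure must have role='tumor'")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)


def desk_profile(
    n_patients: int = 20,
    grid: int = 32,
    spacing: float = 3.0,
    missing_label_prob: float = 0.05,
    noise_sd: float = 15.0,
    seed: int = 0,
    **overrides,
) -> PhantomConfig:
    """Desk-scale three-structure profile, CPU-trainable in minutes.

    One high-contrast deformable "bone" (mandible / spinal-cord analog: easy
    for image-driven models, hard for rigid propagation because of local
    non-rigid motion), one low-contrast deformable "plexus"
    (brachial-plexus analog, hard without a prior), and a variable,
    shrinking, low-contrast "tumor" (GTVp analog, the structure on which
    image-only models fail; it follows only the rigid pose offset, which
    also makes it the ground-truth-recoverable structure for registration
    fixtures).
    """
    structures = [
        StructureSpec(
            "bone", (12.0, 7.0, 30.0), 800.0, (0.50, 0.34, 0.50),
            position_sd_mm=2.0, role="organ", rigidity="deformable",
            missing_label_prob=missing_label_prob,
        ),
        StructureSpec(
            "plexus", (9.0, 6.0, 26.0), 60.0, (0.66, 0.56, 0.50),
            position_sd_mm=3.0, role="organ", rigidity="deformable",
            missing_label_prob=missing_label_prob,
        ),
        StructureSpec(
            "tumor", (15.0, 11.0, 13.0), 25.0, (0.40, 0.60, 0.46),
            position_sd_mm=7.0, radius_jitter=0.2, role="tumor",
            rigidity="rigid", missing_label_prob=0.0,
        ),
    ]
    cfg = PhantomConfig(
        n_patients=n_patients,
        grid_shape=(grid, grid, grid),
        spacing_mm=(spacing, spacing, spacing),
        structures=structures,
        noise_sd=noise_sd,
        seed=seed,
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown PhantomConfig field {key!r}")
        setattr(cfg, key, val)
    return cfg


# ---------------------------------------------------------------------------
# Scene evaluation
# ---------------------------------------------------------------------------

def _voxel_centers(cfg: PhantomConfig) -> np.ndarray:
    """(3, N) world coordinates of voxel centers (origin at 0)."""
    axes = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(cfg.grid_shape, cfg.spacing_mm)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grids])


def _ellipsoid(points: np.ndarray, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    d = (points - center[:, None]) / radii[:, None]
    return (d * d).sum(axis=0) <= 1.0


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    # matches SimpleITK's Euler3DTransform default composition R = Rz Rx Ry
    return rz @ rx @ ry


def _sample_deform_field(rng: np.random.Generator, cfg: PhantomConfig):
    """Band-limited random displacement field, max amplitude ~ deform_amplitude_mm."""
    g = cfg.deform_grid
    coarse = rng.uniform(-1.0, 1.0, size=(3, g, g, g))
    extent = cfg.extent_mm

    def displace(points: np.ndarray) -> np.ndarray:
        # map mm coords onto the coarse control grid and spline-interpolate
        u = points / extent[:, None] * (g - 1)
        d = np.stack(
            [map_coordinates(coarse[i], u, order=3, mode="nearest") for i in range(3)]
        )
        return d * cfg.deform_amplitude_mm

    return coarse, displace


@dataclass
class _PatientScene:
    head_center: np.ndarray
    head_radii: np.ndarray
    centers: dict[str, np.ndarray]
    radii: dict[str, np.ndarray]


def _sample_scene(rng: np.random.Generator, cfg: PhantomConfig) -> _PatientScene:
    extent = cfg.extent_mm
    head_center = extent / 2
    # triaxial on purpose: a rotationally symmetric head would make the
    # inter-timepoint rotation unidentifiable
    head_radii = extent * np.array([0.36, 0.43, 0.46]) * (1 + 0.04 * rng.standard_normal(3))
    centers, radii = {}, {}
    for spec in cfg.structures:
        r = np.asarray(spec.radii_mm) * spec.volume_scale ** (1 / 3)
        r = r * (1 + spec.radius_jitter * rng.standard_normal(3)).clip(0.5, 1.5)
        c = extent * np.asarray(spec.center_frac) + spec.position_sd_mm * rng.standard_normal(3)
        lo, hi = r + 1.0, extent - r - 1.0
        if np.any(lo > hi):
            raise ValueError(f"structure {spec.name!r} cannot fit in the grid")
        centers[spec.name] = np.clip(c, lo, hi)
        radii[spec.name] = r
    return _PatientScene(head_center, head_radii, centers, radii)


def _render(
    cfg: PhantomConfig,
    scene: _PatientScene,
    points: np.ndarray,
    rng_noise: np.random.Generator,
    rigid_map=None,
    displace=None,
    tumor_shrink: float = 1.0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Evaluate image and masks at the given voxel centers.

    ``rigid_map`` maps output-frame points back into the scene frame (None =
    identity); ``displace`` is the extra displacement for deformable
    structures; ``tumor_shrink`` multiplies tumor volume (radius scaled by its
    cube root).
    """
    p_rigid = rigid_map(points) if rigid_map is not None else points
    p_deform = p_rigid + displace(p_rigid) if displace is not None else p_rigid

    shape = cfg.grid_shape
    head = _ellipsoid(p_rigid, scene.head_center, scene.head_radii)
    image = np.full(points.shape[1], AIR_HU, dtype=np.float64)
    image[head] = HEAD_HU
    extent = cfg.extent_mm
    for off_frac, r in MARKER_NODULES:
        c = scene.head_center + np.asarray(off_frac) * extent
        image[_ellipsoid(p_rigid, c, np.full(3, r))] += BONE_HU
    masks: dict[str, np.ndarray] = {}
    for spec in cfg.structures:
        r = scene.radii[spec.name].copy()
        if spec.role == "tumor":
            r = r * tumor_shrink ** (1 / 3)
        pts = p_deform if spec.rigidity == "deformable" else p_rigid
        m = _ellipsoid(pts, scene.centers[spec.name], r)
        image[m] += spec.contrast
        masks[spec.name] = m.reshape(shape)
    image = image.reshape(shape)
    image = gaussian_filter(image, cfg.smooth_sigma_vox)
    image += rng_noise.normal(0.0, cfg.noise_sd, size=shape)
    return image.astype(np.float32), masks


# ---------------------------------------------------------------------------
# Cohort generation and summary
# ---------------------------------------------------------------------------

def generate_cohort(cfg: PhantomConfig) -> tuple[list[PatientCase], dict]:
    """Generate a deterministic cohort; returns (cases, manifest extras).

    The manifest extras record, per patient, the sampled ground-truth rigid
    transform (the point map from the mid frame back to the pre frame, i.e.
    the transform a pre->mid registration should recover), the tumor
    shrinkage fraction, and the deformation amplitude.
    """
    rng = np.random.default_rng(cfg.seed)
    points = _voxel_centers(cfg)
    center = cfg.extent_mm / 2
    cases, truth = [], []
    for i in range(cfg.n_patients):
        pid = f"P{i:03d}"
        scene = _sample_scene(rng, cfg)
        angles = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg, 3)
        trans = rng.uniform(-cfg.translation_mm, cfg.translation_mm, 3)
        shrink = rng.uniform(*cfg.shrink_range)
        _, displace = _sample_deform_field(rng, cfg)
        rot = _rotation_matrix(angles)

        def rigid_map(p, rot=rot, trans=trans):
            return rot @ (p - center[:, None]) + center[:, None] + trans[:, None]

        pre_img, pre_masks = _render(cfg, scene, points, rng)
        mid_img, mid_masks = _render(
            cfg, scene, points, rng,
            rigid_map=rigid_map,
            displace=displace if cfg.deform_amplitude_mm > 0 else None,
            tumor_shrink=shrink,
        )
        tps = {}
        for tp_name, img, masks in (("pre", pre_img, pre_masks), ("mid", mid_img, mid_masks)):
            present = {
                s.name: bool(rng.random() >= s.missing_label_prob) for s in cfg.structures
            }
            ss = StructureSet(
                cfg.grid_shape,
                cfg.spacing_mm,
                np.asarray(cfg.spacing_mm) / 2,
                {
                    s.name: (masks[s.name] if present[s.name] else np.zeros(cfg.grid_shape, bool))
                    for s in cfg.structures
                },
                present,
            )
            vol = ImageVolume(img, cfg.spacing_mm, np.asarray(cfg.spacing_mm) / 2)
            tps[tp_name] = Timepoint(vol, ss)
        cases.append(PatientCase(pid, tps["pre"], tps["mid"], interval_days=int(rng.integers(14, 80))))
        truth.append(
            {
                "id": pid,
                "rigid_mid_to_pre": {
                    "angles_deg": list(angles),
                    "translation_mm": list(trans),
                    "center_mm": list(center),
                },
                "tumor_shrink_fraction": float(shrink),
                "deform_amplitude_mm": float(cfg.deform_amplitude_mm),
            }
        )
    extras = {
        "phantom_truth": truth,
        "structure_roles": {s.name: s.role for s in cfg.structures},
        "structure_rigidity": {s.name: s.rigidity for s in cfg.structures},
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
            if k != "structures"
        },
    }
    return cases, extras


def cohort_summary(cases: list[PatientCase]) -> pd.DataFrame:
    """Per-structure label counts and mean volumes (cm^3), split by timepoint."""
    if not cases:
        raise ValueError("cohort is empty")
    names = cases[0].pre.structures.names
    rows = []
    for name in names:
        counts = {"pre": 0, "mid": 0}
        vols = {"pre": [], "mid": []}
        for case in cases:
            for tp_name in ("pre", "mid"):
                ss = getattr(case, tp_name).structures
                if ss.present[name]:
                    counts[tp_name] += 1
                    vols[tp_name].append(ss.mask_volume_cm3(name))
        rows.append(
            {
                "structure": name,
                "n_pre": counts["pre"],
                "n_mid": counts["mid"],
                "n_total": counts["pre"] + counts["mid"],
                "mean_volume_pre_cm3": float(np.mean(vols["pre"])) if vols["pre"] else np.nan,
                "mean_volume_mid_cm3": float(np.mean(vols["mid"])) if vols["mid"] else np.nan,
            }
        )
    return pd.DataFrame(rows)
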