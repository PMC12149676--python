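"""Segmentation metrics and cross-validated model comparison.

Implements the dice similarity coefficient (DSC), the symmetric mean surface
distance (MSD, mm), prediction resampling to the reference grid, the
validation-DSC convergence audit, the corrected resampled t-test for
comparing models trained under k-fold cross-validation, and a per-structure
comparison table with pairwise significance markers.

The corrected resampled t-test inflates the variance of the mean fold-score
difference by ``c = 1/k + n2/n1`` (n2 test patients, n1 training patients
per run) to account for the overlap of training sets across folds, which
makes the naive paired t-test anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .imaging import ImageVolume, StructureSet, resample

__all__ = [
    "dsc",
    "msd",
    "evaluate_predictions",
    "convergence_audit",
    "TTestResult",
    "corrected_resampled_ttest",
    "comparison_report",
]

#: Validation-DSC threshold operationalizing "non-zero validation DSC".
CONVERGENCE_TAU = 0.01


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``.

    Both masks empty is scored 1 (correct prediction of absence); callers
    that need to exclude that case should test emptiness explicitly.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface_points(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Boundary voxel centers in mm: foreground with a face-adjacent background neighbour."""
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    boundary = mask & ~interior
    return np.argwhere(boundary) * spacing


def msd(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Symmetric mean surface distance in mm.

    Average, over both directions, of the mean nearest-boundary distance
    between the two masks' surfaces (face-connected surface extraction,
    physical units). Either mask empty raises ``ValueError`` — the caller
    flags such records as undefined rather than assigning a penalty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("mean surface distance is undefined for an empty mask")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    pa = _surface_points(a, spacing)
    pb = _surface_points(b, spacing)
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def evaluate_predictions(
    predictions: dict[str, StructureSet],
    references: dict[str, "object"],
    method: str,
) -> pd.DataFrame:
    """Metric table for per-patient predicted structure sets.

    ``predictions`` maps patient id to a predicted :class:`StructureSet` (any
    working resolution); ``references`` maps patient id to the reference
    mid-treatment :class:`~adaptseg.imaging.Timepoint` at the original
    resolution. Predictions are resampled (nearest-neighbour) to the
    reference grid before scoring, and only structures present in the
    reference are scored. Rows carry ``msd = NaN`` with ``msd_defined =
    False`` when either surface is empty.
    """
    rows = []
    for pid, pred in predictions.items():
        ref_tp = references[pid]
        ref = ref_tp.structures
        ref_grid = ref_tp.image
        work = pred
        if tuple(pred.shape) != tuple(ref.shape) or not np.allclose(
            pred.spacing, ref.spacing
        ):
            work = resample(pred, ref_grid.spacing)
            if tuple(work.shape) != tuple(ref.shape):
                raise ValueError(
                    f"{pid}: prediction grid {work.shape} not resample-compatible "
                    f"with reference {ref.shape}"
                )
        for name in ref.names:
            if not ref.present[name]:
                continue
            if name not in work.masks:
                raise KeyError(f"{pid}: prediction is missing channel {name!r}")
            p = work.masks[name]
            t = ref.masks[name]
            d = dsc(p, t)
            both_nonempty = bool(p.any() and t.any())
            rows.append(
                {
                    "patient_id": pid,
                    "structure": name,
                    "method": method,
                    "dsc": d,
                    "msd": msd(p, t, ref.spacing) if both_nonempty else np.nan,
                    "msd_defined": both_nonempty,
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "structure", "method", "dsc", "msd", "msd_defined"]
    )


def convergence_audit(
    traces: dict[str, dict[str, list[float]]], tau: float = CONVERGENCE_TAU
) -> pd.DataFrame:
    """Flag, per run and structure, whether validation DSC ever exceeded ``tau``.

    ``traces`` maps run name to {structure: per-epoch validation DSC}. A
    structure "converged" when the model produced any correct foreground for
    it at some epoch (max over the trace strictly greater than ``tau``).
    """
    rows = [
        {
            "run": run,
            "structure": name,
            "max_val_dsc": float(np.max(trace)) if len(trace) else 0.0,
            "converged": bool(len(trace) and np.max(trace) > tau),
        }
        for run, per_structure in traces.items()
        for name, trace in per_structure.items()
    ]
    return pd.DataFrame(rows, columns=["run", "structure", "max_val_dsc", "converged"])


@dataclass
class TTestResult:
    differences: np.ndarray  # per-fold score differences d_j
    k: int
    n_train: int
    n_test: int
    correction: float  # c = 1/k + n_test/n_train
    t: float
    df: int
    p: float
    degenerate: bool = False


def corrected_resampled_ttest(
    scores_a, scores_b, n_train: int, n_test: int
) -> TTestResult:
    """Corrected resampled t-test on paired per-fold scores.

    ``t = mean(d) / sqrt((1/k + n2/n1) * var(d))`` with ``d_j = a_j - b_j``,
    sample variance over the k folds, and a two-sided p from Student's t
    with k-1 degrees of freedom. With ``n2/n1 -> 0`` this recovers the naive
    resampled t-test. Zero variance is degenerate: p = 1 if the mean
    difference is 0, else p = 0, flagged.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 fold scores")
    d = a - b
    k = d.size
    c = 1.0 / k + n_test / n_train
    var = float(d.var(ddof=1))
    mean = float(d.mean())
    if var == 0.0:
        return TTestResult(d, k, n_train, n_test, c, np.inf if mean else 0.0,
                           k - 1, 0.0 if mean else 1.0, degenerate=True)
    t = mean / np.sqrt(c * var)
    p = 2.0 * float(stats.t.sf(abs(t), df=k - 1))
    return TTestResult(d, k, n_train, n_test, c, float(t), k - 1, p)


def _fold_means(records: pd.DataFrame, fold_of: dict[str, int], value: str) -> pd.DataFrame:
    df = records.copy()
    df["fold"] = df["patient_id"].map(fold_of)
    if df["fold"].isna().any():
        missing = df.loc[df["fold"].isna(), "patient_id"].unique()
        raise ValueError(f"patients missing from fold plan: {missing[:5]}")
    return (
        df.groupby(["structure", "method", "fold"], sort=False)[value]
        .mean()
        .reset_index()
    )


def comparison_report(
    records: pd.DataFrame,
    fold_plan,
    methods: list[str] | None = None,
    baseline: str | None = None,
    value: str = "dsc",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-structure table of per-method mean ± sd over fold means.

    Fold means are computed per test fold over patients, then summarized as
    mean ± sd over folds. When ``baseline`` is given, every other method is
    compared against it with the corrected resampled t-test on the per-fold
    means (two-sided, no multiplicity correction across structures), and a
    ``*`` marker is attached where p < ``alpha``. Structures scored in fewer
    than 2 folds for a method are reported without sd.
    """
    if methods is None:
        methods = list(records["method"].unique())
    for m in methods:
        if m not in set(records["method"]):
            raise ValueError(f"method {m!r} absent from records")
    fold_of = {pid: j for j, fold in enumerate(fold_plan.folds) for pid in fold}
    n_train = len(fold_of) - len(fold_plan.folds[0])
    n_test = len(fold_plan.folds[0])
    fm = _fold_means(records[records["method"].isin(methods)], fold_of, value)

    rows = []
    for structure, grp in fm.groupby("structure", sort=False):
        row: dict = {"structure": structure}
        per_method = {m: g.set_index("fold")[value] for m, g in grp.groupby("method")}
        for m in methods:
            scores = per_method.get(m, pd.Series(dtype=float))
            if len(scores) == 0:
                row[f"{m}_mean"], row[f"{m}_sd"] = np.nan, np.nan
            elif len(scores) == 1:
                row[f"{m}_mean"], row[f"{m}_sd"] = float(scores.iloc[0]), np.nan
            else:
                row[f"{m}_mean"], row[f"{m}_sd"] = float(scores.mean()), float(scores.std(ddof=1))
            if baseline and m != baseline:
                marker = ""
                a = per_method.get(m)
                b = per_method.get(baseline)
                if a is not None and b is not None:
                    common = sorted(set(a.index) & set(b.index))
                    if len(common) >= 2:
                        res = corrected_resampled_ttest(
                            a.loc[common].to_numpy(), b.loc[common].to_numpy(),
                            n_train, n_test,
                        )
                        if res.p < alpha:
                            marker = "*"
                row[f"{m}_vs_{baseline}"] = marker
        rows.append(row)
    return pd.DataFrame(rows)
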