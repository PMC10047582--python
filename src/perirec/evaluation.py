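"""Voxelwise and cavity-centered sector (region-based) evaluation.

Voxelwise scoring compares each peritumoral voxel's prediction with ground
truth.  Because recurrence regions evolve and coregistration is imperfect,
exact voxel overlap understates clinically meaningful agreement, so the
peritumor is additionally partitioned into up to 26 directional sectors
around the cavity centroid (6 faces, 12 edges, 8 corners) and predictions are
scored at the sector level with the same six metrics: AUC, accuracy,
precision, recall, F1 and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, cohen_kappa_score, f1_score,
                             precision_score, recall_score, roc_auc_score)

from .io import MaskVolume
from .labeling import RECURRENCE, LabelVolume
from .postprocess import ProbabilityMap

METRIC_NAMES = ("auc", "accuracy", "precision", "recall", "f1", "kappa")

_AXIS_NAMES = {"R": ("left", "right"), "L": ("right", "left"),
               "A": ("posterior", "anterior"), "P": ("anterior", "posterior"),
               "S": ("inferior", "superior"), "I": ("superior", "inferior")}


@dataclass
class SectorPartition:
    """Assignment of each peritumoral voxel to one of 26 directional sectors."""

    sector_ids: np.ndarray      # 3D int array, -1 outside the peritumor
    centroid_mm: np.ndarray
    names: dict[int, str]       # sector id -> anatomical name

    @property
    def present_ids(self) -> np.ndarray:
        ids = np.unique(self.sector_ids)
        return ids[ids >= 0]


def sector_partition(peritumor: MaskVolume, cavity: MaskVolume,
                     neutral_band_deg: float = 22.5) -> SectorPartition:
    """Partition the peritumor by per-axis direction signs around the cavity centroid.

    A displacement's axis component is neutral when the direction vector makes
    an angle of at most ``neutral_band_deg`` with the plane orthogonal to that
    axis (|u_axis| < sin(band)); the remaining sign triple (at least one axis
    is always non-neutral) indexes one of 3^3 - 1 = 26 sectors.  A voxel
    exactly at the centroid is assigned by the nearest-nonzero-axis rule
    (positive along the last axis).
    """
    if peritumor.n_voxels == 0 or cavity.n_voxels == 0:
        raise ValueError("peritumor and cavity masks must be nonempty")
    if not peritumor.same_geometry(cavity):
        raise ValueError("peritumor and cavity geometry differ")
    cav_idx = cavity.indices
    centroid_vox = cav_idx.mean(axis=0)
    A, b = peritumor.affine[:3, :3], peritumor.affine[:3, 3]
    centroid_mm = A @ centroid_vox + b

    idx = peritumor.indices
    disp = (idx @ A.T + b) - centroid_mm
    norm = np.linalg.norm(disp, axis=1)
    unit = np.divide(disp, norm[:, None], out=np.zeros_like(disp), where=norm[:, None] > 0)
    thr = np.sin(np.deg2rad(neutral_band_deg))
    signs = np.zeros(disp.shape, dtype=np.int8)
    signs[unit > thr] = 1
    signs[unit < -thr] = -1
    degenerate = (signs == 0).all(axis=1)
    signs[degenerate, 2] = 1  # centroid voxel: nearest-nonzero-axis rule

    codes = (signs[:, 0] + 1) * 9 + (signs[:, 1] + 1) * 3 + (signs[:, 2] + 1)
    sector_ids = np.full(peritumor.shape, -1, dtype=np.int8)
    sector_ids[tuple(idx.T)] = codes

    axcodes = peritumor.orientation
    names = {}
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                if sx == sy == sz == 0:
                    continue
                parts = [_AXIS_NAMES[axcodes[a]][(s + 1) // 2]
                         for a, s in enumerate((sx, sy, sz)) if s != 0]
                names[(sx + 1) * 9 + (sy + 1) * 3 + (sz + 1)] = "-".join(parts)
    return SectorPartition(sector_ids=sector_ids, centroid_mm=centroid_mm, names=names)


def sector_labels(partition: SectorPartition, voxel_mask: MaskVolume,
                  activation_fraction: float = 0.05) -> dict[int, bool]:
    """A sector is positive iff its positive-voxel count reaches
    ``activation_fraction`` of the sector's peritumoral voxel count."""
    ids = partition.sector_ids
    out: dict[int, bool] = {}
    pos = voxel_mask.data > 0
    for sid in partition.present_ids:
        sel = ids == sid
        size = int(sel.sum())
        if size == 0:
            continue
        out[int(sid)] = bool(pos[sel].sum() >= activation_fraction * size)
    return out


def _threshold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    kappa = cohen_kappa_score(y_true, y_pred, labels=[0, 1])
    if not np.isfinite(kappa):
        # degenerate case (single class on both sides): no chance correction
        kappa = 0.0
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "kappa": float(kappa),
    }


def voxel_metrics(scores: np.ndarray, predicted: MaskVolume,
                  truth: LabelVolume) -> dict[str, float | None]:
    """Six voxelwise metrics: AUC from continuous corrected scores, the rest
    from the thresholded prediction.  Single-class truth reports AUC as None."""
    support = truth.support
    y_true = (truth.data[support] == RECURRENCE).astype(int)
    y_pred = predicted.data[support].astype(int)
    s = np.asarray(scores, dtype=float)
    out: dict[str, float | None] = {}
    if np.unique(y_true).size < 2:
        out["auc"] = None
        out["auc_missing_reason"] = "single-class ground truth"
    else:
        out["auc"] = float(roc_auc_score(y_true, s))
    out.update(_threshold_metrics(y_true, y_pred))
    return out


def sector_metrics(partition: SectorPartition, truth_mask: MaskVolume,
                   predicted: MaskVolume, corrected: ProbabilityMap,
                   activation_fraction: float = 0.05,
                   score_percentile: float = 95.0) -> dict[str, float | None]:
    """Six metrics over sectors; the sector score for AUC is a high percentile
    (default 95th) of the corrected voxel probabilities within the sector."""
    truth = sector_labels(partition, truth_mask, activation_fraction)
    pred = sector_labels(partition, predicted, activation_fraction)
    sids = sorted(truth)
    if len(sids) < 2:
        raise ValueError("need at least two scored sectors")
    y_true = np.array([truth[s] for s in sids], dtype=int)
    y_pred = np.array([pred[s] for s in sids], dtype=int)
    scores = np.array([
        float(np.percentile(corrected.values[partition.sector_ids == s],
                            score_percentile))
        for s in sids])
    out: dict[str, float | None] = {}
    if np.unique(y_true).size < 2:
        out["auc"] = None
        out["auc_missing_reason"] = "single-class sector truth"
    else:
        out["auc"] = float(roc_auc_score(y_true, scores))
    out.update(_threshold_metrics(y_true, y_pred))
    return out


def roc_points(scores: np.ndarray, truth: LabelVolume) -> pd.DataFrame:
    """Per-case ROC curve points (fpr, tpr, threshold) as a DataFrame, the
    data behind a per-patient ROC plot."""
    from sklearn.metrics import roc_curve

    y_true = (truth.data[truth.support] == RECURRENCE).astype(int)
    if np.unique(y_true).size < 2:
        raise ValueError("single-class ground truth: ROC undefined")
    fpr, tpr, thr = roc_curve(y_true, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def aggregate_cohort(per_case: list[dict], mode: str = "voxel",
                     algorithm: str = "") -> pd.DataFrame:
    """Mean and SD (population convention) per metric across cases.

    Cases with a missing metric (e.g. undefined AUC) are excluded from that
    metric's aggregation; the contributing count is reported.
    """
    if not per_case:
        raise ValueError("no cases to aggregate")
    rows = []
    for m in METRIC_NAMES:
        vals = np.array([c[m] for c in per_case if c.get(m) is not None], dtype=float)
        rows.append({"algorithm": algorithm, "mode": mode, "metric": m,
                     "mean": float(vals.mean()) if vals.size else np.nan,
                     "sd": float(vals.std(ddof=0)) if vals.size else np.nan,
                     "n_cases": int(vals.size),
                     "formatted": (f"{vals.mean():.2f} ± {vals.std(ddof=0):.2f}"
                                   if vals.size else "n/a")})
    return pd.DataFrame(rows)
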