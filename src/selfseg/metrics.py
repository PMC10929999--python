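"""Spacing-aware segmentation evaluation.

Implements the four standard mask-agreement measures between a prediction
P and a reference G:

* DSC = 2|P∩G| / (|P|+|G|) — volumetric overlap in [0, 1];
* HD — the symmetric Hausdorff distance between mask surfaces, in mm;
* HD95 — the 95th percentile of the pooled directed surface distances,
  robust to single outlier voxels;
* ASD = (Σ_p min_g ‖p−g‖ + Σ_g min_p ‖p−g‖) / (|S(P)|+|S(G)|) — the
  average symmetric surface distance.

Surfaces are the centers (index · spacing, in mm) of foreground voxels
with at least one non-foreground face-neighbor; voxels on the grid edge
count as boundary. Distance metrics are undefined for empty masks and are
reported as such, never as a silent zero.

Also provided: the six-bin expert revision score (5 = no revision needed,
0 = more than 80% of the volume needs revision) and the composite accuracy
score Σ_organ (DSC + mean expert score / 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import (
    ContractError,
    LabelMap,
    ORGAN_CLASSES,
    ORGAN_NAMES,
    UndefinedMetricError,
)

# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------


def dsc(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice similarity coefficient 2|P∩G|/(|P|+|G|).

    Conventions at the degenerate ends: both masks empty → 1.0 (perfect
    agreement on absence); exactly one empty → 0.0.
    """
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(ref_mask, dtype=bool)
    if p.shape != g.shape:
        raise ContractError(f"shape mismatch: {p.shape} vs {g.shape}")
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return 1.0
    if np_ == 0 or ng == 0:
        return 0.0
    return 2.0 * int((p & g).sum()) / (np_ + ng)


# ---------------------------------------------------------------------------
# surfaces and distances
# ---------------------------------------------------------------------------


@dataclass
class SurfacePointSet:
    """Physical (mm) coordinates of a mask's boundary-voxel centers."""

    points: np.ndarray  # (n, ndim) float64, mm
    source_class: int = -1


def surface_points(mask: np.ndarray, spacing_mm) -> SurfacePointSet:
    """Boundary voxels of a nonempty mask as physical points.

    A foreground voxel is boundary if any of its face-neighbors is
    background, counting positions beyond the grid edge as background.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise UndefinedMetricError("surface of an empty mask is undefined")
    structure = ndimage.generate_binary_structure(m.ndim, 1)
    interior = ndimage.binary_erosion(m, structure=structure, border_value=0)
    boundary = m & ~interior
    idx = np.argwhere(boundary).astype(np.float64)
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    if spacing.shape != (m.ndim,):
        raise ContractError(f"spacing must have {m.ndim} entries")
    return SurfacePointSet(points=idx * spacing)


def _directed_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distance from every point of a to the set b."""
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return np.asarray(d, dtype=np.float64)


def _surface_pair(pred_mask, ref_mask, spacing_mm):
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(ref_mask, dtype=bool)
    if p.shape != g.shape:
        raise ContractError(f"shape mismatch: {p.shape} vs {g.shape}")
    sp = surface_points(p, spacing_mm).points
    sg = surface_points(g, spacing_mm).points
    return _directed_distances(sp, sg), _directed_distances(sg, sp)


def hausdorff(pred_mask, ref_mask, spacing_mm) -> float:
    """Symmetric Hausdorff distance max(max min ‖p−g‖, max min ‖g−p‖), mm."""
    d_pg, d_gp = _surface_pair(pred_mask, ref_mask, spacing_mm)
    return float(max(d_pg.max(), d_gp.max()))


def hd95(pred_mask, ref_mask, spacing_mm) -> float:
    """95th percentile (linear interpolation) of the pooled directed
    surface distances of both directions, mm."""
    d_pg, d_gp = _surface_pair(pred_mask, ref_mask, spacing_mm)
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


def asd(pred_mask, ref_mask, spacing_mm) -> float:
    """Average symmetric surface distance, mm."""
    d_pg, d_gp = _surface_pair(pred_mask, ref_mask, spacing_mm)
    return float((d_pg.sum() + d_gp.sum()) / (len(d_pg) + len(d_gp)))


# ---------------------------------------------------------------------------
# expert scoring
# ---------------------------------------------------------------------------


def revision_score(revised_volume_fraction: float) -> int:
    """Map the revised-volume fraction to the six-bin expert score.

    0 → 5 (no revision); (0, 0.2] → 4; (0.2, 0.4] → 3; (0.4, 0.6] → 2;
    (0.6, 0.8] → 1; (0.8, 1.0] → 0.
    """
    f = float(revised_volume_fraction)
    if not 0.0 <= f <= 1.0:
        raise ContractError(f"fraction must lie in [0, 1], got {f}")
    if f == 0.0:
        return 5
    return int(5 - np.ceil(f / 0.2 - 1e-12))


def composite_accuracy(per_organ_dsc: Sequence[float],
                       per_organ_expert_scores: Sequence) -> float:
    """Σ_organ (DSC + mean expert score / 5).

    Each entry of ``per_organ_expert_scores`` may be a single score or an
    iterable of scores from several experts (averaged before scaling).
    """
    if len(per_organ_dsc) == 0 or len(per_organ_dsc) != len(per_organ_expert_scores):
        raise ContractError("need equal-length, nonempty per-organ lists")
    total = 0.0
    for d, s in zip(per_organ_dsc, per_organ_expert_scores):
        s_mean = float(np.mean(s))
        total += float(d) + s_mean / 5.0
    return total


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------


def evaluate_pair(
    pred: LabelMap,
    ref: LabelMap,
    organs: Iterable[int] = ORGAN_CLASSES,
) -> List[dict]:
    """Per-organ metric rows for one case.

    Distance metrics undefined for an organ (empty in either mask) are
    reported as NaN with ``defined`` False.
    """
    if pred.shape != ref.shape:
        raise ContractError("prediction and reference shapes differ")
    spacing = ref.spacing_mm
    rows = []
    for cls in organs:
        p = pred.data == cls
        g = ref.data == cls
        row = {
            "case_id": ref.case_id or pred.case_id,
            "organ_class": cls,
            "organ": ORGAN_NAMES.get(cls, str(cls)),
            "dsc": dsc(p, g),
        }
        try:
            d_pg, d_gp = _surface_pair(p, g, spacing)
            pooled = np.concatenate([d_pg, d_gp])
            row.update(hd_mm=float(pooled.max()),
                       hd95_mm=float(np.percentile(pooled, 95)),
                       asd_mm=float(pooled.sum() / len(pooled)),
                       defined=True)
        except UndefinedMetricError:
            row.update(hd_mm=np.nan, hd95_mm=np.nan, asd_mm=np.nan, defined=False)
        rows.append(row)
    return rows


def evaluate_cases(
    pairs: Sequence[Tuple[LabelMap, LabelMap]],
    organs: Iterable[int] = ORGAN_CLASSES,
) -> pd.DataFrame:
    """MetricsReport over (prediction, reference) pairs: one row per
    (case, organ) with dsc / hd_mm / hd95_mm / asd_mm."""
    rows = []
    for pred, ref in pairs:
        rows.extend(evaluate_pair(pred, ref, organs))
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Per-organ means of the metric columns (NaN-aware for distances)."""
    cols = ["dsc", "hd_mm", "hd95_mm", "asd_mm"]
    return report.groupby(["organ_class", "organ"], as_index=False)[cols].mean()
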