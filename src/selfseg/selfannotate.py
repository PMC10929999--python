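"""Ensemble pseudo-labeling ("self-annotation") of unlabeled volumes.

The k fold-models trained by cross-validation each predict per-class
probability maps for an unlabeled case; the maps are combined by average
voting (voxelwise arithmetic mean of softmax probabilities) and decoded to
hard labels by argmax, ties broken toward the lowest class index so
background wins. The resulting pseudo-labels, after post-processing, can
be added to the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd

from .core import ContractError, LabelMap, ProbabilityMap, check_aligned
from .network import UNet, load_checkpoint, predict_probabilities


@dataclass
class EnsembleSpec:
    """An ordered collection of trained fold-models.

    ``model_refs`` may hold in-memory :class:`UNet` objects or checkpoint
    paths; paths are loaded lazily. All members must share the output class
    count (enforced on load).
    """

    model_refs: Sequence = field(default_factory=list)
    tie_rule: str = "lowest_index"

    def __post_init__(self):
        if len(self.model_refs) < 1:
            raise ContractError("an ensemble needs at least one model")

    def load_models(self) -> List[UNet]:
        models = []
        for ref in self.model_refs:
            if isinstance(ref, UNet):
                models.append(ref)
            else:
                try:
                    models.append(load_checkpoint(ref))
                except Exception as exc:
                    raise ContractError(
                        f"failed to load ensemble model {ref!r}: {exc}") from exc
        out_channels = {m.config.out_channels for m in models}
        if len(out_channels) != 1:
            raise ContractError("ensemble members disagree on output channels")
        return models


def ensemble_average(maps: Sequence[ProbabilityMap]) -> ProbabilityMap:
    """Voxelwise arithmetic mean of aligned probability maps.

    The mean of distributions is a distribution, so per-voxel sums remain
    1; the operation is permutation-invariant and idempotent on identical
    inputs.
    """
    if len(maps) < 1:
        raise ContractError("need at least one probability map")
    first = maps[0]
    for m in maps[1:]:
        check_aligned(first, m, "probability maps")
        if m.case_id != first.case_id:
            raise ContractError(
                f"probability maps belong to different cases: "
                f"{first.case_id!r} vs {m.case_id!r}")
    mean = np.mean([m.data.astype(np.float64) for m in maps], axis=0)
    return ProbabilityMap(mean.astype(np.float32), first.spacing_mm,
                          case_id=first.case_id)


def labels_from_probabilities(pmap: ProbabilityMap) -> LabelMap:
    """Per-voxel argmax over the 5 classes; ties go to the lowest index."""
    # np.argmax returns the first maximal index, which is the lowest class
    labels = np.argmax(pmap.data, axis=0).astype(np.uint8)
    return LabelMap(labels, pmap.spacing_mm, case_id=pmap.case_id)


def self_annotate(
    ensemble: EnsembleSpec,
    unlabeled_cases: Sequence,
    out_dir=None,
    window: Optional[Tuple[int, ...]] = None,
    overlap: float = 0.5,
) -> Tuple[List[LabelMap], pd.DataFrame]:
    """Pseudo-label unlabeled volumes with the fold-model ensemble.

    ``unlabeled_cases`` holds preprocessed (normalized, resampled)
    :class:`Volume` objects. For each case every model predicts
    probabilities, the maps are averaged and decoded to labels. Returns the
    pseudo-label maps plus a per-case confidence summary (mean max
    probability). When ``out_dir`` is given, pseudo-labels are written as
    NIfTI and the summary as CSV. Input images are never modified.
    """
    from . import preprocess

    models = ensemble.load_models()
    if len(unlabeled_cases) == 0:
        warnings.warn("self_annotate called with zero unlabeled cases; no-op")
        return [], pd.DataFrame(columns=["case_id", "mean_max_probability"])

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    pseudo, rows = [], []
    for vol in unlabeled_cases:
        maps = [predict_probabilities(m, vol, window=window, overlap=overlap)
                for m in models]
        mean_map = ensemble_average(maps)
        labels = labels_from_probabilities(mean_map)
        confidence = float(mean_map.data.max(axis=0).mean())
        pseudo.append(labels)
        rows.append({"case_id": vol.case_id, "mean_max_probability": confidence})
        if out is not None:
            preprocess.write_labelmap(labels, out / f"{vol.case_id}_pseudo.nii.gz")
    summary = pd.DataFrame(rows)
    if out is not None:
        summary.to_csv(out / "confidence.csv", index=False)
    return pseudo, summary
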