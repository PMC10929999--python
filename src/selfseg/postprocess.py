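"""Morphological repair of pseudo-labels and predictions.

Raw network output typically contains two easily-removed error modes:
interior cavities inside an organ and small spurious fragments away from
it. Each foreground class is repaired independently by (1) filling
enclosed background holes, (2) keeping only the k largest connected
components — k encodes anatomy: one bladder, two femoral heads, one
rectum, any number of intestine lobes — and (3) optional binary closing
with a ball element. Classes are processed in index order and never
overwrite one another, preserving label exclusivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional
import warnings

import numpy as np
from scipy import ndimage

from .core import ContractError, ConfigurationError, LabelMap, ORGAN_CLASSES

#: unlimited component budget
UNLIMITED = None


@dataclass
class ClassRule:
    keep_components: Optional[int] = 1  # None = unlimited
    fill_holes: bool = True
    closing_radius_vox: int = 0

    def __post_init__(self):
        if self.keep_components is not None and self.keep_components < 1:
            raise ConfigurationError("keep_components must be >= 1 or None")
        if self.closing_radius_vox < 0:
            raise ConfigurationError("closing_radius_vox must be >= 0")


def default_rules() -> Dict[int, ClassRule]:
    return {
        1: ClassRule(keep_components=1),
        2: ClassRule(keep_components=2),  # bilateral
        3: ClassRule(keep_components=1),
        4: ClassRule(keep_components=UNLIMITED),  # multi-lobed
    }


@dataclass
class PostprocessRules:
    """Per-class repair budgets plus the connectivity convention.

    ``connectivity`` is "face" (6-neighborhood) or "full"
    (26-neighborhood, the default).
    """

    per_class: Dict[int, ClassRule] = field(default_factory=default_rules)
    connectivity: str = "full"

    def __post_init__(self):
        if self.connectivity not in ("face", "full"):
            raise ConfigurationError("connectivity must be 'face' or 'full'")

    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, 1 if self.connectivity == "face"
                                                 else 3)


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ContractError("mask must be binary")
        mask = mask.astype(bool)
    return mask


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the grid border.

    Face connectivity defines the background's reachability, so any cavity
    a flood fill from the border cannot reach becomes foreground. Singleton
    axes are squeezed away first: a one-slice image is a 2D image, and its
    in-plane cavities must not escape through the nonexistent third
    dimension. The output is a superset of the input and the operation is
    idempotent.
    """
    mask = _check_binary(mask)
    squeezed = [ax for ax, n in enumerate(mask.shape) if n == 1]
    if squeezed and mask.ndim - len(squeezed) >= 1:
        filled = ndimage.binary_fill_holes(np.squeeze(mask,
                                                      axis=tuple(squeezed)))
        return filled.reshape(mask.shape)
    return ndimage.binary_fill_holes(mask)


def keep_largest_components(
    mask: np.ndarray,
    k: Optional[int] = 1,
    connectivity: str = "full",
) -> np.ndarray:
    """Retain the k largest connected components by voxel count.

    ``k=None`` keeps everything. Size ties are broken toward the component
    whose first voxel appears earliest in scan order. An empty input is
    returned empty with a warning.
    """
    mask = _check_binary(mask)
    if k is not None and k < 1:
        raise ContractError("k must be >= 1 or None")
    if not mask.any():
        warnings.warn("keep_largest_components called on an empty mask")
        return mask.copy()
    if k is None:
        return mask.copy()
    structure = ndimage.generate_binary_structure(
        mask.ndim, 1 if connectivity == "face" else mask.ndim)
    lab, n = ndimage.label(mask, structure=structure)
    if n <= k:
        return mask.copy()
    flat = lab.ravel()
    sizes = np.bincount(flat)[1:]  # component ids 1..n
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first scan-order occurrence of each id
    ids, idx = np.unique(flat[nz], return_index=True)
    first[ids] = nz[idx]
    order = sorted(range(1, n + 1), key=lambda i: (-sizes[i - 1], first[i]))
    keep = set(order[:k])
    return np.isin(lab, list(keep))


def _ball(radius: int, ndim: int = 3) -> np.ndarray:
    r = int(radius)
    grids = np.meshgrid(*([np.arange(-r, r + 1)] * ndim), indexing="ij")
    return np.sum([g ** 2 for g in grids], axis=0) <= r ** 2


def morphological_smooth(mask: np.ndarray, radius_vox: int = 1) -> np.ndarray:
    """Binary closing with a ball element; radius 0 is the identity.

    The grid is padded before closing so structures touching the border are
    not eroded by the boundary condition.
    """
    mask = _check_binary(mask)
    r = int(radius_vox)
    if r < 0:
        raise ContractError("radius must be >= 0")
    if r == 0 or not mask.any():
        return mask.copy()
    ball = _ball(r, mask.ndim)
    padded = np.pad(mask, r, constant_values=False)
    closed = ndimage.binary_erosion(ndimage.binary_dilation(padded, ball), ball)
    core = tuple(slice(r, r + n) for n in mask.shape)
    return closed[core]


def postprocess_labelmap(labels: LabelMap,
                         rules: Optional[PostprocessRules] = None) -> LabelMap:
    """Repair every foreground class of a label map.

    Per class, in index order 1..4: binarize → fill holes → keep the k
    largest components → close. Earlier classes own contested voxels
    (first-writer-wins), so the output remains overlap-free; background is
    the complement of all repaired organs.
    """
    rules = rules if rules is not None else PostprocessRules()
    out = np.zeros_like(labels.data)
    for cls in ORGAN_CLASSES:
        rule = rules.per_class.get(cls, ClassRule())
        mask = labels.data == cls
        if not mask.any():
            continue
        if rule.fill_holes:
            mask = fill_holes(mask)
        mask = keep_largest_components(mask, rule.keep_components,
                                       rules.connectivity)
        if rule.closing_radius_vox > 0:
            mask = morphological_smooth(mask, rule.closing_radius_vox)
        mask &= out == 0
        out[mask] = cls
    return labels.with_data(out)


def rules_matching_labels(labels: LabelMap,
                          connectivity: str = "full") -> PostprocessRules:
    """Rules whose component budgets equal the actual counts in ``labels``.

    Useful when a clean reference is available (e.g. phantom ground truth):
    repairing a corrupted copy with these rules removes all spurious
    fragments.
    """
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == "face"
                                                  else 3)
    per_class = {}
    for cls in ORGAN_CLASSES:
        mask = labels.data == cls
        n = ndimage.label(mask, structure=structure)[1] if mask.any() else 1
        per_class[cls] = ClassRule(keep_components=max(n, 1))
    return PostprocessRules(per_class=per_class, connectivity=connectivity)
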