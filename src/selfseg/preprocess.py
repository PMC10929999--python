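"""Image I/O and preparation: NIfTI read/write, per-image z-score
normalization, spacing resampling, patch extraction and augmentation.

Conventions
-----------
* Arrays are (z, y, x); NIfTI files store (x, y, z), so axes are reversed
  on load/save. Affines are written axis-aligned (RAS); rotational parts of
  input affines are ignored, only the zooms and translation are used.
* Images are float32, labels unsigned 8-bit.
* Resampling is applied before per-image normalization in the pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import (
    ContractError,
    DimensionalityError,
    LabelMap,
    Volume,
    check_aligned,
)

# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _to_nifti(data_zyx: np.ndarray, spacing_zyx, origin_zyx, dtype) -> nib.Nifti1Image:
    data_xyz = np.ascontiguousarray(np.transpose(data_zyx, (2, 1, 0)).astype(dtype))
    affine = np.diag([spacing_zyx[2], spacing_zyx[1], spacing_zyx[0], 1.0])
    affine[:3, 3] = [origin_zyx[2], origin_zyx[1], origin_zyx[0]]
    img = nib.Nifti1Image(data_xyz, affine)
    img.header.set_zooms((spacing_zyx[2], spacing_zyx[1], spacing_zyx[0]))
    return img


def _from_nifti(path) -> Tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin_xyz = img.affine[:3, 3]
    data_zyx = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    spacing_zyx = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin_zyx = (float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0]))
    return data_zyx, spacing_zyx, origin_zyx


def read_volume(path) -> Volume:
    """Read a 3D NIfTI image as a float32 :class:`Volume`."""
    data, spacing, origin = _from_nifti(path)
    return Volume(data.astype(np.float32), spacing, origin, case_id=Path(path).stem)


def write_volume(volume: Volume, path) -> None:
    nib.save(_to_nifti(volume.data, volume.spacing_mm, volume.origin_mm, np.float32),
             str(path))


def read_labelmap(path) -> LabelMap:
    """Read a 3D NIfTI label image; values must lie in 0..4 (validated)."""
    data, spacing, origin = _from_nifti(path)
    if not np.issubdtype(data.dtype, np.integer):
        data = np.rint(data)
    return LabelMap(data, spacing, origin, case_id=Path(path).stem)


def write_labelmap(labels: LabelMap, path) -> None:
    nib.save(_to_nifti(labels.data, labels.spacing_mm, labels.origin_mm, np.uint8),
             str(path))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def zscore_normalize(volume: Volume) -> Volume:
    """Per-image z-score: subtract the mean, divide by the population sd.

    A constant image maps to all zeros (the z-score is undefined there; the
    all-zero convention keeps the operation total and deterministic).
    """
    x = volume.data.astype(np.float64)
    mu = x.mean()
    sd = x.std()  # population sd
    if sd < 1e-12:
        out = np.zeros_like(x, dtype=np.float32)
    else:
        out = ((x - mu) / sd).astype(np.float32)
    return volume.with_data(out)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def resample(
    obj: Union[Volume, LabelMap],
    target_spacing_mm,
    mode: Optional[str] = None,
) -> Union[Volume, LabelMap]:
    """Resample a volume or label map to a new voxel spacing.

    The new grid shape per axis is round(old_shape * old_spacing / target),
    rounding half away from zero, with a minimum of 1. Voxel centers align
    at the origin. Images use linear interpolation, labels nearest-neighbor
    (requesting linear for labels is an error). A target equal to the source
    spacing returns the input unchanged.
    """
    target = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target):
        raise ContractError(f"target spacing must be > 0, got {target}")
    is_labels = isinstance(obj, LabelMap)
    if mode is None:
        mode = "nearest" if is_labels else "linear"
    if is_labels and mode != "nearest":
        raise ContractError("labels must be resampled with mode='nearest'")
    if mode not in ("linear", "nearest"):
        raise ContractError(f"unknown mode {mode!r}")

    old_shape = np.array(obj.shape, dtype=np.float64)
    old_spacing = np.array(obj.spacing_mm)
    if np.allclose(old_spacing, target, rtol=0, atol=1e-12):
        return obj
    new_shape = np.maximum(
        _round_half_away(old_shape * old_spacing / np.array(target)), 1
    ).astype(int)

    # source index of each target voxel center: i_new * target / old
    coords = np.meshgrid(
        *(np.arange(n) * t / s for n, t, s in zip(new_shape, target, old_spacing)),
        indexing="ij",
    )
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        obj.data.astype(np.float32 if not is_labels else obj.data.dtype),
        np.stack([c.ravel() for c in coords]),
        order=order, mode="nearest",
    ).reshape(tuple(new_shape))
    if is_labels:
        return LabelMap(out.astype(obj.data.dtype), target, obj.origin_mm, obj.case_id)
    return Volume(out.astype(np.float32), target, obj.origin_mm, obj.case_id)


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------


@dataclass
class PatchPair:
    """An image patch and its aligned label patch, with provenance."""

    image_patch: np.ndarray
    label_patch: np.ndarray
    provenance: tuple = ("", (0, 0, 0))

    def __post_init__(self):
        if self.image_patch.shape != self.label_patch.shape:
            raise ContractError("image and label patch shapes differ")


def _pad_to(arr: np.ndarray, size, cval) -> Tuple[np.ndarray, tuple]:
    """Symmetrically pad ``arr`` up to ``size``; returns array + lead pads."""
    pads, leads = [], []
    for n, s in zip(arr.shape, size):
        extra = max(s - n, 0)
        lo = extra // 2
        pads.append((lo, extra - lo))
        leads.append(lo)
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, constant_values=cval)
    return arr, tuple(leads)


def extract_patch(
    volume: Volume,
    labels: Optional[LabelMap],
    patch_size,
    rng: np.random.Generator,
    foreground_fraction: float = 0.0,
) -> PatchPair:
    """Sample one training patch of exactly ``patch_size`` voxels.

    If the source is smaller than the patch along an axis, the image is
    symmetrically zero-padded and the labels background-padded. The patch
    corner is drawn uniformly from valid corners; with probability
    ``foreground_fraction`` the patch is instead centered on a randomly
    chosen foreground voxel (oversampling the organs).
    """
    size = tuple(int(s) for s in patch_size)
    if any(s < 1 for s in size):
        raise ContractError(f"patch_size must be >= 1 per axis, got {size}")
    img = volume.data
    if labels is not None:
        check_aligned(volume, labels, "volume and labels")
        lab = labels.data
    else:
        lab = np.zeros(img.shape, dtype=np.uint8)

    img, _ = _pad_to(img, size, 0.0)
    lab, _ = _pad_to(lab, size, 0)

    max_corner = [n - s for n, s in zip(img.shape, size)]
    if foreground_fraction > 0 and rng.random() < foreground_fraction:
        fg = np.argwhere(lab > 0)
        if len(fg):
            center = fg[rng.integers(len(fg))]
            corner = [int(np.clip(c - s // 2, 0, m))
                      for c, s, m in zip(center, size, max_corner)]
        else:
            corner = [int(rng.integers(m + 1)) for m in max_corner]
    else:
        corner = [int(rng.integers(m + 1)) for m in max_corner]

    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    return PatchPair(img[sl].copy(), lab[sl].copy(),
                     provenance=(volume.case_id, tuple(corner)))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def rotate_inplane(arr: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Rotate about the (y, x) plane, preserving shape.

    Multiples of 90° are lattice-exact (pure axis permutation/reflection);
    other angles interpolate (linear for images, nearest for labels) with
    constant padding.
    """
    a = angle_deg % 360.0
    if np.isclose(a % 90.0, 0.0, atol=1e-9):
        k = int(round(a / 90.0)) % 4
        # np.rot90 changes shape only for non-square planes; in-plane patches
        # are square in all presets, and rot90 twice is always shape-safe.
        if k == 0:
            return arr.copy()
        if arr.shape[-1] == arr.shape[-2] or k == 2:
            return np.rot90(arr, k=k, axes=(-2, -1)).copy()
    return ndimage.rotate(arr, angle_deg, axes=(-2, -1), reshape=False,
                          order=order, mode="constant", cval=0)


def _shift_pad(arr: np.ndarray, shift: Tuple[int, int], cval) -> np.ndarray:
    out = np.full_like(arr, cval)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for ax, s in zip((-2, -1), shift):
        n = arr.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src[ax], dst[ax] = slice(0, n - s), slice(s, n)
        else:
            src[ax], dst[ax] = slice(-s, n), slice(0, n + s)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def augment(
    pair: PatchPair,
    rng: np.random.Generator,
    rotation_deg: float = 15.0,
    jitter_vox: int = 2,
) -> PatchPair:
    """Random in-plane crop/pad jitter followed by random in-plane rotation.

    The image is interpolated linearly, labels nearest-neighbor; the output
    shape equals the input shape and the label codomain is unchanged. With
    ``rotation_deg=0`` and ``jitter_vox=0`` this is the identity.
    """
    img, lab = pair.image_patch, pair.label_patch
    if jitter_vox > 0:
        shift = tuple(int(rng.integers(-jitter_vox, jitter_vox + 1)) for _ in range(2))
        img = _shift_pad(img, shift, 0.0)
        lab = _shift_pad(lab, shift, 0)
    if rotation_deg > 0:
        angle = float(rng.uniform(-rotation_deg, rotation_deg))
        img = rotate_inplane(img, angle, order=1)
        lab = rotate_inplane(lab, angle, order=0)
    return PatchPair(np.ascontiguousarray(img), np.ascontiguousarray(lab),
                     provenance=pair.provenance)
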