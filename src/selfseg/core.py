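"""Shared containers and exceptions.

The package works on pelvic-like grayscale volumes with four organ-at-risk
(OAR) classes on top of background:

====== ===================
index  structure
====== ===================
0      background
1      bladder
2      femoral heads
3      rectum
4      small intestine
====== ===================

Arrays are always ordered ``(z, y, x)`` — slice axis first — and voxel
spacing is carried alongside the data in millimetres per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

N_CLASSES = 5
ORGAN_CLASSES = (1, 2, 3, 4)
ORGAN_NAMES = {
    1: "bladder",
    2: "femoral_heads",
    3: "rectum",
    4: "small_intestine",
}


class SelfsegError(Exception):
    """Base class for package errors."""


class ContractError(SelfsegError):
    """An operation was called with arguments violating its contract."""


class ConfigurationError(SelfsegError):
    """A configuration object is internally inconsistent or infeasible."""


class DimensionalityError(ContractError):
    """An image does not have the expected number of dimensions."""


class ValidationError(ContractError):
    """Data violates a container invariant (e.g. label values outside 0..4)."""


class DegenerateCorruptionError(SelfsegError):
    """A requested label corruption cannot fit inside the organ."""


class UndefinedMetricError(SelfsegError):
    """A surface-distance metric is undefined (empty mask)."""


class TrainingDivergedError(SelfsegError):
    """Training produced a non-finite loss."""


def _as_tuple3(v) -> Tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ContractError(f"expected a length-3 per-axis value, got {v!r}")
    return t


@dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing.

    ``data`` is indexed ``(z, y, x)``; ``spacing_mm`` and ``origin_mm`` follow
    the same axis order.
    """

    data: np.ndarray
    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"Volume must be 3D, got {self.data.ndim}D for case {self.case_id!r}"
            )
        self.spacing_mm = _as_tuple3(self.spacing_mm)
        self.origin_mm = _as_tuple3(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"Volume {self.case_id!r} contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class LabelMap:
    """Integer segmentation aligned to a :class:`Volume`; values in 0..4."""

    data: np.ndarray
    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    case_id: str = ""
    n_classes: int = N_CLASSES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"LabelMap must be 3D, got {self.data.ndim}D for case {self.case_id!r}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.any(self.data != np.round(self.data)):
                raise ValidationError("LabelMap data must be integer-valued")
            self.data = self.data.astype(np.uint8)
        self.spacing_mm = _as_tuple3(self.spacing_mm)
        self.origin_mm = _as_tuple3(self.origin_mm)
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.n_classes):
            raise ValidationError(
                f"label values must lie in 0..{self.n_classes - 1}, "
                f"found range [{self.data.min()}, {self.data.max()}]"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "LabelMap":
        return replace(self, data=data)

    def mask(self, cls: int) -> np.ndarray:
        return self.data == cls


@dataclass
class ProbabilityMap:
    """Per-class probabilities on a voxel grid, shape ``(5, z, y, x)``.

    Per-voxel probabilities over the 5 classes sum to 1 (tolerance 1e-5).
    """

    data: np.ndarray
    spacing_mm: Tuple[float, float, float]
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionalityError("ProbabilityMap must be (class, z, y, x)")
        if self.data.shape[0] != N_CLASSES:
            raise ValidationError(
                f"expected {N_CLASSES} class channels, got {self.data.shape[0]}"
            )
        self.spacing_mm = _as_tuple3(self.spacing_mm)
        if self.data.size:
            if self.data.min() < -1e-7:
                raise ValidationError("probabilities must be non-negative")
            s = self.data.sum(axis=0)
            if np.abs(s - 1.0).max() > 1e-5:
                raise ValidationError("per-voxel class probabilities must sum to 1")

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        return self.data.shape[1:]


def check_aligned(a, b, what: str = "operands") -> None:
    """Raise ContractError unless two gridded objects share shape and spacing."""
    sa = a.shape if not hasattr(a, "spatial_shape") else a.spatial_shape
    sb = b.shape if not hasattr(b, "spatial_shape") else b.spatial_shape
    if tuple(sa) != tuple(sb):
        raise ContractError(f"{what} have mismatched shapes: {sa} vs {sb}")
    if hasattr(a, "spacing_mm") and hasattr(b, "spacing_mm"):
        if not np.allclose(a.spacing_mm, b.spacing_mm, atol=1e-6):
            raise ContractError(
                f"{what} have mismatched spacings: {a.spacing_mm} vs {b.spacing_mm}"
            )
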