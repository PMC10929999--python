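"""Synthetic pelvic phantoms with ground-truth labels.

Real pelvic MR studies of this kind are rarely shareable, so the package
ships a phantom generator that emulates their geometry at desk scale:
anisotropic voxels (thick slices, fine in-plane spacing), four organ-like
structures — bladder (superellipsoid), femoral heads (two lateral
ellipsoids), rectum (curved vertical tube) and small intestine (a chain of
overlapping blobs) — with per-class intensity, global noise, a smooth
multiplicative bias field, and per-case shape/position jitter.

`corrupt_labels` injects the error modes a raw segmentation network
produces — interior cavities, small spurious fragments, boundary jitter —
so post-processing can be validated against a known clean reference.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    ConfigurationError,
    ContractError,
    DegenerateCorruptionError,
    LabelMap,
    ORGAN_CLASSES,
    ORGAN_NAMES,
    Volume,
)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_organ_params() -> Dict[int, dict]:
    """Per-class shape parameters, as fractions of the grid extent per axis.

    Ranges are sampled per case, giving inter-patient variability while
    keeping organs inside the grid and mutually disjoint for typical draws.
    """
    return {
        1: dict(  # bladder: rounded superellipsoid, mid-pelvis
            center=(0.50, 0.46, 0.50),
            center_jitter=(0.06, 0.05, 0.04),
            radii=((0.14, 0.24), (0.11, 0.19), (0.12, 0.20)),
            exponent=2.5,
        ),
        2: dict(  # femoral heads: one ellipsoid per side, lateral
            center=(0.50, 0.58, 0.15),
            center_jitter=(0.05, 0.03, 0.012),
            radii=((0.10, 0.17), (0.075, 0.115), (0.065, 0.088)),
        ),
        3: dict(  # rectum: curved tube running along z, posterior
            center_y=0.80,
            center_jitter=(0.0, 0.03, 0.03),
            z_extent=(0.10, 0.90),
            radius=(0.050, 0.080),
            curvature=(0.015, 0.060),
        ),
        4: dict(  # small intestine: chain of overlapping blobs, anterior/superior
            start=(0.18, 0.22, 0.50),
            start_jitter=(0.05, 0.04, 0.08),
            blob_count=(3, 8),
            radii=((0.08, 0.14), (0.055, 0.09), (0.055, 0.09)),
            step_scale=0.75,
        ),
    }


def default_intensity_params() -> dict:
    """Intensity model: class mean + per-class texture + global noise + bias.

    Means are spread over [0.2, 0.8] with per-class sd 0.08 and global noise
    sd 0.10; on top of that every case draws its own per-class mean offsets
    (sd ``class_mean_jitter``), emulating the non-quantitative intensity
    scale of MR, where tissue brightness varies between patients. Together
    with the shape jitter this keeps a 10-case sample from covering the
    population — the data-scarce regime self-annotation targets.
    """
    return dict(
        class_means={0: 0.20, 1: 0.80, 2: 0.50, 3: 0.35, 4: 0.65},
        class_sds={0: 0.08, 1: 0.08, 2: 0.08, 3: 0.08, 4: 0.08},
        class_mean_jitter=0.06,
        noise_sd=0.10,
        bias_amplitude=0.15,
    )


@dataclass
class PhantomConfig:
    """Geometry, intensity and randomness of a phantom cohort.

    grid_shape / spacing_mm follow the package's (z, y, x) convention; the
    default grid mimics thick-slice acquisitions resampled to an anisotropic
    target spacing.
    """

    grid_shape: Tuple[int, int, int] = (24, 96, 96)
    spacing_mm: Tuple[float, float, float] = (6.5, 2.656, 2.656)
    organ_params: Dict[int, dict] = field(default_factory=default_organ_params)
    intensity_params: dict = field(default_factory=default_intensity_params)
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.grid_shape) != 3 or len(self.spacing_mm) != 3:
            raise ConfigurationError("grid_shape and spacing_mm must be length 3")
        if any(s < 8 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape axes must be >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError(f"spacings must be > 0, got {self.spacing_mm}")


@dataclass
class CorruptionConfig:
    """Controlled label damage mimicking raw network predictions.

    Holes are interior cavities (organ voxels set to background), fragments
    are small spurious organ-labeled components in background, and boundary
    jitter randomly flips voxels in a band around each organ surface.
    All-zero config is the identity.
    """

    hole_count: int = 1
    hole_radius_vox: int = 2
    fragment_count: int = 2
    fragment_radius_vox: int = 1
    boundary_jitter_vox: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("hole_count", "hole_radius_vox", "fragment_count",
                     "fragment_radius_vox", "boundary_jitter_vox"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# geometry helpers (index space, (z, y, x))
# ---------------------------------------------------------------------------


def _grids(shape):
    return np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")


def _superellipsoid(shape, center, radii, exponent=2.0):
    zz, yy, xx = _grids(shape)
    t = (
        np.abs((zz - center[0]) / radii[0]) ** exponent
        + np.abs((yy - center[1]) / radii[1]) ** exponent
        + np.abs((xx - center[2]) / radii[2]) ** exponent
    )
    return t <= 1.0


def _check_fit(name, center, radii, shape):
    for ax in range(3):
        if center[ax] - radii[ax] < 0.5 - 1e-9 \
                or center[ax] + radii[ax] > shape[ax] - 1.5 + 1e-9:
            raise ConfigurationError(
                f"organ {name!r} does not fit inside the grid along axis {ax}: "
                f"center {center[ax]:.1f}, radius {radii[ax]:.1f}, extent {shape[ax]}"
            )


def _sample(rng, lohi):
    return rng.uniform(lohi[0], lohi[1])


def _case_rng(seed: int, case_id: str) -> np.random.Generator:
    tag = zlib.crc32(str(case_id).encode("utf8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _bladder_mask(shape, params, rng):
    c = np.asarray(params["center"]) * shape
    c = c + np.asarray(params["center_jitter"]) * shape * rng.uniform(-1, 1, 3)
    r = np.array([_sample(rng, params["radii"][ax]) * shape[ax] for ax in range(3)])
    _check_fit("bladder", c, r, shape)
    return _superellipsoid(shape, c, r, params.get("exponent", 2.5))


def _femoral_heads_mask(shape, params, rng):
    mask = np.zeros(shape, dtype=bool)
    for side, xfrac in ((0, params["center"][2]), (1, 1.0 - params["center"][2])):
        c = np.array([params["center"][0] * shape[0],
                      params["center"][1] * shape[1],
                      xfrac * shape[2]])
        c = c + np.asarray(params["center_jitter"]) * shape * rng.uniform(-1, 1, 3)
        r = np.array([_sample(rng, params["radii"][ax]) * shape[ax] for ax in range(3)])
        # nudge inward rather than fail when a lateral head grazes the edge
        c = np.clip(c, r + 0.5, np.asarray(shape) - r - 1.5)
        _check_fit("femoral_heads", c, r, shape)
        mask |= _superellipsoid(shape, c, r, 2.0)
    return mask


def _rectum_mask(shape, params, rng):
    nz, ny, nx = shape
    cy = params["center_y"] * ny + params["center_jitter"][1] * ny * rng.uniform(-1, 1)
    cx0 = 0.5 * nx + params["center_jitter"][2] * nx * rng.uniform(-1, 1)
    amp = _sample(rng, params["curvature"]) * nx
    phase = rng.uniform(0, 2 * np.pi)
    radius = _sample(rng, params["radius"]) * ny
    z0, z1 = (int(round(f * nz)) for f in params["z_extent"])
    z1 = min(z1, nz - 1)
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    for z in range(z0, z1 + 1):
        cx = cx0 + amp * np.sin(2 * np.pi * z / nz + phase)
        mask[z] = ((yy - cy) / radius) ** 2 + ((xx - cx) / radius) ** 2 <= 1.0
    if cy + radius > ny - 1.5 or cy - radius < 0.5:
        raise ConfigurationError("organ 'rectum' does not fit inside the grid along axis 1")
    return mask


def _intestine_mask(shape, params, rng):
    n_blobs = int(rng.integers(params["blob_count"][0], params["blob_count"][1] + 1))
    c = np.asarray(params["start"]) * shape
    c = c + np.asarray(params["start_jitter"]) * shape * rng.uniform(-1, 1, 3)
    mask = np.zeros(shape, dtype=bool)
    prev_r = None
    for _ in range(n_blobs):
        r = np.array([_sample(rng, params["radii"][ax]) * shape[ax] for ax in range(3)])
        c = np.clip(c, r + 0.5, np.asarray(shape) - r - 1.5)
        _check_fit("small_intestine", c, r, shape)
        mask |= _superellipsoid(shape, c, r, 2.0)
        # step short enough that consecutive blobs overlap
        direction = rng.normal(size=3)
        direction /= max(np.linalg.norm(direction), 1e-9)
        step = params["step_scale"] * (r if prev_r is None else 0.5 * (r + prev_r))
        c = c + direction * step
        prev_r = r
    return mask


_ORGAN_BUILDERS = {
    1: _bladder_mask,
    2: _femoral_heads_mask,
    3: _rectum_mask,
    4: _intestine_mask,
}


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------


def generate_phantom(config: PhantomConfig, case_id: str = "case") -> Tuple[Volume, LabelMap]:
    """Generate one phantom: image volume plus exclusive labels 0..4.

    Identical (config, case_id) pairs produce bit-identical output. Organ
    classes are painted in index order with first-writer-wins overlap
    resolution, so labels never overlap; femoral heads always consist of
    exactly two connected components.
    """
    shape = config.grid_shape
    rng = _case_rng(config.seed, case_id)
    labels = np.zeros(shape, dtype=np.uint8)
    for cls in ORGAN_CLASSES:
        if cls not in config.organ_params:
            continue
        mask = _ORGAN_BUILDERS[cls](shape, config.organ_params[cls], rng)
        mask &= labels == 0
        labels[mask] = cls

    for cls in ORGAN_CLASSES:
        if cls in config.organ_params and not np.any(labels == cls):
            raise ConfigurationError(
                f"organ {ORGAN_NAMES[cls]!r} occupies no voxels for case {case_id!r}"
            )
    if 2 in config.organ_params:
        n_comp = ndimage.label(labels == 2, structure=np.ones((3, 3, 3)))[1]
        if n_comp != 2:
            raise ConfigurationError(
                f"organ 'femoral_heads' has {n_comp} components (expected 2) "
                f"for case {case_id!r}"
            )

    ip = config.intensity_params
    means = np.array([ip["class_means"][c] for c in range(5)], dtype=np.float64)
    means = means + ip.get("class_mean_jitter", 0.0) * rng.standard_normal(5)
    sds = np.array([ip["class_sds"][c] for c in range(5)], dtype=np.float64)
    img = means[labels] + sds[labels] * rng.standard_normal(shape)
    img += ip["noise_sd"] * rng.standard_normal(shape)

    amp = ip.get("bias_amplitude", 0.0)
    if amp > 0:
        zz, yy, xx = (g / (n - 1) * 2.0 - 1.0 for g, n in zip(_grids(shape), shape))
        coeffs = rng.uniform(-1, 1, 6)
        poly = (coeffs[0] * zz + coeffs[1] * yy + coeffs[2] * xx
                + coeffs[3] * zz * yy + coeffs[4] * yy * xx + coeffs[5] * zz * xx) / 6.0
        img *= 1.0 + amp * poly

    vol = Volume(img.astype(np.float32), config.spacing_mm, case_id=str(case_id))
    lab = LabelMap(labels, config.spacing_mm, case_id=str(case_id))
    return vol, lab


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CaseEntry:
    case_id: str
    role: str  # "labeled" | "unlabeled" | "test"
    seed: int
    image_path: str
    label_path: Optional[str] = None


@dataclass
class CohortManifest:
    """On-disk inventory of a generated (or user-supplied) cohort."""

    root: str
    seed: int
    spacing_mm: Tuple[float, float, float]
    cases: List[CaseEntry] = field(default_factory=list)

    def by_role(self, role: str) -> List[CaseEntry]:
        return [c for c in self.cases if c.role == role]

    @property
    def labeled(self) -> List[CaseEntry]:
        return self.by_role("labeled")

    @property
    def unlabeled(self) -> List[CaseEntry]:
        return self.by_role("unlabeled")

    @property
    def test(self) -> List[CaseEntry]:
        return self.by_role("test")

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "seed": self.seed,
            "spacing_mm": list(self.spacing_mm),
            "cases": [asdict(c) for c in self.cases],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "CohortManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            root=d["root"],
            seed=d["seed"],
            spacing_mm=tuple(d["spacing_mm"]),
            cases=[CaseEntry(**c) for c in d["cases"]],
        )


def _derived_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, index])
               .generate_state(1)[0]) & 0x7FFFFFFF


def generate_cohort(
    config: PhantomConfig,
    n_labeled: int,
    n_unlabeled: int,
    out_dir,
    n_test: int = 0,
) -> CohortManifest:
    """Write a phantom cohort to ``out_dir`` and return its manifest.

    Produces ``n_labeled`` image+label pairs, ``n_unlabeled`` image-only
    cases, and optionally ``n_test`` held-out labeled cases (role "test",
    reserved for evaluation). Each case uses a distinct sub-seed derived
    deterministically from ``config.seed``, so equal configs give equal
    cohorts.
    """
    from . import preprocess  # deferred: preprocess owns NIfTI I/O

    if n_labeled < 1:
        raise ContractError("n_labeled must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = CohortManifest(root=str(out), seed=config.seed,
                              spacing_mm=config.spacing_mm)
    roles = (["labeled"] * n_labeled + ["unlabeled"] * n_unlabeled
             + ["test"] * n_test)
    for idx, role in enumerate(roles):
        case_id = f"case_{idx:03d}"
        sub_seed = _derived_seed(config.seed, idx)
        sub_cfg = replace(config, seed=sub_seed)
        vol, lab = generate_phantom(sub_cfg, case_id)
        img_path = out / f"{case_id}_image.nii.gz"
        preprocess.write_volume(vol, img_path)
        label_path = None
        if role in ("labeled", "test"):
            label_path = out / f"{case_id}_label.nii.gz"
            preprocess.write_labelmap(lab, label_path)
        manifest.cases.append(CaseEntry(
            case_id=case_id, role=role, seed=sub_seed,
            image_path=str(img_path),
            label_path=str(label_path) if label_path else None,
        ))
    manifest.save(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# corruptions
# ---------------------------------------------------------------------------


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.meshgrid(*([np.arange(-r, r + 1)] * 3), indexing="ij")
    return zz ** 2 + yy ** 2 + xx ** 2 <= r ** 2


def _stamp(target: np.ndarray, center, radius: int, value) -> None:
    r = int(radius)
    sl = tuple(slice(max(c - r, 0), min(c + r + 1, n))
               for c, n in zip(center, target.shape))
    ball = _ball(r)
    bsl = tuple(slice(s.start - (c - r), s.stop - (c - r))
                for s, c in zip(sl, center))
    region = target[sl]
    region[ball[bsl]] = value
    target[sl] = region


def _stamp_disk(target: np.ndarray, center, radius: int, value) -> None:
    z, cy, cx = (int(c) for c in center)
    r = int(radius)
    ny, nx = target.shape[1:]
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    plane = target[z]
    plane[disk] = value


def corrupt_labels(labels: LabelMap, config: CorruptionConfig) -> LabelMap:
    """Damage a label map with holes, fragments and boundary jitter.

    Holes are carved strictly interior to each organ (never touching its
    boundary), so they are fully enclosed cavities; fragments are placed in
    background at least 2 voxels from any foreground. A zero config returns
    the input unchanged. The paired intensity volume is never touched.
    """
    rng = np.random.default_rng(config.seed)
    out = labels.data.copy()

    for cls in ORGAN_CLASSES:
        mask = labels.data == cls
        if not np.any(mask):
            continue
        # interior cavities: in-plane disks fully enclosed by organ tissue,
        # including the slices above and below (slices are thick, so a 3D
        # ball rarely fits; prediction cavities are in-plane artifacts)
        r = config.hole_radius_vox
        for _ in range(config.hole_count):
            organ = out == cls
            dt2d = np.stack([ndimage.distance_transform_edt(sl) for sl in organ])
            ok = np.zeros_like(organ)
            ok[1:-1] = (
                (dt2d[1:-1] > r + 1.5)
                & (dt2d[:-2] > r + 0.5)
                & (dt2d[2:] > r + 0.5)
            )
            candidates = np.argwhere(ok)
            if len(candidates) == 0:
                raise DegenerateCorruptionError(
                    f"hole radius {r} does not fit inside organ "
                    f"{ORGAN_NAMES[cls]!r}"
                )
            center = candidates[rng.integers(len(candidates))]
            _stamp_disk(out, center, r, 0)

    for cls in ORGAN_CLASSES:
        if not np.any(labels.data == cls):
            continue
        # spurious fragments in background
        for _ in range(config.fragment_count):
            bg_dt = ndimage.distance_transform_edt(out == 0)
            ok = bg_dt > config.fragment_radius_vox + 2.0
            ok[:1], ok[-1:] = False, False
            ok[:, :1], ok[:, -1:] = False, False
            ok[:, :, :1], ok[:, :, -1:] = False, False
            candidates = np.argwhere(ok)
            if len(candidates) == 0:
                raise DegenerateCorruptionError(
                    f"fragment radius {config.fragment_radius_vox} does not fit "
                    f"in background for organ {ORGAN_NAMES[cls]!r}"
                )
            center = candidates[rng.integers(len(candidates))]
            _stamp(out, center, config.fragment_radius_vox, cls)

    if config.boundary_jitter_vox > 0:
        j = config.boundary_jitter_vox
        struct = ndimage.generate_binary_structure(3, 1)
        for cls in ORGAN_CLASSES:
            mask = out == cls
            if not np.any(mask):
                continue
            band = (ndimage.binary_dilation(mask, struct, iterations=j)
                    & ~ndimage.binary_erosion(mask, struct, iterations=j,
                                              border_value=0))
            band &= (out == 0) | (out == cls)
            flips = rng.random(int(band.sum())) < 0.5
            vals = np.where(flips, cls, 0).astype(out.dtype)
            out[band] = vals

    return labels.with_data(out)
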