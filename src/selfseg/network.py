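"""2D/3D U-Net built on a small self-contained NumPy layer engine.

The segmentation network follows the standard encoder–decoder pattern:
every computational block is convolution → instance normalization → leaky
ReLU; down-sampling uses strided convolutions and up-sampling transposed
convolutions; skip connections concatenate encoder features into the
decoder; a final 1×1(×1) convolution maps to 5 class channels decoded by a
softmax. For anisotropic 3D inputs the z axis is down-sampled only in the
first ``n_stages_z`` stages while the in-plane axes are down-sampled at
every stage, so e.g. a (32, 256, 256) patch with 2 z-stages and 6 in-plane
stages reaches a (8, 4, 4) bottleneck.

Layers implement explicit forward/backward passes in float32; convolutions
are evaluated as a loop over kernel offsets, each offset a batched matrix
product, which is fast enough on one CPU at the patch sizes the package
uses and keeps results bit-reproducible run to run.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ConfigurationError,
    ContractError,
    N_CLASSES,
    ProbabilityMap,
    SelfsegError,
    Volume,
)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of the U-Net.

    ``n_stages_xy`` counts in-plane down-samplings (each a factor of 2);
    for 3D networks ``n_stages_z`` of those stages also halve z. Channel
    widths grow from ``base_channels`` by ``channel_growth`` per stage,
    capped at ``max_channels``.
    """

    dims: int = 2
    in_channels: int = 1
    out_channels: int = N_CLASSES
    n_stages_xy: int = 6
    n_stages_z: int = 2
    kernel: int = 3
    base_channels: int = 32
    channel_growth: float = 2.0
    max_channels: int = 320
    negative_slope: float = 0.01

    def __post_init__(self):
        if self.dims not in (2, 3):
            raise ConfigurationError(f"dims must be 2 or 3, got {self.dims}")
        if self.out_channels != N_CLASSES:
            raise ConfigurationError("out_channels must be 5 (background + 4 OARs)")
        if self.n_stages_xy < 1:
            raise ConfigurationError("n_stages_xy must be >= 1")
        if self.dims == 3 and not (0 <= self.n_stages_z <= self.n_stages_xy):
            raise ConfigurationError("need 0 <= n_stages_z <= n_stages_xy")

    # -- derived architecture arithmetic ------------------------------------

    def stage_widths(self) -> List[int]:
        """Channel width at each resolution level, levels 0..n_stages_xy."""
        return [
            min(int(round(self.base_channels * self.channel_growth ** s)),
                self.max_channels)
            for s in range(self.n_stages_xy + 1)
        ]

    def stage_strides(self) -> List[Tuple[int, ...]]:
        """Down-sampling stride entering each level 1..n_stages_xy."""
        out = []
        for s in range(1, self.n_stages_xy + 1):
            if self.dims == 2:
                out.append((2, 2))
            else:
                out.append((2 if s <= self.n_stages_z else 1, 2, 2))
        return out

    def divisors(self) -> Tuple[int, ...]:
        """Required divisibility of the input patch extent per spatial axis."""
        div = np.ones(self.dims, dtype=int)
        for st in self.stage_strides():
            div *= np.array(st)
        return tuple(int(d) for d in div)

    @classmethod
    def preset(cls, name: str) -> "NetworkConfig":
        presets = {
            "2d_full": cls(dims=2, n_stages_xy=6, base_channels=32, max_channels=320),
            "3d_full": cls(dims=3, n_stages_xy=6, n_stages_z=2,
                           base_channels=32, max_channels=320),
            "2d_test": cls(dims=2, n_stages_xy=3, base_channels=8, max_channels=32),
            "3d_test": cls(dims=3, n_stages_xy=3, n_stages_z=1,
                           base_channels=4, max_channels=16),
        }
        if name not in presets:
            raise ConfigurationError(
                f"unknown preset {name!r}; choose from {sorted(presets)}")
        return presets[name]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# layer engine
# ---------------------------------------------------------------------------


class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _Conv:
    """N-D convolution, 'same' padding for stride 1, halving for stride 2.

    Evaluated im2col-style: the padded input is unfolded into a
    (N, C·∏kernel, S) column matrix and the whole convolution becomes one
    batched matrix product, which is what keeps CPU training fast.
    """

    def __init__(self, rng, dims, cin, cout, kernel, stride=1):
        self.dims = dims
        self.kernel = tuple(kernel) if isinstance(kernel, (tuple, list)) \
            else (kernel,) * dims
        self.stride = tuple(stride) if isinstance(stride, (tuple, list)) \
            else (stride,) * dims
        self.pad = tuple(k // 2 for k in self.kernel)
        fan_in = cin * int(np.prod(self.kernel))
        self.W = _Param(_he_init(rng, (cout, cin) + self.kernel, fan_in))
        self.b = _Param(np.zeros(cout, dtype=np.float32))
        self.offsets = list(itertools.product(*(range(k) for k in self.kernel)))
        self._cols = None
        self._meta = None

    def params(self):
        return [self.W, self.b]

    def _out_shape(self, sp):
        return tuple((n + 2 * p - k) // s + 1 for n, p, k, s in
                     zip(sp, self.pad, self.kernel, self.stride))

    def _unfold(self, xpad, out_sp):
        """(N, C, *padded) -> contiguous (N, C*K, S) column matrix."""
        view = np.lib.stride_tricks.sliding_window_view(
            xpad, self.kernel, axis=tuple(range(2, 2 + self.dims)))
        # subsample by stride along each spatial axis
        sub = (slice(None), slice(None)) + tuple(
            slice(None, None, s) for s in self.stride)
        view = view[sub]  # (N, C, *out_sp, *kernel)
        # -> (N, C, *kernel, *out_sp)
        perm = (0, 1) + tuple(range(2 + self.dims, 2 + 2 * self.dims)) \
            + tuple(range(2, 2 + self.dims))
        N, C = xpad.shape[:2]
        K = int(np.prod(self.kernel))
        S = int(np.prod(out_sp))
        return np.ascontiguousarray(view.transpose(perm)).reshape(N, C * K, S)

    def forward(self, x):
        N, C = x.shape[:2]
        out_sp = self._out_shape(x.shape[2:])
        pad_width = ((0, 0), (0, 0)) + tuple((p, p) for p in self.pad)
        xpad = np.pad(x, pad_width) if any(self.pad) else x
        cols = self._unfold(xpad, out_sp)
        self._cols = cols
        self._meta = (x.shape, xpad.shape, out_sp)
        O = self.W.value.shape[0]
        Wf = self.W.value.reshape(O, -1)
        out = np.matmul(Wf, cols) + self.b.value[None, :, None]
        return out.reshape((N, O) + out_sp)

    def backward(self, g):
        x_shape, xpad_shape, out_sp = self._meta
        cols = self._cols
        N, C = xpad_shape[:2]
        O = g.shape[1]
        S = int(np.prod(out_sp))
        K = int(np.prod(self.kernel))
        gf = np.ascontiguousarray(g).reshape(N, O, S)
        gT = gf.transpose(1, 0, 2).reshape(O, N * S)
        colsT = cols.transpose(0, 2, 1).reshape(N * S, C * K)
        self.W.grad += (gT @ colsT).reshape(self.W.value.shape)
        self.b.grad += gf.sum(axis=(0, 2))
        Wf = self.W.value.reshape(O, -1)
        dcols = np.matmul(Wf.T, gf).reshape((N, C) + self.kernel + out_sp)
        dxpad = np.zeros(xpad_shape, dtype=np.float32)
        for oi, off in enumerate(self.offsets):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s * (n - 1) + 1, s)
                for o, s, n in zip(off, self.stride, out_sp))
            idx = np.unravel_index(oi, self.kernel)
            dxpad[sl] += dcols[(slice(None), slice(None)) + idx]
        if any(self.pad):
            core = (slice(None), slice(None)) + tuple(
                slice(p, xpad_shape[i + 2] - p) for i, p in enumerate(self.pad))
            dx = dxpad[core]
        else:
            dx = dxpad
        self._cols = None
        return dx


class _ConvTranspose:
    """Transposed convolution with kernel == stride (exact upsampling)."""

    def __init__(self, rng, dims, cin, cout, stride):
        self.dims = dims
        self.stride = tuple(stride) if isinstance(stride, (tuple, list)) \
            else (stride,) * dims
        fan_in = cin
        self.W = _Param(_he_init(rng, (cin, cout) + self.stride, fan_in))
        self.b = _Param(np.zeros(cout, dtype=np.float32))
        self.offsets = list(itertools.product(*(range(s) for s in self.stride)))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        N, C = x.shape[:2]
        in_sp = x.shape[2:]
        out_sp = tuple(n * s for n, s in zip(in_sp, self.stride))
        O = self.W.value.shape[1]
        self._x = x
        S = int(np.prod(in_sp))
        xf = np.ascontiguousarray(x).reshape(N, C, S)
        out = np.empty((N, O) + out_sp, dtype=np.float32)
        for off in self.offsets:
            Wk = self.W.value[(slice(None), slice(None)) + off]  # (C, O)
            block = np.matmul(Wk.T, xf).reshape((N, O) + in_sp)
            sl = (slice(None), slice(None)) + tuple(
                slice(o, None, s) for o, s in zip(off, self.stride))
            out[sl] = block
        out += self.b.value[(None, slice(None)) + (None,) * self.dims]
        return out

    def backward(self, g):
        x = self._x
        N, C = x.shape[:2]
        in_sp = x.shape[2:]
        S = int(np.prod(in_sp))
        xf = np.ascontiguousarray(x).reshape(N, C, S)
        xT = xf.transpose(1, 0, 2).reshape(C, N * S)
        dx = np.zeros_like(xf)
        for off in self.offsets:
            sl = (slice(None), slice(None)) + tuple(
                slice(o, None, s) for o, s in zip(off, self.stride))
            gf = np.ascontiguousarray(g[sl]).reshape(N, -1, S)
            Wk = self.W.value[(slice(None), slice(None)) + off]  # (C, O)
            self.W.grad[(slice(None), slice(None)) + off] += \
                xT @ gf.transpose(0, 2, 1).reshape(N * S, -1)
            dx += np.matmul(Wk, gf)
        self.b.grad += g.sum(axis=(0,) + tuple(range(2, g.ndim)))
        self._x = None
        return dx.reshape(x.shape)


class _InstanceNorm:
    """Per-sample, per-channel normalization over the spatial axes."""

    eps = 1e-5

    def __init__(self, channels):
        self.gamma = _Param(np.ones(channels, dtype=np.float32))
        self.beta = _Param(np.zeros(channels, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, axes)
        shape = (1, -1) + (1,) * (x.ndim - 2)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, g):
        xhat, inv, axes = self._cache
        shape = (1, -1) + (1,) * (g.ndim - 2)
        self.gamma.grad += (g * xhat).sum(axis=(0,) + axes)
        self.beta.grad += g.sum(axis=(0,) + axes)
        dxhat = g * self.gamma.value.reshape(shape)
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        self._cache = None
        return inv * (dxhat - m1 - xhat * m2)


class _LeakyReLU:
    def __init__(self, slope):
        self.slope = np.float32(slope)
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        out = np.where(self._mask, g, self.slope * g)
        self._mask = None
        return out


class _Block:
    """conv → instance norm → leaky ReLU."""

    def __init__(self, rng, dims, cin, cout, kernel, stride, slope):
        self.layers = [
            _Conv(rng, dims, cin, cout, kernel, stride),
            _InstanceNorm(cout),
            _LeakyReLU(slope),
        ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class _Stage:
    """Two blocks; the first may down-sample."""

    def __init__(self, rng, dims, cin, cout, kernel, stride, slope):
        self.blocks = [
            _Block(rng, dims, cin, cout, kernel, stride, slope),
            _Block(rng, dims, cout, cout, kernel, 1, slope),
        ]

    def params(self):
        return [p for b in self.blocks for p in b.params()]

    def forward(self, x):
        for b in self.blocks:
            x = b.forward(x)
        return x

    def backward(self, g):
        for b in reversed(self.blocks):
            g = b.backward(g)
        return g


# ---------------------------------------------------------------------------
# the U-Net
# ---------------------------------------------------------------------------


class UNet:
    """Encoder–decoder segmentation network with skip connections.

    ``forward`` maps (N, in_channels, *spatial) to (N, 5, *spatial) logits;
    :meth:`predict_proba` applies the softmax. After a forward pass,
    ``bottleneck_shape_`` records the spatial extent of the deepest
    feature map.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        d = config.dims
        widths = config.stage_widths()
        strides = config.stage_strides()
        k, slope = config.kernel, config.negative_slope
        S = config.n_stages_xy

        self.encoder = [_Stage(rng, d, config.in_channels, widths[0], k, 1, slope)]
        for s in range(1, S + 1):
            self.encoder.append(
                _Stage(rng, d, widths[s - 1], widths[s], k, strides[s - 1], slope))
        self.ups = []
        self.decoder = []
        for s in range(S - 1, -1, -1):
            self.ups.append(_ConvTranspose(rng, d, widths[s + 1], widths[s],
                                           strides[s]))
            self.decoder.append(
                _Stage(rng, d, 2 * widths[s], widths[s], k, 1, slope))
        self.head = _Conv(rng, d, widths[0], config.out_channels, 1, 1)
        self.bottleneck_shape_: Optional[Tuple[int, ...]] = None
        self._skip_channels = widths

    # -- parameter access ----------------------------------------------------

    def parameters(self) -> List[_Param]:
        ps = []
        for st in self.encoder:
            ps += st.params()
        for up, dec in zip(self.ups, self.decoder):
            ps += up.params() + dec.params()
        ps += self.head.params()
        return ps

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_dict(self, values: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(values) != len(params):
            raise ContractError("checkpoint does not match the architecture")
        for p, v in zip(params, values):
            if p.value.shape != v.shape:
                raise ContractError("checkpoint tensor shape mismatch")
            p.value[...] = v.astype(np.float32)

    # -- shape contract ------------------------------------------------------

    def validate_input_shape(self, spatial: Sequence[int]) -> None:
        div = self.config.divisors()
        if len(spatial) != self.config.dims:
            raise ConfigurationError(
                f"expected {self.config.dims} spatial dims, got {len(spatial)}")
        for n, dv in zip(spatial, div):
            if n % dv != 0 or n < dv:
                raise ConfigurationError(
                    f"patch extent {tuple(spatial)} not divisible by the "
                    f"network's down-sampling factors {div}")

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.validate_input_shape(x.shape[2:])
        x = x.astype(np.float32, copy=False)
        skips = []
        h = self.encoder[0].forward(x)
        skips.append(h)
        S = self.config.n_stages_xy
        for s in range(1, S + 1):
            h = self.encoder[s].forward(h)
            if s < S:
                skips.append(h)
        self.bottleneck_shape_ = h.shape[2:]
        for i, (up, dec) in enumerate(zip(self.ups, self.decoder)):
            level = S - 1 - i
            h = up.forward(h)
            h = np.concatenate([h, skips[level]], axis=1)
            h = dec.forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        S = self.config.n_stages_xy
        g = self.head.backward(dlogits)
        skip_grads = [None] * S
        for i in range(len(self.decoder) - 1, -1, -1):
            level = S - 1 - i
            g = self.decoder[i].backward(g)
            w = self._skip_channels[level]
            g_up, g_skip = g[:, :w], g[:, w:]
            skip_grads[level] = g_skip
            g = self.ups[i].backward(np.ascontiguousarray(g_up))
        for s in range(S, 0, -1):
            g = self.encoder[s].backward(g)
            g = g + skip_grads[s - 1]
        self.encoder[0].backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return (e / e.sum(axis=axis, keepdims=True)).astype(np.float32)


def build_unet(config: NetworkConfig, seed: int = 0) -> UNet:
    """Construct a U-Net from its configuration (deterministic under seed)."""
    return UNet(config, seed=seed)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: UNet, path) -> None:
    """Save weights with the architecture config embedded."""
    arrays = {f"p{i:04d}": v for i, v in enumerate(model.state_dict())}
    np.savez(str(path), __config__=json.dumps(model.config.to_dict()), **arrays)


def load_checkpoint(path) -> UNet:
    with np.load(str(path), allow_pickle=False) as z:
        config = NetworkConfig.from_dict(json.loads(str(z["__config__"])))
        keys = sorted(k for k in z.files if k.startswith("p"))
        values = [z[k] for k in keys]
    model = UNet(config)
    model.load_state_dict(values)
    return model


# ---------------------------------------------------------------------------
# full-volume inference
# ---------------------------------------------------------------------------


def _window_starts(n: int, w: int, step: int) -> List[int]:
    if n <= w:
        return [0]
    starts = list(range(0, n - w, step))
    starts.append(n - w)
    return sorted(set(starts))


def predict_probabilities(
    model: UNet,
    volume: Volume,
    window: Optional[Tuple[int, ...]] = None,
    overlap: float = 0.5,
) -> ProbabilityMap:
    """Sliding-window inference over a full (normalized) volume.

    2D models are applied slice-by-slice in-plane; 3D models slide a 3D
    window. Overlapping windows are blended by uniform averaging, so the
    per-voxel class probabilities still sum to 1. Volumes smaller than the
    window are zero-padded and the output cropped back to the input grid.
    """
    dims = model.config.dims
    div = model.config.divisors()
    div3 = (1,) * (3 - dims) + div
    arr = volume.data.astype(np.float32)
    orig_shape = arr.shape

    if window is None:
        w3 = tuple(
            1 if (dims == 2 and ax == 0)
            else int(np.ceil(n / d) * d)
            for ax, (n, d) in enumerate(zip(orig_shape, div3))
        )
    else:
        window = tuple(int(w) for w in window)
        if len(window) == dims:
            w3 = (1,) * (3 - dims) + window
        elif len(window) == 3 and dims == 2:
            w3 = (1, window[1], window[2])
        elif len(window) == 3:
            w3 = window
        else:
            raise ContractError(f"window must have {dims} (or 3) axes")
        for ax in range(3):
            if dims == 2 and ax == 0:
                continue
            if w3[ax] % div3[ax]:
                raise ConfigurationError(
                    f"window {w3} not divisible by down-sampling factors {div3}")

    pad = [(0, max(w - n, 0)) for w, n in zip(w3, orig_shape)]
    arr = np.pad(arr, pad)
    steps = [max(int(round(w * (1.0 - overlap))), 1) for w in w3]
    acc = np.zeros((N_CLASSES,) + arr.shape, dtype=np.float64)
    cnt = np.zeros(arr.shape, dtype=np.float64)

    for z0 in _window_starts(arr.shape[0], w3[0], steps[0]):
        for y0 in _window_starts(arr.shape[1], w3[1], steps[1]):
            for x0 in _window_starts(arr.shape[2], w3[2], steps[2]):
                sl = (slice(z0, z0 + w3[0]), slice(y0, y0 + w3[1]),
                      slice(x0, x0 + w3[2]))
                chunk = arr[sl]
                if dims == 2:
                    x = chunk.reshape((1, 1) + chunk.shape[1:])
                else:
                    x = chunk[None, None]
                probs = model.predict_proba(x)[0]  # (5, *window_spatial)
                if dims == 2:
                    probs = probs[:, None]
                acc[(slice(None),) + sl] += probs
                cnt[sl] += 1.0
    out = acc / cnt[None]
    out = out[:, : orig_shape[0], : orig_shape[1], : orig_shape[2]]
    if not np.all(np.isfinite(out)):
        raise SelfsegError("non-finite values in predicted probabilities")
    return ProbabilityMap(out.astype(np.float32), volume.spacing_mm,
                          case_id=volume.case_id)
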