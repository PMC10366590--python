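"""Fixed random-weight 3D residual convolutional feature extractor.

The extractor is *never trained*: its weights are drawn once from a seeded
He-style distribution and frozen.  Architecture (channel counts, kernel
sizes, block counts) is fixed:

=====================  ======  ========  =======================
stage                  blocks  channels  kernel / stride
=====================  ======  ========  =======================
stem 3D conv           --      64        7x7x7, stride (1,2,2)
stem 3D avg-pool       --      64        3x3x3, stride (2,2,2)
residual module 1      3       256       1-3-1 bottleneck, stride 1
global avg-pool        --      256       -> shallow vector x_d
residual module 2      4       512       1-3-1 bottleneck, stride (2,2,2)
global avg-pool        --      512       -> deep vector x_e
=====================  ======  ========  =======================

For a 224 x 224 x 128 input the spatial shapes are
(224,112,64) -> (112,56,32) -> (112,56,32) -> (56,28,16); module 2 consumes
module 1's pre-pool tensor, so x_e = pool(module2(module1(stem(v)))).

There are no normalization layers (nothing is trained, so there is nothing
to stabilise, and their absence preserves exact zero-propagation); variance
of the random features is controlled by the He initialisation instead.
Convolutions use "same"-style zero padding, so spatial size is governed
only by stride (output = ceil(input / stride) per axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from ._archive import load_arrays, save_arrays
from ._exceptions import ConfigurationError, StructuralError

__all__ = [
    "ExtractorConfig",
    "BlockWeights",
    "ExtractorParams",
    "FeatureTensor",
    "DeepFeaturePair",
    "init_extractor",
    "conv3d",
    "avg_pool3d",
    "conv_pool_stem",
    "bottleneck_block",
    "global_avg_pool",
    "extract_features",
    "extract_features_batch",
    "save_extractor",
    "load_extractor",
]

#: stride of (stem conv, stem pool, module 1, module 2) per scheme
_STRIDE_SCHEMES = {
    # Reference scheme: the stem conv halves only the
    # last two axes, every later downsampling halves all three.
    "stem_aniso": ((1, 2, 2), (2, 2, 2), (1, 1, 1), (2, 2, 2)),
    # Uniform alternative: every downsampling stage halves all three axes.
    "uniform": ((2, 2, 2), (2, 2, 2), (1, 1, 1), (2, 2, 2)),
}


@dataclass(frozen=True)
class ExtractorConfig:
    """Architecture + initialisation of the frozen extractor.

    ``m1_inner``/``m2_inner`` are the bottleneck widths (default
    ``channels // 4``, the standard 4x expansion).  Reducing them, and
    ``stem_channels``, shrinks compute without changing the 256/512 output
    dimensions, which are fixed by ``m1_channels``/``m2_channels``.
    """

    seed: int = 0
    init_scheme: str = "he_normal"
    stem_channels: int = 64
    stem_kernel: int = 7
    pool_kernel: int = 3
    m1_blocks: int = 3
    m1_channels: int = 256
    m1_inner: int | None = None
    m2_blocks: int = 4
    m2_channels: int = 512
    m2_inner: int | None = None
    stride_scheme: str = "stem_aniso"
    dtype: str = "float64"

    def __post_init__(self):
        if self.stride_scheme not in _STRIDE_SCHEMES:
            raise ConfigurationError(
                f"unknown stride_scheme {self.stride_scheme!r}; "
                f"choose from {sorted(_STRIDE_SCHEMES)}"
            )
        if self.init_scheme not in _INIT_SCHEMES:
            raise ConfigurationError(
                f"unknown init_scheme {self.init_scheme!r}; "
                f"choose from {sorted(_INIT_SCHEMES)}"
            )
        if self.dtype not in ("float64", "float32"):
            raise ConfigurationError("dtype must be 'float64' or 'float32'")

    @property
    def strides(self) -> tuple:
        return _STRIDE_SCHEMES[self.stride_scheme]

    def inner(self, module: int) -> int:
        if module == 1:
            return self.m1_inner if self.m1_inner is not None else self.m1_channels // 4
        return self.m2_inner if self.m2_inner is not None else self.m2_channels // 4

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractorConfig":
        return cls(**d)


def _he_normal(rng, shape, fan_in):
    return rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)


def _he_uniform(rng, shape, fan_in):
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


_INIT_SCHEMES = {"he_normal": _he_normal, "he_uniform": _he_uniform}


@dataclass
class BlockWeights:
    """Weights of one 1-3-1 bottleneck block (optionally with projection)."""

    w1: np.ndarray  # (inner, c_in, 1, 1, 1)
    b1: np.ndarray
    w2: np.ndarray  # (inner, inner, 3, 3, 3)
    b2: np.ndarray
    w3: np.ndarray  # (c_out, inner, 1, 1, 1)
    b3: np.ndarray
    proj_w: np.ndarray | None = None  # (c_out, c_in, 1, 1, 1) when shape changes
    proj_b: np.ndarray | None = None
    stride: tuple = (1, 1, 1)

    @property
    def in_channels(self) -> int:
        return self.w1.shape[1]

    @property
    def out_channels(self) -> int:
        return self.w3.shape[0]


@dataclass
class ExtractorParams:
    """All frozen weights of the extractor.  Immutable after construction.

    Externally supplied weights can be injected by constructing this class
    directly (or via :func:`load_extractor`); nothing in the package ever
    updates them.
    """

    config: ExtractorConfig
    stem_w: np.ndarray = None  # (stem_channels, 1, k, k, k)
    stem_b: np.ndarray = None
    blocks1: list = field(default_factory=list)
    blocks2: list = field(default_factory=list)

    def __post_init__(self):
        for arr in self._arrays():
            if not np.all(np.isfinite(arr)):
                raise ValueError("extractor weights must be finite")
            arr.setflags(write=False)

    def _arrays(self):
        out = [self.stem_w, self.stem_b]
        for blk in [*self.blocks1, *self.blocks2]:
            out += [blk.w1, blk.b1, blk.w2, blk.b2, blk.w3, blk.b3]
            if blk.proj_w is not None:
                out += [blk.proj_w, blk.proj_b]
        return out


@dataclass
class FeatureTensor:
    """A channels-first 4D activation tensor with its producing stage."""

    data: np.ndarray  # (channels, x, y, z)
    stage: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise StructuralError(f"FeatureTensor needs 4 axes, got {self.data.ndim}")

    @property
    def channels(self) -> int:
        return self.data.shape[0]


@dataclass
class DeepFeaturePair:
    """Shallow (x_d) and deep (x_e) pooled feature vectors."""

    x_d: np.ndarray
    x_e: np.ndarray

    def __post_init__(self):
        self.x_d = np.asarray(self.x_d).ravel()
        self.x_e = np.asarray(self.x_e).ravel()
        if not (np.all(np.isfinite(self.x_d)) and np.all(np.isfinite(self.x_e))):
            raise ValueError("feature vectors must be finite")


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------


def _normalize_stride(stride):
    if np.isscalar(stride):
        return (int(stride),) * 3
    return tuple(int(s) for s in stride)


def conv3d(x, w, b=None, stride=1, method="auto"):
    """Strided 3D cross-correlation with "same" zero padding.

    ``x``: (c_in, X, Y, Z); ``w``: (c_out, c_in, kx, ky, kz) with odd
    kernels; output axis length is ``ceil(n / stride)``.  ``method`` is
    ``"shift"`` (offset-wise matmul, efficient for small kernels),
    ``"fft"`` (per-channel FFT convolution, efficient for large kernels on
    few input channels) or ``"auto"``.
    """
    x = np.asarray(x)
    w = np.asarray(w)
    if x.ndim != 4 or w.ndim != 5:
        raise StructuralError("conv3d expects x (c,X,Y,Z) and w (o,c,kx,ky,kz)")
    if x.shape[0] != w.shape[1]:
        raise StructuralError(
            f"channel mismatch: input has {x.shape[0]}, weights expect {w.shape[1]}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("conv3d input contains non-finite values")
    c_out, c_in = w.shape[:2]
    kernel = w.shape[2:]
    if any(k % 2 == 0 for k in kernel):
        raise ConfigurationError("conv3d supports odd kernel sizes only")
    stride = _normalize_stride(stride)
    pads = tuple((k - 1) // 2 for k in kernel)
    for n, k, p in zip(x.shape[1:], kernel, pads):
        if n + 2 * p < k:
            raise StructuralError(f"input axis {n} smaller than receptive field {k}")
    out_shape = tuple(-(-n // s) for n, s in zip(x.shape[1:], stride))

    if method == "auto":
        method = "fft" if int(np.prod(kernel)) > 27 else "shift"

    if method == "fft":
        out = np.empty((c_out, *out_shape), dtype=x.dtype if x.dtype.kind == "f" else float)
        sx, sy, sz = stride
        for o in range(c_out):
            acc = 0.0
            for c in range(c_in):
                # fftconvolve flips the kernel; flip back for correlation
                acc = acc + fftconvolve(x[c], w[o, c, ::-1, ::-1, ::-1], mode="same")
            out[o] = acc[::sx, ::sy, ::sz]
    elif method == "shift":
        xp = np.pad(x, ((0, 0), *((p, p) for p in pads)))
        out = np.zeros((c_out, *out_shape), dtype=np.result_type(x, w))
        sx, sy, sz = stride
        ox, oy, oz = out_shape
        for i in range(kernel[0]):
            for j in range(kernel[1]):
                for k in range(kernel[2]):
                    sl = xp[
                        :,
                        i : i + (ox - 1) * sx + 1 : sx,
                        j : j + (oy - 1) * sy + 1 : sy,
                        k : k + (oz - 1) * sz + 1 : sz,
                    ]
                    out += np.tensordot(w[:, :, i, j, k], sl, axes=1)
    else:
        raise ConfigurationError(f"unknown conv3d method {method!r}")

    if b is not None:
        out = out + np.asarray(b)[:, None, None, None]
    return out


def avg_pool3d(x, kernel=3, stride=2):
    """Strided average pooling with "same" zero padding (zeros counted)."""
    x = np.asarray(x)
    if x.ndim != 4:
        raise StructuralError("avg_pool3d expects (c, X, Y, Z)")
    k = (kernel,) * 3 if np.isscalar(kernel) else tuple(kernel)
    stride = _normalize_stride(stride)
    pads = tuple((kk - 1) // 2 for kk in k)
    out_shape = tuple(-(-n // s) for n, s in zip(x.shape[1:], stride))
    xp = np.pad(x, ((0, 0), *((p, p) for p in pads)))
    out = np.zeros((x.shape[0], *out_shape), dtype=np.result_type(x, float))
    sx, sy, sz = stride
    ox, oy, oz = out_shape
    for i in range(k[0]):
        for j in range(k[1]):
            for kk in range(k[2]):
                out += xp[
                    :,
                    i : i + (ox - 1) * sx + 1 : sx,
                    j : j + (oy - 1) * sy + 1 : sy,
                    kk : kk + (oz - 1) * sz + 1 : sz,
                ]
    return out / float(np.prod(k))


def _relu(x):
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------------


def init_extractor(seed: int = 0, init_scheme: str = "he_normal",
                   config: ExtractorConfig | None = None) -> ExtractorParams:
    """Draw and freeze all extractor weights from a seeded RNG.

    Identical ``(seed, init_scheme, config)`` yields bitwise-identical
    parameters.  Biases are zero (the network is untrained; zero biases
    preserve exact zero-propagation and linear-scale equivariance of the
    stem).
    """
    if config is None:
        config = ExtractorConfig(seed=seed, init_scheme=init_scheme)
    else:
        config = replace(config, seed=seed, init_scheme=init_scheme)
    init = _INIT_SCHEMES[config.init_scheme]
    rng = np.random.default_rng(config.seed)
    dtype = np.dtype(config.dtype)

    k = config.stem_kernel
    stem_w = init(rng, (config.stem_channels, 1, k, k, k), fan_in=k**3).astype(dtype)
    stem_b = np.zeros(config.stem_channels, dtype=dtype)

    def make_block(c_in, inner, c_out, stride):
        def w(shape, fan_in):
            return init(rng, shape, fan_in).astype(dtype)

        needs_proj = (c_in != c_out) or any(s != 1 for s in stride)
        return BlockWeights(
            w1=w((inner, c_in, 1, 1, 1), c_in),
            b1=np.zeros(inner, dtype=dtype),
            w2=w((inner, inner, 3, 3, 3), inner * 27),
            b2=np.zeros(inner, dtype=dtype),
            w3=w((c_out, inner, 1, 1, 1), inner),
            b3=np.zeros(c_out, dtype=dtype),
            proj_w=w((c_out, c_in, 1, 1, 1), c_in) if needs_proj else None,
            proj_b=np.zeros(c_out, dtype=dtype) if needs_proj else None,
            stride=stride,
        )

    _, _, s_m1, s_m2 = config.strides
    blocks1, c_in = [], config.stem_channels
    for i in range(config.m1_blocks):
        blocks1.append(make_block(c_in, config.inner(1), config.m1_channels,
                                  s_m1 if i == 0 else (1, 1, 1)))
        c_in = config.m1_channels
    blocks2 = []
    for i in range(config.m2_blocks):
        blocks2.append(make_block(c_in, config.inner(2), config.m2_channels,
                                  s_m2 if i == 0 else (1, 1, 1)))
        c_in = config.m2_channels

    return ExtractorParams(config=config, stem_w=stem_w, stem_b=stem_b,
                           blocks1=blocks1, blocks2=blocks2)


# ---------------------------------------------------------------------------
# forward stages
# ---------------------------------------------------------------------------


def conv_pool_stem(v, p: ExtractorParams) -> FeatureTensor:
    """Stem: 7x7x7 conv then 3x3x3 average pool on a single-channel volume."""
    x = np.asarray(v, dtype=p.config.dtype)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[0] != 1:
        raise StructuralError("stem expects a single-channel 3D volume")
    s_conv, s_pool, _, _ = p.config.strides
    x = conv3d(x, p.stem_w, p.stem_b, stride=s_conv)
    x = avg_pool3d(x, kernel=p.config.pool_kernel, stride=s_pool)
    return FeatureTensor(data=x, stage="stem")


def bottleneck_block(t: FeatureTensor, weights: BlockWeights) -> FeatureTensor:
    """One residual 1-3-1 bottleneck: relu(shortcut(x) + branch(x)).

    The 3x3x3 conv carries the block's stride; the shortcut is identity
    when channels and spatial shape are unchanged, otherwise a strided
    1x1x1 projection.
    """
    x = t.data
    if x.shape[0] != weights.in_channels:
        raise StructuralError(
            f"block expects {weights.in_channels} input channels, got {x.shape[0]}"
        )
    h = _relu(conv3d(x, weights.w1, weights.b1, stride=1))
    h = _relu(conv3d(h, weights.w2, weights.b2, stride=weights.stride))
    h = conv3d(h, weights.w3, weights.b3, stride=1)
    if weights.proj_w is not None:
        shortcut = conv3d(x, weights.proj_w, weights.proj_b, stride=weights.stride)
    else:
        shortcut = x
    return FeatureTensor(data=_relu(shortcut + h), stage=t.stage + "+block")


def _run_module(t: FeatureTensor, blocks, stage: str) -> FeatureTensor:
    for blk in blocks:
        t = bottleneck_block(t, blk)
    return FeatureTensor(data=t.data, stage=stage)


def global_avg_pool(t: FeatureTensor) -> np.ndarray:
    """Mean over all spatial positions, one value per channel."""
    return t.data.mean(axis=(1, 2, 3))


def extract_features(v, p: ExtractorParams) -> DeepFeaturePair:
    """Full forward pass: x_d = pool(m1(stem(v))), x_e = pool(m2(m1(stem(v)))).

    Module 2 consumes module 1's *pre-pool* tensor (the deep path is the
    composition of both residual modules).
    """
    base = conv_pool_stem(v, p)
    m1 = _run_module(base, p.blocks1, "module1")
    m2 = _run_module(m1, p.blocks2, "module2")
    return DeepFeaturePair(x_d=global_avg_pool(m1), x_e=global_avg_pool(m2))


def extract_features_batch(volumes, p: ExtractorParams):
    """Extract features for a sequence of volumes; items are independent.

    Returns ``(X_d, X_e)`` with one row per input volume.
    """
    pairs = [extract_features(v, p) for v in volumes]
    x_d = np.stack([pr.x_d for pr in pairs]) if pairs else np.empty((0, p.config.m1_channels))
    x_e = np.stack([pr.x_e for pr in pairs]) if pairs else np.empty((0, p.config.m2_channels))
    return x_d, x_e


def stage_shapes(config: ExtractorConfig, input_shape) -> dict:
    """Spatial shape after each stage for a given input, from the stride
    contract alone (output = ceil(input / stride) per axis)."""

    def div(shape, stride):
        return tuple(-(-n // s) for n, s in zip(shape, stride))

    s_conv, s_pool, s_m1, s_m2 = config.strides
    conv = div(tuple(input_shape), s_conv)
    pool = div(conv, s_pool)
    m1 = div(pool, s_m1)
    m2 = div(m1, s_m2)
    return {"stem_conv": conv, "stem_pool": pool, "module1": m1, "module2": m2}


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_extractor(p: ExtractorParams, path) -> None:
    """Serialize all weights to a single archive keyed by stage names."""
    arrays = {"stem/w": p.stem_w, "stem/b": p.stem_b}
    for mod_name, blocks in (("module1", p.blocks1), ("module2", p.blocks2)):
        for i, blk in enumerate(blocks):
            pre = f"{mod_name}/block{i}"
            arrays[f"{pre}/w1"] = blk.w1
            arrays[f"{pre}/b1"] = blk.b1
            arrays[f"{pre}/w2"] = blk.w2
            arrays[f"{pre}/b2"] = blk.b2
            arrays[f"{pre}/w3"] = blk.w3
            arrays[f"{pre}/b3"] = blk.b3
            if blk.proj_w is not None:
                arrays[f"{pre}/proj_w"] = blk.proj_w
                arrays[f"{pre}/proj_b"] = blk.proj_b
    meta = {"config": _config_to_dict(p.config),
            "strides": {"module1": [list(b.stride) for b in p.blocks1],
                        "module2": [list(b.stride) for b in p.blocks2]}}
    save_arrays(path, arrays, meta)


def load_extractor(path) -> ExtractorParams:
    arrays, meta = load_arrays(path)
    config = ExtractorConfig(**meta["config"])

    def blocks_for(mod_name, n):
        out = []
        for i in range(n):
            pre = f"{mod_name}/block{i}"
            out.append(BlockWeights(
                w1=arrays[f"{pre}/w1"], b1=arrays[f"{pre}/b1"],
                w2=arrays[f"{pre}/w2"], b2=arrays[f"{pre}/b2"],
                w3=arrays[f"{pre}/w3"], b3=arrays[f"{pre}/b3"],
                proj_w=arrays.get(f"{pre}/proj_w"),
                proj_b=arrays.get(f"{pre}/proj_b"),
                stride=tuple(meta["strides"][mod_name][i]),
            ))
        return out

    return ExtractorParams(
        config=config, stem_w=arrays["stem/w"], stem_b=arrays["stem/b"],
        blocks1=blocks_for("module1", config.m1_blocks),
        blocks2=blocks_for("module2", config.m2_blocks),
    )


def _config_to_dict(config: ExtractorConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)
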