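"""The ReLCNN murmur-detection network.

A light CNN in the LCNN-9 lineage: five spatial convolutions and four
interleaved network-in-network (1x1) convolutions, every convolution emitting
2f maps that a max-feature-map (MFM) activation halves to f, with post-MFM
channel counts 32, 32, 48, 48, 64, 64, 32, 32, 32. The stack is organised as
a stem (5x5 conv + MFM + pool) followed by four NIN+conv groups; the last
three groups carry residual connections whose skip paths max-pool and/or 1x1
convolve the input when shapes change. Batch normalization and the (trainable
beta) Swish activation are applied selectively at group ends. After the
convolutional stack each time frame is flattened, linearly projected, passed
through multi-head self-attention over frames, mean-pooled over time,
concatenated with scalar side features (mean peak interval), and mapped by a
fully connected layer to a 2-way softmax.

Ablation switches mirror the structural variants studied for this model:
``use_mha=False`` removes the attention block, ``mha_heads`` varies the head
count, and ``activation`` selects none / ReLU / Swish at the group ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as _sigmoid

from ._nn import (
    MFM,
    Adam,
    BatchNorm2d,
    Conv2d,
    Dense,
    Identity,
    Layer,
    MaxPool2,
    MeanPoolTime,
    MultiHeadSelfAttention,
    Param,
    ReLULayer,
    ResidualBlock,
    Sequential,
    Swish,
    ToFrames,
    softmax,
)

__all__ = [
    "LcnnBlockSpec",
    "RelcnnConfig",
    "LcnnBlock",
    "ReLCNN",
    "build_relcnn",
    "mfm",
    "swish",
    "residual_add",
    "multi_head_self_attention",
    "lcnn_block",
]

DEFAULT_BLOCK_FILTERS = (32, 32, 48, 48, 64, 64, 32, 32, 32)
ACTIVATIONS = ("none", "relu", "swish")


@dataclass(frozen=True)
class LcnnBlockSpec:
    """One LCNN block: (f, k, m, b, a) = post-MFM filters, kernel size,
    max-pool flag, batch-norm flag, activation flag."""

    f: int
    k: int
    m: int = 0
    b: int = 0
    a: int = 0

    def __post_init__(self) -> None:
        if self.f < 1:
            raise ValueError("f must be >= 1")
        if self.k not in (1, 3, 5):
            raise ValueError("k must be one of 1, 3, 5")


@dataclass(frozen=True)
class RelcnnConfig:
    block_filters: tuple[int, ...] = DEFAULT_BLOCK_FILTERS
    first_kernel: int = 5
    mha_heads: int = 8
    d_model: int = 64
    use_mha: bool = True
    activation: str = "swish"
    swish_beta: float = 1.0
    n_outputs: int = 2
    scalar_feature_names: tuple[str, ...] = ("mean_peak_interval",)

    def __post_init__(self) -> None:
        if len(self.block_filters) != 9:
            raise ValueError("block_filters must list 9 entries")
        if self.use_mha and self.d_model % self.mha_heads:
            raise ValueError(
                f"mha_heads={self.mha_heads} must divide d_model={self.d_model}"
            )
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


# ---------------------------------------------------------------------------
# Functional primitives (thin views of the layer implementations)


def mfm(x: np.ndarray) -> np.ndarray:
    """Max-feature-map over paired channel halves (channel axis is -3)."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    out = MFM().forward(x)
    return out[0] if squeeze else out


def swish(x: np.ndarray, beta: float = 1.0) -> np.ndarray:
    """Swish(x) = x * sigmoid(beta * x), elementwise."""
    x = np.asarray(x, dtype=np.float64)
    return x * _sigmoid(beta * x)


def residual_add(
    x: np.ndarray, fx: np.ndarray, skip_conv_weight: np.ndarray | None = None
) -> np.ndarray:
    """x + F(x) with shape reconciliation on the skip path.

    When spatial dims differ by powers of two the input is 2x2 max-pooled;
    when channel counts differ a 1x1 convolution is applied (with
    ``skip_conv_weight`` of shape (out_ch, in_ch) when given, else a
    deterministic He-initialized projection).
    """
    x = np.asarray(x, dtype=np.float64)
    fx = np.asarray(fx, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x, fx = x[None], fx[None]
    while x.shape[2] > fx.shape[2] or x.shape[3] > fx.shape[3]:
        shrunk = MaxPool2().forward(x)
        if shrunk.shape[2:] == x.shape[2:]:
            break
        x = shrunk
    if x.shape[1] != fx.shape[1]:
        rng = np.random.default_rng(0)
        conv = Conv2d(x.shape[1], fx.shape[1], 1, rng)
        if skip_conv_weight is not None:
            conv.w.value = np.asarray(skip_conv_weight, float)[:, :, None, None]
        x = conv.forward(x)
    if x.shape != fx.shape:
        raise ValueError(f"irreconcilable shapes {x.shape} vs {fx.shape}")
    out = x + fx
    return out[0] if squeeze else out


def multi_head_self_attention(
    x: np.ndarray, heads: int, seed: int = 0
) -> np.ndarray:
    """Apply a randomly initialized (seeded) MHA layer to (N, T, D) or (T, D)."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    layer = MultiHeadSelfAttention(x.shape[-1], heads, np.random.default_rng(seed))
    out = layer.forward(x)
    return out[0] if squeeze else out


class LcnnBlock(Layer):
    """Conv(2f, k) -> MFM -> [maxpool] -> [batch norm] -> [activation]."""

    def __init__(
        self,
        in_ch: int,
        spec: LcnnBlockSpec,
        rng: np.random.Generator,
        activation: str = "swish",
        swish_beta: float = 1.0,
    ):
        self.spec = spec
        self.conv = Conv2d(in_ch, 2 * spec.f, spec.k, rng)
        layers: list[Layer] = [self.conv, MFM()]
        if spec.m:
            layers.append(MaxPool2())
        if spec.b:
            layers.append(BatchNorm2d(spec.f))
        if spec.a:
            layers.append(_make_activation(activation, swish_beta))
        self.seq = Sequential(*layers)

    def params(self):
        return self.seq.params()

    def forward(self, x, train=False):
        return self.seq.forward(x, train)

    def backward(self, dout):
        return self.seq.backward(dout)


def lcnn_block(
    x: np.ndarray, spec: LcnnBlockSpec, block: LcnnBlock | None = None, seed: int = 0
) -> np.ndarray:
    """Functional LCNN block application (builds a seeded block if not given)."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if block is None:
        block = LcnnBlock(x.shape[1], spec, np.random.default_rng(seed))
    out = block.forward(x)
    return out[0] if squeeze else out


def _make_activation(kind: str, beta: float = 1.0) -> Layer:
    if kind == "swish":
        return Swish(beta)
    if kind == "relu":
        return ReLULayer()
    return Identity()


# ---------------------------------------------------------------------------
# Full model


@dataclass
class _Group:
    nin_f: int
    conv_f: int
    pool: bool
    bn: bool
    residual: bool


class ReLCNN:
    """The assembled network; see the module docstring for the wiring."""

    def __init__(self, cfg: RelcnnConfig, input_shape: tuple[int, int, int],
                 seed: int = 0):
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        f = cfg.block_filters
        c_in, h, w = self.input_shape

        def act() -> Layer:
            return _make_activation(cfg.activation, cfg.swish_beta)

        stem = [Conv2d(c_in, 2 * f[0], cfg.first_kernel, rng), MFM(), MaxPool2()]
        h, w = h // 2, w // 2

        groups = [
            _Group(f[1], f[2], pool=True, bn=True, residual=False),
            _Group(f[3], f[4], pool=True, bn=False, residual=True),
            _Group(f[5], f[6], pool=False, bn=True, residual=True),
            _Group(f[7], f[8], pool=True, bn=False, residual=True),
        ]
        layers: list[Layer] = list(stem)
        ch = f[0]
        for g in groups:
            main: list[Layer] = [
                Conv2d(ch, 2 * g.nin_f, 1, rng), MFM(),
                Conv2d(g.nin_f, 2 * g.conv_f, 3, rng), MFM(),
            ]
            if g.pool:
                main.append(MaxPool2())
                h, w = h // 2, w // 2
            if g.bn:
                main.append(BatchNorm2d(g.conv_f))
            if g.residual:
                skip_conv = (
                    Conv2d(ch, g.conv_f, 1, rng) if g.conv_f != ch else None
                )
                layers.append(
                    ResidualBlock(
                        Sequential(*main),
                        skip_pools=1 if g.pool else 0,
                        skip_conv=skip_conv,
                        post=act(),
                    )
                )
            else:
                layers += [Sequential(*main), act()]
            ch = g.conv_f
        if h < 1 or w < 1:
            raise ValueError(f"input {input_shape} too small for the conv stack")

        layers.append(ToFrames())
        layers.append(Dense(ch * h, cfg.d_model, rng))
        if cfg.use_mha:
            layers.append(MultiHeadSelfAttention(cfg.d_model, cfg.mha_heads, rng))
        layers.append(MeanPoolTime())
        self.backbone = Sequential(*layers)
        self.n_scalars = len(cfg.scalar_feature_names)
        self.head = Dense(cfg.d_model + self.n_scalars, cfg.n_outputs, rng)
        self._frame_dim = ch * h

    # -- introspection ------------------------------------------------------

    @property
    def block_filters(self) -> list[int]:
        """Post-MFM channel count of each main-path convolution, in network
        order (residual skip-path 1x1 convolutions are not blocks)."""
        return [
            layer.w.value.shape[0] // 2
            for layer in _walk_main(self.backbone)
            if isinstance(layer, Conv2d)
        ]

    def parameters(self) -> dict[str, Param]:
        out = {f"backbone.{k}": p for k, p in self.backbone.params().items()}
        out.update({f"head.{k}": p for k, p in self.head.params().items()})
        return out

    # -- forward / backward -------------------------------------------------

    def forward_logits(
        self, x: np.ndarray, scalars: np.ndarray | None = None, train: bool = False
    ) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        feats = self.backbone.forward(x, train)
        if self.n_scalars:
            if scalars is None:
                scalars = np.zeros((x.shape[0], self.n_scalars))
            feats = np.concatenate([feats, np.asarray(scalars, float)], axis=1)
        return self.head.forward(feats, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        if self.n_scalars:
            dfeat = dfeat[:, : -self.n_scalars]
        self.backbone.backward(dfeat)

    def predict_proba(
        self, x: np.ndarray, scalars: np.ndarray | None = None
    ) -> np.ndarray:
        return softmax(self.forward_logits(x, scalars, train=False))

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.parameters(), lr=lr)

    def refresh_batchnorm(
        self, x: np.ndarray, scalars: np.ndarray | None = None, batch: int = 64
    ) -> None:
        """Re-estimate batch-norm running statistics under the final weights.

        During short trainings the exponential running stats lag behind the
        current parameters, skewing eval-mode outputs; one cumulative-average
        sweep over the (training) data fixes them.
        """
        bn_layers = self._batchnorm_layers()
        if not bn_layers:
            return
        saved = [(l.momentum, l.running_mean.copy(), l.running_var.copy())
                 for l in bn_layers]
        for l in bn_layers:
            l.running_mean[:] = 0.0
            l.running_var[:] = 0.0
        try:
            for i, start in enumerate(range(0, x.shape[0], batch)):
                for l in bn_layers:
                    l.momentum = 1.0 / (i + 1)
                self.forward_logits(
                    x[start : start + batch],
                    None if scalars is None else scalars[start : start + batch],
                    train=True,
                )
        finally:
            for l, (mom, _, _) in zip(bn_layers, saved):
                l.momentum = mom

    # -- checkpointing ------------------------------------------------------

    def _batchnorm_layers(self) -> list[BatchNorm2d]:
        return [l for l in _walk(self.backbone) if isinstance(l, BatchNorm2d)]

    def save(self, path) -> None:
        arrays = {k: p.value for k, p in self.parameters().items()}
        for i, bn in enumerate(self._batchnorm_layers()):
            arrays[f"_bn{i}.running_mean"] = bn.running_mean
            arrays[f"_bn{i}.running_var"] = bn.running_var
        np.savez(path, **arrays)

    def load(self, path) -> None:
        with np.load(path) as archive:
            for k, p in self.parameters().items():
                p.value = archive[k].astype(np.float64)
            for i, bn in enumerate(self._batchnorm_layers()):
                bn.running_mean = archive[f"_bn{i}.running_mean"].astype(np.float64)
                bn.running_var = archive[f"_bn{i}.running_var"].astype(np.float64)


def _walk(layer: Layer):
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _walk(sub)
    elif isinstance(layer, ResidualBlock):
        yield from _walk(layer.main)
        if layer.skip_conv is not None:
            yield from _walk(layer.skip_conv)
        yield from _walk(layer.post)
    elif isinstance(layer, LcnnBlock):
        yield from _walk(layer.seq)


def _walk_main(layer: Layer):
    """Like _walk but skipping residual skip paths (main computation only)."""
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _walk_main(sub)
    elif isinstance(layer, ResidualBlock):
        yield from _walk_main(layer.main)
    elif isinstance(layer, LcnnBlock):
        yield from _walk_main(layer.seq)


def build_relcnn(
    cfg: RelcnnConfig, input_shape: tuple[int, int, int], seed: int = 0
) -> ReLCNN:
    """Construct a ReLCNN for inputs of shape (channels, n_mels, frames)."""
    return ReLCNN(cfg, input_shape, seed=seed)
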