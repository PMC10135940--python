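"""MSA-ResNet: a 1-D residual network for PPG-to-blood-pressure regression.

The architecture is a ResNet34-style 1-D backbone with two modifications:

* the stem is a **multi-scale feature-extraction (MSFE) block**: four
  parallel convolutional branches — regular convolutions with kernels 3, 5
  and 7, plus a large-kernel (13) branch realised as a depthwise
  convolution followed by a pointwise (kernel-1) channel-mixing
  convolution — whose same-padded outputs are concatenated along channels
  and reshaped by a kernel-1 convolution;
* every residual block carries a **squeeze-and-excitation (SE)** channel
  attention module on its residual branch, applied before the shortcut
  addition.

Residual learning follows ``H(x) = F(x) + x`` with a projection shortcut
(kernel-1 convolution + batch norm) wherever the stride or channel count
changes.  The head is a global average pool followed by a fully connected
layer with two outputs: systolic and diastolic pressure in mmHg.

All convolutions that feed a batch-norm layer are bias-free (the batch
norm's shift subsumes the bias).  A ``width_multiplier`` scales every
channel count so that a quarter-width model runs the identical code path
as the full-size network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn.layers import (
    Layer, Conv1d, DepthwiseConv1d, BatchNorm1d, ReLU, MaxPool1d,
    GlobalAvgPool1d, Linear, SEBlock, conv_out_len,
)

__all__ = [
    "MSFEConfig",
    "SEConfig",
    "ModelConfig",
    "MSFE",
    "SEResidualBlock",
    "MSAResNet",
    "build_model",
    "count_parameters",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass
class MSFEConfig:
    regular_kernels: tuple[int, ...] = (3, 5, 7)
    large_kernel: int = 13
    branch_channels: int = 16
    out_channels: int = 64
    stride: int = 2

    def validate(self) -> None:
        for k in (*self.regular_kernels, self.large_kernel):
            if k % 2 == 0 or k < 1:
                raise ValueError(f"all MSFE kernels must be odd and positive, got {k}")
        if self.branch_channels < 1 or self.out_channels < 1:
            raise ValueError("MSFE channel counts must be >= 1")


@dataclass
class SEConfig:
    reduction: int = 16

    def validate(self) -> None:
        if self.reduction < 1:
            raise ValueError(f"SE reduction must be >= 1, got {self.reduction}")


@dataclass
class ModelConfig:
    in_channels: int = 3
    input_length: int = 375
    msfe: MSFEConfig = field(default_factory=MSFEConfig)
    se: SEConfig = field(default_factory=SEConfig)
    blocks_per_stage: tuple[int, ...] = (3, 4, 6, 3)
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    width_multiplier: float = 1.0
    out_dim: int = 2

    def validate(self) -> None:
        self.msfe.validate()
        self.se.validate()
        if len(self.blocks_per_stage) != len(self.stage_channels):
            raise ValueError(
                "blocks_per_stage and stage_channels must have equal length, got "
                f"{len(self.blocks_per_stage)} vs {len(self.stage_channels)}"
            )
        if self.out_dim != 2:
            raise ValueError("out_dim must be 2 (SBP, DBP)")
        if self.msfe.out_channels != self.stage_channels[0]:
            raise ValueError(
                f"MSFE out_channels ({self.msfe.out_channels}) must equal the first "
                f"stage width ({self.stage_channels[0]})"
            )
        if not self.width_multiplier > 0:
            raise ValueError("width_multiplier must be positive")

    def scaled(self, c: int) -> int:
        """Channel count after width scaling (at least 1)."""
        return max(1, int(round(c * self.width_multiplier)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["msfe"] = MSFEConfig(**{**d.get("msfe", {}),
                                  "regular_kernels": tuple(d.get("msfe", {}).get("regular_kernels", (3, 5, 7)))})
        d["se"] = SEConfig(**d.get("se", {}))
        d["blocks_per_stage"] = tuple(d["blocks_per_stage"])
        d["stage_channels"] = tuple(d["stage_channels"])
        return cls(**d)


class MSFE(Layer):
    """Multi-scale feature-extraction stem (four parallel branches)."""

    def __init__(self, in_ch: int, cfg: MSFEConfig, width: float = 1.0,
                 rng=None, dtype=np.float32):
        bc = max(1, int(round(cfg.branch_channels * width)))
        oc = max(1, int(round(cfg.out_channels * width)))
        s = cfg.stride
        self.branch_channels, self.out_channels, self.stride = bc, oc, s
        self.regular = []
        for k in cfg.regular_kernels:
            self.regular.append((
                Conv1d(in_ch, bc, k, stride=s, bias=False, rng=rng, dtype=dtype),
                BatchNorm1d(bc, dtype=dtype), ReLU(),
            ))
        self.dw = DepthwiseConv1d(in_ch, cfg.large_kernel, stride=s, bias=False,
                                  rng=rng, dtype=dtype)
        self.pw = Conv1d(in_ch, bc, 1, bias=False, rng=rng, dtype=dtype)
        self.bn_large = BatchNorm1d(bc, dtype=dtype)
        self.relu_large = ReLU()
        concat_ch = bc * (len(cfg.regular_kernels) + 1)
        self.reshape = Conv1d(concat_ch, oc, 1, bias=False, rng=rng, dtype=dtype)
        self.bn_out = BatchNorm1d(oc, dtype=dtype)
        self.relu_out = ReLU()

    def _layers(self):
        out = []
        for conv, bn, relu in self.regular:
            out += [conv, bn, relu]
        out += [self.dw, self.pw, self.bn_large, self.relu_large,
                self.reshape, self.bn_out, self.relu_out]
        return out

    def params(self):
        return [p for lay in self._layers() for p in lay.params()]

    def buffers(self):
        return [b for lay in self._layers() for b in lay.buffers()]

    def branch_outputs(self, x: np.ndarray, training: bool = False) -> list[np.ndarray]:
        """Outputs of the four parallel branches (before concatenation)."""
        outs = []
        for conv, bn, relu in self.regular:
            outs.append(relu.forward(bn.forward(conv.forward(x, training), training)))
        h = self.dw.forward(x, training)
        h = self.pw.forward(h, training)
        outs.append(self.relu_large.forward(self.bn_large.forward(h, training)))
        return outs

    def forward(self, x, training=False):
        outs = self.branch_outputs(x, training)
        cat = np.concatenate(outs, axis=1)
        y = self.reshape.forward(cat, training)
        y = self.bn_out.forward(y, training)
        return self.relu_out.forward(y)

    def backward(self, gy):
        g = self.relu_out.backward(gy)
        g = self.bn_out.backward(g)
        gcat = self.reshape.backward(g)
        bc = self.branch_channels
        gx = None
        for i, (conv, bn, relu) in enumerate(self.regular):
            gb = gcat[:, i * bc : (i + 1) * bc]
            gxi = conv.backward(bn.backward(relu.backward(gb)))
            gx = gxi if gx is None else gx + gxi
        glarge = gcat[:, len(self.regular) * bc :]
        gl = self.bn_large.backward(self.relu_large.backward(glarge))
        gl = self.dw.backward(self.pw.backward(gl))
        return gx + gl


class SEResidualBlock(Layer):
    """Residual block with squeeze-and-excitation on the residual branch.

    ``y = ReLU(SE(BN(conv(ReLU(BN(conv(x)))))) + shortcut(x))``; the
    shortcut is the identity, or a strided kernel-1 projection when the
    stride or channel count changes.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 se_reduction: int = 16, rng=None, dtype=np.float32):
        self.conv1 = Conv1d(in_ch, out_ch, 3, stride=stride, bias=False, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm1d(out_ch, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_ch, out_ch, 3, bias=False, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm1d(out_ch, dtype=dtype)
        self.se = SEBlock(out_ch, reduction=se_reduction, rng=rng, dtype=dtype)
        self.relu_out = ReLU()
        self.projection = stride != 1 or in_ch != out_ch
        if self.projection:
            self.conv_sc = Conv1d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng, dtype=dtype)
            self.bn_sc = BatchNorm1d(out_ch, dtype=dtype)
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride

    def _layers(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.se, self.relu_out]
        if self.projection:
            out += [self.conv_sc, self.bn_sc]
        return out

    def params(self):
        return [p for lay in self._layers() for p in lay.params()]

    def buffers(self):
        return [b for lay in self._layers() for b in lay.buffers()]

    def forward(self, x, training=False):
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        h = self.se.forward(h, training)
        if self.projection:
            sc = self.bn_sc.forward(self.conv_sc.forward(x, training), training)
        else:
            sc = x
        return self.relu_out.forward(h + sc)

    def backward(self, gy):
        g = self.relu_out.backward(gy)
        gb = self.se.backward(g)
        gb = self.bn2.backward(gb)
        gb = self.conv2.backward(gb)
        gb = self.relu1.backward(gb)
        gb = self.bn1.backward(gb)
        gx = self.conv1.backward(gb)
        if self.projection:
            gx = gx + self.conv_sc.backward(self.bn_sc.backward(g))
        else:
            gx = gx + g
        return gx


class MSAResNet(Layer):
    """Full network: MSFE stem -> max pool -> SE-residual stages -> GAP -> FC."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.dtype = dtype
        self.stem = MSFE(cfg.in_channels, cfg.msfe, width=cfg.width_multiplier,
                         rng=rng, dtype=dtype)
        self.pool = MaxPool1d(kernel=3, stride=2, pad=1)
        self.blocks: list[SEResidualBlock] = []
        in_ch = self.stem.out_channels
        for stage, (n_blocks, ch) in enumerate(zip(cfg.blocks_per_stage, cfg.stage_channels)):
            out_ch = cfg.scaled(ch)
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(
                    SEResidualBlock(in_ch, out_ch, stride=stride,
                                    se_reduction=cfg.se.reduction, rng=rng, dtype=dtype)
                )
                in_ch = out_ch
        self.gap = GlobalAvgPool1d()
        self.head = Linear(in_ch, cfg.out_dim, rng=rng, dtype=dtype)

    def _layers(self):
        return [self.stem, self.pool, *self.blocks, self.gap, self.head]

    def params(self):
        return [p for lay in self._layers() for p in lay.params()]

    def buffers(self):
        return [b for lay in self._layers() for b in lay.buffers()]

    def forward(self, x, training=False):
        x = np.ascontiguousarray(np.asarray(x, dtype=self.dtype))
        if x.ndim != 3 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input of shape (batch, {self.cfg.in_channels}, length), "
                f"got {x.shape}"
            )
        h = self.stem.forward(x, training)
        h = self.pool.forward(h, training)
        for blk in self.blocks:
            h = blk.forward(h, training)
        h = self.gap.forward(h, training)
        return self.head.forward(h, training)

    def backward(self, gy):
        g = self.head.backward(np.asarray(gy, dtype=self.dtype))
        g = self.gap.backward(g)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        g = self.pool.backward(g)
        return self.stem.backward(g)

    # -- state management ---------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.params()] + self.buffers()

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            if dst.shape != src.shape:
                raise ValueError("state shape mismatch")
            dst[...] = src

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def summary(self) -> str:
        """Per-stage output shapes and parameter counts."""
        cfg = self.cfg
        L = cfg.input_length
        rows = [("input", cfg.in_channels, L, 0)]
        L = conv_out_len(L, cfg.msfe.stride)
        rows.append(("msfe_stem", self.stem.out_channels, L, self.stem.n_params()))
        L = (L + 2 * self.pool.pad - self.pool.kernel) // self.pool.stride + 1
        rows.append(("maxpool", self.stem.out_channels, L, 0))
        for i, blk in enumerate(self.blocks):
            L = conv_out_len(L, blk.stride)
            rows.append((f"se_res_block_{i}", blk.out_ch, L, blk.n_params()))
        rows.append(("global_avg_pool", rows[-1][1], 1, 0))
        rows.append(("fc_head", cfg.out_dim, 1, self.head.n_params()))
        lines = [f"{'layer':<18}{'channels':>9}{'length':>8}{'params':>10}"]
        for name, ch, length, n in rows:
            lines.append(f"{name:<18}{ch:>9}{length:>8}{n:>10}")
        lines.append(f"{'total':<18}{'':>9}{'':>8}{self.n_params():>10}")
        return "\n".join(lines)


def build_model(cfg: ModelConfig | None = None, seed: int = 0,
                dtype=np.float32) -> MSAResNet:
    """Construct a seeded MSA-ResNet from a configuration."""
    return MSAResNet(cfg or ModelConfig(), seed=seed, dtype=dtype)


def count_parameters(model: MSAResNet) -> int:
    return model.n_params()


def predict(model: MSAResNet, inputs: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Inference-mode predictions, ``(n, 2)`` mmHg, input order preserved.

    Batch-norm layers use their frozen running statistics, so results do
    not depend on how the batch is composed.
    """
    x = np.asarray(inputs)
    if x.ndim == 2:  # single sample (channels, length)
        x = x[None]
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(model.forward(x[i : i + batch_size], training=False))
    return np.concatenate(outs, axis=0).astype(float)


def save_checkpoint(path, model: MSAResNet, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights + config echo + format version."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": model.cfg.to_dict(),
        "extra": extra or {},
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[MSAResNet, dict]:
    """Rebuild a model from a checkpoint; returns (model, extra metadata)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = ModelConfig.from_dict(meta["config"])
        model = MSAResNet(cfg)
        n = len(model.state_arrays())
        state = [z[f"arr_{i}"] for i in range(n)]
    model.set_state(state)
    return model, meta["extra"]
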