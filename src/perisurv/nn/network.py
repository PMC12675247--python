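"""The 3D squeeze-and-excitation residual survival network.

Architecture: a stem 3x3x3 convolution (stride 2) and 3x3x3 max pool
(stride 2), four residual blocks of two convolutional units each with
progressively doubling filter counts, an SE channel-attention module after
every block, global average pooling (the exported feature vector), and a
fully connected head with dropout ending in a single tanh-bounded risk
output.  The first block keeps stride 1 with its first convolution acting
directly on the pooled stem output; all other units are pre-activation
("BN + ReLU + conv"), and down-sampling blocks use a projection shortcut
(1x1x1 convolution, stride 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm,
    Conv3d,
    Dense,
    Dropout,
    GlobalAvgPool,
    Layer,
    MaxPool3d,
    Param,
    ReLU,
    SEBlock,
    Tanh,
)

__all__ = ["ArchitectureConfig", "SEResNet3D"]


@dataclass
class ArchitectureConfig:
    """Hyperparameters of the survival network.

    The default is the full-scale architecture (64^3 input, filters
    64-512, 512-wide feature vector); :meth:`desk` returns the scaled-down
    preset used for CPU-scale experiments.
    """

    input_size: int = 64
    stem_kernel: int = 3
    stem_stride: int = 2
    pool_kernel: int = 3
    pool_stride: int = 2
    filters: tuple[int, int, int, int] = (64, 128, 256, 512)
    se_ratio: int = 64
    se_enabled: bool = True
    fc_widths: tuple[int, ...] = (512, 256, 128)
    dropout: float = 0.4
    l2: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filters) != 4:
            raise ValueError("exactly 4 residual blocks are required")
        if any(a >= b for a, b in zip(self.filters, self.filters[1:])):
            raise ValueError("filter counts must be strictly increasing")
        if self.se_ratio < 1 or self.dropout < 0 or self.dropout >= 1 or self.l2 < 0:
            raise ValueError("invalid SE ratio, dropout rate, or L2 coefficient")

    @classmethod
    def desk(cls, **kw) -> "ArchitectureConfig":
        """Quarter-width preset on 32^3 blocks for single-CPU training."""
        kw.setdefault("input_size", 32)
        kw.setdefault("filters", (8, 16, 32, 64))
        kw.setdefault("fc_widths", (64, 32, 16))
        kw.setdefault("se_ratio", 8)
        return cls(**kw)

    @property
    def gap_width(self) -> int:
        return self.filters[-1]


class _ResidualBlock:
    """Two convolutional units + skip connection (+ optional SE)."""

    def __init__(self, c_in: int, c_out: int, stride: int, first: bool,
                 se: bool, se_ratio: int, rng):
        self.first = first
        self.stride = stride
        if first:
            assert c_in == c_out and stride == 1
            self.conv1 = Conv3d(c_in, c_out, 3, 1, rng)
        else:
            self.bn1 = BatchNorm(c_in)
            self.relu1 = ReLU()
            self.conv1 = Conv3d(c_in, c_out, 3, stride, rng)
        self.bn2 = BatchNorm(c_out)
        self.relu2 = ReLU()
        self.conv2 = Conv3d(c_out, c_out, 3, 1, rng)
        self.proj = Conv3d(c_in, c_out, 1, stride, rng) if (stride != 1 or c_in != c_out) else None
        self.se = SEBlock(c_out, se_ratio, rng) if se else None

    def layers(self) -> list[Layer]:
        out = [self.conv1, self.bn2, self.relu2, self.conv2]
        if not self.first:
            out = [self.bn1, self.relu1] + out
        if self.proj is not None:
            out.append(self.proj)
        if self.se is not None:
            out.append(self.se)
        return out

    def params(self) -> list[Param]:
        return [p for l in self.layers() for p in l.params()]

    def forward(self, x, training=False):
        h = x if self.first else self.relu1.forward(self.bn1.forward(x, training), training)
        h = self.conv1.forward(h, training)
        h = self.conv2.forward(self.relu2.forward(self.bn2.forward(h, training), training), training)
        skip = x if self.proj is None else self.proj.forward(x, training)
        out = (skip + h).astype(np.float32)
        if self.se is not None:
            out = self.se.forward(out, training)
        return out

    def backward(self, dy):
        if self.se is not None:
            dy = self.se.backward(dy)
        dh = self.conv2.backward(dy)
        dh = self.bn2.backward(self.relu2.backward(dh))
        dh = self.conv1.backward(dh)
        if not self.first:
            dh = self.bn1.backward(self.relu1.backward(dh))
        dskip = dy if self.proj is None else self.proj.backward(dy)
        return (dskip + dh).astype(np.float32)


class SEResNet3D:
    """The full network; see the module docstring for the layer graph."""

    def __init__(self, config: ArchitectureConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.filters
        self.stem = Conv3d(1, f[0], config.stem_kernel, config.stem_stride, rng)
        self.pool = MaxPool3d(config.pool_kernel, config.pool_stride)
        self.blocks = [
            _ResidualBlock(f[0], f[0], 1, True, config.se_enabled, config.se_ratio, rng),
            _ResidualBlock(f[0], f[1], 2, False, config.se_enabled, config.se_ratio, rng),
            _ResidualBlock(f[1], f[2], 2, False, config.se_enabled, config.se_ratio, rng),
            _ResidualBlock(f[2], f[3], 2, False, config.se_enabled, config.se_ratio, rng),
        ]
        self.final_bn = BatchNorm(f[3])
        self.final_relu = ReLU()
        self.gap = GlobalAvgPool()
        widths = [f[3], *config.fc_widths]
        self.head: list[Layer] = []
        for a, b in zip(widths, widths[1:]):
            self.head += [Dense(a, b, rng), ReLU(), Dropout(config.dropout)]
        self.out = Dense(widths[-1], 1, rng)
        self.tanh = Tanh()
        self._gap_features = None

    # -- parameter plumbing -------------------------------------------------

    def _all_layers(self) -> list[Layer]:
        out = [self.stem, self.pool]
        for b in self.blocks:
            out += b.layers()
        out += [self.final_bn, self.final_relu, self.gap, *self.head, self.out, self.tanh]
        return out

    def params(self) -> list[Param]:
        return [p for l in self._all_layers() for p in l.params()]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def seed_dropout(self, seed: int) -> None:
        for i, l in enumerate(self._all_layers()):
            if isinstance(l, Dropout):
                l.rng = np.random.default_rng(np.random.SeedSequence([seed, i]))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, l in enumerate(self._all_layers()):
            for j, p in enumerate(l.params()):
                state[f"layer{i}.param{j}"] = p.value.copy()
            if isinstance(l, BatchNorm):
                state[f"layer{i}.running_mean"] = l.running_mean.copy()
                state[f"layer{i}.running_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self._all_layers()):
            for j, p in enumerate(l.params()):
                p.value = np.asarray(state[f"layer{i}.param{j}"], dtype=np.float32).copy()
            if isinstance(l, BatchNorm):
                l.running_mean = np.asarray(state[f"layer{i}.running_mean"], dtype=np.float32).copy()
                l.running_var = np.asarray(state[f"layer{i}.running_var"], dtype=np.float32).copy()

    # -- passes -------------------------------------------------------------

    def forward(self, blocks: np.ndarray, training: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Risk scores and GAP features for a batch of (N, D, H, W) cubes."""
        x = np.asarray(blocks, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.config.input_size:
            raise ValueError(
                f"expected (N, {self.config.input_size}^3) blocks, got {x.shape}"
            )
        x = x[:, None]  # single channel
        x = self.pool.forward(self.stem.forward(x, training), training)
        for b in self.blocks:
            x = b.forward(x, training)
        x = self.final_relu.forward(self.final_bn.forward(x, training), training)
        feats = self.gap.forward(x, training)
        self._gap_features = feats
        h = feats
        for l in self.head:
            h = l.forward(h, training)
        score = self.tanh.forward(self.out.forward(h, training), training)
        if not np.all(np.isfinite(score)):
            raise FloatingPointError("non-finite network output")
        return score[:, 0], feats

    def backward(self, dscore: np.ndarray) -> None:
        dy = self.out.backward(self.tanh.backward(dscore[:, None]))
        for l in reversed(self.head):
            dy = l.backward(dy)
        dy = self.gap.backward(dy)
        dy = self.final_bn.backward(self.final_relu.backward(dy))
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        self.stem.backward(self.pool.backward(dy))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def l2_penalty(self) -> float:
        return float(self.config.l2 * sum((p.value**2).sum() for p in self.params() if p.weight_decay))

    def add_l2_gradients(self) -> None:
        for p in self.params():
            if p.weight_decay:
                p.grad += 2.0 * self.config.l2 * p.value

    def extract_gap_features(self, blocks: np.ndarray) -> np.ndarray:
        """Deterministic inference pass returning the GAP feature vectors."""
        _, feats = self.forward(blocks, training=False)
        return feats
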