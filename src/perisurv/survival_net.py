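"""Deep survival model: Cox partial-likelihood training of the 3D-SE-ResNet.

The training objective is the negative log Cox partial likelihood (Breslow
convention for tied event times, normalized by the number of events in the
batch) plus an L2 weight penalty.  Optimization is Adam with an
exponentially decayed learning rate; data augmentation mirrors standard
3D medical-image policies (intensity transforms at 15%, mirroring and
z-rotation at 30%).  The 512-dimensional global-average-pooling activations
are the exported deep features; the tanh output is only the training head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Adam, ArchitectureConfig, SEResNet3D

__all__ = [
    "cox_ph_loss",
    "AugmentationConfig",
    "TrainingConfig",
    "augment",
    "DeepSurvivalModel",
    "DeepSurvivalResults",
]


# ---------------------------------------------------------------------------
# Cox partial-likelihood loss


def cox_ph_loss(scores, time, event, return_grad: bool = False):
    """Negative log Cox partial likelihood, Breslow ties, event-normalized.

    loss = -(1/D) sum_{i: event} [h_i - log sum_{j: T_j >= T_i} exp(h_j)]

    An event-free batch has loss 0 (with a warning).  The log-sum-exp is
    stabilized, so any finite scores give a finite loss.
    """
    h = np.asarray(scores, dtype=np.float64)
    t = np.asarray(time, dtype=np.float64)
    d = np.asarray(event, dtype=int)
    if np.any(~np.isfinite(h)):
        raise ValueError("non-finite risk scores")
    n_events = int(d.sum())
    if n_events == 0:
        warnings.warn("batch contains no events; Cox loss is 0")
        return (0.0, np.zeros_like(h)) if return_grad else 0.0

    order = np.argsort(-t, kind="stable")  # descending time
    hs, ts, ds = h[order], t[order], d[order]
    m = hs.max()
    cum = np.logaddexp.accumulate(hs - m) + m  # lse of prefix in desc order
    # tied times share the risk set: use the lse at the END of each tie group
    group_end = np.empty(len(ts), dtype=int)
    i = 0
    while i < len(ts):
        j = i
        while j + 1 < len(ts) and ts[j + 1] == ts[i]:
            j += 1
        group_end[i : j + 1] = j
        i = j + 1
    denom = cum[group_end]
    ev = ds == 1
    loss = -(hs[ev] - denom[ev]).sum() / n_events

    if not return_grad:
        return float(loss)

    # dL/dh_j = -(1/D)[d_j - sum_{i in events, pos_j <= group_end_i} exp(h_j - denom_i)]
    shift = denom[ev].min()
    b = np.zeros(len(ts))
    np.add.at(b, group_end[ev], np.exp(-(denom[ev] - shift)))
    a_cum = np.cumsum(b[::-1])[::-1]  # suffix sum: events whose risk set covers position p
    r = np.exp(hs - shift) * a_cum
    grad_s = -(ds - r) / n_events
    grad = np.zeros_like(h)
    grad[order] = grad_s
    return float(loss), grad


# ---------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentationConfig:
    """Per-transform parameter ranges and application probabilities."""

    contrast_range: tuple[float, float] = (1.0, 1.75)
    contrast_p: float = 0.15
    brightness_range: tuple[float, float] = (0.7, 1.5)
    brightness_p: float = 0.15
    gamma_range: tuple[float, float] = (0.5, 2.0)
    gamma_p: float = 0.15
    noise_variance_range: tuple[float, float] = (0.0, 0.05)
    noise_p: float = 0.15
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    blur_p: float = 0.15
    mirror_p: float = 0.30
    rotation_range_deg: tuple[float, float] = (0.0, 360.0)
    rotation_p: float = 0.30

    def __post_init__(self) -> None:
        for name in ("contrast_p", "brightness_p", "gamma_p", "noise_p", "blur_p",
                     "mirror_p", "rotation_p"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        for name in ("contrast_range", "brightness_range", "gamma_range",
                     "noise_variance_range", "blur_sigma_range", "rotation_range_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be a nonempty range")

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        return cls(contrast_p=0, brightness_p=0, gamma_p=0, noise_p=0, blur_p=0,
                   mirror_p=0, rotation_p=0)


def augment(block: np.ndarray, config: AugmentationConfig, seed) -> np.ndarray:
    """Apply the stochastic 3D augmentation stack to one cube.

    Transforms trigger independently with their configured probabilities;
    parameters are uniform draws from the stated ranges.  Identical seeds
    reproduce identical outputs.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(block, dtype=np.float64).copy()

    if rng.random() < config.contrast_p:
        f = rng.uniform(*config.contrast_range)
        mean = x.mean()
        x = mean + (x - mean) * f
    if rng.random() < config.brightness_p:
        x = x * rng.uniform(*config.brightness_range)
    if rng.random() < config.gamma_p:
        g = rng.uniform(*config.gamma_range)
        lo, hi = x.min(), x.max()
        if hi > lo:
            x = ((x - lo) / (hi - lo)) ** g * (hi - lo) + lo
    if rng.random() < config.noise_p:
        var = rng.uniform(*config.noise_variance_range)
        x = x + rng.normal(0.0, np.sqrt(var), size=x.shape)
    if rng.random() < config.blur_p:
        x = ndimage.gaussian_filter(x, rng.uniform(*config.blur_sigma_range))
    if rng.random() < config.mirror_p:
        for axis in range(3):
            if rng.random() < 0.5:
                x = np.flip(x, axis=axis)
    if rng.random() < config.rotation_p:
        angle = rng.uniform(*config.rotation_range_deg)
        x = ndimage.rotate(x, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
    return np.ascontiguousarray(x)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingConfig:
    """Optimization schedule of the survival network."""

    learning_rate: float = 1e-4
    lr_decay: float = 0.96
    lr_decay_steps: int = 1000
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 15
    val_fraction: float = 0.2
    augment: bool = True
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    event_stratified_batches: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.lr_decay, self.lr_decay_steps,
               self.batch_size, self.max_epochs, self.patience) < 0:
            raise ValueError("training hyperparameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("early-stopping patience must be below max epochs")

    @classmethod
    def desk(cls, **kw) -> "TrainingConfig":
        """Short-schedule preset for CPU-scale experiments."""
        kw.setdefault("learning_rate", 1e-3)
        kw.setdefault("batch_size", 16)
        kw.setdefault("max_epochs", 20)
        kw.setdefault("patience", 19)
        return cls(**kw)


@dataclass
class DeepSurvivalResults:
    """Fitted network plus its training history and split bookkeeping."""

    network: SEResNet3D
    history: pd.DataFrame
    best_epoch: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    val_loss: float

    def predict_risk(self, blocks: np.ndarray) -> np.ndarray:
        scores, _ = self.network.forward(np.asarray(blocks), training=False)
        return scores

    def extract_gap_features(self, blocks: np.ndarray) -> np.ndarray:
        return self.network.extract_gap_features(np.asarray(blocks))

    def summary(self) -> str:
        lines = [
            "Deep survival network (3D-SE-ResNet)",
            f"  parameters:        {self.network.n_parameters:,}",
            f"  GAP feature width: {self.network.config.gap_width}",
            f"  SE enabled:        {self.network.config.se_enabled}",
            f"  epochs run:        {len(self.history)} (best: {self.best_epoch + 1})",
            f"  best val loss:     {self.val_loss:.4f}",
        ]
        return "\n".join(lines)


class DeepSurvivalModel:
    """Cox-loss training of the 3D-SE-ResNet on preprocessed input blocks.

    Statsmodels-style: construct with data and configuration, call
    :meth:`fit` for a :class:`DeepSurvivalResults`.
    """

    def __init__(self, blocks: np.ndarray, time, event,
                 arch: ArchitectureConfig | None = None,
                 training: TrainingConfig | None = None):
        self.blocks = np.asarray(blocks, dtype=np.float32)
        self.time = np.asarray(time, dtype=np.float64)
        self.event = np.asarray(event, dtype=int)
        if self.blocks.ndim != 4:
            raise ValueError("blocks must be (N, D, H, W)")
        if len(self.blocks) != len(self.time) or len(self.time) != len(self.event):
            raise ValueError("blocks and survival data must align")
        self.arch = arch or ArchitectureConfig()
        self.training = training or TrainingConfig()

    def _split(self, rng) -> tuple[np.ndarray, np.ndarray]:
        """Event-stratified train/validation split."""
        n = len(self.blocks)
        val_n = max(int(round(self.training.val_fraction * n)), 1)
        ev = np.flatnonzero(self.event == 1)
        ce = np.flatnonzero(self.event == 0)
        rng.shuffle(ev)
        rng.shuffle(ce)
        n_ev = min(max(int(round(val_n * len(ev) / n)), 1), max(len(ev) - 1, 0))
        val = np.concatenate([ev[:n_ev], ce[: val_n - n_ev]])
        train = np.setdiff1d(np.arange(n), val)
        return train, val

    def _batches(self, idx: np.ndarray, rng) -> list[np.ndarray]:
        idx = idx.copy()
        rng.shuffle(idx)
        bs = self.training.batch_size
        batches = [idx[i : i + bs] for i in range(0, len(idx), bs)]
        if self.training.event_stratified_batches and len(batches) > 1:
            # move an event into any event-free batch from the richest batch
            for b in batches:
                if self.event[b].sum() == 0:
                    donor = max(batches, key=lambda bb: self.event[bb].sum())
                    if self.event[donor].sum() >= 2:
                        di = next(i for i in range(len(donor)) if self.event[donor[i]] == 1)
                        bi = 0
                        b[bi], donor[di] = donor[di], b[bi]
        return batches

    def fit(self) -> DeepSurvivalResults:
        cfg = self.training
        if len(self.blocks) < 2 or self.event.sum() < 1:
            raise ValueError("training needs >= 2 subjects with >= 1 event")
        rng = np.random.default_rng(cfg.seed)
        train_idx, val_idx = self._split(rng)
        if self.event[train_idx].sum() == 0:
            raise ValueError("no events in the training split")

        net = SEResNet3D(replace(self.arch, seed=cfg.seed))
        net.seed_dropout(cfg.seed)
        opt = Adam(net.params(), lr=cfg.learning_rate, decay=cfg.lr_decay,
                   decay_steps=cfg.lr_decay_steps)

        best_val = np.inf
        best_state = net.state_dict()
        best_epoch = 0
        stale = 0
        rows = []
        for epoch in range(cfg.max_epochs):
            epoch_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, epoch]))
            train_loss, train_events = 0.0, 0
            for batch in self._batches(train_idx, epoch_rng):
                xb = self.blocks[batch]
                if cfg.augment:
                    xb = np.stack([
                        augment(x, cfg.augmentation, np.random.SeedSequence([cfg.seed, epoch, int(i)]))
                        for x, i in zip(xb, batch)
                    ])
                scores, _ = net.forward(xb, training=True)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    loss, grad = cox_ph_loss(scores, self.time[batch], self.event[batch],
                                             return_grad=True)
                net.zero_grad()
                net.backward(grad.astype(np.float32))
                net.add_l2_gradients()
                opt.step()
                d = int(self.event[batch].sum())
                train_loss += loss * max(d, 1)
                train_events += max(d, 1)

            val_scores, _ = net.forward(self.blocks[val_idx], training=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val_loss = cox_ph_loss(val_scores, self.time[val_idx], self.event[val_idx])
            rows.append({
                "epoch": epoch + 1,
                "train_loss": train_loss / max(train_events, 1),
                "val_loss": val_loss,
                "lr": opt.current_lr,
            })
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = net.state_dict()
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break

        net.load_state_dict(best_state)
        return DeepSurvivalResults(
            network=net,
            history=pd.DataFrame(rows),
            best_epoch=best_epoch,
            train_idx=train_idx,
            val_idx=val_idx,
            val_loss=float(best_val),
        )
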