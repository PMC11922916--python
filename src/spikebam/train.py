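"""Stage-1 optimization: encoder + LIF population + decoder with joint loss.

All subjects' training trials are pooled and shuffled into mini-batches
(this is the cross-subject sharing), and the network minimizes

    L = L_reg + lambda * L_cls

where ``L_reg`` is the mean-squared reconstruction error of the trial from
its own spike train, and ``L_cls`` the cross-entropy of a trainable
auxiliary linear classifier reading the flattened spike train.  The
classification term keeps the latent spike space class-identifiable; the
default mixing factor is lambda = 0.1.  Gradients cross the spike
non-linearity through the rectangular surrogate window only; every other
layer uses exact gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .codec import CodecSpec, SpikingAutoencoder
from .data import TrialSet
from .lif import LIFConfig
from .nn import Adam

logger = logging.getLogger(__name__)


@dataclass
class LossBreakdown:
    """The two Stage-1 loss terms and their mix."""

    l_reg: float
    l_cls: float
    lam: float
    total: float

    def __post_init__(self) -> None:
        if self.l_reg < 0 or self.l_cls < 0:
            raise ValueError("loss terms must be non-negative")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    lam: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.optimizer != "adam":
            raise ValueError("only 'adam' is implemented")


# ---------------------------------------------------------------------------
# Loss functions
# ---------------------------------------------------------------------------

def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared error over all elements."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean -log p(label) under the softmax of ``logits`` (batch, n_class)."""
    p = softmax(np.atleast_2d(logits))
    labels = np.atleast_1d(labels)
    return float(-np.mean(np.log(p[np.arange(len(labels)), labels] + 1e-300)))


def classification_loss(
    spikes: np.ndarray, label: int | np.ndarray, aux_w: np.ndarray, aux_b: np.ndarray
) -> float:
    """Cross-entropy of the auxiliary linear classifier on flattened spikes."""
    s = np.asarray(spikes, dtype=np.float64)
    if s.ndim == 2:
        s = s[None]
    flat = s.reshape(len(s), -1)
    logits = flat @ np.asarray(aux_w).T + np.asarray(aux_b)
    return cross_entropy(logits, np.atleast_1d(label))


def joint_loss(l_reg: float, l_cls: float, lam: float) -> LossBreakdown:
    """Combine the two terms: total = l_reg + lam * l_cls."""
    if l_reg < 0 or l_cls < 0:
        raise ValueError("loss terms must be non-negative")
    return LossBreakdown(l_reg=l_reg, l_cls=l_cls, lam=lam, total=l_reg + lam * l_cls)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _train_batch(
    model: SpikingAutoencoder, x: np.ndarray, labels: np.ndarray, lam: float, opt: Adam
) -> tuple[float, float]:
    """One forward/backward/update step; returns (l_reg, l_cls)."""
    batch = len(x)
    opt.zero_grad()
    h = model.encoder.forward(x)
    currents = model.fc_in.forward(h)
    spikes = model.lif.forward(currents)
    x_hat = model.decoder.forward(spikes)
    flat = spikes.reshape(batch, -1)
    logits = model.aux.forward(flat)

    l_reg = float(np.mean((x - x_hat) ** 2))
    l_cls = cross_entropy(logits, labels)

    # reconstruction path
    gx_hat = 2.0 * (x_hat - x) / x.size
    g_spikes = model.decoder.backward(gx_hat)

    # classification path (skipped entirely at lam = 0: aux stays untrained)
    if lam > 0:
        p = softmax(logits)
        p[np.arange(batch), labels] -= 1.0
        g_logits = lam * p / batch
        g_flat = model.aux.backward(g_logits)
        g_spikes = g_spikes + g_flat.reshape(spikes.shape)

    g_currents = model.lif.backward(g_spikes)
    gh = model.fc_in.backward(g_currents)
    model.encoder.backward(gh)
    opt.step()
    return l_reg, l_cls


def train_stage1(
    train: TrialSet,
    spec: CodecSpec,
    lif: LIFConfig | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[SpikingAutoencoder, list[LossBreakdown]]:
    """Fit the spiking autoencoder on all subjects' trials pooled.

    Returns the trained model and the per-epoch loss history (epoch means).
    Deterministic under ``cfg.seed``; aborts with a diagnostic if the loss
    diverges to a non-finite value.
    """
    cfg = cfg or TrainConfig()
    if train.n_samples != spec.T or train.n_channels != spec.C:
        raise ValueError(
            f"data (C={train.n_channels}, T={train.n_samples}) does not match "
            f"spec (C={spec.C}, T={spec.T})"
        )
    n_class = train.n_classes
    model = SpikingAutoencoder(spec, lif, n_class=n_class, seed=cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)

    history: list[LossBreakdown] = []
    n = train.n_trials
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        reg_sum = cls_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            l_reg, l_cls = _train_batch(
                model, train.data[idx], train.labels[idx], cfg.lam, opt
            )
            if not (np.isfinite(l_reg) and np.isfinite(l_cls)):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: l_reg={l_reg}, l_cls={l_cls}"
                )
            reg_sum += l_reg * len(idx)
            cls_sum += l_cls * len(idx)
        breakdown = joint_loss(reg_sum / n, cls_sum / n, cfg.lam)
        history.append(breakdown)
        logger.info(
            "epoch %d: l_reg=%.5f l_cls=%.5f total=%.5f",
            epoch, breakdown.l_reg, breakdown.l_cls, breakdown.total,
        )
    return model, history


def aux_accuracy(model: SpikingAutoencoder, ts: TrialSet, batch_size: int = 32) -> float:
    """Accuracy of the Stage-1 auxiliary classifier on a TrialSet."""
    correct = 0
    for start in range(0, ts.n_trials, batch_size):
        x = ts.data[start : start + batch_size]
        spikes = model.spike_encode(x)
        logits = model.aux.forward(spikes.reshape(len(x), -1))
        correct += int((logits.argmax(axis=1) == ts.labels[start : start + batch_size]).sum())
    return correct / ts.n_trials
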