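"""Per-subject Hebbian bidirectional associative memory (BAM) classifier.

Stage 2 of the pipeline.  For each subject, every training trial's spike
train is flattened to a bipolar vector ``x in {-1,+1}^n`` and paired with a
bipolar one-hot label ``y in {-1,+1}^m``; the memory is the Hebbian sum of
outer products

    W = sum_j  y_j x_j^T        (one pass, integer entries)

Retrieval alternates ``y <- sgn(W x)`` and ``x <- sgn(W^T y)`` with the
convention ``sgn(z) = -1 for z <= 0, +1 for z > 0``, which descends the
energy ``E = -y^T W x``.  With bipolar one-hot outputs the forward pass
settles in a single step, so classification is simply the argmax of the
scores ``W x`` (each score is, up to a constant shift, the summed
correlation of ``x`` with the stored patterns of that class).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codec import SpikingAutoencoder
from .data import TrialSet, encode_bipolar_onehot, savez_deterministic


@dataclass
class PatternPair:
    """A bipolar spike vector and its bipolar one-hot label."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        for name, v in (("x", self.x), ("y", self.y)):
            if not np.isin(v, (-1, 1)).all():
                raise ValueError(f"{name} entries must be in {{-1, +1}}")


@dataclass
class AssociativeMemory:
    """One subject's Hebbian matrix; entries are exact integer pair-sums."""

    W: np.ndarray
    subject_id: int = -1
    n_stored: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.int64)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (m x n)")

    @property
    def n_class(self) -> int:
        return self.W.shape[0]


def _sgn(z: np.ndarray) -> np.ndarray:
    """Printed sign convention: -1 for z <= 0, +1 for z > 0."""
    return np.where(np.asarray(z) > 0, 1, -1).astype(np.int64)


def spikes_to_bipolar(spikes: np.ndarray) -> np.ndarray:
    """Flatten a {0,1} spike train (neuron-major, then time) to {-1,+1}."""
    s = np.asarray(spikes)
    if not np.isin(s, (0, 1)).all():
        raise ValueError("spike train must be binary")
    return (2 * s.astype(np.int64) - 1).reshape(-1)


def hebbian_store(pairs: list[PatternPair], subject_id: int = -1) -> AssociativeMemory:
    """Single-pass Hebbian storage: W = sum_j y_j x_j^T.

    Linear in the number of pairs; the result is order-independent and
    storing a pair twice contributes twice.
    """
    if not pairs:
        raise ValueError("cannot store an empty pair list")
    n = pairs[0].x.size
    m = pairs[0].y.size
    for p in pairs:
        if p.x.size != n or p.y.size != m:
            raise ValueError("all pairs must share dimensions")
    X = np.stack([p.x for p in pairs])  # (K, n)
    Y = np.stack([p.y for p in pairs])  # (K, m)
    return AssociativeMemory(W=Y.T @ X, subject_id=subject_id, n_stored=len(pairs))


def recall_forward(mem: AssociativeMemory, x: np.ndarray) -> np.ndarray:
    """y = sgn(W x)."""
    x = np.asarray(x)
    if x.size != mem.W.shape[1]:
        raise ValueError(f"x has {x.size} entries, W expects {mem.W.shape[1]}")
    return _sgn(mem.W @ x)


def recall_backward(mem: AssociativeMemory, y: np.ndarray) -> np.ndarray:
    """x = sgn(W^T y) — also the inverse-recall path used for interpretability."""
    y = np.asarray(y)
    if y.size != mem.W.shape[0]:
        raise ValueError(f"y has {y.size} entries, W expects {mem.W.shape[0]}")
    return _sgn(mem.W.T @ y)


def bam_energy(mem: AssociativeMemory, x: np.ndarray, y: np.ndarray) -> float:
    """Kosko energy E = -y^T W x; non-increasing along retrieval updates."""
    return float(-(np.asarray(y) @ (mem.W @ np.asarray(x))))


def bam_iterate(
    mem: AssociativeMemory, x0: np.ndarray, max_iters: int = 50
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Alternate the two recalls from ``x0`` until a fixpoint.

    Returns ``(x*, y*, energy_trace, converged)``.  The energy trace is
    recorded after every half-update and is non-increasing because each
    half-step minimizes the energy given the other side.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    x = np.asarray(x0, dtype=np.int64)
    y = recall_forward(mem, x)
    trace = [bam_energy(mem, x, y)]
    converged = False
    for _ in range(max_iters):
        x_new = recall_backward(mem, y)
        trace.append(bam_energy(mem, x_new, y))
        y_new = recall_forward(mem, x_new)
        trace.append(bam_energy(mem, x_new, y_new))
        if np.array_equal(x_new, x) and np.array_equal(y_new, y):
            converged = True
            x, y = x_new, y_new
            break
        x, y = x_new, y_new
    return x, y, trace, converged


def classify(
    mem: AssociativeMemory, x: np.ndarray, mode: str = "argmax"
) -> tuple[int, np.ndarray]:
    """Classify a bipolar vector; returns (label, scores = W x).

    ``mode="argmax"`` (default) picks the class with the largest score —
    the similarity-weighted reading of the retrieval dynamics.  The
    ``"literal-argmin"`` switch picks the smallest score instead.  Ties
    break toward the lowest index.  Scores are scale-invariant in sign, so
    positive rescaling of ``x`` never changes the label.
    """
    scores = (mem.W @ np.asarray(x, dtype=np.float64)).astype(np.float64)
    if mode == "argmax":
        label = int(np.argmax(scores))
    elif mode == "literal-argmin":
        label = int(np.argmin(scores))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return label, scores


# ---------------------------------------------------------------------------
# Stage 2 over a TrialSet
# ---------------------------------------------------------------------------

def train_stage2(
    train: TrialSet, model: SpikingAutoencoder, batch_size: int = 32
) -> dict[int, AssociativeMemory]:
    """Build one associative memory per subject from frozen Stage-1 spikes.

    For each subject independently: encode trials with the (frozen)
    autoencoder, binarize to bipolar vectors, pair with bipolar one-hot
    labels and Hebbian-store.  Runtime is linear in the trial count.
    """
    n_class = model.n_class
    memories: dict[int, AssociativeMemory] = {}
    for s in train.subjects():
        idx = np.flatnonzero(train.subject_ids == s)
        pairs: list[PatternPair] = []
        for start in range(0, idx.size, batch_size):
            sel = idx[start : start + batch_size]
            spikes = model.spike_encode(train.data[sel])
            for i, trial_idx in enumerate(sel):
                pairs.append(
                    PatternPair(
                        x=spikes_to_bipolar(spikes[i]),
                        y=encode_bipolar_onehot(train.labels[trial_idx], n_class),
                    )
                )
        memories[int(s)] = hebbian_store(pairs, subject_id=int(s))
    return memories


def predict(
    ts: TrialSet,
    model: SpikingAutoencoder,
    memories: dict[int, AssociativeMemory],
    mode: str = "argmax",
    batch_size: int = 32,
) -> pd.DataFrame:
    """Classify every trial with its subject's memory.

    Returns a DataFrame with columns ``trial, subject_id, true_label,
    predicted_label, score_0..score_{m-1}``.

    Raises
    ------
    KeyError
        for a trial whose subject has no trained memory (message lists the
        known subjects).
    """
    known = sorted(memories)
    rows = []
    for start in range(0, ts.n_trials, batch_size):
        sel = np.arange(start, min(start + batch_size, ts.n_trials))
        spikes = model.spike_encode(ts.data[sel])
        for i, t in enumerate(sel):
            sid = int(ts.subject_ids[t])
            if sid not in memories:
                raise KeyError(f"no memory for subject {sid}; known subjects: {known}")
            label, scores = classify(memories[sid], spikes_to_bipolar(spikes[i]), mode=mode)
            rows.append(
                {"trial": int(t), "subject_id": sid, "true_label": int(ts.labels[t]),
                 "predicted_label": label,
                 **{f"score_{j}": float(v) for j, v in enumerate(scores)}}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_memories(memories: dict[int, AssociativeMemory], path: str | Path) -> None:
    arrays = {}
    for sid, mem in memories.items():
        arrays[f"W_{sid}"] = mem.W
        arrays[f"n_{sid}"] = np.int64(mem.n_stored)
    savez_deterministic(Path(path), **arrays)


def load_memories(path: str | Path) -> dict[int, AssociativeMemory]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"memories not found: {path}")
    memories: dict[int, AssociativeMemory] = {}
    with np.load(path) as f:
        for key in f.files:
            if key.startswith("W_"):
                sid = int(key[2:])
                memories[sid] = AssociativeMemory(
                    W=f[key], subject_id=sid, n_stored=int(f[f"n_{sid}"])
                )
    return memories
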