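"""Inverse recall, characteristic waveforms, ERPs, R² and raster export.

The associative memory is bidirectional, so feeding a class label backward
(``x = sgn(W^T y_label)``) yields the characteristic spike pattern of that
class; decoding it with the Stage-1 decoder produces a characteristic
EEG-like waveform.  Comparing these waveforms against the class ERPs
(trial averages) with the coefficient of determination R² quantifies how
faithfully the model's memory reflects the data — interpretability beyond
the classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bam import AssociativeMemory, recall_backward
from .codec import SpikingAutoencoder
from .data import TrialSet, encode_bipolar_onehot


@dataclass
class CharacteristicWaveform:
    """Decoder output for one class's characteristic spike pattern."""

    values: np.ndarray  # (C, T)
    class_label: int
    subject_id: int = -1


@dataclass
class ERP:
    """Event-related potential: the trial average of one class."""

    values: np.ndarray  # (C, T)
    class_label: int
    n_trials_averaged: int = 1

    def __post_init__(self) -> None:
        if self.n_trials_averaged < 1:
            raise ValueError("n_trials_averaged must be >= 1")


def characteristic_spikes(
    mem: AssociativeMemory, class_label: int, n_neurons: int, n_bins: int
) -> np.ndarray:
    """Inverse recall of a class label to its spike pattern.

    The bipolar one-hot label is pushed through ``sgn(W^T y)``, mapped back
    to {0, 1} and reshaped to ``(n_neurons, n_bins)``.
    """
    y = encode_bipolar_onehot(class_label, mem.n_class)
    x = recall_backward(mem, y)
    if x.size != n_neurons * n_bins:
        raise ValueError(
            f"memory dimension {x.size} != n_neurons*n_bins = {n_neurons * n_bins}"
        )
    return ((x + 1) // 2).astype(np.float64).reshape(n_neurons, n_bins)


def reconstruct_characteristic_waveform(
    mem: AssociativeMemory, class_label: int, model: SpikingAutoencoder
) -> CharacteristicWaveform:
    """Decode the characteristic spike pattern into channel space."""
    spikes = characteristic_spikes(
        mem, class_label, model.spec.n_neurons, model.spec.latent_len
    )
    return CharacteristicWaveform(
        values=model.decode(spikes), class_label=class_label, subject_id=mem.subject_id
    )


def compute_erp(ts: TrialSet, class_label: int, subject_id: int | None = None) -> ERP:
    """Pointwise mean over a class's trials (optionally one subject's)."""
    mask = ts.labels == class_label
    if subject_id is not None:
        mask &= ts.subject_ids == subject_id
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"no trials of class {class_label}"
                         + (f" for subject {subject_id}" if subject_id is not None else ""))
    return ERP(values=ts.data[idx].mean(axis=0), class_label=class_label,
               n_trials_averaged=int(idx.size))


def r_square(recon: CharacteristicWaveform | np.ndarray, erp: ERP | np.ndarray) -> float:
    """Coefficient of determination R² = 1 - SS_res / SS_tot.

    ``SS_tot`` uses the grand mean of the ERP over all (channel, time)
    points.  Returns 1 for a perfect reconstruction, 0 for reconstructing
    the mean, and NaN (the undefined flag) for a constant ERP.
    """
    yhat = recon.values if isinstance(recon, CharacteristicWaveform) else np.asarray(recon)
    y = erp.values if isinstance(erp, ERP) else np.asarray(erp)
    if yhat.shape != y.shape:
        raise ValueError(f"shape mismatch: {yhat.shape} vs {y.shape}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((yhat - y) ** 2))
    return 1.0 - ss_res / ss_tot


def pooled_r_square(
    recons: list[CharacteristicWaveform | np.ndarray], erps: list[ERP | np.ndarray]
) -> float:
    """R² over all classes' points pooled, with one grand ERP mean."""
    if len(recons) != len(erps) or not recons:
        raise ValueError("need matching, non-empty waveform/ERP lists")
    yhat = np.concatenate([
        (r.values if isinstance(r, CharacteristicWaveform) else np.asarray(r)).ravel()
        for r in recons
    ])
    y = np.concatenate([
        (e.values if isinstance(e, ERP) else np.asarray(e)).ravel() for e in erps
    ])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((yhat - y) ** 2)) / ss_tot


def accuracy_summary(predictions: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Per-subject accuracy plus the cross-subject mean and sample std.

    ``predictions`` needs columns ``subject_id, true_label,
    predicted_label``.  The std is the (n-1)-denominator sample standard
    deviation across subjects (0.0 for a single subject).
    """
    if len(predictions) == 0:
        raise ValueError("no predictions")
    per_subject = (
        predictions.assign(correct=predictions.true_label == predictions.predicted_label)
        .groupby("subject_id")["correct"].mean()
    )
    mean = float(per_subject.mean())
    std = float(per_subject.std(ddof=1)) if len(per_subject) > 1 else 0.0
    return per_subject, mean, std


def synchrony_index(spikes: np.ndarray) -> float:
    """Mean pairwise Pearson correlation of neuron spike vectors.

    Neurons with constant spike vectors carry no correlation and are
    excluded; if fewer than two variable neurons remain the index is 0.
    """
    s = np.asarray(spikes, dtype=np.float64)
    var = s.var(axis=1)
    active = s[var > 0]
    if active.shape[0] < 2:
        return 0.0
    corr = np.corrcoef(active)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    return float(off.mean())


def export_raster(spikes: np.ndarray, path: str | Path, class_label: int | None = None) -> float:
    """Write a (neuron, time_bin) event list as TSV; returns the synchrony index.

    One row per emitted spike; an optional class tag column supports
    per-class coloring in downstream plots.
    """
    s = np.asarray(spikes)
    neurons, bins = np.nonzero(s)
    df = pd.DataFrame({"neuron": neurons, "time_bin": bins})
    if class_label is not None:
        df["class"] = class_label
    df.to_csv(Path(path), sep="\t", index=False)
    return synchrony_index(s)
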