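"""Synthetic multi-subject EEG generator with known ground truth.

Emulates the structure of motor-imagery BCI data at desk scale: each class
has a distinct ERP-like template waveform (a damped sinusoid with a
class-specific frequency and latency), each subject mixes every template
into the channels through a fixed random spatial pattern (this is the
cross-subject variability), and trials are the mixed template plus white
Gaussian noise at a controlled linear SNR.

Because the templates and mixings are known, end-to-end tests can check
that the pipeline recovers labels and class-average waveforms it provably
could recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TrialSet


@dataclass
class SynthConfig:
    """Generator settings.

    Defaults produce the standard study fixture: 3 subjects x 4 classes x
    20 trials per class, 8 channels, 256 samples at 128 Hz, linear SNR 10.
    Template frequencies/latencies default to one distinct (freq, latency)
    pair per class (4 + 3c Hz, latency 16(c+1) samples).
    """

    n_subjects: int = 3
    n_classes: int = 4
    C: int = 8
    T: int = 256
    fs: float = 128.0
    n_trials_per_class: int = 20
    snr: float = 10.0
    template_freqs: list[float] | None = field(default=None)
    template_latencies: list[int] | None = field(default=None)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template_freqs is None:
            self.template_freqs = [4.0 + 3.0 * c for c in range(self.n_classes)]
        if self.template_latencies is None:
            self.template_latencies = [16 * (c + 1) for c in range(self.n_classes)]
        if self.n_classes != len(self.template_freqs) or self.n_classes != len(
            self.template_latencies
        ):
            raise ValueError("need one (freq, latency) pair per class")
        if self.snr <= 0:
            raise ValueError("snr must be > 0 (linear power ratio)")
        if self.T % 4 != 0:
            raise ValueError("T must be divisible by 4")


def make_class_templates(cfg: SynthConfig) -> np.ndarray:
    """Damped-sinusoid ERP templates, one per class; shape (n_classes, T).

    Template c is ``exp(-3 (t - lat_c)/T) * sin(2 pi f_c (t - lat_c)/fs)``
    for ``t >= lat_c`` and zero before the latency.  Classes must be
    distinguishable: duplicate (frequency, latency) pairs are rejected and
    pairwise cosine similarity between distinct templates must stay < 0.8.
    """
    pairs = list(zip(cfg.template_freqs, cfg.template_latencies))
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (freq, latency) pairs: classes would be indistinguishable")
    t = np.arange(cfg.T, dtype=np.float64)
    out = np.zeros((cfg.n_classes, cfg.T))
    for c, (f, lat) in enumerate(pairs):
        dt = t - lat
        active = dt >= 0
        out[c, active] = np.exp(-3.0 * dt[active] / cfg.T) * np.sin(
            2.0 * np.pi * f * dt[active] / cfg.fs
        )
    norms = np.linalg.norm(out, axis=1)
    sims = (out @ out.T) / np.outer(norms, norms)
    off = sims[~np.eye(cfg.n_classes, dtype=bool)]
    if off.size and np.abs(off).max() >= 0.8:
        raise ValueError(
            "class templates too similar (|cosine| >= 0.8); pick more distinct freqs/latencies"
        )
    return out


def make_subject_mixing(cfg: SynthConfig, subject: int) -> np.ndarray:
    """Per-class spatial mixing vectors for one subject; shape (n_classes, C).

    Each (subject, class) gets a fixed C-vector of channel weights, drawn
    once from a seeded standard normal and L2-normalized.  All trials of
    that subject and class share the vector; different subjects get
    different draws, which is the model of cross-subject variability.
    """
    if not 0 <= subject < cfg.n_subjects:
        raise ValueError(f"subject {subject} out of range")
    mix = np.empty((cfg.n_classes, cfg.C))
    for c in range(cfg.n_classes):
        rng = np.random.default_rng([cfg.seed, 1, subject, c])
        v = rng.standard_normal(cfg.C)
        mix[c] = v / np.linalg.norm(v)
    return mix


def generate_dataset(cfg: SynthConfig) -> TrialSet:
    """Generate the full multi-subject TrialSet.

    Trial for (subject s, class c) is ``a * mixing_{s,c} (x) template_c +
    noise`` with iid unit-variance Gaussian noise and the signal gain ``a``
    chosen so the per-trial signal-power / noise-power ratio equals
    ``cfg.snr``.  Bit-identical under a fixed config (single master seed;
    all sub-draws derive from it by fixed offsets).
    """
    templates = make_class_templates(cfg)
    n = cfg.n_subjects * cfg.n_classes * cfg.n_trials_per_class
    data = np.empty((n, cfg.C, cfg.T))
    labels = np.empty(n, dtype=np.int64)
    subject_ids = np.empty(n, dtype=np.int64)
    i = 0
    for s in range(cfg.n_subjects):
        mix = make_subject_mixing(cfg, s)
        for c in range(cfg.n_classes):
            signal = np.outer(mix[c], templates[c])  # (C, T), rank 1
            p_sig = float(np.mean(signal**2))
            gain = np.sqrt(cfg.snr / p_sig)  # noise power is 1
            rng = np.random.default_rng([cfg.seed, 2, s, c])
            noise = rng.standard_normal((cfg.n_trials_per_class, cfg.C, cfg.T))
            data[i : i + cfg.n_trials_per_class] = gain * signal + noise
            labels[i : i + cfg.n_trials_per_class] = c
            subject_ids[i : i + cfg.n_trials_per_class] = s
            i += cfg.n_trials_per_class
    return TrialSet(
        data=data,
        labels=labels,
        subject_ids=subject_ids,
        fs=cfg.fs,
        channel_names=[f"ch{i:02d}" for i in range(cfg.C)],
        meta={"generator": "spikebam.synth", "snr": cfg.snr, "seed": cfg.seed},
    )
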