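"""Shared fixtures: small synthetic fixtures and the full end-to-end run.

The expensive two-stage pipeline (the study-scale synthetic fixture: 3
subjects, 4 classes, 8 channels, 256 samples, 20 trials/class/subject at
SNR 10) is run once per session and shared by the end-to-end tests; a
second identical run backs the determinism check.
"""

from __future__ import annotations

import numpy as np
import pytest

from spikebam import CodecSpec, SynthConfig, generate_dataset, preprocess
from spikebam.pipeline import run_synthetic_pipeline

PIPELINE_SEED = 7


@pytest.fixture
def small_synth_cfg() -> SynthConfig:
    """2 subjects x 2 classes x 6 trials, 4 channels, 64 samples."""
    return SynthConfig(
        n_subjects=2,
        n_classes=2,
        C=4,
        T=64,
        fs=64.0,
        n_trials_per_class=6,
        snr=10.0,
        template_freqs=[4.0, 9.0],
        template_latencies=[4, 16],
        seed=11,
    )


@pytest.fixture
def small_trialset(small_synth_cfg):
    return preprocess(generate_dataset(small_synth_cfg))


@pytest.fixture
def tiny_spec() -> CodecSpec:
    """A very small codec for unit tests that need a real network."""
    return CodecSpec(
        C=4,
        T=64,
        enc_block_widths=(6, 8, 8),
        dec_block_widths=(6, 6),
        n_conv_enc=(2, 2, 1),
        n_conv_dec=(2, 2, 2),
        n_neurons=10,
    )


@pytest.fixture(scope="session")
def pipeline_run():
    """Full two-stage run on the study-scale synthetic fixture."""
    return run_synthetic_pipeline(seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def pipeline_run_repeat():
    """Second, independent run with the identical master seed."""
    return run_synthetic_pipeline(seed=PIPELINE_SEED)


def lif_scalar_oracle(currents: np.ndarray, tau: float, u_th: float) -> np.ndarray:
    """Brute-force per-neuron scalar-loop LIF recurrence (independent oracle).

    Iterates u <- (1-tau)u - s*u_th + I, s <- 1[u >= u_th] one neuron and
    one step at a time with plain Python floats.
    """
    n, steps = currents.shape
    spikes = np.zeros((n, steps))
    for i in range(n):
        u, s = 0.0, 0.0
        for t in range(steps):
            u = (1.0 - tau) * u - s * u_th + float(currents[i, t])
            s = 1.0 if u - u_th >= 0 else 0.0
            spikes[i, t] = s
    return spikes


def hebbian_double_loop_oracle(xs: list, ys: list) -> np.ndarray:
    """Naive O(K m n) double-loop outer-product sum (independent oracle)."""
    m, n = len(ys[0]), len(xs[0])
    w = np.zeros((m, n), dtype=np.int64)
    for x, y in zip(xs, ys):
        for i in range(m):
            for j in range(n):
                w[i, j] += y[i] * x[j]
    return w
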