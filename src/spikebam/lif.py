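"""Leaky integrate-and-fire population and its surrogate-gradient backward pass.

The population converts the encoder's real-valued feature map into a binary
spike train.  Membrane dynamics follow the discrete recurrence

    u_t = (1 - tau) * u_{t-1} - s_{t-1} * u_th + I_{t-1}
    s_t = step(u_t - u_th),          step(x) = 1 for x >= 0 else 0

where ``tau`` is the leak, ``u_th`` the firing threshold, and ``I`` the
per-neuron input current (the fully connected projection of the encoder
features).  The spike subtracts the threshold from the membrane ("soft"
reset); a "hard" reset-to-zero variant is available since both readings of
the reset are defensible.

Backpropagation through the non-differentiable spike uses a rectangular
surrogate window: the spike derivative is taken as
``u_th * rect(u - u_th)`` with ``rect(x) = 1 for |x| <= 0.5 else 0``, and the
membrane-potential gradient recursion is

    grad_u_{t-1} = (1 - tau) * grad_u_t + u_th * rect(u_{t-1} - u_th) * grad_s_{t-1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LIFConfig:
    """Population parameters.

    ``tau`` is the per-step leak fraction in (0, 1]; ``u_th`` the threshold
    in membrane-potential units.  The input resistance is absorbed into the
    trainable fully connected weights upstream, so currents arrive already
    summed per neuron.
    """

    n_neurons: int = 200
    tau: float = 0.5
    u_th: float = 1.0
    n_in: int = 256
    reset: str = "soft"  # "soft": u -= u_th on spike; "hard": u set to 0

    def __post_init__(self) -> None:
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")
        if self.u_th <= 0:
            raise ValueError("u_th must be positive")
        if self.reset not in ("soft", "hard"):
            raise ValueError("reset must be 'soft' or 'hard'")


@dataclass
class LIFState:
    """Membrane potentials and the previous step's spikes."""

    u: np.ndarray
    s_prev: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.s_prev is None:
            self.s_prev = np.zeros_like(self.u)
        else:
            self.s_prev = np.asarray(self.s_prev, dtype=np.float64)


def lif_step(
    state: LIFState, input_current: np.ndarray, cfg: LIFConfig
) -> tuple[LIFState, np.ndarray]:
    """One step of the membrane recurrence; returns (new state, spikes)."""
    current = np.asarray(input_current, dtype=np.float64)
    if not np.all(np.isfinite(current)):
        raise ValueError("non-finite input current")
    if current.shape != state.u.shape:
        raise ValueError(f"current shape {current.shape} != state shape {state.u.shape}")
    if cfg.reset == "soft":
        u = (1.0 - cfg.tau) * state.u - state.s_prev * cfg.u_th + current
    else:  # hard: a spike zeroes the carried-over membrane potential
        u = (1.0 - cfg.tau) * state.u * (1.0 - state.s_prev) + current
    s = (u - cfg.u_th >= 0).astype(np.float64)
    return LIFState(u=u, s_prev=s), s


def rect_window(x):
    """Rectangular surrogate for the spike derivative: 1 where |x| <= 0.5."""
    x = np.asarray(x, dtype=np.float64)
    out = (np.abs(x) <= 0.5).astype(np.float64)
    return out if out.ndim else float(out)


def surrogate_backward(
    grad_u_next: np.ndarray, grad_s: np.ndarray, state: LIFState, cfg: LIFConfig
) -> np.ndarray:
    """One step of the surrogate-gradient recursion.

    Given the gradient flowing into the next membrane potential and the
    direct gradient on this step's spikes, returns the gradient on this
    step's membrane potential:
    ``(1 - tau) * grad_u_next + u_th * rect(u - u_th) * grad_s``.
    """
    if state is None or state.u is None:
        raise ValueError("missing stored membrane state for backward pass")
    window = rect_window(state.u - cfg.u_th)
    return (1.0 - cfg.tau) * np.asarray(grad_u_next) + cfg.u_th * window * np.asarray(grad_s)


def run_population(
    h: np.ndarray, fc_w: np.ndarray, cfg: LIFConfig, fc_b: np.ndarray | None = None
) -> np.ndarray:
    """Drive the population with a feature map; return the binary spike train.

    ``h`` has shape (n_in, n_bins); ``fc_w`` (n_neurons, n_in) projects the
    features to per-neuron currents.  Membrane potentials start at 0.
    Output shape is (n_neurons, n_bins), entries in {0, 1}.
    """
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] != fc_w.shape[1]:
        raise ValueError(f"feature map shape {h.shape} incompatible with fc {fc_w.shape}")
    currents = fc_w @ h
    if fc_b is not None:
        currents = currents + np.asarray(fc_b)[:, None]
    n_bins = currents.shape[1]
    state = LIFState(u=np.zeros(fc_w.shape[0]))
    spikes = np.zeros((fc_w.shape[0], n_bins))
    for t in range(n_bins):
        state, spikes[:, t] = lif_step(state, currents[:, t], cfg)
    return spikes


class LIFLayer:
    """Batched LIF population with BPTT, for use inside the Stage-1 model.

    Forward maps currents ``(B, N, n_bins)`` to spikes of the same shape,
    bit-identical to iterating :func:`lif_step`.  Backward implements the
    surrogate recursion of :func:`surrogate_backward` across time and
    returns the gradient on the input currents.
    """

    def __init__(self, cfg: LIFConfig):
        self.cfg = cfg

    def params(self) -> list:
        return []

    def forward(self, currents: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        batch, n, n_bins = currents.shape
        u = np.zeros((batch, n))
        s = np.zeros((batch, n))
        us = np.empty((n_bins, batch, n))
        spikes = np.empty((batch, n, n_bins))
        for t in range(n_bins):
            if cfg.reset == "soft":
                u = (1.0 - cfg.tau) * u - s * cfg.u_th + currents[:, :, t]
            else:
                u = (1.0 - cfg.tau) * u * (1.0 - s) + currents[:, :, t]
            s = (u - cfg.u_th >= 0).astype(np.float64)
            us[t] = u
            spikes[:, :, t] = s
        self._us = us
        return spikes

    def backward(self, grad_spikes: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        us = self._us
        n_bins = us.shape[0]
        grad_currents = np.empty_like(grad_spikes)
        gu_next = np.zeros_like(us[0])  # gradient on u_{t+1}
        for t in range(n_bins - 1, -1, -1):
            window = (np.abs(us[t] - cfg.u_th) <= 0.5).astype(np.float64)
            gu = (1.0 - cfg.tau) * gu_next + cfg.u_th * window * grad_spikes[:, :, t]
            grad_currents[:, :, t] = gu
            gu_next = gu
        return grad_currents
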