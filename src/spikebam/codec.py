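"""The 1-D convolutional encoder/decoder pair around the spiking population.

Architecture (default widths):

* encoder — three conv blocks (widths 128, 256, 256; 5, 5, 3 stacked
  kernel-5 ReLU convolutions per block) with a stride-2 pooling after the
  first two blocks, so the time axis shrinks to T/4;
* population — a pointwise FC (256 -> n_neurons) feeding the LIF neurons,
  and a pointwise FC (n_neurons -> 256) mapping spikes back to features;
* decoder — conv blocks of widths 128, 128 interleaved with two transposed
  convolutions (kernel 8, stride 2, padding 3: exact 2x upsampling) and a
  final conv stack ending in C output channels.  The very last conv carries
  no ReLU so reconstructions can be signed.

All convolutions are length-preserving (kernel 5, padding 2).  Widths and
block depths are configurable; the defaults are what the shape plan below
documents.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data import savez_deterministic
from .lif import LIFConfig, LIFLayer


def _enc_widths() -> tuple[int, ...]:
    return (128, 256, 256)


def _dec_widths() -> tuple[int, ...]:
    return (128, 128)


def _enc_depths() -> tuple[int, ...]:
    return (5, 5, 3)


def _dec_depths() -> tuple[int, ...]:
    return (5, 5, 3)


@dataclass
class CodecSpec:
    """Static architecture description.

    ``dec_block_widths`` lists the hidden widths of the first two decoder
    blocks; the third decoder block ends in ``C`` channels.  ``n_neurons``
    is the LIF population size and also the channel count of the spike
    train entering the decoder.
    """

    C: int = 22
    T: int = 1000
    enc_block_widths: tuple[int, ...] = field(default_factory=_enc_widths)
    dec_block_widths: tuple[int, ...] = field(default_factory=_dec_widths)
    n_conv_enc: tuple[int, ...] = field(default_factory=_enc_depths)
    n_conv_dec: tuple[int, ...] = field(default_factory=_dec_depths)
    kernel_size: int = 5
    pool_size: int = 2
    pool_stride: int = 2
    upsample_kernel: int = 8
    upsample_stride: int = 2
    n_neurons: int = 200
    pool: str = "avg"  # "avg" or "max"

    def __post_init__(self) -> None:
        self.enc_block_widths = tuple(self.enc_block_widths)
        self.dec_block_widths = tuple(self.dec_block_widths)
        self.n_conv_enc = tuple(self.n_conv_enc)
        self.n_conv_dec = tuple(self.n_conv_dec)
        if self.T % 4 != 0:
            raise ValueError("T must be divisible by 4 (two stride-2 poolings)")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if min(self.enc_block_widths + self.dec_block_widths) < 1 or self.C < 1:
            raise ValueError("all widths must be >= 1")
        if len(self.enc_block_widths) != 3 or len(self.n_conv_enc) != 3:
            raise ValueError("encoder has three blocks")
        if len(self.dec_block_widths) != 2 or len(self.n_conv_dec) != 3:
            raise ValueError("decoder has two hidden blocks plus the output block")
        if self.pool not in ("avg", "max"):
            raise ValueError("pool must be 'avg' or 'max'")

    @property
    def latent_channels(self) -> int:
        return self.enc_block_widths[-1]

    @property
    def latent_len(self) -> int:
        return self.T // 4

    @property
    def flat_spike_dim(self) -> int:
        return self.n_neurons * self.latent_len


def shape_plan(spec: CodecSpec, n_class: int | None = None) -> list[tuple[str, tuple]]:
    """Per-layer output shapes, symbolic in (C, T).

    Matches the actual forward pass for any valid spec (property-tested).
    If ``n_class`` is given, the per-subject associative-memory row is
    appended with its ``(n_neurons * T/4, n_class)`` weight shape.
    """
    c, t = spec.C, spec.T
    w1, w2, w3 = spec.enc_block_widths
    d1, d2 = spec.dec_block_widths
    pool_name = "AvgPool1D" if spec.pool == "avg" else "MaxPool1D"
    plan = [
        ("Input", (c, t)),
        ("Conv1D block", (w1, t)),
        (pool_name, (w1, t // 2)),
        ("Conv1D block", (w2, t // 2)),
        (pool_name, (w2, t // 4)),
        ("Conv1D block", (w3, t // 4)),
        ("FC", (spec.n_neurons, t // 4)),
        ("LIF neurons", (spec.n_neurons, t // 4)),
        ("FC", (w3, t // 4)),
        ("Conv1D block", (d1, t // 4)),
        ("ConvTranspose1D", (d1, t // 2)),
        ("Conv1D block", (d2, t // 2)),
        ("ConvTranspose1D", (d2, t)),
        ("Conv1D block", (c, t)),
    ]
    if n_class is not None:
        plan.append(("AMM", (spec.n_neurons * t // 4, n_class)))
    return plan


def _conv_block(
    c_in: int, width: int, depth: int, kernel: int, rng: np.random.Generator,
    final_relu: bool = True, c_out: int | None = None,
) -> list[nn.Layer]:
    """``depth`` stacked kernel-``kernel`` convolutions with ReLU activations.

    If ``c_out`` is given the last conv maps to ``c_out`` channels;
    ``final_relu=False`` leaves the last conv linear (used for the signed
    reconstruction output).
    """
    layers: list[nn.Layer] = []
    chans = [c_in] + [width] * (depth - 1) + [c_out if c_out is not None else width]
    for i in range(depth):
        layers.append(nn.Conv1dSame(chans[i], chans[i + 1], kernel, rng))
        if i < depth - 1 or final_relu:
            layers.append(nn.ReLU())
    return layers


class Encoder(nn.Sequential):
    def __init__(self, spec: CodecSpec, rng: np.random.Generator):
        w1, w2, w3 = spec.enc_block_widths
        n1, n2, n3 = spec.n_conv_enc
        pool = nn.AvgPool1d if spec.pool == "avg" else nn.MaxPool1d
        layers = (
            _conv_block(spec.C, w1, n1, spec.kernel_size, rng)
            + [pool(spec.pool_size, spec.pool_stride)]
            + _conv_block(w1, w2, n2, spec.kernel_size, rng)
            + [pool(spec.pool_size, spec.pool_stride)]
            + _conv_block(w2, w3, n3, spec.kernel_size, rng)
        )
        super().__init__(layers)


class Decoder(nn.Sequential):
    """FC from spikes plus the transposed-conv upsampling stack."""

    def __init__(self, spec: CodecSpec, rng: np.random.Generator):
        d1, d2 = spec.dec_block_widths
        m1, m2, m3 = spec.n_conv_dec
        pad = (spec.upsample_kernel - spec.upsample_stride) // 2
        layers = (
            [nn.PointwiseLinear(spec.n_neurons, spec.latent_channels, rng)]
            + _conv_block(spec.latent_channels, d1, m1, spec.kernel_size, rng)
            + [nn.ConvTranspose1d(d1, d1, spec.upsample_kernel, spec.upsample_stride, pad, rng)]
            + _conv_block(d1, d2, m2, spec.kernel_size, rng)
            + [nn.ConvTranspose1d(d2, d2, spec.upsample_kernel, spec.upsample_stride, pad, rng)]
            + _conv_block(d2, d2, m3, spec.kernel_size, rng, final_relu=False, c_out=spec.C)
        )
        super().__init__(layers)


class SpikingAutoencoder:
    """Encoder + FC + LIF population + decoder, plus the auxiliary classifier.

    This is the Stage-1 network.  ``encode`` stops at the latent feature
    map, ``spike_encode`` at the binary spike train (the representation the
    associative memories consume), ``decode`` maps spike trains back to
    channel space, and ``forward`` runs the whole autoencoding path.
    """

    def __init__(
        self,
        spec: CodecSpec,
        lif_cfg: LIFConfig | None = None,
        n_class: int = 4,
        seed: int = 0,
    ):
        self.spec = spec
        self.lif_cfg = lif_cfg or LIFConfig(
            n_in=spec.latent_channels, n_neurons=spec.n_neurons
        )
        if self.lif_cfg.n_in != spec.latent_channels:
            raise ValueError(
                f"LIF fan-in {self.lif_cfg.n_in} != encoder output width {spec.latent_channels}"
            )
        if self.lif_cfg.n_neurons != spec.n_neurons:
            raise ValueError("LIFConfig.n_neurons must match CodecSpec.n_neurons")
        self.n_class = n_class
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(spec, rng)
        self.fc_in = nn.PointwiseLinear(spec.latent_channels, spec.n_neurons, rng)
        self.lif = LIFLayer(self.lif_cfg)
        self.decoder = Decoder(spec, rng)
        self.aux = nn.Dense(spec.flat_spike_dim, n_class, rng)

    # -- parameter plumbing ----------------------------------------------
    def params(self) -> list[nn.Param]:
        return (
            self.encoder.params() + self.fc_in.params() + self.decoder.params()
            + self.aux.params()
        )

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != (self.spec.C, self.spec.T):
            raise ValueError(
                f"trial shape {x.shape[1:]} does not match spec (C={self.spec.C}, T={self.spec.T})"
            )
        return x, single

    # -- inference paths --------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        """Latent feature map(s), shape (latent_channels, T/4) per trial."""
        xb, single = self._check_input(x)
        h = self.encoder.forward(xb)
        return h[0] if single else h

    def spike_encode(self, x: np.ndarray) -> np.ndarray:
        """Binary spike train(s), shape (n_neurons, T/4) per trial."""
        xb, single = self._check_input(x)
        h = self.encoder.forward(xb)
        s = self.lif.forward(self.fc_in.forward(h))
        return s[0] if single else s

    def decode(self, spikes: np.ndarray) -> np.ndarray:
        """Reconstruct channel-space epochs from spike trains."""
        s = np.asarray(spikes, dtype=np.float64)
        single = s.ndim == 2
        if single:
            s = s[None]
        expect = (self.spec.n_neurons, self.spec.latent_len)
        if s.shape[1:] != expect:
            raise ValueError(f"spike train shape {s.shape[1:]} != expected {expect}")
        x_hat = self.decoder.forward(s)
        return x_hat[0] if single else x_hat

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Full pass: returns (reconstruction, spikes, aux logits) for a batch."""
        xb, _ = self._check_input(x)
        h = self.encoder.forward(xb)
        spikes = self.lif.forward(self.fc_in.forward(h))
        x_hat = self.decoder.forward(spikes)
        logits = self.aux.forward(spikes.reshape(len(xb), -1))
        return x_hat, spikes, logits


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: SpikingAutoencoder, path: str | Path) -> None:
    """Serialize all weights with the CodecSpec/LIFConfig embedded."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    meta = {
        "spec": asdict(model.spec),
        "lif": asdict(model.lif_cfg),
        "n_class": model.n_class,
    }
    savez_deterministic(Path(path), __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path) -> SpikingAutoencoder:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path, allow_pickle=True) as f:
        meta = json.loads(str(f["__meta__"]))
        spec = CodecSpec(**meta["spec"])
        lif_cfg = LIFConfig(**meta["lif"])
        model = SpikingAutoencoder(spec, lif_cfg, n_class=meta["n_class"])
        params = model.params()
        for i, p in enumerate(params):
            stored = f[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint param {i} shape {stored.shape} != model {p.value.shape}"
                )
            p.value[...] = stored
    return model
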