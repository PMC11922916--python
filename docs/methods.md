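# Methods

## Model

`spikebam` implements a two-stage multi-task classifier for epoched
multi-channel EEG.

**Stage 1** trains a spiking autoencoder on all subjects' trials pooled.
The encoder is three blocks of length-preserving 1-D convolutions
(kernel 5, ReLU) with a stride-2 pooling after the first two blocks, so a
`(C, T)` epoch becomes a `(256, T/4)` feature map at full width. A
pointwise fully connected layer converts features into per-neuron input
currents for 200 leaky integrate-and-fire neurons:

    u_t = (1 − τ) u_{t−1} − s_{t−1} u_th + I_{t−1},   s_t = 1[u_t ≥ u_th].

The binary spike train is the latent representation. The decoder maps
spikes through a pointwise FC back to 256 channels and upsamples twice
with transposed convolutions (kernel 8, stride 2, padding 3 — exact 2×
length doubling) interleaved with conv blocks, ending in `C` channels.
The loss is `L = L_reg + λ·L_cls` with `L_reg` the reconstruction MSE and
`L_cls` the cross-entropy of an auxiliary linear classifier reading the
flattened spikes; `λ = 0.1` by default. The auxiliary term exists to make
the spike code class-identifiable; it is discarded after Stage 1.

**Stage 2** freezes the autoencoder and builds one bidirectional
associative memory per subject: `W = Σ_j y_j x_jᵀ` over that subject's
training trials, with `x_j` the flattened spike train mapped
`{0,1} → {−1,+1}` and `y_j` the bipolar one-hot label (+1 at the class,
−1 elsewhere). Prediction is `argmax(W x)`. Since the stored outputs are
bipolar one-hot, the score vector is (up to a class-independent shift) the
summed correlation between `x` and each class's stored patterns, so the
retrieval dynamics settle immediately and no iteration is needed at
predict time. The retrieval iteration `y ← sgn(Wx)`, `x ← sgn(Wᵀy)`
(with `sgn(0) = −1`) is nevertheless implemented in full, with the energy
`E = −yᵀWx` tracked; each half-update minimizes `E` given the other side,
so traces are non-increasing.

**Interpretability.** The memory is invertible: `x_label = sgn(Wᵀ
y_label)` is the characteristic spike pattern of a class, and decoding it
gives a characteristic waveform, compared against the class ERP (trial
average) by `R² = 1 − SS_res/SS_tot`, where `SS_tot` uses the grand mean
of the ERP over all (channel, time) points. Per-class values are
reported alongside a pooled value computed over all (subject, class)
waveforms concatenated.

## Gradient treatment of the spike nonlinearity

The spike step function has no useful derivative, so the backward pass
uses a rectangular surrogate window: the spike derivative is taken as
`u_th · rect(u − u_th)` with `rect(x) = 1 for |x| ≤ 0.5`, and the
membrane gradient recursion is

    ∇u_{t−1} = (1 − τ) ∇u_t + u_th · rect(u_{t−1} − u_th) · ∇s_{t−1}.

Only the leak path carries gradient between time steps; the contribution
of the reset term to `∂u_t/∂u_{t−1}` is deliberately dropped (treating
the reset as a detached constant), which is the standard
surrogate-gradient simplification and keeps the recursion stable. All
other layers use exact gradients; correctness of every hand-written
backward pass is enforced by central-finite-difference tests.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| τ (leak) | 0.5 | per-step decay fraction; mid-range value giving a 2-step effective memory. Exposed in `LIFConfig`. |
| u_th | 1.0 | firing threshold in membrane units, matching the unit-variance z-scored inputs. |
| reset | soft | a spike subtracts `u_th`; `reset="hard"` zeroes the carried membrane instead. The soft form follows the update equation exactly; the hard form matches the verbal "reset to 0" description. |
| n_neurons | 200 | LIF population size; also the channel count of the latent spike train. |
| λ | 0.1 | loss mixing factor. |
| optimizer | Adam, lr 1e-3, batch 32, 100 epochs | ordinary choices for a small conv net; all exposed in `TrainConfig`. |
| pooling | average | the architecture table form; `pool="max"` available. |
| conv padding | 2 | length-preserving for kernel 5. |
| init | He/Kaiming fan-in uniform | variance-preserving through stacked ReLU convs. With a smaller init the membrane potentials never reach the surrogate window `|u − u_th| ≤ 0.5` and the population is silent with zero gradient, so this choice is load-bearing. |
| sgn(0), step(0) | −1, 1 | the printed piecewise conventions, applied literally. |
| classification | argmax of `W x` | the similarity reading of the retrieval dynamics; a `literal-argmin` switch exists for comparison. |

Design choices worth flagging:

* **Final decoder conv is linear.** The hidden convolutions of the last
  decoder block keep ReLU, but the output layer has no activation:
  z-scored EEG is signed and a ReLU output could never reproduce negative
  deflections.
* **Per-trial per-channel z-scoring** is the only normalization, with an
  sd floor of 1e-8 (constant channels become zeros and log a warning).
* **T divisible by 4** is enforced at preprocessing (default zero-pad,
  `crop` available) because of the two stride-2 poolings; e.g. a 3 s ×
  250 Hz epoch (750 samples) becomes 752 (pad) or 748 (crop).
* **Integer memory matrices.** `W` is stored as int64 — exact sums of ±1
  outer products; after storing K pairs every entry lies in [−K, K] with
  parity K mod 2.
* **Auxiliary classifier input** is the flattened spike train
  (`n_neurons · T/4`), the same dimensionality the associative memory
  consumes.

## Synthetic data generator

The generator emulates the structure that makes multi-subject
motor-imagery data hard and the pipeline's claims testable:

* each class `c` has an ERP-like template — a damped sinusoid
  `exp(−3(t−lat_c)/T)·sin(2πf_c(t−lat_c)/fs)`, zero before its latency —
  with per-class frequency/latency defaults `4+3c` Hz and `16(c+1)`
  samples; templates must stay below 0.8 pairwise cosine similarity;
* each (subject, class) has a fixed rank-1 spatial mixing vector (seeded
  standard normal, L2-normalized) — the model of cross-subject
  variability;
* trials are `gain · mixing ⊗ template + N(0,1)` noise with the gain set
  so the per-trial signal/noise power ratio equals the configured linear
  SNR (default 10).

Default study fixture: 3 subjects × 4 classes × 20 trials/class, 8
channels, 256 samples at 128 Hz. A single master seed drives every
sub-draw by fixed offsets, so regeneration is bit-identical.

What the generator does **not** model: 1/f spectra, volume conduction,
artifacts, non-stationarity, trial-to-trial latency jitter. Passing
end-to-end tests therefore demonstrates that the pipeline recovers
structure it provably can recover (rank-1 class signals above noise), not
performance on real EEG; the real-data path exists but requires
user-supplied recordings.

## Problem sizes used in tests and the acceptance script

The end-to-end runs use the study fixture above with a width-reduced
codec profile (`pipeline.compact_spec`: encoder widths 32/64/64, decoder
48/48, block depths 2/2/1 and 2/2/2, the full 200-neuron population) and
40 training epochs — the package's standard profile for desk-scale
synthetic data, chosen so a complete two-stage run finishes in about a
minute on one CPU while leaving large margins on the recovery metrics.
The full-width architecture (128/256/256, depths 5/5/3) remains the
default `CodecSpec` and is exercised by a real forward pass in the shape
tests at (C=22, T=1000) and (C=8, T=256).

## Numerical and degenerate-input behavior

* Non-finite input currents, shape mismatches, empty pattern lists,
  out-of-range labels and missing files raise immediately with named
  offenders.
* Training aborts with a diagnostic if any loss turns non-finite.
* `r_square` returns NaN for a constant ERP (SS_tot = 0).
* The cross-subject STD row uses the sample (n−1) standard deviation; a
  single subject reports 0.
* Classification ties break toward the lowest class index.
* The synchrony index (mean pairwise Pearson correlation of neuron spike
  vectors) excludes constant neurons and reports 0 when fewer than two
  variable neurons exist.
* Containers are written with pinned zip timestamps so identical data
  produces byte-identical files.

## Known limitations

* The NumPy implementation is single-threaded BLAS-bound; the full-width
  architecture trains slowly on large datasets (hours, not minutes). The
  module boundaries would admit a GPU backend without API changes.
* BAM capacity is the classical Hebbian limit; with many stored pairs per
  class the memory behaves as a class-mean correlation classifier rather
  than an exact recaller. This is intended — classification only needs
  the class aggregate.
* GDF/EDF epoching delegates to `mne` and uses annotation events as
  labels; dataset-specific event maps (e.g. selecting cue codes) must be
  handled by the caller.
* The train/test protocol on real data (session-based vs. random split)
  is a user decision; both are expressible through `split_by_subject` or
  by supplying separate files.
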