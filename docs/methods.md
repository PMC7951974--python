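# Methods

## The estimation problem

Two-photon calcium imaging reports neural activity only indirectly: each
action potential triggers a calcium influx that the indicator (GCaMP,
OGB) transduces into a slow fluorescence transient, with rise times of
tens of milliseconds and decay times of hundreds of milliseconds, on top
of baseline drift and shot noise.  Spike inference is the inverse
problem — recovering the spike train, or a spike-rate signal, from the
fluorescence trace.

`s2spike` treats this as signal-to-signal conversion: a small neural
network reads the fluorescence signal and synthesizes a same-length,
same-rate spike signal, trained end to end against ground-truth spike
counts.  No explicit generative model of the indicator is inverted; the
network learns the deconvolution implicitly.

## The network

For a trace sampled at 100 Hz the network operates on overlapping frames
of `w_seq = 100` samples (1 s) taken at every sample position (hop 1),
with centered zero-padding so that frame *t* is centered on sample *t*:

1. **Analysis layer** — `nFilt_in = 30` learned kernels of length 100
   plus biases; an inner product with each kernel per frame, followed by
   ReLU.  Equivalent to a stride-1 convolution over the full signal.
2. **Hidden stack** — `I ∈ {0, 1, 2, 3}` dense layers of 30 units with
   bias and ReLU, applied *time-distributed*: the same weights process
   every frame independently.
3. **Synthesis layer** — a bias-free linear map from the last
   30-dimensional feature vector to 100 output samples per frame.

The per-frame outputs are overlap-added at their frame positions.  Every
output sample is divided by the number of frames covering it, which
removes the amplitude taper that plain overlap-add would impose at the
edges, and the padded margins are cropped so the estimate has exactly
the input length.  Because all layers are frame-wise and the framing is
uniform, the mapping is shift-covariant away from the edges.

Trainable-parameter counts follow directly: `(100·30 + 30)` analysis,
`(30·30 + 30)` per hidden layer, `30·100` synthesis without bias — 6,030
for no hidden layer, 6,960 for one, 8,820 for three.

Input traces are standardized (zero mean, unit variance, guard 1e-8)
before framing.  The training objective is scale-invariant, so
standardization costs nothing in expressiveness while making traces of
different amplitude commensurate.

Weights are initialized with Glorot-uniform draws
(`U(±sqrt(6/(fan_in+fan_out)))`) from a seeded generator; biases start
at zero.  Initialization is a design choice, not part of the method's
identity — the test suite checks that training outcomes are reproducible
for a fixed seed rather than assuming any particular scheme.

## Training objective and schedule

The loss for a training chunk is the negative Pearson correlation
between the network output `y` and the target `s`:

    L(y, s) = − cov(y, s) / ((σ_y + ε)(σ_s + ε)),   ε = 1e-8

The ε-guard makes the loss well-defined (value ≈ 0, finite gradient) on
silent chunks with constant targets, which are deliberately retained in
training.  The loss is invariant under positive affine transforms of
either argument, so the network is only asked to reproduce the *shape*
of the spike signal; output amplitude is unconstrained.  Gradients are
analytic (the quotient rule through the centered moments, then standard
backpropagation through the linear/ReLU stack and the overlap-add
adjoint) and are verified against finite differences in the test suite.

Targets are the ground-truth spike counts, optionally convolved with a
unit-sum Gaussian window of width 11 samples and standard deviation 5
samples ("same" convolution, zero-padded edges).  Unit-sum
normalization preserves total spike mass for interior spikes; since the
loss is scale-invariant the normalization only fixes reported
amplitudes.

Optimization: Adam, learning rate 0.001 (other moments at their standard
defaults), mini-batches of 20 chunks, loss computed per chunk and the
batch gradient averaged.  Recordings are standardized, converted to
targets, and cut into non-overlapping chunks of 1,000 samples (10 s); a
final fragment shorter than one frame (100 samples) is dropped.  The
recordings are split 80/20 into training and validation *at the
recording level*, so no neuron contributes to both sets.

Early stopping watches the validation loss with patience 6 and a
minimum meaningful improvement `min_delta = 1e-3`: the best epoch (and
the restored weights) track every strict improvement, but the patience
counter resets only when an epoch beats the running best by more than
`min_delta`.  On a loss bounded in [−1, 1], gains below 1e-3 are noise
for any scientific purpose; without the threshold, a validation curve
that creeps down by ~1e-4 per epoch would postpone stopping
indefinitely even though training has converged.  Training halts when
patience is exhausted or at `max_epochs = 100`, and the weights of the
best-validation epoch are returned.

## Evaluation protocol

Estimates are compared to ground truth at 25 Hz: both signals are
partitioned into 40 ms bins (4 native samples) and bin-summed, with a
trailing partial bin dropped.  Evaluation at the native 100 Hz is the
factor-1 identity path.  Three per-recording metrics:

- **Pearson correlation** of the binned signals (primary);
- **Spearman rank correlation** (average ranks under ties);
- **ROC-AUC** for detecting spike-containing bins (label = bin count
  > 0, score = binned estimate); equals the tie-corrected pair-ordering
  probability.

Bin *summation* is used for both signals: spike bins must represent
counts, and the correlation metrics are scale-invariant so sum versus
mean is immaterial for the estimate.  A recording on which a metric is
undefined (constant binned signal, or single-class labels) is excluded
from that metric's average with a warning rather than scored zero.
Per-dataset means are unweighted means over recordings, and the grand
mean is the unweighted mean over dataset means, so datasets of different
size count equally.

## The synthetic benchmark

The simulator generates what the method assumes: sparse spikes driving
slow calcium transients.  Per neuron, at 100 Hz:

- **Spikes** — a Poisson process with mean rate `rate_hz` (default
  1 Hz; the reference study conditions use 0.8 Hz).  Each spike
  triggers, with probability `burst_prob = 0.2`, a Poisson(2) number of
  follow-on spikes in the immediately following samples, producing the
  multi-spike bins and counts > 1 seen in real recordings.  The
  effective rate is `rate_hz·(1 + burst_prob·burst_len_mean)`.
- **Transient kernel** — `k(t) = (1 − e^(−t/τ_rise))·e^(−t/τ_decay)`
  with τ_rise = 50 ms and τ_decay = 500 ms, normalized to unit peak and
  truncated at 10·τ_decay (tail < 5e-5 of peak); GCaMP/OGB-like
  dynamics.  The trace is the spike train convolved with this kernel at
  amplitude `amp = 1` per spike.
- **Nuisance structure** — additive white Gaussian noise with
  σ = 0.2 (per-sample transient SNR ≈ 5, the clean end of what imaging
  delivers) and a sinusoidal baseline drift of amplitude 0.1 with a 30 s
  period and random phase.

Per-neuron random streams are spawned deterministically from the master
seed, so a benchmark is bit-reproducible.  What the simulator does *not*
emulate: indicator nonlinearity and saturation, dye-dependent kernel
diversity across datasets, movement artifacts, neuropil contamination,
and scan-rate variation.  Passing the synthetic tests therefore
demonstrates that the pipeline can invert its own generative
assumptions, not that it matches any published benchmark number on real
recordings — the evaluation machinery accepts real benchmark files in
the same CSV dialect whenever they are available.

One consequence is worth stating explicitly because it reverses a
real-data finding.  On data this clean the network nearly reaches the
evaluation ceiling of whichever target it is trained on.  A perfect
reproduction of the Gaussian-smoothed target scores only ≈ 0.78 binned
Pearson against the discrete counts (the smoothing spreads mass across
bin boundaries), whereas a perfect reproduction of the discrete target
scores 1.0 — so on the synthetic fixture discrete targets evaluate
*better* than smoothed ones, and the documented real-data benefit of
target smoothing (an optimization effect under heavy noise) does not
manifest.

## Numerical and design choices

- Framing uses centered zero-padding; together with coverage
  normalization this is the only edge convention that keeps the
  estimate unbiased in amplitude at both ends.
- Chunk length 1,000 samples spans many transients while keeping a
  20-chunk batch trivial in memory; chunks with constant targets are
  retained (the ε-guard handles them).
- The recording-level validation split uses `round(0.2·N)` recordings
  with a minimum of one on each side.
- CSV round-trips are exact: floats are written in shortest round-trip
  representation and parsed with correctly rounded conversion.
- Checkpoints are single-file `.npz` containers with the architecture
  embedded as JSON; loading restores weights bit-exactly.
- Interpretability reductions: the per-layer "total response" is the
  channel sum of post-activation outputs per frame; cumulative filter
  spectra are sums of per-kernel DFT magnitudes on a 1,024-point grid
  from 0 to Nyquist.

## Problem sizes used in the automated checks

The end-to-end checks train on 20 simulated neurons of 60 s each
(120,000 training samples) and evaluate on 8 held-out neurons from an
independent seed stream, with the two ablations (discrete targets, no
hidden layer) trained under identical conditions.  These sizes give
stable metric estimates (held-out Pearson varies by < 0.03 across
seeds) with a full run in about a minute on one CPU core.

## Known limitations

- The network assumes a 100 Hz input rate and a 1 s receptive field; no
  resampling is built in.
- Correlation training leaves output scale and offset undefined;
  downstream users must threshold or rescale per application.
- The simulator's single fixed kernel cannot probe generalization
  across indicators.
- Training is single-threaded, dense numpy; adequate for these model
  sizes (≤ 8,820 parameters), not for architecture search.
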