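"""Training: Pearson-correlation objective, chunking, splitting, Adam loop.

The network is trained to maximize the Pearson correlation between its
spike-signal estimate and the (optionally Gaussian-smoothed) ground-truth
target — equivalently, to minimize ``-r``.  The correlation cost is
invariant to positive affine transforms of either signal, so only the
shape of the estimate is constrained, not its absolute scale.

Recordings are standardized and cut into non-overlapping chunks (default
1,000 samples, i.e. 10 s at 100 Hz); an epoch is one pass over the
shuffled training chunks in mini-batches, with the loss computed per
chunk and averaged over the batch.  Early stopping monitors the
validation loss with a patience of 6 epochs and restores the weights of
the best-validation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording
from .network import (
    NetworkParams,
    S2SConfig,
    SpikeEstimate,
    build_network,
    frame_signal,
    overlap_add,
    standardize,
    _forward_frames,
)
from .targets import GaussianTargetSpec, smooth_targets

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "correlation_loss",
    "correlation_loss_grad",
    "chunk_recordings",
    "split_train_val",
    "fit",
]

_EPS = 1e-8


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters.

    Adam with a starting learning rate of 0.001 and mini-batches of 20
    chunks; patience-6 early stopping on the validation loss; recordings
    split 80/20 into training and validation at the recording level.

    ``min_delta`` is the smallest validation-loss improvement that resets
    the patience counter: the correlation loss lives on a [-1, 1] scale,
    so gains below 1e-3 are scientifically negligible and should count as
    convergence, not progress.
    """

    learning_rate: float = 0.001
    batch_size: int = 20
    patience: int = 6
    min_delta: float = 1e-3
    max_epochs: int = 100
    chunk_len: int = 1000
    val_fraction: float = 0.2
    seed: int = 0
    target_spec: GaussianTargetSpec = field(default_factory=GaussianTargetSpec)

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")
        if min(self.batch_size, self.patience, self.max_epochs, self.chunk_len) < 1:
            raise ValueError("batch_size, patience, max_epochs, chunk_len must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch losses and the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epoch_of_best_validation: int = 0
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def correlation_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Negative Pearson correlation, epsilon-guarded against flat signals.

    Returns ``-cov(pred, target) / ((sd(pred) + eps) * (sd(target) + eps))``
    with ``eps = 1e-8``; a perfect match gives -1, a perfect sign flip +1,
    and a constant signal 0 (rather than an undefined value).
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {target.shape}")
    if pred.size < 2:
        raise ValueError("need at least 2 samples")
    pc = pred - pred.mean()
    tc = target - target.mean()
    cov = np.mean(pc * tc)
    return float(-cov / ((pc.std() + _EPS) * (tc.std() + _EPS)))


def correlation_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`correlation_loss` with respect to ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    n = pred.size
    pc = pred - pred.mean()
    tc = target - target.mean()
    sd_p = pc.std()
    sd_t = tc.std()
    cov = np.mean(pc * tc)
    denom = (sd_p + _EPS) * (sd_t + _EPS)
    # d cov / d pred = tc / n ;  d sd_p / d pred = pc / (n * sd_p)
    d_cov = tc / n
    d_sd = pc / (n * max(sd_p, _EPS))
    dr = d_cov / denom - cov * d_sd / ((sd_p + _EPS) ** 2 * (sd_t + _EPS))
    return -dr


def chunk_recordings(
    recordings: list[Recording],
    chunk_len: int,
    target_spec: GaussianTargetSpec | None = None,
    w_seq: int = 100,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut recordings into non-overlapping (trace, target) training chunks.

    Traces are standardized per recording before chunking; spike counts
    are converted to targets via ``target_spec`` (pass-through when None).
    A final partial chunk shorter than ``w_seq`` is dropped; chunks with
    zero target variance are retained (the epsilon guard in the loss
    handles them).
    """
    if chunk_len < w_seq:
        raise ValueError("chunk_len must be >= the frame length w_seq")
    chunks = []
    for rec in recordings:
        trace = standardize(rec.trace)
        target = (
            smooth_targets(rec.spikes, target_spec)
            if target_spec is not None
            else rec.spikes.astype(np.float64)
        )
        for start in range(0, len(trace), chunk_len):
            piece_x = trace[start : start + chunk_len]
            if len(piece_x) < w_seq:
                break
            chunks.append((piece_x, target[start : start + len(piece_x)]))
    return chunks


def split_train_val(
    recordings: list[Recording], val_fraction: float, seed: int
) -> tuple[list[Recording], list[Recording]]:
    """Split at the recording level so no neuron straddles the two sets."""
    n = len(recordings)
    if n < 2:
        raise ValueError("need at least 2 recordings to split")
    n_val = int(round(val_fraction * n))
    n_val = min(max(n_val, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [recordings[i] for i in range(n) if i not in val_idx]
    val = [recordings[i] for i in range(n) if i in val_idx]
    return train, val


def _forward_chunk(params: NetworkParams, x: np.ndarray):
    """Forward pass on a pre-standardized chunk, keeping backprop state."""
    frames, pad_left = frame_signal(x, params.config.w_seq, hop=1)
    acts = _forward_frames(params, frames)
    est = overlap_add(acts[-1], hop=1, pad_left=pad_left, out_len=len(x))
    return est, frames, acts, pad_left


def _coverage(n_frames: int, w: int) -> np.ndarray:
    cov = np.zeros(n_frames + w - 1)
    for j in range(w):
        cov[j : j + n_frames] += 1.0
    return cov


def _backward_chunk(
    params: NetworkParams,
    frames: np.ndarray,
    acts: list[np.ndarray],
    pad_left: int,
    g_est: np.ndarray,
) -> list[np.ndarray]:
    """Gradients of the chunk loss w.r.t. every parameter array.

    Returned in the order of ``NetworkParams.flat_arrays``.
    """
    n_frames, w = frames.shape
    cov = _coverage(n_frames, w)
    g_acc = np.zeros(n_frames + w - 1)
    out_len = len(g_est)
    g_acc[pad_left : pad_left + out_len] = g_est / cov[pad_left : pad_left + out_len]
    # overlap-add adjoint: frame f, sample j drew from padded position f + j
    g_frames_out = np.empty((n_frames, w))
    for j in range(w):
        g_frames_out[:, j] = g_acc[j : j + n_frames]

    h_last = acts[-2] if params.hidden else acts[0]
    g_synthesis = h_last.T @ g_frames_out
    g = g_frames_out @ params.synthesis.T

    hidden_grads: list[np.ndarray] = []
    for i in range(len(params.hidden) - 1, -1, -1):
        w_i, _ = params.hidden[i]
        g = g * (acts[1 + i] > 0)
        below = acts[i]
        hidden_grads.append(g.sum(axis=0))  # bias
        hidden_grads.append(g.T @ below)  # weight
        g = g @ w_i
    g = g * (acts[0] > 0)
    g_analysis_w = g.T @ frames
    g_analysis_b = g.sum(axis=0)

    grads = [g_analysis_w, g_analysis_b]
    for i in range(len(params.hidden)):
        gw = hidden_grads[2 * (len(params.hidden) - 1 - i) + 1]
        gb = hidden_grads[2 * (len(params.hidden) - 1 - i)]
        grads.extend([gw, gb])
    grads.append(g_synthesis)
    return grads


def _mean_loss(params: NetworkParams, chunks) -> float:
    losses = [
        correlation_loss(_forward_chunk(params, x)[0], t) for x, t in chunks
    ]
    return float(np.mean(losses))


class _Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, arrays: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def fit(
    config: S2SConfig,
    tcfg: TrainConfig,
    recordings: list[Recording],
) -> tuple[NetworkParams, TrainHistory]:
    """Train the network on a set of recordings.

    Returns the parameters of the best-validation epoch together with the
    training history.  Fully deterministic for fixed seeds.
    """
    train_recs, val_recs = split_train_val(recordings, tcfg.val_fraction, tcfg.seed)
    spec = tcfg.target_spec
    train_chunks = chunk_recordings(train_recs, tcfg.chunk_len, spec, config.w_seq)
    val_chunks = chunk_recordings(val_recs, tcfg.chunk_len, spec, config.w_seq)
    if not train_chunks or not val_chunks:
        raise ValueError("no usable training/validation chunks after splitting")

    params = build_network(config)
    arrays = params.flat_arrays()
    opt = _Adam(arrays, tcfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(tcfg.seed, spawn_key=(1,)))

    history = TrainHistory()
    best_val = np.inf
    best_params = params.copy()
    epochs_since_best = 0

    for epoch in range(1, tcfg.max_epochs + 1):
        order = shuffle_rng.permutation(len(train_chunks))
        epoch_losses = []
        for start in range(0, len(order), tcfg.batch_size):
            batch = [train_chunks[i] for i in order[start : start + tcfg.batch_size]]
            batch_grads = None
            for x, t in batch:
                est, frames, acts, pad_left = _forward_chunk(params, x)
                epoch_losses.append(correlation_loss(est, t))
                g_est = correlation_loss_grad(est, t)
                grads = _backward_chunk(params, frames, acts, pad_left, g_est)
                if batch_grads is None:
                    batch_grads = grads
                else:
                    for bg, g in zip(batch_grads, grads):
                        bg += g
            for bg in batch_grads:
                bg /= len(batch)
            opt.step(arrays, batch_grads)

        history.train_loss.append(float(np.mean(epoch_losses)))
        val_loss = _mean_loss(params, val_chunks)
        history.val_loss.append(val_loss)

        meaningful = val_loss < best_val - tcfg.min_delta
        if val_loss < best_val:
            best_val = val_loss
            best_params = params.copy()
            history.epoch_of_best_validation = epoch
        if meaningful:
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= tcfg.patience:
                history.stopped_early = True
                break

    return best_params, history
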