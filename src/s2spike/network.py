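"""The analysis-synthesis (S2S) network mapping a calcium trace to a spike signal.

Architecture
------------
The input trace is standardized, framed into overlapping windows of
``w_seq`` samples at a hop of one sample, and every frame is processed
independently:

* analysis layer: ``nFilt_in`` learned kernels of length ``kW_in == w_seq``
  plus biases, followed by ReLU — an inner product of each kernel with the
  frame (a stride-1 convolution over the full signal);
* ``I`` time-distributed hidden layers (dense + bias + ReLU, identical
  weights at every frame position);
* synthesis layer: a bias-free linear map from the last feature vector to
  ``w_seq`` output samples per frame.

The per-frame outputs are overlap-added at their frame positions,
normalized by per-sample frame coverage, and cropped to the input length,
so the estimated spike signal has exactly the length and sampling rate of
the input fluorescence trace.

The network is small (8,820 trainable scalars for the default
three-hidden-layer configuration) and is implemented directly on numpy
arrays, with the backward pass in :mod:`s2spike.train`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "S2SConfig",
    "NetworkParams",
    "SpikeEstimate",
    "count_parameters",
    "build_network",
    "frame_signal",
    "overlap_add",
    "forward",
    "standardize",
    "save_checkpoint",
    "load_checkpoint",
]

#: guard added to the standard deviation when standardizing traces
STANDARDIZE_EPS = 1e-8


@dataclass(frozen=True)
class S2SConfig:
    """Architecture hyper-parameters.

    ``kW_in == w_seq`` and unit hops are structural constraints of the
    architecture; ``n_hidden`` in {0, 1, 2, 3} selects the hidden-stack
    depth and ``nhu`` the per-layer widths.
    """

    w_seq: int = 100
    nFilt_in: int = 30
    n_hidden: int = 3
    nhu: tuple[int, ...] | int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_seq < 1 or self.nFilt_in < 1:
            raise ValueError("w_seq and nFilt_in must be strictly positive")
        if self.n_hidden < 0:
            raise ValueError("n_hidden must be >= 0")
        nhu = self.nhu
        if np.isscalar(nhu):
            nhu = (int(nhu),) * self.n_hidden
        else:
            nhu = tuple(int(u) for u in nhu)
        if len(nhu) != self.n_hidden:
            raise ValueError("nhu must provide one width per hidden layer")
        if any(u < 1 for u in nhu):
            raise ValueError("hidden-layer widths must be strictly positive")
        object.__setattr__(self, "nhu", nhu)

    @property
    def kW_in(self) -> int:
        return self.w_seq

    @property
    def dW_in(self) -> int:
        return 1

    @property
    def dW_out(self) -> int:
        return 1

    @property
    def nFilt_out(self) -> int:
        return self.w_seq

    @property
    def kW_out(self) -> int:
        """Synthesis kernel width: width of the last feature vector."""
        return self.nhu[-1] if self.n_hidden else self.nFilt_in

    def layer_widths(self) -> list[int]:
        """Feature widths after the analysis layer and each hidden layer."""
        return [self.nFilt_in, *self.nhu]


@dataclass
class NetworkParams:
    """Learned weights: analysis kernels, hidden stack, synthesis map.

    ``analysis_w`` has shape (nFilt_in, kW_in); each ``hidden`` entry is a
    (fan_out, fan_in) matrix with a bias vector; ``synthesis`` has shape
    (kW_out, w_seq) and no bias.
    """

    config: S2SConfig
    analysis_w: np.ndarray
    analysis_b: np.ndarray
    hidden: list[tuple[np.ndarray, np.ndarray]]
    synthesis: np.ndarray

    @property
    def n_parameters(self) -> int:
        """Trainable-scalar count by direct introspection of the arrays."""
        n = self.analysis_w.size + self.analysis_b.size + self.synthesis.size
        for w, b in self.hidden:
            n += w.size + b.size
        return int(n)

    def flat_arrays(self) -> list[np.ndarray]:
        """All parameter arrays in a fixed order (for the optimizer)."""
        arrays = [self.analysis_w, self.analysis_b]
        for w, b in self.hidden:
            arrays.extend([w, b])
        arrays.append(self.synthesis)
        return arrays

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            config=self.config,
            analysis_w=self.analysis_w.copy(),
            analysis_b=self.analysis_b.copy(),
            hidden=[(w.copy(), b.copy()) for w, b in self.hidden],
            synthesis=self.synthesis.copy(),
        )


@dataclass(frozen=True)
class SpikeEstimate:
    """Real-valued spike-signal estimate, same length/rate as the input."""

    values: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        if len(self.values) != self.source_length:
            raise ValueError("estimate length must equal the source length")


def count_parameters(config: S2SConfig) -> int:
    """Closed-form trainable-parameter count.

    (kW_in * nFilt_in + nFilt_in) for the analysis layer, a dense term
    (fan_in * width + width) per hidden layer, and a bias-free
    (kW_out * w_seq) synthesis term.
    """
    n = config.kW_in * config.nFilt_in + config.nFilt_in
    fan_in = config.nFilt_in
    for width in config.nhu:
        n += fan_in * width + width
        fan_in = width
    n += config.kW_out * config.w_seq
    return n


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def build_network(config: S2SConfig) -> NetworkParams:
    """Initialize parameters with a variance-scaled uniform scheme from config.seed."""
    rng = np.random.default_rng(config.seed)
    analysis_w = _glorot_uniform(
        rng, config.kW_in, config.nFilt_in, (config.nFilt_in, config.kW_in)
    )
    analysis_b = np.zeros(config.nFilt_in)
    hidden = []
    fan_in = config.nFilt_in
    for width in config.nhu:
        w = _glorot_uniform(rng, fan_in, width, (width, fan_in))
        hidden.append((w, np.zeros(width)))
        fan_in = width
    synthesis = _glorot_uniform(rng, fan_in, config.w_seq, (fan_in, config.w_seq))
    return NetworkParams(
        config=config,
        analysis_w=analysis_w,
        analysis_b=analysis_b,
        hidden=hidden,
        synthesis=synthesis,
    )


def frame_signal(x: np.ndarray, w: int, hop: int = 1) -> tuple[np.ndarray, int]:
    """Frame ``x`` into centered windows of length ``w``.

    The signal is zero-padded with ``pad_left = (w - 1) // 2`` samples on
    the left and ``w - 1 - pad_left`` on the right so that, at hop 1,
    exactly ``len(x)`` frames are produced and frame ``t`` is centered on
    sample ``t``.  Returns ``(frames, pad_left)`` with frames of shape
    (n_frames, w).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("input must be a non-empty 1-D sequence")
    if w < 1:
        raise ValueError("frame length must be >= 1")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    pad_left = (w - 1) // 2
    padded = np.pad(x, (pad_left, w - 1 - pad_left))
    frames = sliding_window_view(padded, w)[::hop]
    return frames, pad_left


def overlap_add(
    frame_outputs: np.ndarray,
    hop: int = 1,
    pad_left: int = 0,
    out_len: int | None = None,
) -> np.ndarray:
    """Overlap-add per-frame outputs with per-sample coverage normalization.

    Frame ``f`` contributes its ``w`` samples at padded positions
    ``[f * hop, f * hop + w)``; every accumulated sample is divided by the
    number of frames covering it, and the padded margins are cropped to
    return ``out_len`` samples starting at ``pad_left``.
    """
    frames = np.asarray(frame_outputs, dtype=np.float64)
    if frames.ndim != 2:
        raise ValueError("frame outputs must form a rectangular (n_frames, w) array")
    n_frames, w = frames.shape
    if n_frames < 1:
        raise ValueError("at least one frame is required")
    if out_len is None:
        out_len = n_frames
    if out_len < 1:
        raise ValueError("out_len must be >= 1")
    total = (n_frames - 1) * hop + w
    if pad_left + out_len > total:
        raise ValueError("out_len exceeds the reconstructed support")
    acc = np.zeros(total)
    cov = np.zeros(total)
    if hop == 1:
        for j in range(w):  # w vectorized shifts instead of an n_frames loop
            acc[j : j + n_frames] += frames[:, j]
            cov[j : j + n_frames] += 1.0
    else:
        for f in range(n_frames):
            acc[f * hop : f * hop + w] += frames[f]
            cov[f * hop : f * hop + w] += 1.0
    out = acc / np.maximum(cov, 1.0)
    return out[pad_left : pad_left + out_len]


def standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance standardization with an epsilon guard."""
    x = np.asarray(x, dtype=np.float64)
    return (x - x.mean()) / (x.std() + STANDARDIZE_EPS)


def _forward_frames(params: NetworkParams, frames: np.ndarray) -> list[np.ndarray]:
    """Per-frame activations: [analysis, hidden_1.., synthesis frame outputs]."""
    acts = []
    h = np.maximum(frames @ params.analysis_w.T + params.analysis_b, 0.0)
    acts.append(h)
    for w, b in params.hidden:
        h = np.maximum(h @ w.T + b, 0.0)
        acts.append(h)
    acts.append(h @ params.synthesis)
    return acts


def forward(
    params: NetworkParams,
    trace: np.ndarray,
    normalize_input: bool = True,
    return_activations: bool = False,
):
    """Run the network on a fluorescence trace.

    Returns a :class:`SpikeEstimate` of the same length as the input; with
    ``return_activations=True`` also returns the per-frame post-activation
    arrays of every layer (analysis, hidden stack, synthesis frames).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or len(trace) < 1:
        raise ValueError("trace must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    x = standardize(trace) if normalize_input else trace
    frames, pad_left = frame_signal(x, params.config.w_seq, hop=1)
    acts = _forward_frames(params, frames)
    values = overlap_add(acts[-1], hop=1, pad_left=pad_left, out_len=len(trace))
    estimate = SpikeEstimate(values=values, source_length=len(trace))
    if return_activations:
        return estimate, acts
    return estimate


def save_checkpoint(params: NetworkParams, path: str | os.PathLike) -> None:
    """Save parameters and config to a single-file container (npz)."""
    cfg = params.config
    meta = json.dumps(
        {
            "w_seq": cfg.w_seq,
            "nFilt_in": cfg.nFilt_in,
            "n_hidden": cfg.n_hidden,
            "nhu": list(cfg.nhu),
            "seed": cfg.seed,
        }
    )
    arrays = {
        "analysis_w": params.analysis_w,
        "analysis_b": params.analysis_b,
        "synthesis": params.synthesis,
    }
    for i, (w, b) in enumerate(params.hidden):
        arrays[f"hidden_w_{i}"] = w
        arrays[f"hidden_b_{i}"] = b
    np.savez(path, config=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | os.PathLike) -> NetworkParams:
    """Load a checkpoint written by :func:`save_checkpoint`, bit-exactly."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["config"]).decode())
            config = S2SConfig(
                w_seq=meta["w_seq"],
                nFilt_in=meta["nFilt_in"],
                n_hidden=meta["n_hidden"],
                nhu=tuple(meta["nhu"]) if meta["nhu"] else 0,
                seed=meta["seed"],
            )
            hidden = [
                (data[f"hidden_w_{i}"], data[f"hidden_b_{i}"])
                for i in range(config.n_hidden)
            ]
            return NetworkParams(
                config=config,
                analysis_w=data["analysis_w"],
                analysis_b=data["analysis_b"],
                hidden=hidden,
                synthesis=data["synthesis"],
            )
    except (KeyError, ValueError, json.JSONDecodeError, OSError) as exc:
        raise ValueError(f"corrupt or incompatible checkpoint {path}: {exc}") from exc
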