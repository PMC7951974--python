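"""Interpretability: layer-wise responses and cumulative filter spectra.

Two views into what the trained network computes: (a) the total
(channel-summed) post-activation response of each layer as a function of
time, aligned frame-for-frame with the input trace, and (b) the
cumulative magnitude frequency response of a filter bank — the sum over
filters of each kernel's DFT magnitude on a grid from 0 to the Nyquist
frequency.  Applied to the analysis kernels and to the rows of the
synthesis map (each row is the time-domain output kernel of one unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkParams, forward

__all__ = [
    "LayerResponse",
    "FrequencyResponse",
    "layer_responses",
    "filter_frequency_response",
]


@dataclass(frozen=True)
class LayerResponse:
    """Channel-summed response of one layer, one value per input sample."""

    layer_name: str
    response: np.ndarray


@dataclass(frozen=True)
class FrequencyResponse:
    """Cumulative magnitude spectrum of a filter bank on [0, fs/2]."""

    freqs: np.ndarray
    magnitude: np.ndarray


def layer_responses(params: NetworkParams, trace: np.ndarray) -> list[LayerResponse]:
    """Total per-frame response of every layer for one input trace.

    Returns one entry per layer — analysis, each hidden layer, and the
    final synthesis/overlap-add output (which equals the spike estimate
    itself).  With hop-1 centered framing each response has exactly one
    value per input sample.
    """
    estimate, acts = forward(params, trace, return_activations=True)
    responses = [LayerResponse("analysis", acts[0].sum(axis=1))]
    for i in range(len(params.hidden)):
        responses.append(LayerResponse(f"hidden_{i + 1}", acts[1 + i].sum(axis=1)))
    responses.append(LayerResponse("synthesis", estimate.values))
    return responses


def filter_frequency_response(
    kernels: np.ndarray, fs: float = 100.0, n_freq: int = 1024
) -> FrequencyResponse:
    """Cumulative |DFT| of a set of kernels on an ``n_freq``-point grid.

    ``kernels`` is (n_filters, kernel_len); each kernel is zero-padded to
    the grid length, and magnitudes are summed over filters.
    """
    kernels = np.atleast_2d(np.asarray(kernels, dtype=np.float64))
    if kernels.size == 0:
        raise ValueError("at least one kernel is required")
    if n_freq < kernels.shape[1]:
        raise ValueError("n_freq must be >= the kernel length")
    nfft = 2 * (n_freq - 1)
    spectra = np.abs(np.fft.rfft(kernels, n=nfft, axis=1))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return FrequencyResponse(freqs=freqs, magnitude=spectra.sum(axis=0))
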