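"""Synthetic calcium-imaging benchmark generator.

Produces paired (spike train, fluorescence trace) recordings with the
statistical structure spike-inference methods assume: sparse Poisson
spiking with occasional bursts, an indicator-like calcium transient per
spike, slow sinusoidal baseline drift, and additive white noise.  The
output files use the same column-per-neuron CSV dialect as public
spike-inference benchmarks, so the whole pipeline is exercisable without
any external download.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import io as sio

__all__ = [
    "SimConfig",
    "SimulatedRecording",
    "sample_spike_train",
    "render_fluorescence",
    "simulate_recording",
    "simulate_neurons",
    "benchmark_recordings",
    "make_benchmark",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic recording generator.

    Attributes
    ----------
    duration_s : float
        Recording length in seconds; ``fs * duration_s`` must be a whole
        number of samples.
    fs : float
        Sampling rate in Hz (100 Hz matches the benchmark dialect).
    rate_hz : float
        Mean rate of the primary Poisson spike process.
    burst_prob : float
        Probability that a spike event triggers a short burst.
    burst_len_mean : float
        Mean number of extra burst spikes (Poisson), placed in the
        samples immediately following the trigger.
    amp : float
        Peak fluorescence amplitude contributed by a single spike.
    tau_rise_s, tau_decay_s : float
        Rise/decay time constants of the calcium transient kernel;
        decay must exceed rise for the transient shape to be defined.
    noise_sigma : float
        Standard deviation of the additive white Gaussian noise.
    drift_amp, drift_period_s : float
        Amplitude and period of the slow sinusoidal baseline drift
        (random phase per recording).
    seed : int
        Master seed; per-neuron streams are derived from it.
    """

    duration_s: float = 60.0
    fs: float = 100.0
    rate_hz: float = 1.0
    burst_prob: float = 0.2
    burst_len_mean: float = 2.0
    amp: float = 1.0
    tau_rise_s: float = 0.05
    tau_decay_s: float = 0.5
    noise_sigma: float = 0.2
    drift_amp: float = 0.1
    drift_period_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.duration_s > 0 and math.isfinite(self.duration_s)):
            raise ValueError("duration_s must be a positive finite number")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ValueError("fs must be a positive finite number")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("fs * duration_s must be a positive integer sample count")
        if not (math.isfinite(self.rate_hz) and self.rate_hz >= 0):
            raise ValueError("rate_hz must be finite and >= 0")
        if not 0.0 <= self.burst_prob <= 1.0:
            raise ValueError("burst_prob must be in [0, 1]")
        if self.burst_len_mean < 0:
            raise ValueError("burst_len_mean must be >= 0")
        if not self.amp > 0:
            raise ValueError("amp must be > 0")
        if not self.tau_rise_s > 0:
            raise ValueError("tau_rise_s must be > 0")
        if not self.tau_decay_s > self.tau_rise_s:
            raise ValueError("tau_decay_s must exceed tau_rise_s")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.drift_amp < 0:
            raise ValueError("drift_amp must be >= 0")
        if not self.drift_period_s > 0:
            raise ValueError("drift_period_s must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass(frozen=True)
class SimulatedRecording:
    """One simulated neuron: spike counts and fluorescence at ``config.fs``."""

    spikes: np.ndarray
    trace: np.ndarray
    config: SimConfig

    def __post_init__(self) -> None:
        if len(self.spikes) != len(self.trace) or len(self.spikes) != self.config.n_samples:
            raise ValueError("spikes and trace must both have fs * duration_s samples")


def sample_spike_train(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw a per-sample spike-count sequence.

    The primary process is Poisson with rate ``rate_hz``; each primary
    spike independently triggers, with probability ``burst_prob``, a
    Poisson(``burst_len_mean``) number of follow-on spikes laid down one
    per subsequent sample (counts may exceed one where bursts overlap).
    """
    n = config.n_samples
    counts = rng.poisson(config.rate_hz / config.fs, size=n).astype(np.int64)
    if config.burst_prob > 0 and config.burst_len_mean > 0:
        bursts = np.zeros(n, dtype=np.int64)
        for t in np.flatnonzero(counts):
            for _ in range(int(counts[t])):
                if rng.random() < config.burst_prob:
                    extra = int(rng.poisson(config.burst_len_mean))
                    stop = min(n, t + 1 + extra)
                    bursts[t + 1 : stop] += 1
        counts += bursts
    return counts


def calcium_kernel(config: SimConfig) -> np.ndarray:
    """Unit-peak calcium transient kernel sampled at ``config.fs``.

    k(t) = (1 - exp(-t/tau_rise)) * exp(-t/tau_decay) for t >= 0,
    truncated at 10 * tau_decay (tail contribution < 5e-5 of peak).
    """
    t = np.arange(0.0, 10.0 * config.tau_decay_s, 1.0 / config.fs)
    k = (1.0 - np.exp(-t / config.tau_rise_s)) * np.exp(-t / config.tau_decay_s)
    peak = k.max()
    if peak <= 0:  # single-sample support degenerate case
        raise ValueError("kernel support too short at this sampling rate")
    return k / peak


def render_fluorescence(
    spikes: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Render a fluorescence trace from a spike-count sequence.

    trace(t) = drift(t) + sum_i n_i * amp * k(t - t_i) + eps(t), with a
    unit-peak transient kernel, sinusoidal drift with random phase, and
    iid Gaussian noise.
    """
    spikes = np.asarray(spikes)
    if len(spikes) != config.n_samples:
        raise ValueError(
            f"spike sequence length {len(spikes)} does not match "
            f"config ({config.n_samples} samples)"
        )
    if np.any(spikes < 0):
        raise ValueError("spike counts must be non-negative")
    n = config.n_samples
    kernel = calcium_kernel(config)
    transients = np.convolve(spikes.astype(np.float64), kernel)[:n] * config.amp
    t = np.arange(n) / config.fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = config.drift_amp * np.sin(2.0 * np.pi * t / config.drift_period_s + phase)
    noise = rng.normal(0.0, config.noise_sigma, size=n) if config.noise_sigma > 0 else 0.0
    return transients + drift + noise


def simulate_recording(config: SimConfig, rng: np.random.Generator | None = None) -> SimulatedRecording:
    """Simulate one neuron (spike train + fluorescence trace)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spikes = sample_spike_train(config, rng)
    trace = render_fluorescence(spikes, config, rng)
    return SimulatedRecording(spikes=spikes, trace=trace, config=config)


def simulate_neurons(n_neurons: int, config: SimConfig) -> list[SimulatedRecording]:
    """Simulate a cohort of neurons with per-neuron streams derived from config.seed."""
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    out = []
    for j in range(n_neurons):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(j,)))
        out.append(simulate_recording(config, rng))
    return out


def benchmark_recordings(
    n_neurons: int, config: SimConfig, dataset_id: str = "synthetic"
) -> list[sio.Recording]:
    """Simulate a cohort and package it as paired :class:`~s2spike.io.Recording`s."""
    return [
        sio.Recording(
            trace=r.trace, spikes=r.spikes, dataset_id=dataset_id, neuron_id=str(j)
        )
        for j, r in enumerate(simulate_neurons(n_neurons, config))
    ]


def make_benchmark(
    n_neurons: int, config: SimConfig, out_dir: str | os.PathLike
) -> tuple[str, str]:
    """Write a paired calcium/spikes CSV benchmark with ``n_neurons`` columns.

    Per-neuron random streams are derived deterministically from
    ``config.seed``, so the same config always produces the same files.
    Returns ``(calcium_path, spikes_path)``.
    """
    recs = simulate_neurons(n_neurons, config)
    os.makedirs(out_dir, exist_ok=True)
    calcium_path = os.path.join(out_dir, "calcium.csv")
    spikes_path = os.path.join(out_dir, "spikes.csv")
    sio.write_column_csv([r.trace for r in recs], calcium_path)
    sio.write_column_csv([r.spikes for r in recs], spikes_path)
    return calcium_path, spikes_path
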