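"""Benchmark evaluation protocol: binning, Pearson, Spearman rank, ROC-AUC.

Estimates and ground-truth spike counts are binned down from the native
100 Hz to the evaluation rate (25 Hz, i.e. 40 ms bins, by default; 100 Hz
is the factor-1 identity path).  Per-recording metrics are averaged per
dataset and the grand mean is the unweighted mean over dataset means, so
small and large datasets count equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io import Recording
from .network import SpikeEstimate

__all__ = [
    "EvalConfig",
    "EvalResult",
    "bin_signal",
    "pearson_corr",
    "spearman_corr",
    "roc_auc",
    "evaluate",
]

METRICS = ("pearson", "spearman", "auc")


class ConstantInputError(ValueError):
    """A metric is undefined because one input has zero variance."""


@dataclass(frozen=True)
class EvalConfig:
    """Native and evaluation sampling rates; native must divide evenly."""

    native_fs: float = 100.0
    eval_fs: float = 25.0

    def __post_init__(self) -> None:
        factor = self.native_fs / self.eval_fs
        if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
            raise ValueError("native_fs must be an integer multiple of eval_fs")

    @property
    def bin_factor(self) -> int:
        return int(round(self.native_fs / self.eval_fs))


@dataclass
class EvalResult:
    """Per-recording metrics plus dataset-level and grand means."""

    per_recording: pd.DataFrame
    dataset_means: pd.DataFrame
    grand_mean: dict[str, float]
    eval_fs: float

    def summary(self) -> str:
        g = self.grand_mean
        return (
            f"eval @ {self.eval_fs:g} Hz — "
            f"pearson {g['pearson']:.4f}, spearman {g['spearman']:.4f}, "
            f"auc {g['auc']:.4f}"
        )


def bin_signal(x: np.ndarray, factor: int) -> np.ndarray:
    """Sum consecutive groups of ``factor`` samples; drop the remainder."""
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).sum(axis=1)


def _require_nonconstant(*seqs: np.ndarray) -> None:
    for s in seqs:
        if np.ptp(s) == 0:
            raise ConstantInputError("correlation undefined for a constant input")


def pearson_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    _require_nonconstant(a, b)
    return float(stats.pearsonr(a, b).statistic)


def spearman_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    _require_nonconstant(a, b)
    return float(stats.spearmanr(a, b).statistic)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve for detecting spike-containing bins.

    ``labels`` are binary (bin count > 0); ties in the scores contribute
    half a pair, so the value equals P(score+ > score-) + 0.5 P(=).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ConstantInputError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def evaluate(
    estimates: list[SpikeEstimate | np.ndarray],
    recordings: list[Recording],
    cfg: EvalConfig | None = None,
) -> EvalResult:
    """Score estimates against ground truth at the evaluation rate.

    Both the estimate and the spike counts are binned by summation; AUC
    uses binarized spike bins (count > 0) as labels.  Recordings where a
    metric is undefined (constant signal or single-class labels) are
    excluded from that metric's averages with a warning.
    """
    if cfg is None:
        cfg = EvalConfig()
    if len(estimates) != len(recordings):
        raise ValueError("estimates and recordings must be matched lists")
    factor = cfg.bin_factor
    rows = []
    for est, rec in zip(estimates, recordings):
        values = est.values if isinstance(est, SpikeEstimate) else np.asarray(est)
        if len(values) != len(rec):
            raise ValueError(
                f"estimate length {len(values)} != recording length {len(rec)}"
            )
        pred = bin_signal(values, factor)
        truth = bin_signal(rec.spikes, factor)
        row = {"dataset_id": rec.dataset_id, "neuron_id": rec.neuron_id}
        for name, fn, args in (
            ("pearson", pearson_corr, (pred, truth)),
            ("spearman", spearman_corr, (pred, truth)),
            ("auc", roc_auc, (pred, (truth > 0).astype(int))),
        ):
            try:
                row[name] = fn(*args)
            except ConstantInputError as exc:
                warnings.warn(
                    f"recording {rec.dataset_id}/{rec.neuron_id}: {name} "
                    f"excluded ({exc})"
                )
                row[name] = np.nan
        rows.append(row)
    per_recording = pd.DataFrame(rows)
    dataset_means = per_recording.groupby("dataset_id")[list(METRICS)].mean()
    grand_mean = {m: float(dataset_means[m].mean()) for m in METRICS}
    return EvalResult(
        per_recording=per_recording,
        dataset_means=dataset_means,
        grand_mean=grand_mean,
        eval_fs=cfg.eval_fs,
    )
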