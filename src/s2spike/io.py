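"""Column-per-neuron CSV reading/writing and recording pairing.

The dialect: UTF-8 comma-separated file with a header row of column
labels, one neuron per column, samples at 100 Hz top to bottom, and
empty cells only as bottom padding for ragged column lengths.  The same
layout is used for calcium traces, ground-truth spike counts, and
prediction files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Recording", "read_column_csv", "write_column_csv", "pair_recordings"]

#: spikes within this distance of an integer are rounded; beyond it they
#: are treated as corrupt ground truth.
_INT_TOL = 1e-6


@dataclass(frozen=True)
class Recording:
    """Paired fluorescence trace and spike counts for one neuron."""

    trace: np.ndarray
    spikes: np.ndarray
    dataset_id: str = "default"
    neuron_id: str = "0"
    fs: float = 100.0

    def __post_init__(self) -> None:
        trace = np.asarray(self.trace, dtype=np.float64)
        spikes = np.asarray(self.spikes)
        if trace.ndim != 1 or spikes.ndim != 1:
            raise ValueError("trace and spikes must be 1-D sequences")
        if len(trace) != len(spikes):
            raise ValueError(
                f"trace length {len(trace)} != spikes length {len(spikes)}"
            )
        if not np.all(np.isfinite(trace)):
            raise ValueError("trace contains non-finite values")
        rounded = np.round(spikes)
        if np.any(np.abs(spikes - rounded) > _INT_TOL) or np.any(rounded < 0):
            raise ValueError("spikes must be non-negative integers")
        object.__setattr__(self, "trace", trace)
        object.__setattr__(self, "spikes", rounded.astype(np.int64))

    def __len__(self) -> int:
        return len(self.trace)


def read_column_csv(path: str | os.PathLike, kind: str = "calcium") -> list[np.ndarray]:
    """Read one sequence per column, trimming trailing empty cells.

    ``kind`` is ``"calcium"`` (float sequences) or ``"spikes"``
    (validated non-negative integer counts).  Empty cells in the interior
    of a column, non-numeric cells, and out-of-tolerance spike values are
    format/validation errors.
    """
    if kind not in ("calcium", "spikes"):
        raise ValueError(f"unknown kind {kind!r}")
    raw = pd.read_csv(path, header=0, dtype=str, skip_blank_lines=False)
    seqs: list[np.ndarray] = []
    for col in raw.columns:
        cells = raw[col]
        missing = cells.isna() | (cells.str.strip() == "")
        filled = np.flatnonzero(~missing.to_numpy())
        if len(filled) == 0:
            raise ValueError(f"column {col!r} is entirely empty")
        last = filled[-1]
        if missing.iloc[: last + 1].any():
            row = int(np.flatnonzero(missing.to_numpy()[: last + 1])[0])
            raise ValueError(
                f"interior empty cell in column {col!r} at data row {row}"
            )
        try:
            # python float() is correctly rounded; pandas' fast parser is not
            values = np.array([float(v) for v in cells.iloc[: last + 1]])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in column {col!r}: {exc}") from exc
        if kind == "spikes":
            rounded = np.round(values)
            if np.any(np.abs(values - rounded) > _INT_TOL):
                raise ValueError(f"non-integer spike count in column {col!r}")
            if np.any(rounded < 0):
                raise ValueError(f"negative spike count in column {col!r}")
            values = rounded.astype(np.int64)
        seqs.append(values)
    return seqs


def write_column_csv(seqs: list[np.ndarray], path: str | os.PathLike) -> None:
    """Write sequences as columns, bottom-padding ragged lengths.

    Header labels are 0-based column indices; floats are written with
    shortest round-trip precision so that read(write(x)) == x exactly.
    """
    if len(seqs) == 0:
        raise ValueError("at least one sequence is required")

    def _cells(a: np.ndarray) -> list[str]:
        if np.issubdtype(a.dtype, np.integer):
            return [str(int(v)) for v in a]
        # repr of a python float is the shortest exact round-trip form
        return [repr(float(v)) for v in a]

    arrays = [np.asarray(s) for s in seqs]
    frame = pd.DataFrame(
        {str(j): pd.Series(_cells(a), dtype=object) for j, a in enumerate(arrays)}
    )
    frame.to_csv(path, index=False, na_rep="")


def pair_recordings(
    calcium_seqs: list[np.ndarray],
    spike_seqs: list[np.ndarray],
    dataset_id: str = "default",
    neuron_ids: list[str] | None = None,
) -> list[Recording]:
    """Pair calcium and spike columns positionally into Recordings.

    Lengths differing by at most 2 samples (off-by-one resampling
    artifacts, ~20 ms) are trimmed to the shorter; larger mismatches are
    errors.
    """
    if len(calcium_seqs) != len(spike_seqs):
        raise ValueError(
            f"column count mismatch: {len(calcium_seqs)} calcium vs "
            f"{len(spike_seqs)} spike columns"
        )
    if neuron_ids is None:
        neuron_ids = [str(j) for j in range(len(calcium_seqs))]
    recordings = []
    for j, (trace, spikes) in enumerate(zip(calcium_seqs, spike_seqs)):
        if abs(len(trace) - len(spikes)) > 2:
            raise ValueError(
                f"column {j}: length mismatch {len(trace)} vs {len(spikes)} "
                "exceeds 2 samples"
            )
        n = min(len(trace), len(spikes))
        recordings.append(
            Recording(
                trace=np.asarray(trace)[:n],
                spikes=np.asarray(spikes)[:n],
                dataset_id=dataset_id,
                neuron_id=neuron_ids[j],
            )
        )
    return recordings
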