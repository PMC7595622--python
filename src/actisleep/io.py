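"""Epoch-level actigraphy I/O and individual-level quality control.

Activity-count records arrive as one CSV per individual with columns
``timestamp,count`` at a fixed epoch spacing (e.g. 5 s or 5 min).  Reading
materializes any timestamp gaps as missing epochs so every series lives on a
uniform grid; downstream consumers (HMM decoding, FFT) decide their own
missing-data policy.

Quality control mirrors large-cohort accelerometer practice: individuals are
dropped when any qualitative flag is set (data problem, poor wear time, poor
calibration, interrupted record, device needing external calibration) or when
their recording-error count exceeds Q3 + 1.5*IQR across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "IndividualMeta",
    "QCResult",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_meta_csv",
    "qc_exclude",
]

_FLAG_COLUMNS = (
    "flagged_problem",
    "poor_wear_time",
    "poor_calibration",
    "interrupted",
    "needs_external_calibration",
)


@dataclass
class EpochSeries:
    """One individual's activity counts on a uniform epoch grid.

    ``counts`` is a float array: non-negative integer-valued entries are
    observed counts, NaN marks a missing epoch.
    """

    individual_id: str
    start_time: pd.Timestamp
    epoch_seconds: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        observed = self.counts[~np.isnan(self.counts)]
        if observed.size and (np.any(observed < 0) or np.any(observed != np.round(observed))):
            raise ValueError("counts must be non-negative integers or NaN")

    @property
    def n_epochs(self) -> int:
        return self.counts.size

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=self.n_epochs, freq=pd.Timedelta(seconds=self.epoch_seconds)
        )

    @property
    def duration_days(self) -> float:
        return self.n_epochs * self.epoch_seconds / 86400.0


@dataclass(frozen=True)
class IndividualMeta:
    """Per-individual QC metadata (flags precomputed upstream)."""

    individual_id: str
    flagged_problem: bool = False
    poor_wear_time: bool = False
    poor_calibration: bool = False
    interrupted: bool = False
    needs_external_calibration: bool = False
    n_errors: int = 0

    def __post_init__(self) -> None:
        if self.n_errors < 0:
            raise ValueError("n_errors must be non-negative")


@dataclass
class QCResult:
    kept: list[str]
    excluded: dict[str, list[str]] = field(default_factory=dict)
    error_threshold: float | None = None


def read_epoch_csv(path: str | Path, epoch_seconds: int, individual_id: str | None = None) -> EpochSeries:
    """Read a ``timestamp,count`` CSV onto a uniform epoch grid.

    Timestamps must be strictly increasing multiples of ``epoch_seconds``
    apart; gaps are filled with NaN so ``n_epochs`` spans the full grid.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"timestamp", "count"}.issubset(df.columns):
        raise ValueError(f"{path}: expected header columns 'timestamp,count'")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp: {exc}") from exc
    counts = pd.to_numeric(df["count"], errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(counts) & df["count"].notna().to_numpy()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed count at line {line}")
    if len(ts) == 0:
        return EpochSeries(individual_id or path.stem, pd.Timestamp(0), epoch_seconds, np.array([]))
    step = pd.Timedelta(seconds=epoch_seconds)
    deltas = ts.diff().iloc[1:]
    if (deltas <= pd.Timedelta(0)).any():
        line = int(np.flatnonzero((deltas <= pd.Timedelta(0)).to_numpy())[0]) + 3
        raise ValueError(f"{path}: timestamps not strictly increasing at line {line}")
    offsets = (ts - ts.iloc[0]) / step
    if not np.allclose(offsets, np.round(offsets)):
        raise ValueError(f"{path}: timestamps not aligned to the {epoch_seconds}-s epoch grid")
    idx = np.round(offsets).astype(int).to_numpy()
    grid = np.full(idx[-1] + 1, np.nan)
    grid[idx] = counts
    return EpochSeries(individual_id or path.stem, ts.iloc[0], epoch_seconds, grid)


def write_epoch_csv(series: EpochSeries, path: str | Path) -> None:
    """Write ``timestamp,count`` CSV; missing epochs become empty count cells."""
    counts = pd.array(series.counts, dtype="Int64")
    pd.DataFrame({"timestamp": series.timestamps, "count": counts}).to_csv(
        path, index=False, date_format="%Y-%m-%dT%H:%M:%S"
    )


def read_meta_csv(path: str | Path) -> list[IndividualMeta]:
    df = pd.read_csv(path)
    required = {"individual_id", "n_errors", *_FLAG_COLUMNS}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing metadata columns {sorted(required - set(df.columns))}")
    return [
        IndividualMeta(
            individual_id=str(row["individual_id"]),
            n_errors=int(row["n_errors"]),
            **{c: bool(row[c]) for c in _FLAG_COLUMNS},
        )
        for _, row in df.iterrows()
    ]


def qc_exclude(
    meta_table: Iterable[IndividualMeta],
    quartile_method: str = "linear",
) -> QCResult:
    """Partition individuals into kept and excluded with reasons.

    An individual is excluded when any QC flag is true, or when its
    recording-error count exceeds Q3 + 1.5*IQR of ``n_errors`` over the whole
    table (quartiles by ``quartile_method``, any method accepted by
    :func:`numpy.quantile`; default linear interpolation, i.e. type 7).
    """
    meta = list(meta_table)
    if not meta:
        raise ValueError("empty metadata table")
    ids = [m.individual_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual_id in metadata table")
    if len(meta) < 4:
        raise ValueError(
            "need >=4 individuals for the Q3+1.5*IQR error rule; "
            "filter flags manually to skip it explicitly"
        )
    errors = np.array([m.n_errors for m in meta], dtype=float)
    q1, q3 = np.quantile(errors, [0.25, 0.75], method=quartile_method)
    threshold = q3 + 1.5 * (q3 - q1)

    result = QCResult(kept=[], excluded={}, error_threshold=float(threshold))
    for m in meta:
        reasons = [c for c in _FLAG_COLUMNS if getattr(m, c)]
        if m.n_errors > threshold:
            reasons.append("n_errors_outlier")
        if reasons:
            result.excluded[m.individual_id] = reasons
        else:
            result.kept.append(m.individual_id)
    return result
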