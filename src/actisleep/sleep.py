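"""Sleep phenotypes from decoded sleep/wake sequences.

Each noon-to-noon window (so a night is never split across days) yields one
main sleep period: maximal sleep runs are merged across short non-sleep gaps,
and the merged bout with the most sleep time, provided it is long enough,
defines sleep start, sleep end and duration.  Duration counts only sleep
epochs inside the main period, so mid-night wake does not inflate it.

Per-individual phenotypes combine sleep timing averaged over valid days with
the fitted HMM emission parameters (mean and SD of log-activity in each
state), plus categorical short (<5 h) / long (>10 h) mean-duration flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hmm import HMMParams, StateSequence, SLEEP, MISSING

__all__ = ["SleepRecord", "main_sleep_periods", "phenotype_table", "write_pheno"]

SHORT_SLEEP_HOURS = 5.0
LONG_SLEEP_HOURS = 10.0

PHENO_COLUMNS = [
    "mean_act_sleep", "sd_act_sleep", "mean_act_wake", "sd_act_wake",
    "sleep_start_mean", "sleep_end_mean", "duration_mean",
    "short_sleeper", "long_sleeper", "n_valid_days",
]


@dataclass
class SleepRecord:
    """Main sleep period of one noon-to-noon day.

    ``sleep_start`` and ``sleep_end`` are hours since the window's noon
    (0-24), so end > start even when sleep crosses midnight; clock time is
    ``(value + 12) % 24``.
    """

    individual_id: str
    day_index: int
    sleep_start: float
    sleep_end: float
    duration_h: float
    valid: bool

    @property
    def sleep_start_clock(self) -> float:
        return (self.sleep_start + 12.0) % 24.0

    @property
    def sleep_end_clock(self) -> float:
        return (self.sleep_end + 12.0) % 24.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def main_sleep_periods(
    states: StateSequence,
    timestamps: pd.DatetimeIndex,
    merge_gap_min: float = 30.0,
    min_bout_min: float = 180.0,
    individual_id: str = "",
    max_missing_frac: float = 0.2,
) -> list[SleepRecord]:
    """Extract one main sleep period per noon-to-noon day.

    Sleep bouts (maximal sleep runs) separated by non-sleep gaps of at most
    ``merge_gap_min`` minutes are merged; the merged bout with the most sleep
    time, if it holds at least ``min_bout_min`` minutes of sleep, is the main
    period.  Days with no qualifying bout, or with more than
    ``max_missing_frac`` of their epochs missing (epochs outside the record
    count as missing), get ``valid=False``.
    """
    labels = states.states
    if len(timestamps) != labels.size:
        raise ValueError("timestamps and states have different lengths")
    if len(timestamps) > 1:
        steps = np.diff(timestamps.view("int64"))
        if steps.min() != steps.max():
            raise ValueError("timestamps must be on a uniform grid")
        epoch_h = steps[0] / 1e9 / 3600.0
    else:
        raise ValueError("need at least two epochs")
    epochs_per_day = int(round(24.0 / epoch_h))
    merge_gap = int(round(merge_gap_min / 60.0 / epoch_h))

    first_noon = timestamps[0].normalize() + pd.Timedelta(hours=12)
    if first_noon > timestamps[0]:
        first_noon -= pd.Timedelta(days=1)
    n_days = int(np.ceil((timestamps[-1] - first_noon) / pd.Timedelta(days=1)))

    records: list[SleepRecord] = []
    for d in range(n_days):
        w0 = first_noon + pd.Timedelta(days=d)
        off = int(round((w0 - timestamps[0]) / pd.Timedelta(hours=epoch_h)))
        idx = np.arange(off, off + epochs_per_day)
        inside = (idx >= 0) & (idx < labels.size)
        day = np.full(epochs_per_day, MISSING, dtype=np.int8)
        day[inside] = labels[idx[inside]]

        missing_frac = float(np.mean(day == MISSING))
        bouts = _runs(day == SLEEP)
        merged: list[tuple[int, int]] = []
        for b in bouts:
            if merged and b[0] - merged[-1][1] <= merge_gap:
                merged[-1] = (merged[-1][0], b[1])
            else:
                merged.append(b)

        best, best_sleep = None, 0
        for m in merged:
            n_sleep = int(np.sum(day[m[0] : m[1]] == SLEEP))
            if n_sleep > best_sleep:
                best, best_sleep = m, n_sleep

        if best is None or best_sleep * epoch_h * 60.0 < min_bout_min or missing_frac > max_missing_frac:
            records.append(SleepRecord(individual_id, d, np.nan, np.nan, np.nan, False))
        else:
            start_h = best[0] * epoch_h
            end_h = best[1] * epoch_h
            records.append(
                SleepRecord(individual_id, d, start_h, end_h, best_sleep * epoch_h, True)
            )
    return records


def phenotype_table(
    fits: Mapping[str, tuple[HMMParams, Sequence[SleepRecord]]],
    min_valid_days: int = 3,
) -> pd.DataFrame:
    """Per-individual phenotype rows from HMM fits and daily sleep records.

    Sleep-timing phenotypes are means over valid days and are set to missing
    when fewer than ``min_valid_days`` days qualify; the HMM emission
    parameters are kept regardless.  Short/long sleeper flags apply the 5 h
    and 10 h thresholds to the individual's mean duration.
    """
    rows = []
    for iid, (params, recs) in fits.items():
        valid = [r for r in recs if r.valid]
        n_valid = len(valid)
        if n_valid >= min_valid_days:
            start = float(np.mean([r.sleep_start for r in valid]))
            end = float(np.mean([r.sleep_end for r in valid]))
            dur = float(np.mean([r.duration_h for r in valid]))
            short = int(dur < SHORT_SLEEP_HOURS)
            long_ = int(dur > LONG_SLEEP_HOURS)
        else:
            start = end = dur = np.nan
            short = long_ = np.nan
        rows.append({
            "individual_id": iid,
            "mean_act_sleep": params.mu_sleep,
            "sd_act_sleep": params.sigma_sleep,
            "mean_act_wake": params.mu_wake,
            "sd_act_wake": params.sigma_wake,
            "sleep_start_mean": (start + 12.0) % 24.0 if n_valid >= min_valid_days else np.nan,
            "sleep_end_mean": (end + 12.0) % 24.0 if n_valid >= min_valid_days else np.nan,
            "duration_mean": dur,
            "short_sleeper": short,
            "long_sleeper": long_,
            "n_valid_days": n_valid,
        })
    df = pd.DataFrame(rows, columns=["individual_id", *PHENO_COLUMNS])
    if df["individual_id"].duplicated().any():
        raise ValueError("duplicate individual_id in fits")
    return df


def write_pheno(rows: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write the phenotype table as CSV (missing = NA) or PLINK .pheno.

    The PLINK dialect is whitespace-separated with FID and IID columns (both
    the individual id) followed by one column per phenotype; missing is -9.
    """
    if format == "csv":
        rows.to_csv(path, index=False, na_rep="NA")
    elif format == "plink":
        out = rows.copy()
        out.insert(0, "FID", out["individual_id"])
        out = out.rename(columns={"individual_id": "IID"})
        out = out.fillna(-9)
        out.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown phenotype format: {format!r}")
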