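"""Immobility-defined sleep scoring from PIR activity epochs.

Behaviourally-defined sleep in mice is scored as any maximal run of
immobility lasting at least 40 s (four 10 s epochs), a criterion validated
against EEG and beam-break measures.  This module converts epoch activity
into an immobility series, segments sleep bouts, and computes the standard
summaries: percent time asleep per hour / phase / day, sleep latency after
lights-on, bout counts per phase, and bout-duration histograms with bins
<=1 min, 1-10 min, 10-60 min and >60 min.

Missing epochs are conservative: they break immobility runs (a bout cannot
span unobserved time) and are excluded from time-asleep denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pir_io import AnnotatedTrace, LightSchedule, StudyDesign

__all__ = [
    "ImmobilitySeries",
    "SleepBout",
    "detect_immobility",
    "segment_sleep_bouts",
    "bouts_to_frame",
    "sleep_epoch_mask",
    "sleep_fraction_by_hour",
    "sleep_phase_summary",
    "sleep_latency",
    "count_bouts_by_phase",
    "bout_duration_histogram",
    "BIN_LABELS",
    "BIN_EDGES_S",
]

#: bout-duration bin upper edges in seconds (left-closed on the small side:
#: a 60 s bout is "<=1 min", a 600 s bout is "1-10 min", a 3600 s bout is
#: "10-60 min"); comparisons are exact on integer seconds.
BIN_EDGES_S = (60, 600, 3600)
BIN_LABELS = ("le1min", "1to10min", "10to60min", "gt60min")


@dataclass
class ImmobilitySeries:
    """Per-epoch immobility flags aligned to an annotated trace."""

    trace: AnnotatedTrace
    immobile: np.ndarray  # bool; False where mobile OR missing
    missing: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = len(self.trace)
        if len(self.immobile) != n or len(self.missing) != n:
            raise ValueError("immobility series must align with its trace")


@dataclass(frozen=True)
class SleepBout:
    """A maximal immobility run of duration >= the sleep threshold."""

    animal_id: str
    onset_index: int
    onset_time: pd.Timestamp
    duration_s: int
    onset_phase: str  # 'light' | 'dark'
    onset_day: int
    onset_zt: float

    @property
    def n_epochs(self) -> int:
        return self.duration_s // 10 if self.duration_s % 10 == 0 else -1


def detect_immobility(
    trace: AnnotatedTrace, activity_threshold: float = 0.0
) -> ImmobilitySeries:
    """Mark each epoch immobile iff activity <= ``activity_threshold``.

    The default threshold 0 treats any PIR detection within an epoch as
    mobility.  Missing epochs stay missing (neither mobile nor immobile).
    """
    if activity_threshold < 0:
        raise ValueError("activity_threshold must be >= 0")
    missing = trace.missing
    with np.errstate(invalid="ignore"):
        immobile = (trace.activity <= activity_threshold) & ~missing
    return ImmobilitySeries(trace, immobile, missing)


def _immobile_runs(immobile: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of maximal True runs."""
    if immobile.size == 0:
        return np.empty(0, int), np.empty(0, int)
    padded = np.concatenate(([False], immobile, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts, ends - starts


def segment_sleep_bouts(
    imm: ImmobilitySeries, min_duration_s: int = 40
) -> list[SleepBout]:
    """Segment maximal immobility runs of at least ``min_duration_s``.

    Runs shorter than the threshold count as wake; runs interrupted by a
    missing epoch are split at the gap.  ``min_duration_s`` must be a
    positive multiple of the epoch length (no sub-epoch interpolation).
    """
    trace = imm.trace
    step = trace.epoch_length
    if min_duration_s <= 0 or min_duration_s % step != 0:
        raise ValueError(
            f"min_duration_s must be a positive multiple of the epoch "
            f"length ({step} s); got {min_duration_s}"
        )
    min_epochs = min_duration_s // step
    starts, lengths = _immobile_runs(imm.immobile)
    keep = lengths >= min_epochs
    timestamps = trace.trace.timestamps
    bouts = []
    for s, ln in zip(starts[keep], lengths[keep]):
        bouts.append(
            SleepBout(
                animal_id=trace.animal_id,
                onset_index=int(s),
                onset_time=timestamps[s],
                duration_s=int(ln) * step,
                onset_phase="light" if trace.zt[s] < trace.schedule.light_hours else "dark",
                onset_day=int(trace.treatment_day[s]),
                onset_zt=float(trace.zt[s]),
            )
        )
    return bouts


def bouts_to_frame(bouts: list[SleepBout]) -> pd.DataFrame:
    """Tidy bout table: animal_id, onset_time, onset_day, onset_phase, onset_ZT, duration_s."""
    return pd.DataFrame(
        {
            "animal_id": [b.animal_id for b in bouts],
            "onset_time": [b.onset_time for b in bouts],
            "onset_day": [b.onset_day for b in bouts],
            "onset_phase": [b.onset_phase for b in bouts],
            "onset_ZT": [b.onset_zt for b in bouts],
            "duration_s": [b.duration_s for b in bouts],
        }
    )


def sleep_epoch_mask(bouts: list[SleepBout], trace: AnnotatedTrace) -> np.ndarray:
    """Boolean per-epoch mask: epoch lies inside a scored sleep bout."""
    asleep = np.zeros(len(trace), dtype=bool)
    step = trace.epoch_length
    for b in bouts:
        asleep[b.onset_index : b.onset_index + b.duration_s // step] = True
    return asleep


def sleep_fraction_by_hour(
    bouts: list[SleepBout], trace: AnnotatedTrace
) -> pd.DataFrame:
    """Percent of non-missing epoch time asleep, per (treatment day, ZT hour).

    A bout spanning an hour boundary contributes its overlap to each hour
    (epoch-level attribution).  Hours with no observed epochs get NaN; the
    ``coverage`` column records the non-missing fraction of each hour.
    """
    asleep = sleep_epoch_mask(bouts, trace)
    df = pd.DataFrame(
        {
            "day": trace.treatment_day,
            "ZT_hour": trace.zt_hour,
            "asleep": asleep & ~trace.missing,
            "observed": ~trace.missing,
        }
    )
    g = df.groupby(["day", "ZT_hour"], sort=True).agg(
        n_asleep=("asleep", "sum"), n_obs=("observed", "sum"), n=("observed", "size")
    )
    out = g.reset_index()
    with np.errstate(invalid="ignore"):
        out["pct_asleep"] = 100.0 * out["n_asleep"] / out["n_obs"].replace(0, np.nan)
    out["coverage"] = out["n_obs"] / out["n"]
    out.insert(0, "animal_id", trace.animal_id)
    return out[["animal_id", "day", "ZT_hour", "pct_asleep", "coverage"]]


def _window_means(hourly: pd.DataFrame, value_col: str, light_hours: float) -> pd.DataFrame:
    """Collapse an hourly (day, ZT_hour) table to whole/light/dark means."""
    hourly = hourly.copy()
    hourly["window"] = np.where(hourly["ZT_hour"] < light_hours, "light", "dark")
    rows = []
    for (animal, day), sub in hourly.groupby(["animal_id", "day"], sort=True):
        for window, expected in (("whole", 24), ("light", int(light_hours)), ("dark", 24 - int(light_hours))):
            s = sub if window == "whole" else sub[sub["window"] == window]
            vals = s[value_col].dropna()
            rows.append(
                {
                    "animal_id": animal,
                    "day": day,
                    "window": window,
                    value_col: vals.mean() if len(vals) else np.nan,
                    "coverage": len(vals) / expected,
                }
            )
    return pd.DataFrame(rows)


def sleep_phase_summary(
    hourly_sleep: pd.DataFrame, schedule: LightSchedule, design: StudyDesign
) -> pd.DataFrame:
    """Percent asleep per (animal, day) over the whole day, light and dark.

    Means of the available hourly values within each window; the coverage
    column flags windows with excluded or missing hours (< 1.0).
    """
    return _window_means(hourly_sleep, "pct_asleep", schedule.light_hours)


def sleep_latency(
    bouts: list[SleepBout], trace: AnnotatedTrace, day: int
) -> float:
    """Seconds from lights-on of ``day`` to the first sleep bout onset.

    0 if a bout is ongoing at lights-on; NaN if no bout has its onset in
    that day's light phase (and none spans lights-on).
    """
    days = trace.treatment_day
    if not np.any(days == day):
        raise ValueError(f"treatment day {day} outside trace")
    # lights-on instant of this day = first epoch with this day label
    day_start = int(np.argmax(days == day))
    step = trace.epoch_length
    light_epochs = int(round(trace.schedule.light_hours * 3600)) // step
    for b in sorted(bouts, key=lambda b: b.onset_index):
        end = b.onset_index + b.duration_s // step
        if b.onset_index <= day_start < end:
            return 0.0
        if day_start < end and b.onset_index < day_start + light_epochs and b.onset_index >= day_start:
            return float((b.onset_index - day_start) * step)
    return float("nan")


def count_bouts_by_phase(
    bouts: list[SleepBout], design: StudyDesign
) -> pd.DataFrame:
    """Bout counts per (animal, onset day, onset phase).

    Each bout is counted exactly once, in the phase and day of its onset.
    Days/phases with no bouts are absent here; callers reindex against the
    design calendar (zero, not missing).
    """
    if not bouts:
        return pd.DataFrame(columns=["animal_id", "day", "phase", "n_bouts"])
    df = bouts_to_frame(bouts)
    out = (
        df.groupby(["animal_id", "onset_day", "onset_phase"], sort=True)
        .size()
        .rename("n_bouts")
        .reset_index()
        .rename(columns={"onset_day": "day", "onset_phase": "phase"})
    )
    return out


def bout_duration_histogram(
    bouts: list[SleepBout], phase: str | None = None, day: int | None = None
) -> pd.DataFrame:
    """Bout-duration histogram over four duration bins.

    Bins on integer seconds: <=60 s; >60 and <=600 s; >600 and <=3600 s;
    >3600 s.  Percentages are of the total bout count in the selection;
    with zero bouts the counts are 0 and the percentages NaN (0/0).
    """
    sel = [
        b
        for b in bouts
        if (phase is None or b.onset_phase == phase)
        and (day is None or b.onset_day == day)
    ]
    counts = np.zeros(4, dtype=int)
    for b in sel:
        d = b.duration_s
        if d <= BIN_EDGES_S[0]:
            counts[0] += 1
        elif d <= BIN_EDGES_S[1]:
            counts[1] += 1
        elif d <= BIN_EDGES_S[2]:
            counts[2] += 1
        else:
            counts[3] += 1
    total = counts.sum()
    pct = 100.0 * counts / total if total else np.full(4, np.nan)
    return pd.DataFrame({"bin": BIN_LABELS, "count": counts, "pct": pct})
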