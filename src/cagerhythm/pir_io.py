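"""Data model and I/O for passive-infrared (PIR) home-cage activity traces.

A PIR sensor reports, for every 10 s epoch, the percentage of that epoch in
which motion was detected.  This module defines the epoch-level trace
container, the light-schedule and study-design metadata, CSV reading and
writing, and annotation of each epoch with zeitgeber time (ZT, hours since
lights-on), light/dark phase and treatment day.

Conventions
-----------
* Missing epochs are explicit: they are carried as NaN activity values and
  appear in CSV files as rows with an empty ``pct_active`` field.  Silent
  imputation is never performed.
* A treatment day runs lights-on to lights-on (ZT 0 to ZT 24), so each day
  contains its light phase followed by its dark phase, and the daily
  injection (~ZT 11.5) precedes that day's dark phase.
* Baseline calendar days carry non-positive day indices (e.g. -3..0 for a
  4-day baseline); downstream baseline collapsing averages them into the
  "day 0" reference.  Dosing days are 1..dosing_days, discontinuation days
  follow.
* Timestamps are naive local clock times (constant-lab assumption, no DST).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PIRTrace",
    "LightSchedule",
    "StudyDesign",
    "AnnotatedTrace",
    "PIRParseError",
    "read_pir_csv",
    "read_cohort_csv",
    "write_pir_csv",
    "write_cohort_csv",
    "assign_zeitgeber",
    "load_study_config",
]

SECONDS_PER_DAY = 86400


class PIRParseError(ValueError):
    """Raised when a trace CSV violates the epoch-trace contract."""


@dataclass
class PIRTrace:
    """Per-animal sequence of uniformly spaced activity epochs.

    Parameters
    ----------
    animal_id : str
        Identifier of the animal.
    start_time : datetime.datetime
        Naive local-clock timestamp of the first epoch.
    activity : numpy.ndarray
        Percent-of-epoch-active values in [0, 100]; NaN marks a missing
        epoch.  Length >= 1.
    epoch_length : int
        Epoch duration in seconds (default 10).
    """

    animal_id: str
    start_time: dt.datetime
    activity: np.ndarray
    epoch_length: int = 10

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.activity.ndim != 1 or self.activity.size < 1:
            raise ValueError("activity must be a non-empty 1-D sequence")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        finite = self.activity[~np.isnan(self.activity)]
        if np.any(np.isinf(finite)):
            raise ValueError("activity values must be finite or NaN")
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("activity values must lie in [0, 100]")

    def __len__(self) -> int:
        return self.activity.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PIRTrace):
            return NotImplemented
        return (
            self.animal_id == other.animal_id
            and self.start_time == other.start_time
            and self.epoch_length == other.epoch_length
            and len(self) == len(other)
            and bool(
                np.all(
                    (self.activity == other.activity)
                    | (np.isnan(self.activity) & np.isnan(other.activity))
                )
            )
        )

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self), freq=f"{self.epoch_length}s"
        )

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.activity)


@dataclass(frozen=True)
class LightSchedule:
    """12:12 (by default) light-dark schedule; lights-on defines ZT 0."""

    lights_on: dt.time = dt.time(5, 0)
    light_hours: float = 12.0
    dark_hours: float = 12.0
    illuminance_lux: float = 200.0

    def __post_init__(self) -> None:
        if abs(self.light_hours + self.dark_hours - 24.0) > 1e-9:
            raise ValueError("light_hours + dark_hours must equal 24")

    def zt_of(self, t: dt.datetime) -> float:
        """Zeitgeber time (hours in [0, 24)) of a clock timestamp."""
        on = t.replace(
            hour=self.lights_on.hour,
            minute=self.lights_on.minute,
            second=self.lights_on.second,
            microsecond=0,
        )
        return ((t - on).total_seconds() / 3600.0) % 24.0

    def is_light(self, zt: float | np.ndarray) -> np.ndarray:
        return np.asarray(zt) < self.light_hours


@dataclass
class Exclusion:
    """An (animal, treatment day, window) record removed from analysis."""

    animal_id: str
    day: int
    window: str  # 'whole' | 'light' | 'dark'

    def __post_init__(self) -> None:
        if self.window not in ("whole", "light", "dark"):
            raise ValueError(f"unknown exclusion window {self.window!r}")


@dataclass
class StudyDesign:
    """Group allocation and treatment-day calendar of the experiment.

    Days are counted lights-on to lights-on.  ``discontinuation_days`` may be
    a single integer or a per-animal mapping (variable-length follow-up, e.g.
    a 7-day first cohort and a 13-day second cohort).
    """

    groups: dict[str, str]
    baseline_days: int = 4
    dosing_days: int = 12
    discontinuation_days: int | dict[str, int] = 13
    injection_window: tuple[dt.time, dt.time] = (dt.time(16, 0), dt.time(17, 0))
    exclusions: list[Exclusion] = field(default_factory=list)
    start_date: dt.date | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design must assign at least one animal to a group")
        if self.baseline_days < 1:
            raise ValueError("baseline_days must be >= 1")

    def discontinuation_days_for(self, animal_id: str) -> int:
        if isinstance(self.discontinuation_days, dict):
            return int(self.discontinuation_days[animal_id])
        return int(self.discontinuation_days)

    def n_days(self, animal_id: str) -> int:
        return (
            self.baseline_days
            + self.dosing_days
            + self.discontinuation_days_for(animal_id)
        )

    def day_range(self, animal_id: str) -> range:
        """Treatment-day labels for this animal, baseline days non-positive."""
        first = 1 - self.baseline_days
        return range(first, self.dosing_days + self.discontinuation_days_for(animal_id) + 1)

    def period_of_day(self, day: int) -> str:
        if day <= 0:
            return "baseline"
        if day <= self.dosing_days:
            return "dosing"
        return "discontinuation"

    @property
    def animal_ids(self) -> list[str]:
        return sorted(self.groups)

    def is_excluded(self, animal_id: str, day: int, window: str) -> bool:
        for ex in self.exclusions:
            if ex.day == day and ex.window == window and ex.animal_id in (animal_id, "*"):
                return True
        return False


@dataclass
class AnnotatedTrace:
    """A PIRTrace with per-epoch zeitgeber time, phase and treatment day."""

    trace: PIRTrace
    zt: np.ndarray  # hours in [0, 24)
    treatment_day: np.ndarray  # int, lights-on to lights-on
    schedule: LightSchedule
    design: StudyDesign

    @property
    def animal_id(self) -> str:
        return self.trace.animal_id

    @property
    def activity(self) -> np.ndarray:
        return self.trace.activity

    @property
    def epoch_length(self) -> int:
        return self.trace.epoch_length

    @property
    def missing(self) -> np.ndarray:
        return self.trace.missing

    @property
    def is_light(self) -> np.ndarray:
        return self.zt < self.schedule.light_hours

    @property
    def phase(self) -> np.ndarray:
        return np.where(self.is_light, "light", "dark")

    @property
    def zt_hour(self) -> np.ndarray:
        return np.floor(self.zt).astype(int)

    def __len__(self) -> int:
        return len(self.trace)


# ---------------------------------------------------------------------------
# CSV I/O — long format `timestamp,animal_id,pct_active`, ISO-8601 timestamps,
# missing epochs as rows with an empty pct_active field.
# ---------------------------------------------------------------------------

def _trace_from_rows(animal_id, times, values, epoch_length, row_numbers):
    deltas = np.diff(times.astype("datetime64[s]").astype("int64"))
    step = epoch_length
    if np.any(deltas <= 0):
        bad = row_numbers[int(np.argmax(deltas <= 0)) + 1]
        raise PIRParseError(f"non-monotone timestamp at row {bad}")
    if np.any(deltas % step != 0):
        bad = row_numbers[int(np.argmax(deltas % step != 0)) + 1]
        raise PIRParseError(
            f"timestamp spacing not a multiple of {step} s at row {bad}"
        )
    n = int((times[-1] - times[0]) / np.timedelta64(step, "s")) + 1
    activity = np.full(n, np.nan)
    idx = ((times - times[0]) / np.timedelta64(step, "s")).astype(int)
    activity[idx] = values
    start = pd.Timestamp(times[0]).to_pydatetime()
    return PIRTrace(animal_id, start, activity, epoch_length)


def read_cohort_csv(path, epoch_length: int = 10) -> dict[str, PIRTrace]:
    """Read a (possibly multi-animal) long-format trace CSV.

    Returns a mapping animal_id -> PIRTrace.  Rows with an empty
    ``pct_active`` field become explicit missing epochs, as do timestamp
    gaps that are exact multiples of the epoch length.
    """
    df = pd.read_csv(path, dtype={"animal_id": str}, float_precision="round_trip")
    expected = ["timestamp", "animal_id", "pct_active"]
    if list(df.columns) != expected:
        raise PIRParseError(f"expected header {expected}, got {list(df.columns)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as err:
        raise PIRParseError(f"unparseable timestamp: {err}") from None
    vals = pd.to_numeric(df["pct_active"], errors="coerce").to_numpy()
    nonempty = df["pct_active"].notna() & (df["pct_active"].astype(str).str.strip() != "")
    bad_value = nonempty & np.isnan(vals)
    if bad_value.any():
        row = int(np.argmax(bad_value.to_numpy())) + 2  # header is row 1
        raise PIRParseError(f"malformed pct_active at row {row}")
    out_of_range = np.nan_to_num(vals, nan=50.0)
    oob = (out_of_range < 0) | (out_of_range > 100)
    if oob.any():
        row = int(np.argmax(oob)) + 2
        raise PIRParseError(f"activity outside [0, 100] at row {row}")

    traces: dict[str, PIRTrace] = {}
    row_no = np.arange(len(df)) + 2
    for animal, sub_idx in df.groupby("animal_id", sort=True).groups.items():
        sub = df.loc[sub_idx]
        traces[str(animal)] = _trace_from_rows(
            str(animal),
            sub["timestamp"].to_numpy(),
            vals[sub_idx],
            epoch_length,
            row_no[sub_idx],
        )
    if not traces:
        raise PIRParseError("no data rows")
    return traces


def read_pir_csv(path, animal_id: str | None = None, epoch_length: int = 10) -> PIRTrace:
    """Read a single animal's trace from a trace CSV.

    If the file holds several animals, ``animal_id`` selects one.
    """
    traces = read_cohort_csv(path, epoch_length=epoch_length)
    if animal_id is not None:
        if animal_id not in traces:
            raise PIRParseError(f"animal {animal_id!r} not present in {path}")
        return traces[animal_id]
    if len(traces) != 1:
        raise PIRParseError(
            f"{path} holds {len(traces)} animals; pass animal_id to select one"
        )
    return next(iter(traces.values()))


def write_cohort_csv(traces, path) -> None:
    """Write one or many traces to a long-format CSV (round-trip exact)."""
    if isinstance(traces, PIRTrace):
        traces = [traces]
    elif isinstance(traces, dict):
        traces = [traces[k] for k in sorted(traces)]
    frames = []
    for t in traces:
        t.validate()
        vals = np.char.mod("%.17g", t.activity)
        vals[t.missing] = ""
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": t.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                    "animal_id": t.animal_id,
                    "pct_active": vals,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_pir_csv(trace: PIRTrace, path) -> None:
    write_cohort_csv(trace, path)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def assign_zeitgeber(
    trace: PIRTrace, schedule: LightSchedule, design: StudyDesign
) -> AnnotatedTrace:
    """Annotate each epoch with ZT, phase and treatment day.

    ZT 0 coincides with lights-on; an epoch is in the light phase iff its
    ZT lies in [0, light_hours).  Treatment days span lights-on to lights-on;
    the first day of the trace (or of ``design.start_date`` when given) is
    the first baseline day, labelled ``1 - baseline_days``.
    """
    start = trace.start_time
    if design.start_date is not None:
        ref_date = design.start_date
    else:
        ref_date = start.date()
        if start.time() < schedule.lights_on:
            ref_date = ref_date - dt.timedelta(days=1)
    ref = dt.datetime.combine(ref_date, schedule.lights_on)
    offset0 = (start - ref).total_seconds()
    if offset0 < 0:
        raise ValueError(
            f"trace for {trace.animal_id} starts {start}, before the design "
            f"calendar reference {ref}"
        )
    sec = offset0 + np.arange(len(trace), dtype=float) * trace.epoch_length
    zt = (sec % SECONDS_PER_DAY) / 3600.0
    day_index = np.floor_divide(sec.astype(np.int64), SECONDS_PER_DAY)
    treatment_day = day_index.astype(int) + (1 - design.baseline_days)
    return AnnotatedTrace(trace, zt, treatment_day, schedule, design)


# ---------------------------------------------------------------------------
# Study config (YAML)
# ---------------------------------------------------------------------------

def _parse_time(v) -> dt.time:
    if isinstance(v, dt.time):
        return v
    if isinstance(v, int):  # YAML may read 05:00 as sexagesimal 300
        return dt.time(v // 60, v % 60)
    return dt.time.fromisoformat(str(v))


def load_study_config(path) -> tuple[LightSchedule, StudyDesign]:
    """Load schedule and design from a YAML study config.

    Expected layout::

        schedule: {lights_on: "05:00", photoperiod_h: [12, 12], lux: 200}
        design:
          groups: {m01: saline, m02: paroxetine}
          baseline_days: 4
          dosing_days: 12
          discontinuation_days: 13        # or {m01: 7, m02: 13}
          injection_window: ["16:00", "17:00"]
          exclusions: [{animal_id: "*", day: 25, window: light}]
          start_date: 2021-06-01          # optional
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "design" not in cfg:
        raise ValueError(f"{path}: study config must contain a 'design' block")
    sch = cfg.get("schedule", {})
    photo = sch.get("photoperiod_h", [12, 12])
    schedule = LightSchedule(
        lights_on=_parse_time(sch.get("lights_on", "05:00")),
        light_hours=float(photo[0]),
        dark_hours=float(photo[1]),
        illuminance_lux=float(sch.get("lux", 200)),
    )
    d = cfg["design"]
    window = d.get("injection_window", ["16:00", "17:00"])
    exclusions = [
        Exclusion(str(e["animal_id"]), int(e["day"]), str(e["window"]))
        for e in d.get("exclusions", [])
    ]
    start_date = d.get("start_date")
    if isinstance(start_date, str):
        start_date = dt.date.fromisoformat(start_date)
    disc = d.get("discontinuation_days", 13)
    if isinstance(disc, dict):
        disc = {str(k): int(v) for k, v in disc.items()}
    design = StudyDesign(
        groups={str(k): str(v) for k, v in d["groups"].items()},
        baseline_days=int(d.get("baseline_days", 4)),
        dosing_days=int(d.get("dosing_days", 12)),
        discontinuation_days=disc,
        injection_window=(_parse_time(window[0]), _parse_time(window[1])),
        exclusions=exclusions,
        start_date=start_date,
    )
    return schedule, design
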