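"""Synthetic PIR cohort generator with exact ground truth.

Simulates epoch-level (10 s) percent-active traces for a saline vs drug
home-cage study as an alternating-renewal (two-state) sleep/wake process:

* While awake, each epoch transitions into sleep with a phase-dependent
  per-epoch hazard, so wake runs are geometric with mean ``epoch / hazard``
  seconds.
* On entering sleep, a bout length is drawn from a phase-dependent mixture
  of two discretised lognormals — a brief component (including sub-40 s
  bouts, so the scorer's threshold and not the generator decides what
  counts as sleep) and a consolidated component — and held; sleeping epochs
  have activity exactly 0.
* Awake epochs draw activity from a circadian mean profile (low in the
  light phase, nocturnal with early- and late-dark-phase peaks) plus
  truncated-normal noise bounded away from 0, so an awake epoch can never
  masquerade as immobility.
* A daily injection/handling window (default ZT 11.5-12.0) forces
  wakefulness and adds a burst of activity, reproducing the activity spike
  seen at injection time.
* Treatment effects are step functions per study period: a dark-phase wake
  activity multiplier, a dark-phase sleep-hazard multiplier, and a
  dark-onset bout-duration scale multiplier.

Everything is deterministic given (parameters, design, seed), and
:func:`ground_truth_summary` returns the renewal-theory expectations the
scoring pipeline should recover.
"""

from __future__ import annotations

import datetime as dt
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pir_io import LightSchedule, PIRTrace, StudyDesign

__all__ = [
    "CircadianProfile",
    "BoutMixture",
    "TreatmentEffect",
    "SimParams",
    "CohortDataset",
    "simulate_animal",
    "simulate_cohort",
    "ground_truth_summary",
    "default_sim_params",
    "default_study_design",
    "animal_seed",
]

EPOCH_S = 10
EPOCHS_PER_DAY = 86400 // EPOCH_S


@dataclass(frozen=True)
class CircadianProfile:
    """Mean wake activity (% active) as a function of zeitgeber time.

    A phase baseline plus two Gaussian bumps in the dark phase: an
    early-dark peak (post-lights-off activity/feeding) and a late-dark peak
    near the dark-to-light transition, both characteristic of C57BL/6 mice.
    """

    light_baseline: float = 5.0
    dark_baseline: float = 28.0
    early_peak_amp: float = 38.0
    early_peak_zt: float = 13.0
    early_peak_width_h: float = 1.3
    late_peak_amp: float = 28.0
    late_peak_zt: float = 22.5
    late_peak_width_h: float = 1.2
    light_hours: float = 12.0

    def __call__(self, zt) -> np.ndarray:
        zt = np.asarray(zt, dtype=float)
        base = np.where(zt < self.light_hours, self.light_baseline, self.dark_baseline)
        out = base.astype(float)
        for amp, mu, w in (
            (self.early_peak_amp, self.early_peak_zt, self.early_peak_width_h),
            (self.late_peak_amp, self.late_peak_zt, self.late_peak_width_h),
        ):
            d = (zt - mu + 12.0) % 24.0 - 12.0  # circular distance in hours
            out = out + amp * np.exp(-0.5 * (d / w) ** 2)
        return np.clip(out, 0.0, 100.0)


@dataclass(frozen=True)
class BoutMixture:
    """Two-component lognormal sleep-bout duration mixture (seconds).

    The brief component places mass below the 40 s scoring threshold and in
    the <=1 min bin; the consolidated component populates the 1-10 and
    10-60 min bins.
    """

    brief_weight: float = 0.6
    brief_median_s: float = 25.0
    brief_sigma: float = 0.7
    long_median_s: float = 360.0
    long_sigma: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.brief_weight <= 1.0:
            raise ValueError("brief_weight must lie in [0, 1]")
        if min(self.brief_median_s, self.long_median_s) <= 0:
            raise ValueError("bout medians must be positive")


@dataclass(frozen=True)
class TreatmentEffect:
    """Per-period step multipliers; identity = no effect.

    ``bout_scale_multiplier`` rescales every dark-onset bout duration; the
    per-component multipliers compose with it and allow asymmetric shifts —
    lengthening only the consolidated component raises the 10-60 min share
    (drug-on consolidation), while lengthening only the brief component
    moves mass from the <=1 min bin into 1-10 min (post-drug
    de-fragmentation) without touching the long bins.
    """

    dark_activity_multiplier: float = 1.0
    dark_sleep_hazard_multiplier: float = 1.0
    bout_scale_multiplier: float = 1.0
    brief_bout_scale_multiplier: float = 1.0
    long_bout_scale_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for v in (
            self.dark_activity_multiplier,
            self.dark_sleep_hazard_multiplier,
            self.bout_scale_multiplier,
            self.brief_bout_scale_multiplier,
            self.long_bout_scale_multiplier,
        ):
            if v < 0:
                raise ValueError("multipliers must be >= 0")

    @property
    def brief_scale(self) -> float:
        return self.bout_scale_multiplier * self.brief_bout_scale_multiplier

    @property
    def long_scale(self) -> float:
        return self.bout_scale_multiplier * self.long_bout_scale_multiplier


@dataclass(frozen=True)
class SimParams:
    """Full generative parameter set for one treatment group."""

    profile: CircadianProfile = CircadianProfile()
    hazard: dict = field(
        default_factory=lambda: {"light": 0.03, "dark": 0.01}
    )  # per-epoch wake->sleep probability
    bouts: dict = field(
        default_factory=lambda: {
            "light": BoutMixture(
                brief_weight=0.5,
                brief_median_s=25.0,
                brief_sigma=0.7,
                long_median_s=720.0,
                long_sigma=0.7,
            ),
            "dark": BoutMixture(),
        }
    )
    injection_zt: float = 11.5
    injection_duration_h: float = 0.5
    injection_amplitude: float = 45.0
    effects: dict = field(default_factory=dict)  # period -> TreatmentEffect
    noise_sd: float = 6.0
    wake_floor: float = 0.5  # awake activity never reaches 0

    def __post_init__(self) -> None:
        for ph in ("light", "dark"):
            h = self.hazard[ph]
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"{ph} hazard must lie in [0, 1]")
        if self.wake_floor <= 0:
            raise ValueError("wake_floor must be > 0 (awake activity cannot be 0)")

    def effect(self, period: str) -> TreatmentEffect:
        return self.effects.get(period, TreatmentEffect())


@dataclass
class CohortDataset:
    """Simulated cohort: traces, design/schedule, and generative ground truth."""

    traces: dict[str, PIRTrace]
    design: StudyDesign
    schedule: LightSchedule
    group_params: dict[str, SimParams]
    master_seed: int


def default_study_design(
    n_per_group: int = 12,
    baseline_days: int = 4,
    dosing_days: int = 12,
    discontinuation_days: int = 13,
    start_date: dt.date = dt.date(2021, 6, 1),
) -> StudyDesign:
    """The study calendar: saline vs paroxetine, 4+12+13 days, n=12/group."""
    groups = {f"sal{i:02d}": "saline" for i in range(1, n_per_group + 1)}
    groups.update({f"par{i:02d}": "paroxetine" for i in range(1, n_per_group + 1)})
    return StudyDesign(
        groups=groups,
        baseline_days=baseline_days,
        dosing_days=dosing_days,
        discontinuation_days=discontinuation_days,
        start_date=start_date,
    )


def default_sim_params(group: str) -> SimParams:
    """Default generative parameters per group.

    The drug group carries dosing-period dark-activity suppression and
    sleep-hazard elevation with longer bouts, and a discontinuation-period
    bout-duration lengthening with a compensating hazard reduction (fewer,
    longer bouts at roughly unchanged total dark sleep — de-fragmentation).
    """
    if group == "saline":
        return SimParams()
    if group == "paroxetine":
        return SimParams(
            effects={
                "dosing": TreatmentEffect(
                    dark_activity_multiplier=0.55,
                    dark_sleep_hazard_multiplier=1.8,
                    long_bout_scale_multiplier=1.5,
                ),
                "discontinuation": TreatmentEffect(
                    dark_activity_multiplier=1.0,
                    dark_sleep_hazard_multiplier=0.85,
                    brief_bout_scale_multiplier=2.2,
                ),
            }
        )
    raise ValueError(f"no default parameters for group {group!r}")


def animal_seed(master_seed: int, animal_id: str) -> int:
    """Stable per-animal seed derived from (master seed, animal id)."""
    h = zlib.crc32(animal_id.encode("utf-8"))
    return int((int(master_seed) * 1_000_003 + h) % (2**31 - 1))


def _epoch_context(
    params: SimParams, design: StudyDesign, animal_id: str, light_hours: float = 12.0
):
    """Per-epoch ZT, phase, period and forced-wake (injection) arrays."""
    n_days = design.n_days(animal_id)
    n = n_days * EPOCHS_PER_DAY
    sec = np.arange(n, dtype=np.int64) * EPOCH_S
    zt = (sec % 86400) / 3600.0
    day = (sec // 86400).astype(int) + (1 - design.baseline_days)
    dark = zt >= light_hours
    period = np.where(
        day <= 0, "baseline", np.where(day <= design.dosing_days, "dosing", "discontinuation")
    )
    inj = (zt >= params.injection_zt) & (
        zt < params.injection_zt + params.injection_duration_h
    )
    return n, zt, day, dark, period, inj


def simulate_animal(
    params: SimParams,
    design: StudyDesign,
    seed: int,
    animal_id: str = "sim",
    schedule: LightSchedule | None = None,
) -> PIRTrace:
    """Simulate one animal's full-calendar PIR trace.

    Deterministic given (params, design, seed).  The trace starts at the
    lights-on instant of the first baseline day.
    """
    schedule = schedule or LightSchedule()
    rng = np.random.default_rng(seed)
    n, zt, day, dark, period, inj = _epoch_context(
        params, design, animal_id, schedule.light_hours
    )

    hazard = np.where(dark, params.hazard["dark"], params.hazard["light"]).astype(float)
    for per in ("dosing", "discontinuation"):
        eff = params.effect(per)
        m = dark & (period == per)
        hazard[m] = np.clip(hazard[m] * eff.dark_sleep_hazard_multiplier, 0.0, 1.0)
    hazard[inj] = 0.0  # handling keeps the animal awake

    u = rng.random(n)
    onset_candidates = np.flatnonzero(u < hazard)
    forced_wake = np.flatnonzero(inj)

    asleep = np.zeros(n, dtype=bool)
    i = 0
    while True:
        k = np.searchsorted(onset_candidates, i)
        if k == len(onset_candidates):
            break
        j = int(onset_candidates[k])
        ph = "dark" if dark[j] else "light"
        mix = params.bouts[ph]
        s_brief = s_long = 1.0
        if ph == "dark":
            eff = params.effect(str(period[j]))
            s_brief, s_long = eff.brief_scale, eff.long_scale
        if rng.random() < mix.brief_weight:
            d_s = rng.lognormal(math.log(mix.brief_median_s * s_brief), mix.brief_sigma)
        else:
            d_s = rng.lognormal(math.log(mix.long_median_s * s_long), mix.long_sigma)
        length = max(1, math.ceil(d_s / EPOCH_S))
        end = min(j + length, n)
        f = np.searchsorted(forced_wake, j)
        if f < len(forced_wake) and forced_wake[f] < end:
            end = int(forced_wake[f])  # injection truncates the bout
        asleep[j:end] = True
        i = max(end, j + 1)

    mean = params.profile(zt)
    for per in ("dosing", "discontinuation"):
        eff = params.effect(per)
        m = dark & (period == per)
        mean[m] = mean[m] * eff.dark_activity_multiplier
    mean = mean + np.where(inj, params.injection_amplitude, 0.0)
    activity = np.clip(rng.normal(mean, params.noise_sd), params.wake_floor, 100.0)
    activity[asleep] = 0.0

    start_date = design.start_date or dt.date(2021, 6, 1)
    start = dt.datetime.combine(start_date, schedule.lights_on)
    return PIRTrace(animal_id, start, activity, EPOCH_S)


def simulate_cohort(
    group_params: dict[str, SimParams],
    design: StudyDesign,
    seed: int,
    schedule: LightSchedule | None = None,
) -> CohortDataset:
    """Simulate every animal in the design with per-animal derived seeds."""
    schedule = schedule or LightSchedule()
    missing = sorted(set(design.groups.values()) - set(group_params))
    if missing:
        raise ValueError(f"no parameters for groups: {missing}")
    traces = {}
    for animal in design.animal_ids:
        params = group_params[design.groups[animal]]
        traces[animal] = simulate_animal(
            params, design, animal_seed(seed, animal), animal_id=animal, schedule=schedule
        )
    return CohortDataset(traces, design, schedule, dict(group_params), int(seed))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _discrete_bout_pmf(
    mix: BoutMixture, brief_scale: float = 1.0, long_scale: float = 1.0,
    tail: float = 1e-12,
):
    """PMF over bout length in epochs, k = ceil(D / 10 s), D ~ mixture."""
    comps = [
        (mix.brief_weight, mix.brief_median_s * brief_scale, mix.brief_sigma),
        (1.0 - mix.brief_weight, mix.long_median_s * long_scale, mix.long_sigma),
    ]
    kmax = 1
    for w, med, sig in comps:
        if w > 0:
            kmax = max(kmax, int(math.ceil(stats.lognorm(sig, scale=med).isf(tail) / EPOCH_S)))
    edges = np.arange(0, kmax + 1) * EPOCH_S
    pmf = np.zeros(kmax)
    for w, med, sig in comps:
        if w > 0:
            cdf = stats.lognorm(sig, scale=med).cdf(edges)
            pmf += w * np.diff(cdf)
    pmf[-1] += max(0.0, 1.0 - pmf.sum())  # fold the residual tail
    return np.arange(1, kmax + 1), pmf


def ground_truth_summary(
    params: SimParams,
    phase: str,
    period: str = "baseline",
    threshold_s: int = 40,
) -> dict:
    """Renewal-theory expectations of the generative process.

    Returns, for the given phase and study period:

    ``pct_asleep``
        Expected scored percent-asleep: only bouts >= the scoring threshold
        count as sleep, shorter bouts score as wake.
        100 * E[D; D >= tau] / (E[D] + delta/h).
    ``pct_asleep_generated``
        Same ratio counting every generated bout: 100 * E[D] / (E[D] + delta/h).
    ``bin_fractions``
        Expected bout-duration bin shares (<=1, 1-10, 10-60, >60 min),
        conditioned on D >= tau; NaN when no mass reaches the threshold.
    ``mean_wake_activity``
        Phase-mean of the circadian wake-activity profile after the
        period's activity multiplier (injection burst excluded).
    """
    if phase not in ("light", "dark"):
        raise ValueError("phase must be 'light' or 'dark'")
    eff = params.effect(period)
    h = params.hazard[phase]
    if phase == "dark":
        h = min(1.0, h * eff.dark_sleep_hazard_multiplier)
    if phase == "dark":
        k, pmf = _discrete_bout_pmf(params.bouts[phase], eff.brief_scale, eff.long_scale)
    else:
        k, pmf = _discrete_bout_pmf(params.bouts[phase])
    tau_k = threshold_s // EPOCH_S
    e_all = float(np.sum(k * pmf))  # epochs
    scored = k >= tau_k
    e_scored = float(np.sum(k[scored] * pmf[scored]))
    p_scored = float(np.sum(pmf[scored]))

    if h == 0:
        pct = pct_gen = 0.0
    else:
        cycle = e_all + 1.0 / h  # epochs per sleep/wake cycle
        pct = 100.0 * e_scored / cycle
        pct_gen = 100.0 * e_all / cycle

    if p_scored > 0:
        edges_k = np.array([6, 60, 360])  # 60 s, 600 s, 3600 s in epochs
        masses = []
        lo = tau_k
        for hi in list(edges_k) + [None]:
            sel = (k >= lo) & ((k <= hi) if hi is not None else True)
            masses.append(float(np.sum(pmf[sel])) / p_scored)
            lo = (hi + 1) if hi is not None else lo
        bin_fractions = dict(zip(("le1min", "1to10min", "10to60min", "gt60min"), masses))
    else:
        bin_fractions = {b: float("nan") for b in ("le1min", "1to10min", "10to60min", "gt60min")}

    zt_grid = (
        np.linspace(0.0, params.profile.light_hours, 720, endpoint=False)
        if phase == "light"
        else np.linspace(params.profile.light_hours, 24.0, 720, endpoint=False)
    )
    prof = params.profile(zt_grid)
    if phase == "dark":
        prof = prof * eff.dark_activity_multiplier
    return {
        "pct_asleep": pct,
        "pct_asleep_generated": pct_gen,
        "bin_fractions": bin_fractions,
        "mean_wake_activity": float(prof.mean()),
        "expected_bout_epochs": e_all,
        "expected_scored_bout_epochs": e_scored,
        "p_bout_scored": p_scored,
    }
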