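"""Cohort-level orchestration: scoring, tidy metric tables, group comparison.

Runs sleep scoring and circadian metrics over every animal, collapses the
baseline days into the "day 0" per-animal reference, applies design
exclusions, and emits the tidy per-animal-per-day MetricTable the study's
statistics are run on.  Formal inference (mixed-effects models etc.) is
deliberately left to downstream statistics packages; a permutation test on
group means is provided as the pipeline's built-in self-check.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pir_io import (
    AnnotatedTrace,
    LightSchedule,
    StudyDesign,
    assign_zeitgeber,
    load_study_config,
    read_cohort_csv,
)
from .rhythm_metrics import (
    activity_phase_summary,
    actogram_matrix,
    circadian_metrics_table,
    hourly_activity,
)
from .sleep_score import (
    BIN_LABELS,
    bout_duration_histogram,
    bouts_to_frame,
    count_bouts_by_phase,
    detect_immobility,
    segment_sleep_bouts,
    sleep_fraction_by_hour,
    sleep_latency,
    sleep_phase_summary,
)
from .synthetic_cage import CohortDataset

METRIC_COLUMNS = ["animal_id", "group", "day", "window", "metric", "value", "coverage"]

__all__ = [
    "summarize_cohort",
    "collapse_baseline",
    "permutation_group_test",
    "ComparisonResult",
    "run_pipeline",
    "METRIC_COLUMNS",
]


def _score_animal(trace: AnnotatedTrace, activity_threshold: float, min_bout_s: int):
    imm = detect_immobility(trace, activity_threshold)
    bouts = segment_sleep_bouts(imm, min_bout_s)
    hr_act = hourly_activity(trace)
    hr_slp = sleep_fraction_by_hour(bouts, trace)
    return bouts, hr_act, hr_slp


def _metric_rows(animal, group, summary, metric):
    sub = summary[summary["animal_id"] == animal]
    return pd.DataFrame(
        {
            "animal_id": animal,
            "group": group,
            "day": sub["day"],
            "window": sub["window"],
            "metric": metric,
            "value": sub[metric],
            "coverage": sub["coverage"],
        }
    )


def collapse_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Average all baseline-day rows (day <= 0) into a single day-0 row.

    Per-animal mean within (window, metric); coverage is averaged too.
    Linearity holds: the day-0 value equals the mean of the per-day values.
    """
    base = table[table["day"] <= 0]
    rest = table[table["day"] > 0]
    if base.empty:
        return table.reset_index(drop=True)
    collapsed = (
        base.groupby(["animal_id", "group", "window", "metric"], sort=False, dropna=False)
        .agg(value=("value", "mean"), coverage=("coverage", "mean"))
        .reset_index()
    )
    collapsed["day"] = 0
    out = pd.concat([collapsed[METRIC_COLUMNS], rest[METRIC_COLUMNS]], ignore_index=True)
    return out.sort_values(["animal_id", "day", "window", "metric"], kind="stable").reset_index(
        drop=True
    )


def summarize_cohort(
    cohort,
    schedule: LightSchedule | None = None,
    design: StudyDesign | None = None,
    activity_threshold: float = 0.0,
    min_bout_s: int = 40,
    collapse: bool = True,
) -> dict[str, pd.DataFrame]:
    """Score a cohort and emit tidy tables.

    ``cohort`` is a :class:`~cagerhythm.synthetic_cage.CohortDataset` or a
    mapping animal_id -> PIRTrace (then ``schedule`` and ``design`` are
    required).  Returns a dict of DataFrames:

    ``metrics``
        The MetricTable: (animal_id, group, day, window, metric, value,
        coverage) with metrics pct_active, pct_asleep, n_bouts,
        bin_pct_le1min/..., sleep_latency_s.  Baseline days collapsed into
        day 0 (unless ``collapse=False``), exclusions applied.
    ``circadian``
        IS/IV per animal per period.
    ``bouts``, ``hourly_activity``, ``hourly_sleep``
        Supporting epoch-derived tables.
    """
    if isinstance(cohort, CohortDataset):
        traces, schedule, design = cohort.traces, cohort.schedule, cohort.design
    else:
        traces = cohort
        if schedule is None or design is None:
            raise ValueError("schedule and design are required for raw trace mappings")
    unknown = sorted(set(traces) - set(design.groups))
    if unknown:
        raise ValueError(f"animals missing from design: {unknown}")

    all_rows, bout_frames, hr_act_frames, hr_slp_frames = [], [], [], []
    for animal in sorted(traces):
        group = design.groups[animal]
        ann = (
            traces[animal]
            if isinstance(traces[animal], AnnotatedTrace)
            else assign_zeitgeber(traces[animal], schedule, design)
        )
        bouts, hr_act, hr_slp = _score_animal(ann, activity_threshold, min_bout_s)
        bout_frames.append(bouts_to_frame(bouts))
        hr_act_frames.append(hr_act)
        hr_slp_frames.append(hr_slp)

        act_sum = activity_phase_summary(hr_act, design, schedule.light_hours)
        slp_sum = sleep_phase_summary(hr_slp, schedule, design)
        all_rows.append(_metric_rows(animal, group, act_sum, "pct_active"))
        all_rows.append(_metric_rows(animal, group, slp_sum, "pct_asleep"))

        days = list(design.day_range(animal))
        counts = count_bouts_by_phase(bouts, design)
        idx = pd.MultiIndex.from_product([days, ["light", "dark"]], names=["day", "phase"])
        counts = (
            counts.set_index(["day", "phase"])["n_bouts"].reindex(idx, fill_value=0).reset_index()
            if not counts.empty
            else idx.to_frame(index=False).assign(n_bouts=0)
        )
        all_rows.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    "group": group,
                    "day": counts["day"],
                    "window": counts["phase"],
                    "metric": "n_bouts",
                    "value": counts["n_bouts"].astype(float),
                    "coverage": 1.0,
                }
            )
        )

        observed_days = set(np.unique(ann.treatment_day).tolist())
        hist_rows = []
        for day in days:
            for phase in ("light", "dark"):
                hist = bout_duration_histogram(bouts, phase=phase, day=day)
                for label, pct in zip(hist["bin"], hist["pct"]):
                    hist_rows.append((day, phase, f"bin_pct_{label}", pct))
            lat = sleep_latency(bouts, ann, day) if day in observed_days else float("nan")
            hist_rows.append((day, "light", "sleep_latency_s", lat))
        hr = pd.DataFrame(hist_rows, columns=["day", "window", "metric", "value"])
        hr.insert(0, "group", group)
        hr.insert(0, "animal_id", animal)
        hr["coverage"] = 1.0
        all_rows.append(hr[METRIC_COLUMNS])

    table = (
        pd.concat(all_rows, ignore_index=True)
        if all_rows
        else pd.DataFrame(columns=METRIC_COLUMNS)
    )

    # exclusions before baseline collapse, so an excluded baseline day drops
    # out of the day-0 mean as well
    if design.exclusions and not table.empty:
        drop = np.zeros(len(table), dtype=bool)
        for ex in design.exclusions:
            hit = (table["day"] == ex.day) & (table["window"] == ex.window)
            if ex.animal_id != "*":
                hit &= table["animal_id"] == ex.animal_id
            drop |= hit.to_numpy()
        table = table[~drop]

    if collapse and not table.empty:
        table = collapse_baseline(table)

    hourly_act = (
        pd.concat(hr_act_frames, ignore_index=True) if hr_act_frames else pd.DataFrame()
    )
    circadian = (
        circadian_metrics_table(hourly_act, design) if len(hourly_act) else pd.DataFrame()
    )
    return {
        "metrics": table.reset_index(drop=True),
        "circadian": circadian,
        "bouts": pd.concat(bout_frames, ignore_index=True) if bout_frames else pd.DataFrame(),
        "hourly_activity": hourly_act,
        "hourly_sleep": (
            pd.concat(hr_slp_frames, ignore_index=True) if hr_slp_frames else pd.DataFrame()
        ),
    }


@dataclass
class ComparisonResult:
    """Permutation comparison of group means for one metric/day/window."""

    metric: str
    day: int
    window: str
    groups: tuple[str, str]
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    n_per_group: tuple[int, int]
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int


def permutation_group_test(
    table: pd.DataFrame,
    metric: str,
    day: int,
    window: str,
    n_perm: int = 999,
    seed: int = 0,
) -> ComparisonResult:
    """Two-sided permutation test on the difference of group means.

    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm), so p is in (0, 1] and
    reproducible given the seed.  Rows with undefined values are dropped;
    emptying a group is an error.
    """
    sub = table[
        (table["metric"] == metric) & (table["day"] == day) & (table["window"] == window)
    ].dropna(subset=["value"])
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {groups}")
    values = sub["value"].to_numpy(dtype=float)
    labels = (sub["group"] == groups[1]).to_numpy()
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if min(n0, n1) < 2:
        raise ValueError("need >= 2 animals per group with defined values")
    t_obs = values[labels].mean() - values[~labels].mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        t = values[perm].mean() - values[~perm].mean()
        if abs(t) >= abs(t_obs) - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return ComparisonResult(
        metric=metric,
        day=int(day),
        window=window,
        groups=(groups[0], groups[1]),
        group_means=(float(values[~labels].mean()), float(values[labels].mean())),
        group_sds=(float(values[~labels].std(ddof=1)), float(values[labels].std(ddof=1))),
        n_per_group=(n0, n1),
        observed_diff=float(t_obs),
        p_value=float(p),
        n_permutations=int(n_perm),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# End-to-end runner
# ---------------------------------------------------------------------------

def run_pipeline(config, out_dir, seed: int = 0) -> Path:
    """Load or simulate a cohort, score it, and write all report tables.

    ``config`` is a path to a YAML study config (see
    :func:`~cagerhythm.pir_io.load_study_config`) optionally containing a
    ``simulate: true`` flag and ``traces:`` path, plus optional
    ``comparisons:`` [{metric, day, window}] entries.  Outputs under
    ``out_dir``: metrics.csv, circadian.csv, bouts.csv, hourly_activity.csv,
    hourly_sleep.csv, actogram_<animal>.csv, comparisons.csv and a
    manifest.json recording inputs, seed, version and parameters.
    """
    import yaml

    config = Path(config)
    with open(config) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "design" not in cfg:
        raise ValueError(f"{config}: config must contain a 'design' block")
    schedule, design = load_study_config(config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.get("simulate"):
        from .synthetic_cage import default_sim_params, simulate_cohort

        group_params = {g: default_sim_params(g) for g in set(design.groups.values())}
        cohort = simulate_cohort(group_params, design, seed, schedule)
        traces = cohort.traces
        source = {"simulate": True, "seed": int(seed)}
    else:
        trace_path = cfg.get("traces")
        if not trace_path:
            raise ValueError(f"{config}: need either 'simulate: true' or a 'traces' path")
        trace_path = (config.parent / trace_path).resolve()
        traces = read_cohort_csv(trace_path)
        cohort = traces
        source = {"traces": str(trace_path)}

    tables = summarize_cohort(
        cohort if isinstance(cohort, CohortDataset) else traces,
        schedule=schedule,
        design=design,
    )
    for name in ("metrics", "circadian", "bouts", "hourly_activity", "hourly_sleep"):
        tables[name].to_csv(out / f"{name}.csv", index=False, float_format="%.10g")

    for animal in sorted(traces):
        ann = assign_zeitgeber(traces[animal], schedule, design)
        mat = actogram_matrix(ann, bin_width_min=60)
        pd.DataFrame(mat).to_csv(out / f"actogram_{animal}.csv", index=False, header=False,
                                 float_format="%.10g")

    comparisons = []
    for spec in cfg.get("comparisons", []):
        res = permutation_group_test(
            tables["metrics"],
            metric=spec["metric"],
            day=int(spec["day"]),
            window=spec["window"],
            n_perm=int(spec.get("n_perm", 999)),
            seed=seed,
        )
        comparisons.append(asdict(res))
    if comparisons:
        pd.json_normalize(comparisons).to_csv(out / "comparisons.csv", index=False,
                                              float_format="%.10g")

    manifest = {
        "version": __version__,
        "config": str(config),
        "seed": int(seed),
        "source": source,
        "n_animals": len(traces),
        "groups": {g: sorted(a for a, gg in design.groups.items() if gg == g)
                   for g in sorted(set(design.groups.values()))},
        "tables": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
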