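"""Activity summaries and nonparametric circadian statistics.

Computes hourly-binned activity, per-phase/day activity means, actogram
matrices and the two classical nonparametric rest-activity statistics on
hourly bins:

Interdaily stability (IS)
    IS = [N * sum_h (xbar_h - xbar)^2] / [p * sum_i (x_i - xbar)^2]

    with p = 24 hourly bins per day, N total hourly samples, xbar_h the
    mean 24 h profile.  IS is the fraction of variance explained by the
    mean daily profile: 1 for a perfectly repeated daily pattern, ~1/d for
    d days of uncorrelated noise.

Intradaily variability (IV)
    IV = [N * sum_{i=2..N} (x_i - x_{i-1})^2] / [(N-1) * sum_i (x_i - xbar)^2]

    the normalised mean squared successive difference; ~0 for a smooth
    rhythm, 2 for white noise, up to 4 for a perfectly alternating series.
    High IV indicates fragmented rest-activity behaviour.

Both are undefined (NaN) for a zero-variance series.  Missing hours are
excluded from the sums; IV successive-difference pairs spanning a missing
hour are dropped, and the pair-count denominator generalises from N-1 to
the number of valid pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pir_io import AnnotatedTrace, StudyDesign

__all__ = [
    "hourly_activity",
    "activity_phase_summary",
    "interdaily_stability",
    "intradaily_variability",
    "circadian_metrics_table",
    "actogram_matrix",
    "plot_actogram",
]


def hourly_activity(trace: AnnotatedTrace) -> pd.DataFrame:
    """Mean percent-active per (treatment day, ZT hour), with coverage.

    The mean is over non-missing epochs only; hours with zero observed
    epochs are NaN with coverage 0.
    """
    df = pd.DataFrame(
        {
            "day": trace.treatment_day,
            "ZT_hour": trace.zt_hour,
            "activity": trace.activity,
            "observed": ~trace.missing,
        }
    )
    g = df.groupby(["day", "ZT_hour"], sort=True).agg(
        pct_active=("activity", "mean"),  # pandas skips NaN
        n_obs=("observed", "sum"),
        n=("observed", "size"),
    )
    out = g.reset_index()
    out["coverage"] = out["n_obs"] / out["n"]
    out.loc[out["n_obs"] == 0, "pct_active"] = np.nan
    out.insert(0, "animal_id", trace.animal_id)
    return out[["animal_id", "day", "ZT_hour", "pct_active", "coverage"]]


def activity_phase_summary(
    hourly: pd.DataFrame, design: StudyDesign, light_hours: float = 12.0
) -> pd.DataFrame:
    """Mean activity per (animal, day) over the whole day, light and dark.

    Mirrors the sleep phase summary; window means use the available hours
    and record coverage.  Design exclusions are applied downstream, in the
    cohort table assembly, so this summary stays a pure aggregation.
    """
    from .sleep_score import _window_means

    return _window_means(hourly, "pct_active", light_hours)


def _clean(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def interdaily_stability(x, bins_per_day: int = 24) -> float:
    """IS of a time-ordered hourly series (NaN = missing hour).

    The series is assumed aligned so sample i falls in hour-of-day
    ``i % bins_per_day``.  Requires >= 2 days of data; returns NaN for a
    zero-variance (e.g. constant) series.
    """
    x = _clean(x)
    p = int(bins_per_day)
    if x.size < 2 * p:
        raise ValueError("interdaily stability needs at least two full days")
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n == 0:
        return float("nan")
    xbar = np.nanmean(x)
    sst = np.nansum((x - xbar) ** 2)
    if sst == 0:
        return float("nan")
    hour = np.arange(x.size) % p
    profile = np.full(p, np.nan)
    counts = np.zeros(p)
    for h in range(p):
        vals = x[hour == h]
        vals = vals[~np.isnan(vals)]
        counts[h] = vals.size
        if vals.size:
            profile[h] = vals.mean()
    used = ~np.isnan(profile)
    ssb = float(np.sum((profile[used] - xbar) ** 2))
    p_used = int(used.sum())
    return float(n * ssb / (p_used * sst))


def intradaily_variability(x) -> float:
    """IV of a time-ordered hourly series (NaN = missing hour).

    Successive-difference pairs are taken across day boundaries within each
    contiguous observed block; pairs spanning a missing hour are dropped.
    Returns NaN for zero variance or when no valid pair exists.
    """
    x = _clean(x)
    if x.size < 2:
        raise ValueError("intradaily variability needs >= 2 samples")
    obs = ~np.isnan(x)
    n = int(obs.sum())
    pair = obs[1:] & obs[:-1]
    m = int(pair.sum())
    if n < 2 or m == 0:
        return float("nan")
    xbar = np.nanmean(x)
    sst = np.nansum((x - xbar) ** 2)
    if sst == 0:
        return float("nan")
    d = x[1:] - x[:-1]
    ssd = float(np.sum(d[pair] ** 2))
    return float(n * ssd / (m * sst))


def _flat_hourly(hourly: pd.DataFrame, days: list[int], bins_per_day: int = 24) -> np.ndarray:
    """Day-aligned flat hourly vector for the given treatment days."""
    idx = pd.MultiIndex.from_product([days, range(bins_per_day)], names=["day", "ZT_hour"])
    s = hourly.set_index(["day", "ZT_hour"])["pct_active"].reindex(idx)
    return s.to_numpy(dtype=float)


def circadian_metrics_table(
    hourly: pd.DataFrame,
    design: StudyDesign,
    value_col: str = "pct_active",
    bins_per_day: int = 24,
) -> pd.DataFrame:
    """IS and IV per animal per period (whole / baseline / dosing / discontinuation).

    Period-restricted metrics use only the whole days of that period.
    Emits ``n_hours_used`` so low-coverage values can be screened.
    """
    hourly = hourly.rename(columns={value_col: "pct_active"})
    rows = []
    for animal, sub in hourly.groupby("animal_id", sort=True):
        all_days = sorted(sub["day"].unique())
        periods = {
            "whole": all_days,
            "baseline": [d for d in all_days if design.period_of_day(d) == "baseline"],
            "dosing": [d for d in all_days if design.period_of_day(d) == "dosing"],
            "discontinuation": [
                d for d in all_days if design.period_of_day(d) == "discontinuation"
            ],
        }
        for period, days in periods.items():
            x = _flat_hourly(sub, days, bins_per_day) if days else np.empty(0)
            n_used = int(np.sum(~np.isnan(x)))
            if x.size >= 2 * bins_per_day:
                is_v = interdaily_stability(x, bins_per_day)
                iv_v = intradaily_variability(x)
            else:
                is_v = iv_v = float("nan")
            rows.append(
                {
                    "animal_id": animal,
                    "period": period,
                    "IS": is_v,
                    "IV": iv_v,
                    "n_hours_used": n_used,
                }
            )
    return pd.DataFrame(rows)


def actogram_matrix(
    trace: AnnotatedTrace, bin_width_min: int = 60, double_plot: bool = False
) -> np.ndarray:
    """Day-by-bin activity matrix for actogram plotting.

    Rows are whole days (lights-on to lights-on), columns within-day bins
    of ``bin_width_min`` minutes (must divide 24 h).  With ``double_plot``
    each row shows 48 h: day d followed by day d+1, the last row's right
    half NaN.
    """
    if (24 * 60) % bin_width_min != 0:
        raise ValueError(f"bin width {bin_width_min} min does not divide 24 h")
    bins_per_day = (24 * 60) // bin_width_min
    days = trace.treatment_day
    uniq = np.unique(days)
    # keep whole days only
    step = trace.epoch_length
    epochs_per_day = 86400 // step
    whole = [d for d in uniq if np.sum(days == d) == epochs_per_day]
    mat = np.full((len(whole), bins_per_day), np.nan)
    col = (trace.zt * 60 / bin_width_min).astype(int)
    for r, d in enumerate(whole):
        sel = days == d
        df = pd.DataFrame({"col": col[sel], "v": trace.activity[sel]})
        means = df.groupby("col")["v"].mean()
        mat[r, means.index.to_numpy()] = means.to_numpy()
    if double_plot:
        right = np.vstack([mat[1:], np.full((1, bins_per_day), np.nan)])
        mat = np.hstack([mat, right])
    return mat


def plot_actogram(mat: np.ndarray, ax=None, **imshow_kw):
    """Render an actogram matrix as an image (thin, non-contractual layer)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * max(mat.shape[0], 4) + 1))
    im = ax.imshow(mat, aspect="auto", interpolation="nearest", cmap="Greys", **imshow_kw)
    ax.set_xlabel("zeitgeber time (bins)")
    ax.set_ylabel("day")
    return im
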