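"""Seizure-like episode scoring from 10 Hz larval position tracking.

Larvae in 7 x 7 mm wells are tracked at 10 Hz under illuminated and then
dark conditions.  Locomotion is summarised as the total path length in
non-overlapping 1-second windows, and a "seizure-like episode" is a window
whose distance exceeds a large-movement threshold calibrated empirically:
the distance exceeded in only 0.1% of windows pooled across wild-type
vehicle-treated larvae.  Over a 15-minute recording (900 windows) an
untreated wild-type larva is therefore expected to produce slightly less
than one episode; elevated episode rates in other genotype/treatment
groups quantify seizure susceptibility.

Group effects are assessed per phase with an ANOVA on episode rates,
blocking on the experimental replicate, with Benjamini-Hochberg control of
the false discovery rate across measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "window_distances",
    "calibrate_threshold",
    "count_episodes",
    "bout_speed",
    "group_compare",
]

TRACK_COLUMNS = ("larva_id", "time_s", "x_mm", "y_mm")


def _check_track(track: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    return track


def window_distances(
    track: pd.DataFrame,
    window_s: float = 1.0,
    max_gap_s: float = 0.5,
) -> pd.DataFrame:
    """Total path length per larva in non-overlapping windows.

    Windows are anchored at each larva's recording start; the distance of a
    window is the sum of successive Euclidean displacements whose starting
    sample falls inside it, and a trailing partial window is dropped.  Gaps
    in the time stamps up to ``max_gap_s`` are bridged linearly (the
    straight-line displacement across the gap counts toward the window);
    windows touched by a longer dropout are dropped.

    Returns a table with columns larva_id, window_index, distance_mm and
    any constant per-larva label columns (genotype, treatment, phase, ...)
    present in the input, carried through per window.
    """
    _check_track(track)
    rows = []
    label_cols = [
        c for c in track.columns
        if c not in ("time_s", "x_mm", "y_mm") and c != "larva_id"
    ]
    group_keys = ["larva_id"] + (["phase"] if "phase" in track.columns else [])
    for keys, sub in track.groupby(group_keys, sort=False):
        sub = sub.sort_values("time_s")
        t = sub["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("track with a single sample cannot form a window")
        xy = sub[["x_mm", "y_mm"]].to_numpy(dtype=float)
        t0 = t[0]
        steps = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
        gaps = np.diff(t)
        widx = np.floor((t[:-1] - t0) / window_s).astype(int)
        n_windows = int(np.floor((t[-1] - t0 + np.median(gaps)) / window_s + 1e-9))
        if n_windows < 1:
            raise ValueError("track shorter than one window")
        dist = np.zeros(n_windows)
        dropped = np.zeros(n_windows, dtype=bool)
        ok = widx < n_windows
        np.add.at(dist, widx[ok], steps[ok])
        long_gap = gaps > max_gap_s
        for wi in np.unique(widx[ok & long_gap]):
            dropped[wi] = True
        labels = {c: sub[c].iloc[0] for c in label_cols}
        if not isinstance(keys, tuple):
            keys = (keys,)
        for wi in range(n_windows):
            if dropped[wi]:
                continue
            rows.append(
                {"larva_id": keys[0], "window_index": wi,
                 "distance_mm": dist[wi], **labels}
            )
    return pd.DataFrame(rows)


def calibrate_threshold(
    calib_windows: pd.DataFrame | np.ndarray,
    exceed_frac: float = 0.001,
) -> float:
    """Large-movement threshold from pooled calibration window distances.

    The threshold is the empirical ``1 - exceed_frac`` quantile of the
    pooled distances, defined as an order statistic: with ``n`` pooled
    windows, exactly ``floor(exceed_frac * n)`` of them lie strictly above
    the returned value (fewer under ties), so the calibration-pool
    exceedance fraction is at most ``exceed_frac`` by construction.

    Calibration is intended to pool all wild-type vehicle-treated larvae;
    the caller selects that subset.
    """
    if isinstance(calib_windows, pd.DataFrame):
        d = calib_windows["distance_mm"].to_numpy(dtype=float)
    else:
        d = np.asarray(calib_windows, dtype=float)
    n = d.size
    if n == 0:
        raise ValueError("empty calibration pool")
    if not 0.0 < exceed_frac < 1.0:
        raise ValueError("exceed_frac must be in (0, 1)")
    if n < 1.0 / exceed_frac:
        warnings.warn(
            f"calibration pool of {n} windows is smaller than 1/exceed_frac; "
            "the quantile estimate is unstable"
        )
    c = int(np.floor(exceed_frac * n))  # allowed exceedance count
    s = np.sort(d)
    return float(s[n - c - 1]) if c < n else float(s[0])


def count_episodes(
    windows: pd.DataFrame,
    threshold_mm: float,
    window_s: float = 1.0,
) -> pd.DataFrame:
    """Seizure-like episode counts and rates per larva (and phase).

    An episode is a window with distance strictly above ``threshold_mm``.
    Returns one row per larva per phase with n_windows, n_episodes and
    episodes_per_min (= episodes / recorded minutes).
    """
    keys = ["larva_id"] + (["phase"] if "phase" in windows.columns else [])
    label_cols = [
        c for c in windows.columns
        if c not in keys + ["window_index", "distance_mm"]
    ]
    out = []
    for key_vals, sub in windows.groupby(keys, sort=False):
        n_win = len(sub)
        n_ep = int((sub["distance_mm"] > threshold_mm).sum())
        minutes = n_win * window_s / 60.0
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        row.update({c: sub[c].iloc[0] for c in label_cols})
        row.update(
            {"n_windows": n_win, "n_episodes": n_ep,
             "episodes_per_min": n_ep / minutes}
        )
        out.append(row)
    return pd.DataFrame(out)


def bout_speed(
    track: pd.DataFrame,
    movement_threshold_mm_s: float = 0.5,
) -> float:
    """Mean instantaneous speed (mm/s) over frames classified as moving.

    Frames whose speed exceeds ``movement_threshold_mm_s`` count as
    movement; if the larva never moves the result is NaN (absent), which
    downstream statistics must not conflate with a true zero speed.
    """
    _check_track(track)
    sub = track.sort_values("time_s")
    t = sub["time_s"].to_numpy(dtype=float)
    xy = sub[["x_mm", "y_mm"]].to_numpy(dtype=float)
    dt = np.diff(t)
    speed = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1])) / dt
    moving = speed > movement_threshold_mm_s
    if not moving.any():
        return float("nan")
    return float(speed[moving].mean())


def group_compare(
    results: pd.DataFrame,
    value_col: str = "episodes_per_min",
    group_col: str = "genotype",
    replicate_col: str | None = "replicate",
    measure_cols: tuple[str, ...] = ("phase",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genotype main-effect tests per measure, with replicate blocking and BH.

    For each combination of ``measure_cols`` values (e.g. each light phase,
    or phase x treatment), fits ``value ~ C(group) + C(replicate)`` by OLS
    and reports the ANOVA main effect of group; the replicate term blocks
    on the experiment and is dropped automatically when only one replicate
    is present.  p-values are Benjamini-Hochberg corrected across the
    measures.  Groups with fewer than 2 larvae are excluded with a warning.

    Returns one row per measure with the F statistic, raw and BH-corrected
    p, significance at ``alpha``, and per-group mean/sd/n.
    """
    df = results.copy()
    if group_col not in df.columns:
        raise ValueError(f"missing group column {group_col!r}")
    measure_cols = tuple(c for c in measure_cols if c in df.columns)
    rows = []
    grouper = df.groupby(list(measure_cols), sort=True) if measure_cols else [((), df)]
    for mvals, sub in grouper:
        if not isinstance(mvals, tuple):
            mvals = (mvals,)
        counts = sub.groupby(group_col)[value_col].count()
        small = counts[counts < 2].index.tolist()
        if small:
            warnings.warn(f"excluding group(s) with n < 2: {small}")
            sub = sub[~sub[group_col].isin(small)]
        if sub[group_col].nunique() < 2:
            raise ValueError("need at least 2 groups with n >= 2 to compare")
        sub = sub.dropna(subset=[value_col])
        formula = f"{value_col} ~ C({group_col})"
        if replicate_col and replicate_col in sub.columns and sub[replicate_col].nunique() > 1:
            formula += f" + C({replicate_col})"
        fit = smf.ols(formula, data=sub).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        eff = table.loc[f"C({group_col})"]
        stats_by_group = sub.groupby(group_col)[value_col].agg(["mean", "std", "count"])
        row = dict(zip(measure_cols, mvals))
        row.update(
            {"F": float(eff["F"]), "p": float(eff["PR(>F)"]),
             "df_num": float(eff["df"])}
        )
        for g, s in stats_by_group.iterrows():
            row[f"mean_{g}"] = float(s["mean"])
            row[f"sd_{g}"] = float(s["std"]) if s["count"] > 1 else 0.0
            row[f"n_{g}"] = int(s["count"])
        rows.append(row)
    out = pd.DataFrame(rows)
    reject, p_bh, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["p_bh"] = p_bh
    out["significant"] = reject
    return out
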