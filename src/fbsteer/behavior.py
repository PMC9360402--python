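"""Trajectory analysis for wind-tunnel walking assays.

Operates on long-format track tables (columns ``fly, trial, condition, t,
x, y, orientation``; uniform sampling, 50 Hz in the real assay) and applies
the same pipeline to measured and simulated cohorts:

1. zero-phase 2-pole Butterworth low-pass at 2.5 Hz on x, y and unwrapped
   orientation;
2. per-sample kinematics -- groundspeed (mm/s), upwind velocity (Delta-y
   rate), absolute angular velocity (deg/s), curvature (angular velocity /
   groundspeed, deg/mm) -- with samples below 1 mm/s excluded from
   time-averaged parameters;
3. windowed per-fly means, baseline subtraction, and probability of
   movement;
4. trial/fly exclusions (path length, trial counts, wall proximity,
   orientation sample counts);
5. circular summaries: orientation histograms, the orientation index
   (singular-value ratio of the polar histogram) with its preferred
   direction, and upwind displacement after stimulus offset;
6. nonparametric group statistics with Bonferroni correction.

Orientation convention matches the simulator: degrees, 0 = upwind = +y,
increasing toward +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "AnalysisWindows", "lowpass", "kinematics", "pmove", "window_mean",
    "window_delta", "exclusions", "orientation_samples",
    "orientation_histogram", "orientation_index", "upwind_displacement",
    "signed_rank", "rank_sum", "bonferroni_alpha", "group_stats",
    "rayleigh_test", "circ_std_deg", "circ_mean_deg", "display_flags",
]

MOVE_THRESHOLD = 1.0  # mm/s; slower samples are excluded from averages

_TRACK_KEYS = ["fly", "trial"]


# --------------------------------------------------------------------------
# analysis windows
# --------------------------------------------------------------------------

@dataclass
class AnalysisWindows:
    """Named time windows (seconds) used for behavioral quantification.

    ``from_trial`` builds the standard layout for a trial with the given
    stimulus ON/OFF times: baseline 10-25 s after trial start, upwind
    window 0-5 s from ON (0-10 s for FB lines), groundspeed and curvature
    2-5 s from ON, ON curvature 0-1 s, OFF curvature 0-2 s after OFF,
    pmove 0-5 s from ON, place preference ON+7.5 s to OFF+2.5 s, and the
    2-6 s from ON window used for orientation-index analysis.
    """

    stim_on: float
    stim_off: float
    windows: dict = field(default_factory=dict)

    @classmethod
    def from_trial(cls, stim_on: float = 30.0, stim_off: float = 40.0,
                   fb_line: bool = False, baseline: tuple[float, float] | None = None
                   ) -> "AnalysisWindows":
        on, off = stim_on, stim_off
        w = {
            "baseline": baseline if baseline is not None else (10.0, 25.0),
            "baseline_place": (on - 5.0, on),
            "upwind": (on, on + (10.0 if fb_line else 5.0)),
            "upwind_off": (off, off + 2.0),
            "groundspeed": (on + 2.0, on + 5.0),
            "groundspeed_off": (off, off + 2.0),
            "angv": (on + 2.0, on + 5.0),
            "angv_on": (on, on + 1.0),
            "angv_off": (off, off + 2.0),
            "curvature": (on + 2.0, on + 5.0),
            "curvature_on": (on, on + 1.0),
            "curvature_off": (off, off + 2.0),
            "pmove": (on, on + 5.0),
            "place_pref": (on + 7.5, off + 2.5),
            "orientation": (on + 2.0, on + 6.0),
        }
        return cls(stim_on=on, stim_off=off, windows=w)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.windows[name]


# --------------------------------------------------------------------------
# filtering and kinematics
# --------------------------------------------------------------------------

def _frame_dt(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("track must be uniformly sampled")
    return float(dt[0])


def lowpass(tracks: pd.DataFrame, cutoff: float = 2.5, order: int = 2
            ) -> pd.DataFrame:
    """Zero-phase Butterworth low-pass of x, y and unwrapped orientation.

    Filtering is applied per trial; orientation is unwrapped (180 deg jump
    threshold) before filtering and returned unwrapped, which downstream
    differencing expects.  Raises for tracks too short to filter or
    sampled below twice the cutoff.
    """
    out = []
    for _, g in tracks.groupby(_TRACK_KEYS, sort=False):
        g = g.sort_values("t").copy()
        fs = 1.0 / _frame_dt(g["t"].to_numpy())
        if fs <= 2.0 * cutoff:
            raise ValueError(f"sampling rate {fs:.1f} Hz too low for "
                             f"{cutoff} Hz cutoff")
        sos = signal.butter(order, cutoff, fs=fs, output="sos")
        if len(g) <= 3 * (2 * order + 1):
            raise ValueError("track too short to filter")
        for col in ("x", "y"):
            g[col] = signal.sosfiltfilt(sos, g[col].to_numpy())
        unwrapped = np.unwrap(g["orientation"].to_numpy(), period=360.0)
        g["orientation"] = signal.sosfiltfilt(sos, unwrapped)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def kinematics(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-sample groundspeed, upwind velocity, angular velocity, curvature.

    Velocities are first differences divided by the frame interval; the
    first sample of each trial is undefined (NaN).  Curvature is angular
    velocity over groundspeed (deg/mm) and is NaN where groundspeed is
    zero.  Adds a boolean ``moving`` column (groundspeed > 1 mm/s) used by
    all time-averaged quantities.
    """
    out = []
    for _, g in tracks.groupby(_TRACK_KEYS, sort=False):
        g = g.sort_values("t").copy()
        dt = _frame_dt(g["t"].to_numpy())
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        ori = np.unwrap(g["orientation"].to_numpy(), period=360.0)
        nan = np.array([np.nan])
        gs = np.concatenate([nan, np.hypot(np.diff(x), np.diff(y)) / dt])
        g["groundspeed"] = gs
        g["upwind_velocity"] = np.concatenate([nan, np.diff(y) / dt])
        angv = np.concatenate([nan, np.abs(np.diff(ori)) / dt])
        g["angular_velocity"] = angv
        with np.errstate(divide="ignore", invalid="ignore"):
            curv = np.where(gs > 0, angv / gs, np.nan)
        g["curvature"] = curv
        g["moving"] = gs > MOVE_THRESHOLD
        out.append(g)
    return pd.concat(out, ignore_index=True)


def _in_window(df: pd.DataFrame, window: tuple[float, float]) -> pd.Series:
    return (df["t"] >= window[0]) & (df["t"] < window[1])


def pmove(tracks: pd.DataFrame, window: tuple[float, float]) -> pd.Series:
    """Per-fly probability of groundspeed exceeding 1 mm/s in the window."""
    sel = tracks[_in_window(tracks, window) & tracks["groundspeed"].notna()]
    if sel.empty:
        raise ValueError("empty analysis window")
    return sel.groupby("fly")["moving"].mean()


def window_mean(tracks: pd.DataFrame, window: tuple[float, float],
                metric: str) -> pd.Series:
    """Per-fly mean of a kinematic metric over moving samples in a window."""
    sel = tracks[_in_window(tracks, window) & tracks["moving"]]
    if sel.empty:
        raise ValueError("no moving samples in analysis window")
    return sel.groupby("fly")[metric].mean()


def window_delta(tracks: pd.DataFrame, windows: AnalysisWindows,
                 metrics: dict[str, str] | None = None) -> pd.DataFrame:
    """Baseline-subtracted per-fly windowed means.

    ``metrics`` maps metric column -> window name (defaults: upwind
    velocity, groundspeed, angular velocity and curvature in their
    standard windows).  Returns a fly x metric table of
    mean(response window) - mean(baseline window).
    """
    if metrics is None:
        metrics = {"upwind_velocity": "upwind", "groundspeed": "groundspeed",
                   "angular_velocity": "angv", "curvature": "curvature"}
    base_win = windows["baseline"]
    cols = {}
    for metric, wname in metrics.items():
        resp = window_mean(tracks, windows[wname], metric)
        base = window_mean(tracks, base_win, metric)
        cols[metric] = resp - base
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# exclusions
# --------------------------------------------------------------------------

def exclusions(tracks: pd.DataFrame, min_path_mm: float = 25.0,
               min_trials: int = 5) -> pd.DataFrame:
    """Trial- and fly-level exclusions.

    Removes trials where the fly moved less than ``min_path_mm`` total path
    length, then flies left with fewer than ``min_trials`` trials.  Wall
    and movement sample filters for orientation analyses are applied by
    :func:`orientation_samples`.
    """
    def path_len(g):
        return float(np.hypot(np.diff(g["x"]), np.diff(g["y"])).sum())

    lens = tracks.groupby(_TRACK_KEYS, sort=False).apply(path_len,
                                                         include_groups=False)
    keep = lens[lens >= min_path_mm].index
    idx = pd.MultiIndex.from_frame(tracks[_TRACK_KEYS])
    out = tracks[idx.isin(keep)]
    counts = out.groupby("fly")["trial"].nunique()
    good_flies = counts[counts >= min_trials].index
    return out[out["fly"].isin(good_flies)].reset_index(drop=True)


def orientation_samples(tracks: pd.DataFrame,
                        window: tuple[float, float] | None = None,
                        arena: dict | None = None,
                        wall_margin: float = 3.0,
                        min_trials: int | None = None,
                        min_samples: int | None = None) -> pd.DataFrame:
    """Orientation samples retained for circular analyses.

    Keeps moving samples (groundspeed > 1 mm/s) inside the window, drops
    samples within ``wall_margin`` mm of the arena walls when ``arena``
    bounds (``{"x": (lo, hi), "y": (lo, hi)}``) are given, and optionally
    excludes flies with too few trials or too few retained samples (the
    stochastic-labeling analysis uses 15 trials / 2000 samples).
    Returns rows of ``fly, trial, orientation``.
    """
    sel = tracks[tracks["moving"]] if "moving" in tracks else tracks
    if window is not None:
        sel = sel[_in_window(sel, window)]
    if arena is not None:
        (x0, x1), (y0, y1) = arena["x"], arena["y"]
        m = ((sel["x"] >= x0 + wall_margin) & (sel["x"] <= x1 - wall_margin) &
             (sel["y"] >= y0 + wall_margin) & (sel["y"] <= y1 - wall_margin))
        sel = sel[m]
    if min_trials is not None:
        counts = sel.groupby("fly")["trial"].nunique()
        sel = sel[sel["fly"].isin(counts[counts >= min_trials].index)]
    if min_samples is not None:
        counts = sel.groupby("fly")["orientation"].size()
        sel = sel[sel["fly"].isin(counts[counts >= min_samples].index)]
    return sel[["fly", "trial", "orientation"]].reset_index(drop=True)


# --------------------------------------------------------------------------
# circular statistics
# --------------------------------------------------------------------------

def orientation_histogram(orientations, bin_width: float = 10.0):
    """Normalized circular histogram of orientations.

    Returns ``(probabilities, bin_centers)``; probabilities sum to 1.
    """
    ori = np.asarray(orientations, dtype=float) % 360.0
    if ori.size < 1:
        raise ValueError("no orientation samples to histogram")
    nbins = int(round(360.0 / bin_width))
    counts, edges = np.histogram(ori, bins=nbins, range=(0.0, 360.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts / counts.sum(), centers


def orientation_index(orientations, bin_width: float = 10.0,
                      method: str = "histogram"):
    """Directedness of the orientation distribution.

    The orientation histogram is drawn as a polar curve -- one point per
    bin at radius equal to the bin probability -- and decomposed with an
    SVD; the index is the ratio of the first to the second singular value
    (spread along the major axis over spread along the minor axis).  An
    isotropic distribution gives a circle (index ~ 1); a unimodal
    distribution gives an elongated lobe along its preferred direction.
    The preferred direction is the major-axis direction pointing into the
    half-plane holding more histogram mass.  ``method="samples"`` applies
    the same decomposition to the unit-vector embedded raw samples
    (historical variant; its major axis is transverse for unimodal data).

    Returns ``(index, preferred_direction_deg)``; a degenerate
    distribution (all mass in one bin) gives ``index = inf``.
    """
    ori = np.asarray(orientations, dtype=float)
    if np.unique(ori % 360.0).size < 2:
        if ori.size < 1:
            raise ValueError("no orientation samples")
        return np.inf, float(ori.flat[0] % 360.0)
    if method == "histogram":
        prob, centers = orientation_histogram(ori, bin_width)
        rad = np.deg2rad(centers)
        pts = np.stack([prob * np.sin(rad), prob * np.cos(rad)])  # (2, nbins)
        weights = prob
        unit = np.stack([np.sin(rad), np.cos(rad)])
    elif method == "samples":
        rad = np.deg2rad(ori)
        unit = np.stack([np.sin(rad), np.cos(rad)])
        pts = unit - unit.mean(axis=1, keepdims=True)
        weights = np.full(ori.size, 1.0 / ori.size)
    else:
        raise ValueError("method must be 'histogram' or 'samples'")
    u_mat, s, _ = np.linalg.svd(pts, full_matrices=False)
    index = np.inf if s[1] == 0 else float(s[0] / s[1])
    axis = u_mat[:, 0]
    # resolve the sign of the major axis toward the heavier half-plane
    proj = axis @ unit
    mass = float(np.sum(weights * np.sign(proj)))
    if mass < 0:
        axis = -axis
    preferred = float(np.rad2deg(np.arctan2(axis[0], axis[1])) % 360.0)
    return index, preferred


def circ_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, result in [0, 360)."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.rad2deg(np.arctan2(np.sin(rad).mean(),
                                       np.cos(rad).mean())) % 360.0)


def circ_std_deg(angles_deg) -> float:
    """Circular standard deviation in degrees."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.rad2deg(stats.circstd(rad, high=np.pi, low=-np.pi)))


def rayleigh_test(angles_deg):
    """Rayleigh test for a single-mode concentration of circular data.

    Returns ``(R_bar, p)`` with the standard small-sample corrected
    p-value; p > alpha means the directions are indistinguishable from
    uniform (no common mode).
    """
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = rad.size
    r = np.hypot(np.sin(rad).mean(), np.cos(rad).mean())
    z = n * r * r
    p = np.exp(-z) * (1 + (2 * z - z * z) / (4 * n)
                      - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4)
                      / (288 * n * n))
    return float(r), float(min(max(p, 0.0), 1.0))


# --------------------------------------------------------------------------
# displacement and group statistics
# --------------------------------------------------------------------------

def upwind_displacement(tracks: pd.DataFrame, t_off: float) -> pd.DataFrame:
    """Mean upwind displacement relative to the position at stimulus OFF.

    For each fly, ``y(t) - y(t_off)`` is averaged across trials for
    t >= t_off; the returned table has one row per time point with the
    per-fly mean series in columns and the cross-fly mean in ``mean``.
    """
    series = {}
    for (f, tr), g in tracks.groupby(_TRACK_KEYS, sort=False):
        g = g.sort_values("t")
        tt = g["t"].to_numpy()
        i0 = int(np.searchsorted(tt, t_off))
        if i0 >= len(tt):
            continue
        rel = g["y"].to_numpy()[i0:] - g["y"].to_numpy()[i0]
        series.setdefault(f, []).append(pd.Series(rel, index=np.round(
            tt[i0:] - tt[i0], 9)))
    per_fly = {f: pd.concat(s, axis=1).mean(axis=1) for f, s in series.items()}
    out = pd.DataFrame(per_fly)
    out["mean"] = out.mean(axis=1)
    out.index.name = "t_after_off"
    return out


def signed_rank(values, baseline=None):
    """Two-sided Wilcoxon signed-rank test of paired per-fly values."""
    values = np.asarray(values, dtype=float)
    diff = values if baseline is None else values - np.asarray(baseline, float)
    if np.allclose(diff, 0):
        return 0.0, 1.0
    res = stats.wilcoxon(diff, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def rank_sum(a, b):
    """Two-sided Mann-Whitney U test between independent groups."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(alpha: float = 0.05, n_comparisons: int = 1) -> float:
    return alpha / n_comparisons


def display_flags(metric: str, delta: float, angular_velocity: float | None = None,
                  groundspeed: float | None = None) -> bool:
    """Whether a significant effect should be displayed.

    Small upwind-velocity increases (< 1 mm/s) are suppressed, as are
    curvature increases when angular velocity < 50 deg/s and groundspeed
    < 4 mm/s (such increases reflect slowing, not search).
    """
    if metric == "upwind_velocity":
        return not (0.0 < delta < 1.0)
    if metric in ("curvature", "curvature_on", "curvature_off"):
        if angular_velocity is not None and groundspeed is not None:
            return not (angular_velocity < 50.0 and groundspeed < 4.0)
    return True


def group_stats(a, b=None, paired: bool = False, alpha: float = 0.05,
                n_comparisons: int = 1, test: str | None = None) -> dict:
    """Nonparametric comparison with Bonferroni-adjusted significance.

    Within-fly comparisons against baseline use the signed-rank test
    (``paired=True``); between-genotype comparisons of baseline-subtracted
    values use the rank-sum test.  ``test="ttest"`` selects the two-sided
    t-test used for upwind-orientation probability comparisons.  Requires
    at least 3 flies per group.
    """
    a = np.asarray(a, dtype=float)
    if a.size < 3 or (b is not None and np.asarray(b).size < 3):
        raise ValueError("need at least 3 flies per group")
    if test == "ttest":
        if paired:
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif paired:
        statistic, p = signed_rank(a, b)
    else:
        if b is None:
            raise ValueError("unpaired comparison needs two groups")
        statistic, p = rank_sum(a, b)
    adj = bonferroni_alpha(alpha, n_comparisons)
    return {"statistic": statistic, "p": p, "alpha_adjusted": adj,
            "significant": bool(p < adj), "n_comparisons": n_comparisons}
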