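"""Two-channel ROI fluorescence to joint-angle tuning summaries.

The processing chain mirrors ratiometric calcium imaging practice: the
GCaMP/tdTomato ratio cancels shared gain fluctuations (vertical motion of
the nerve cord under the objective); the ratio is z-scored against a
baseline built from the 10% smallest ratio values of the trial; the
z-scored trace is upsampled from the imaging volume rate (8.26 Hz by
default) to the leg-tracking rate (300 Hz) with a natural cubic spline and
low-pass filtered with a 0.2 s moving average. Tuning is then summarized
as binned activity against joint angles, per fly and pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import gaussian_kde

from ._errors import DegenerateBaselineError


@dataclass
class CalciumSession:
    """Two-channel fluorescence at volume rate aligned to angles at
    tracking rate."""

    gcamp: np.ndarray            # (n_vol,)
    tdtom: np.ndarray            # (n_vol,)
    volume_rate: float
    tracking_rate: float
    angles: dict                 # name -> (n_frames,) deg
    mask: Optional[np.ndarray] = None      # (n_frames,) True = excluded
    behavior: Optional[np.ndarray] = None  # (n_frames,) labels
    fly_id: str = ""
    trial_id: str = ""

    def __post_init__(self):
        if len(self.gcamp) != len(self.tdtom):
            raise ValueError("channel lengths differ")
        if self.volume_rate <= 0 or self.tracking_rate <= 0:
            raise ValueError("rates must be positive")
        n = self.n_frames
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        if len(self.mask) != n:
            raise ValueError("mask length must match tracking frames")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.angles.values())))


def ratio_zscore(
    gcamp: np.ndarray, tdtom: np.ndarray, baseline_fraction: float = 0.10
) -> np.ndarray:
    """z-scored GCaMP/tdTomato ratio at volume rate.

    The baseline is the ceil(baseline_fraction * n) smallest ratio values
    (ties resolved by stable sort order); z = (r - mean(B)) / sd(B) with
    the sample SD (ddof=1).
    """
    g = np.asarray(gcamp, dtype=float)
    t = np.asarray(tdtom, dtype=float)
    if len(g) < 10:
        raise ValueError("need at least 10 volume frames")
    if np.any(t <= 0):
        raise ValueError("tdTomato trace must be strictly positive")
    r = g / t
    k = math.ceil(baseline_fraction * len(r))
    baseline = r[np.argsort(r, kind="stable")[:k]]
    mu = baseline.mean()
    sd = baseline.std(ddof=1) if k > 1 else 0.0
    if sd == 0:
        raise DegenerateBaselineError(
            "baseline ratio values are constant; z-score undefined"
        )
    return (r - mu) / sd


def upsample_filter(
    z: np.ndarray,
    volume_rate: float = 8.26,
    tracking_rate: float = 300.0,
    window_s: float = 0.2,
    n_frames: Optional[int] = None,
) -> np.ndarray:
    """Natural cubic spline from volume rate to tracking rate, then a
    centered moving average.

    Volume sample i is timestamped at the middle of its acquisition
    interval, (i + 0.5) / volume_rate. The averaging window is rounded to
    the nearest odd frame count and shrunk symmetrically at the edges, so
    constants and linear ramps pass through unchanged everywhere.
    """
    z = np.asarray(z, dtype=float)
    if len(z) < 4:
        raise ValueError("cubic spline interpolation needs at least 4 samples")
    if n_frames is None:
        n_frames = int(round(len(z) / volume_rate * tracking_rate))
    t_vol = (np.arange(len(z)) + 0.5) / volume_rate
    t_frame = np.arange(n_frames) / tracking_rate
    up = CubicSpline(t_vol, z, bc_type="natural")(t_frame)
    half = int(round(window_s * tracking_rate)) // 2
    return _centered_moving_average(up, half)


def _centered_moving_average(x: np.ndarray, half: int) -> np.ndarray:
    """Odd-window centered mean with symmetric edge shrinkage."""
    if half <= 0:
        return x.copy()
    n = len(x)
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (c[i + h + 1] - c[i - h]) / (2 * h + 1)
    return out


def normalize_unit(traces: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Scale a dataset of traces jointly to [0, 1]: the dataset-wide
    minimum maps to 0 and the maximum to 1."""
    traces = [np.asarray(t, dtype=float) for t in traces]
    if not traces or any(t.size == 0 for t in traces):
        raise ValueError("empty dataset")
    lo = min(np.nanmin(t) for t in traces)
    hi = max(np.nanmax(t) for t in traces)
    if not np.isfinite([lo, hi]).all() or hi == lo:
        raise ValueError("degenerate dataset: max equals min")
    return [(t - lo) / (hi - lo) for t in traces]


def _bin_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = math.floor(np.nanmin(values) / width) * width
    hi = math.ceil(np.nanmax(values) / width) * width
    if hi <= lo:
        hi = lo + width
    return lo + width * np.arange(int(round((hi - lo) / width)) + 1)


@dataclass
class TuningCurve1D:
    edges: np.ndarray            # (b+1,)
    per_fly: pd.DataFrame        # fly x bin means (NaN where count < min_count)
    counts: pd.DataFrame
    pooled: np.ndarray           # unweighted mean of per-fly bin means

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def tuning_curve_1d(
    activity_by_fly: dict,
    angle_by_fly: dict,
    bin_width: float = 5.0,
    min_count: int = 10,
    mask_by_fly: Optional[dict] = None,
    edges: Optional[np.ndarray] = None,
) -> TuningCurve1D:
    """Binned activity vs one joint angle, per fly and pooled across flies.

    Bin edges are aligned to multiples of the bin width over the pooled
    angle range. Bins with fewer than ``min_count`` frames for a fly are
    flagged empty (NaN), never zero-filled; the pooled curve is the
    unweighted mean of per-fly bin means over flies with data in the bin.
    Masked frames never contribute.
    """
    flies = list(activity_by_fly)
    acts, angs = {}, {}
    for f in flies:
        a = np.asarray(activity_by_fly[f], dtype=float)
        th = np.asarray(angle_by_fly[f], dtype=float)
        keep = ~(np.isnan(a) | np.isnan(th))
        if mask_by_fly is not None:
            keep &= ~np.asarray(mask_by_fly[f], dtype=bool)
        acts[f], angs[f] = a[keep], th[keep]
    if all(len(a) == 0 for a in acts.values()):
        raise ValueError("all frames masked; empty tuning curve")
    if edges is None:
        edges = _bin_edges(np.concatenate(list(angs.values())), bin_width)
    nb = len(edges) - 1
    means = np.full((len(flies), nb), np.nan)
    counts = np.zeros((len(flies), nb), dtype=int)
    for i, f in enumerate(flies):
        if len(angs[f]) == 0:
            continue
        which = np.digitize(angs[f], edges) - 1
        which = np.clip(which, 0, nb - 1)
        for b in range(nb):
            sel = which == b
            counts[i, b] = sel.sum()
            if counts[i, b] >= min_count:
                means[i, b] = acts[f][sel].mean()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        pooled = np.nanmean(means, axis=0)
    return TuningCurve1D(
        edges=edges,
        per_fly=pd.DataFrame(means, index=flies),
        counts=pd.DataFrame(counts, index=flies),
        pooled=pooled,
    )


@dataclass
class TuningMap2D:
    rot_edges: np.ndarray
    add_edges: np.ndarray
    per_fly: dict                # fly -> (br, ba) bin means
    pooled_max: np.ndarray       # max across flies per bin
    argmax: pd.DataFrame         # fly, rot, add bin centers of each fly's peak


def tuning_map_2d(
    activity_by_fly: dict,
    rotation_by_fly: dict,
    adduction_by_fly: dict,
    bin_width: float = 5.0,
    min_count: int = 10,
    mask_by_fly: Optional[dict] = None,
) -> TuningMap2D:
    """2-D binned activity over (rotation, adduction).

    The pooled map takes, per bin, the maximum across flies of the per-fly
    bin means. Each fly's argmax bin (rotation, adduction centers) is
    reported; ties break to the first occupied bin in row-major scan order
    (rotation outer, adduction inner).
    """
    flies = list(activity_by_fly)
    rot_all, add_all = [], []
    clean = {}
    for f in flies:
        a = np.asarray(activity_by_fly[f], dtype=float)
        r = np.asarray(rotation_by_fly[f], dtype=float)
        d = np.asarray(adduction_by_fly[f], dtype=float)
        keep = ~(np.isnan(a) | np.isnan(r) | np.isnan(d))
        if mask_by_fly is not None:
            keep &= ~np.asarray(mask_by_fly[f], dtype=bool)
        clean[f] = (a[keep], r[keep], d[keep])
        rot_all.append(r[keep]); add_all.append(d[keep])
    rot_all, add_all = np.concatenate(rot_all), np.concatenate(add_all)
    if rot_all.size == 0:
        raise ValueError("all frames masked; empty tuning map")
    re_, ae = _bin_edges(rot_all, bin_width), _bin_edges(add_all, bin_width)
    br, ba = len(re_) - 1, len(ae) - 1
    per_fly, arg_rows = {}, []
    for f in flies:
        a, r, d = clean[f]
        m = np.full((br, ba), np.nan)
        if len(a):
            ir = np.clip(np.digitize(r, re_) - 1, 0, br - 1)
            ia = np.clip(np.digitize(d, ae) - 1, 0, ba - 1)
            sums = np.zeros((br, ba)); cnts = np.zeros((br, ba))
            np.add.at(sums, (ir, ia), a)
            np.add.at(cnts, (ir, ia), 1)
            with np.errstate(invalid="ignore"):
                m = np.where(cnts >= min_count, sums / np.maximum(cnts, 1), np.nan)
        per_fly[f] = m
        if np.isfinite(m).any():
            flat = np.where(np.isfinite(m), m, -np.inf).ravel()
            k = int(np.argmax(flat))   # first max in row-major scan order
            pr, pa = divmod(k, ba)
            arg_rows.append(
                {"fly": f,
                 "rotation": 0.5 * (re_[pr] + re_[pr + 1]),
                 "adduction": 0.5 * (ae[pa] + ae[pa + 1])}
            )
    import warnings

    stack = np.array(list(per_fly.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        pooled = np.nanmax(stack, axis=0) if len(stack) else np.full((br, ba), np.nan)
    return TuningMap2D(
        rot_edges=re_, add_edges=ae, per_fly=per_fly, pooled_max=pooled,
        argmax=pd.DataFrame(arg_rows, columns=["fly", "rotation", "adduction"]),
    )


def peak_behavior_probability(
    activity: np.ndarray,
    behavior: np.ndarray,
    z_thresh: float = 2.0,
    rotation: Optional[np.ndarray] = None,
    adduction: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    grid_n: int = 60,
) -> tuple[dict, dict]:
    """Behavior probabilities during peak-activity frames, and per-behavior
    joint-angle densities.

    Peak frames have activity >= ``z_thresh``. Probabilities are the
    fraction of peak frames carrying each behavior label (summing to 1).
    When rotation/adduction are supplied, a Gaussian KDE (Scott's rule) of
    the two angles is evaluated per behavior on a common grid and scaled
    to unit maximum.
    """
    act = np.asarray(activity, dtype=float)
    beh = np.asarray(behavior, dtype=object)
    keep = ~np.isnan(act)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    act, beh = act[keep], beh[keep]
    peaks = act >= z_thresh
    if not peaks.any():
        raise ValueError(
            f"no frames reach activity threshold {z_thresh}; lower z_thresh"
        )
    labels, cnt = np.unique(beh[peaks], return_counts=True)
    probs = {str(l): c / peaks.sum() for l, c in zip(labels, cnt)}

    densities: dict = {}
    if rotation is not None and adduction is not None:
        rot = np.asarray(rotation, dtype=float)[keep]
        add = np.asarray(adduction, dtype=float)[keep]
        rg = np.linspace(np.nanmin(rot), np.nanmax(rot), grid_n)
        ag = np.linspace(np.nanmin(add), np.nanmax(add), grid_n)
        gr, ga = np.meshgrid(rg, ag, indexing="ij")
        pts = np.vstack([gr.ravel(), ga.ravel()])
        for l in np.unique(beh):
            sel = beh == l
            if sel.sum() < 3:
                continue
            try:
                kde = gaussian_kde(np.vstack([rot[sel], add[sel]]))
            except np.linalg.LinAlgError:
                continue
            d = kde(pts).reshape(grid_n, grid_n)
            if d.max() > 0:
                densities[str(l)] = {"rotation": rg, "adduction": ag, "density": d / d.max()}
    return probs, densities
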