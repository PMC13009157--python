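"""Behavior classification, step segmentation, and step/posture statistics.

Swing and stance are classified from the Gaussian-smoothed instantaneous
longitudinal velocity of each tarsus (negative = posterior movement): a
leg is in swing when its velocity exceeds +5 mm/s (anterior) or falls
below -25 mm/s, otherwise in stance; isolated one-frame classifications
are flipped. Steps run from one swing onset to the next; the anterior
extreme position (AEP) is the tarsus position at the first stance frame
and the posterior extreme position (PEP) the position at the last stance
frame before the swing. Steps outside the forward-walking envelope
(5-20 steps/s, 15-75 ms swing, < 200 ms stance) are rejected, with every
violated bound counted in the rejection report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

BEHAVIORS = ("forward_walk", "left_turn", "right_turn", "rest", "front_groom", "other")


# ---------------------------------------------------------------------------
# velocity and swing/stance
# ---------------------------------------------------------------------------

def smooth_velocity(x: np.ndarray, frame_rate: float, sigma_frames: float = 2.0) -> np.ndarray:
    """Central-difference velocity (mm/s) smoothed with a truncated
    Gaussian kernel (+-4 sigma, reflected edges). sigma 0 returns the raw
    central differences."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D position trace with at least 3 frames")
    v = np.gradient(x) * frame_rate
    if sigma_frames > 0:
        v = ndimage.gaussian_filter1d(v, sigma_frames, mode="reflect", truncate=4.0)
    return v


def classify_swing_stance(
    vel: np.ndarray, v_swing_fwd: float = 5.0, v_swing_back: float = -25.0
) -> np.ndarray:
    """Boolean swing mask from a velocity trace (mm/s).

    Swing iff v > v_swing_fwd or v < v_swing_back; afterwards every maximal
    1-frame run is flipped to the surrounding phase in a single
    left-to-right pass (with two labels, a flip merges the frame with both
    neighbors, so one pass leaves no 1-frame runs and the operation is
    idempotent).
    """
    vel = np.asarray(vel, dtype=float)
    swing = (vel > v_swing_fwd) | (vel < v_swing_back)
    lab = swing.copy()
    n = len(lab)
    for i in range(n):
        left_diff = i == 0 or lab[i - 1] != lab[i]
        right_diff = i == n - 1 or lab[i + 1] != lab[i]
        if left_diff and right_diff and n > 1:
            lab[i] = not lab[i]
    return lab


@dataclass
class StepCycle:
    """One swing + stance event of a single leg."""

    leg: str
    swing_onset: int          # first swing frame
    swing_offset: int         # first stance frame (half-open swing interval end)
    stance_offset: int        # next swing onset (half-open stance interval end)
    aep: np.ndarray           # tarsus position at first stance frame (mm)
    pep: np.ndarray           # tarsus position at last stance frame before swing
    swing_duration: float     # s
    stance_duration: float    # s
    step_frequency: float     # Hz
    swing_distance: float     # 3-D path length over the swing (mm)
    swing_displacement: float  # straight-line PEP->AEP distance (mm)
    fly_id: str = ""
    laser_state: str = "off"


@dataclass
class RejectionReport:
    n_candidates: int = 0
    n_retained: int = 0
    n_incomplete: int = 0
    step_frequency: int = 0
    swing_duration: int = 0
    stance_duration: int = 0


def segment_and_filter_steps(
    swing: np.ndarray,
    positions: np.ndarray,
    frame_rate: float,
    leg: str = "",
    fly_id: str = "",
    laser_state: Optional[np.ndarray] = None,
    step_freq_bounds: tuple = (5.0, 20.0),
    swing_dur_bounds: tuple = (0.015, 0.075),
    stance_dur_max: float = 0.2,
) -> tuple[list[StepCycle], RejectionReport]:
    """Segment step cycles from a swing mask and 3-D tarsus positions.

    A candidate cycle spans one swing onset to the next and requires a
    stance frame immediately before the onset (so the PEP is defined).
    The swing path length is accumulated from the PEP frame through the
    AEP frame, so it can never undercut the straight PEP->AEP chord.
    """
    swing = np.asarray(swing, dtype=bool)
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != len(swing):
        raise ValueError("positions and labels length mismatch")
    report = RejectionReport()
    d = np.diff(swing.astype(np.int8))
    onsets = np.flatnonzero(d == 1) + 1
    steps: list[StepCycle] = []
    for k in range(len(onsets) - 1):
        on, nxt = int(onsets[k]), int(onsets[k + 1])
        report.n_candidates += 1
        if on == 0 or swing[on - 1]:
            report.n_incomplete += 1
            continue
        stance_frames = np.flatnonzero(~swing[on:nxt])
        if stance_frames.size == 0:
            report.n_incomplete += 1
            continue
        ss = on + int(stance_frames[0])    # first stance frame
        swing_dur = (ss - on) / frame_rate
        stance_dur = (nxt - ss) / frame_rate
        freq = frame_rate / (nxt - on)
        ok = True
        if not (step_freq_bounds[0] <= freq <= step_freq_bounds[1]):
            report.step_frequency += 1
            ok = False
        if not (swing_dur_bounds[0] <= swing_dur <= swing_dur_bounds[1]):
            report.swing_duration += 1
            ok = False
        if not (stance_dur < stance_dur_max):
            report.stance_duration += 1
            ok = False
        if not ok:
            continue
        pep_f, aep_f = on - 1, ss
        path = positions[pep_f:aep_f + 1]
        dist = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
        aep, pep = positions[aep_f], positions[pep_f]
        steps.append(
            StepCycle(
                leg=leg, swing_onset=on, swing_offset=ss, stance_offset=nxt,
                aep=aep.copy(), pep=pep.copy(),
                swing_duration=swing_dur, stance_duration=stance_dur,
                step_frequency=freq, swing_distance=dist,
                swing_displacement=float(np.linalg.norm(aep - pep)),
                fly_id=fly_id,
                laser_state=(
                    str(laser_state[on]) if laser_state is not None else "off"
                ),
            )
        )
        report.n_retained += 1
    return steps, report


def steps_to_frame(steps: list[StepCycle]) -> pd.DataFrame:
    rows = []
    for s in steps:
        rows.append(
            {
                "fly_id": s.fly_id, "leg": s.leg, "laser_state": s.laser_state,
                "swing_onset": s.swing_onset, "swing_offset": s.swing_offset,
                "stance_offset": s.stance_offset,
                "aep_x": s.aep[0], "aep_y": s.aep[1], "aep_z": s.aep[2],
                "pep_x": s.pep[0], "pep_y": s.pep[1], "pep_z": s.pep[2],
                "swing_duration": s.swing_duration,
                "stance_duration": s.stance_duration,
                "step_frequency": s.step_frequency,
                "swing_distance": s.swing_distance,
                "swing_displacement": s.swing_displacement,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavior classification
# ---------------------------------------------------------------------------

def classify_behavior(
    forward_vel: np.ndarray,
    context: str,
    rotational_vel: Optional[np.ndarray] = None,
    heading: Optional[np.ndarray] = None,
    tarsi_speeds: Optional[np.ndarray] = None,
    front_tarsi_distance: Optional[np.ndarray] = None,
    front_tarsi_speed: Optional[np.ndarray] = None,
    walk_fwd_min: float = 5.0,
    turn_rot_min: float = 25.0,
    turn_rot_max: float = 50.0,
    heading_limit: float = 15.0,
    rest_speed_max: float = 5.0,
    groom_proximity: float = 0.5,
    groom_speed_min: float = 5.0,
) -> np.ndarray:
    """Per-frame behavior labels from body/ball velocities.

    tethered_ball: forward walking iff ball forward velocity > 5 mm/s and
    |rotational velocity| < 25 deg/s; left turn iff -50 < rot < -25 deg/s;
    right turn iff 25 < rot < 50 deg/s. treadmill: forward walking iff
    body forward velocity > 5 mm/s and |heading| < 15 deg. In either
    context, rest requires body and all tarsi below 5 mm/s, and front-leg
    grooming requires the front tarsi close together (within
    ``groom_proximity`` mm of each other / the head region) and
    oscillating (speed above ``groom_speed_min``). Anything else is
    "other".

    ``tarsi_speeds`` is (n_frames, n_legs); ``front_tarsi_distance`` and
    ``front_tarsi_speed`` are per-frame scalars for the grooming rule
    (grooming is never assigned when they are omitted).
    """
    fwd = np.asarray(forward_vel, dtype=float)
    n = len(fwd)
    labels = np.full(n, "other", dtype=object)

    if context == "tethered_ball":
        if rotational_vel is None:
            raise ValueError("tethered_ball context requires rotational_vel")
        rot = np.asarray(rotational_vel, dtype=float)
        walk = (fwd > walk_fwd_min) & (np.abs(rot) < turn_rot_min)
        left = (rot < -turn_rot_min) & (rot > -turn_rot_max)
        right = (rot > turn_rot_min) & (rot < turn_rot_max)
    elif context == "treadmill":
        if heading is None:
            raise ValueError("treadmill context requires heading")
        head = np.asarray(heading, dtype=float)
        walk = (fwd > walk_fwd_min) & (np.abs(head) < heading_limit)
        left = right = np.zeros(n, dtype=bool)
    else:
        raise ValueError(f"unknown context {context!r}")

    if tarsi_speeds is not None:
        ts = np.asarray(tarsi_speeds, dtype=float)
        rest = (np.abs(fwd) < rest_speed_max) & np.all(ts < rest_speed_max, axis=-1)
    else:
        rest = np.zeros(n, dtype=bool)
    if front_tarsi_distance is not None and front_tarsi_speed is not None:
        groom = (
            (np.asarray(front_tarsi_distance, float) < groom_proximity)
            & (np.asarray(front_tarsi_speed, float) > groom_speed_min)
        )
    else:
        groom = np.zeros(n, dtype=bool)

    # precedence: locomotion rules, then rest, then grooming
    labels[groom] = "front_groom"
    labels[rest] = "rest"
    labels[right] = "right_turn"
    labels[left] = "left_turn"
    labels[walk] = "forward_walk"
    return labels


# ---------------------------------------------------------------------------
# step statistics
# ---------------------------------------------------------------------------

def swing_trajectory_normalized(
    steps_by_fly: dict,
    positions_by_fly: dict,
    n_points: int = 100,
    lateral_axis: int = 1,
    longitudinal_axis: int = 0,
) -> dict:
    """Average swing trajectory: lateral coordinate vs normalized
    longitudinal progress between the per-fly mean PEP (0) and AEP (1).

    Each swing (PEP frame through AEP frame) is resampled to ``n_points``
    by linear interpolation in time; its longitudinal coordinate is mapped
    to progress with the fly's mean PEP/AEP, and the lateral coordinate is
    re-interpolated onto a uniform progress grid. Swings spanning fewer
    than 3 frames are excluded and counted. Returns the progress grid,
    per-fly mean lateral trajectories, the grand mean (mean of fly means),
    and its 95% CI across flies.
    """
    grid = np.linspace(0.0, 1.0, n_points)
    fly_means: dict[str, np.ndarray] = {}
    n_excluded = 0
    for fly, steps in steps_by_fly.items():
        pos = np.asarray(positions_by_fly[fly], dtype=float)
        if not steps:
            continue
        x_pep = np.mean([s.pep[longitudinal_axis] for s in steps])
        x_aep = np.mean([s.aep[longitudinal_axis] for s in steps])
        span = x_aep - x_pep
        if span == 0:
            raise ValueError(f"fly {fly}: mean AEP equals mean PEP")
        curves = []
        for s in steps:
            f0, f1 = s.swing_onset - 1, s.swing_offset
            if f1 - f0 + 1 < 3:
                n_excluded += 1
                continue
            seg = pos[f0:f1 + 1]
            t = np.linspace(0.0, 1.0, seg.shape[0])
            tq = np.linspace(0.0, 1.0, n_points)
            xq = np.interp(tq, t, seg[:, longitudinal_axis])
            yq = np.interp(tq, t, seg[:, lateral_axis])
            prog = (xq - x_pep) / span
            # enforce monotone progress for re-interpolation
            prog = np.maximum.accumulate(prog)
            curves.append(np.interp(grid, prog, yq))
        if curves:
            fly_means[fly] = np.mean(curves, axis=0)
    if not fly_means:
        raise ValueError("no usable swings")
    stack = np.array(list(fly_means.values()))
    grand = stack.mean(axis=0)
    if stack.shape[0] > 1:
        ci = 1.96 * stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        ci = np.zeros_like(grand)
    return {
        "progress": grid, "per_fly": fly_means, "mean": grand,
        "ci95": ci, "n_excluded": n_excluded,
    }


def relative_phase(
    ref_onsets: np.ndarray, other_onsets: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Circular phases of other-leg swing onsets within reference cycles.

    Each reference cycle is [t_k, t_{k+1}); an event at t gets phase
    (t - t_k) / (t_{k+1} - t_k) in [0, 1). Returns (phases, circular mean
    in [0, 1), vector strength).
    """
    ref = np.sort(np.asarray(ref_onsets, dtype=float))
    ev = np.sort(np.asarray(other_onsets, dtype=float))
    phases = []
    for k in range(len(ref) - 1):
        t0, t1 = ref[k], ref[k + 1]
        if t1 <= t0:
            continue
        for t in ev[(ev >= t0) & (ev < t1)]:
            phases.append((t - t0) / (t1 - t0))
    phases = np.asarray(phases)
    if phases.size == 0:
        return phases, np.nan, np.nan
    z = np.exp(2j * np.pi * phases).mean()
    return phases, float(np.angle(z) / (2 * np.pi) % 1.0), float(np.abs(z))


@dataclass
class RestPosture:
    body_height: float          # mm, thorax above substrate plane
    body_pitch: float           # deg, head-abdomen axis vs substrate plane
    tarsi_positions: np.ndarray  # (6, 3) mean resting tarsi positions, mm
    polygon_area: float          # mm^2, shoelace over tarsi (x, y)
    n_frames: int
    n_skipped: int


#: tarsus ordering giving a simple (non-self-intersecting) polygon
TARSI_ORDER = ("L1", "L2", "L3", "R3", "R2", "R1")


def polygon_area(xy: np.ndarray) -> float:
    """Shoelace area of a polygon given ordered (k, 2) vertices."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def resting_posture(
    rest_mask: np.ndarray,
    keypoints: dict,
    tarsi_order=TARSI_ORDER,
    substrate_z: Optional[float] = None,
) -> RestPosture:
    """Posture metrics over rest frames.

    Body height is the mean thorax z above the substrate plane (the mean
    resting tarsus z unless ``substrate_z`` is given); pitch is the angle
    of the head-abdomen axis against that plane; the stance polygon is the
    shoelace area over the six tarsi in L1,L2,L3,R3,R2,R1 order. Frames
    with any untracked (NaN) tarsus are skipped and counted.
    """
    rest_mask = np.asarray(rest_mask, dtype=bool)
    idx = np.flatnonzero(rest_mask)
    if idx.size == 0:
        raise ValueError("no rest frames")
    tarsi = np.stack([keypoints[f"tarsus_{leg}"] for leg in tarsi_order], axis=1)  # (n, 6, 3)
    good = ~np.isnan(tarsi[idx]).any(axis=(1, 2))
    kept = idx[good]
    n_skipped = int(idx.size - kept.size)
    if kept.size == 0:
        raise ValueError("all rest frames have untracked tarsi")
    mean_tarsi = tarsi[kept].mean(axis=0)
    areas = [polygon_area(tarsi[f][:, :2]) for f in kept]
    sub_z = float(mean_tarsi[:, 2].mean()) if substrate_z is None else float(substrate_z)
    height = float(keypoints["thorax"][kept, 2].mean() - sub_z)
    axis = keypoints["head"][kept] - keypoints["abdomen"][kept]
    axis = axis.mean(axis=0)
    pitch = float(np.degrees(np.arctan2(axis[2], np.hypot(axis[0], axis[1]))))
    return RestPosture(
        body_height=height, body_pitch=pitch, tarsi_positions=mean_tarsi,
        polygon_area=float(np.mean(areas)), n_frames=int(kept.size),
        n_skipped=n_skipped,
    )


def swing_to_stance_snapshot(
    steps: list[StepCycle],
    trace: np.ndarray,
    frame_rate: float,
    baseline_s: Optional[float] = None,
) -> pd.DataFrame:
    """Per-step value of a joint-angle (or position) trace at the
    swing-to-stance transition (the first stance frame).

    With ``baseline_s``, the value at the window start (``baseline_s``
    seconds before the transition) is subtracted, as in laser-aligned
    analyses. Steps whose transition or baseline frame falls outside the
    trace are skipped.
    """
    trace = np.asarray(trace, dtype=float)
    rows = []
    for s in steps:
        f = s.swing_offset
        if not (0 <= f < len(trace)):
            continue
        val = trace[f]
        if baseline_s is not None:
            fb = f - int(round(baseline_s * frame_rate))
            if fb < 0:
                continue
            val = val - trace[fb]
        rows.append(
            {"fly_id": s.fly_id, "leg": s.leg, "laser_state": s.laser_state,
             "frame": f, "value": float(val)}
        )
    return pd.DataFrame(rows)
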