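"""Synthetic connectomes, gait sessions, and calcium sessions with ground truth.

Every generator is a pure function of (spec, seed). Ground truth is
computed from the spec before noise is injected and never re-derived from
the noisy data, so downstream stages can be scored against known answers.

The gait generator produces hexapod tripod walking: within each step
cycle the tarsus translates linearly from AEP to PEP during stance
(belt/ball-consistent posterior movement) and returns along a straight
PEP->AEP chord during swing with a half-sine vertical lift and an
optional medial bow, so the medial-deviation phenotype near the
swing-to-stance transition can be synthesized. Ground-truth swing labels
include the touch-down frame, matching what threshold classification of a
central-difference velocity yields on the noiseless trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._errors import SpecError
from .io import NeuronRecord, PoseSession

LEGS = ("L1", "L2", "L3", "R1", "R2", "R3")

#: tripod coordination: {L1, R2, L3} vs {R1, L2, R3}, half a cycle apart
TRIPOD_PHASES = {"L1": 0.0, "R2": 0.0, "L3": 0.0, "R1": 0.5, "L2": 0.5, "R3": 0.5}

_DEF_AEP = {
    "L1": (2.2, 1.2, 0.0), "R1": (2.2, -1.2, 0.0),
    "L2": (0.6, 1.6, 0.0), "R2": (0.6, -1.6, 0.0),
    "L3": (-1.0, 1.6, 0.0), "R3": (-1.0, -1.6, 0.0),
}
_DEF_PEP = {
    "L1": (1.0, 1.2, 0.0), "R1": (1.0, -1.2, 0.0),
    "L2": (-0.6, 1.6, 0.0), "R2": (-0.6, -1.6, 0.0),
    "L3": (-2.2, 1.6, 0.0), "R3": (-2.2, -1.6, 0.0),
}


# ---------------------------------------------------------------------------
# connectome
# ---------------------------------------------------------------------------

@dataclass
class PremotorSpec:
    """One premotor interneuron: its inputs and motor-module outputs."""

    name: str
    hemilineage: str
    neurotransmitter: str
    hp_input: dict = field(default_factory=dict)      # hair plate -> synapses
    extra_input: int = 0                              # from a background fragment
    module_output: dict = field(default_factory=dict)  # module -> synapses


@dataclass
class ModuleSpec:
    n_motor: int = 3
    extra_input: int = 100    # background input onto the module's motor neurons


@dataclass
class CircuitSpec:
    """Layered sensory -> premotor -> motor circuit with signed interneurons."""

    hair_plates: dict = field(default_factory=lambda: {"CxHP8": 8, "CxHP4": 6})
    premotor: list = field(default_factory=list)
    modules: dict = field(default_factory=lambda: {m: ModuleSpec() for m in (1, 2, 3, 4)})
    mono_synapses: dict = field(default_factory=dict)  # (hair plate, module) -> synapses
    noise: str = "poisson"

    def validate(self):
        if self.noise not in ("poisson", "none"):
            raise SpecError(f"unknown noise law {self.noise!r}")
        counts = list(self.mono_synapses.values())
        counts += [c for p in self.premotor for c in p.hp_input.values()]
        counts += [c for p in self.premotor for c in p.module_output.values()]
        counts += [p.extra_input for p in self.premotor]
        counts += [m.extra_input for m in self.modules.values()]
        if any(c < 0 for c in counts):
            raise SpecError("synapse counts must be non-negative")
        for hp, m in self.mono_synapses:
            if hp not in self.hair_plates or m not in self.modules:
                raise SpecError(f"mono_synapses references unknown ({hp}, {m})")


def default_circuit_spec() -> CircuitSpec:
    """A small two-hair-plate circuit with antagonistic signed pathways,
    loosely patterned on a coxa hair plate exciting a posterior motor
    module and inhibiting its promoter antagonist."""
    return CircuitSpec(
        hair_plates={"CxHP8": 8, "CxHP4": 6},
        premotor=[
            PremotorSpec("pm_20A_1", "20A", "acetylcholine",
                         hp_input={"CxHP8": 120}, extra_input=180,
                         module_output={1: 90, 3: 30}),
            PremotorSpec("pm_19A_1", "19A", "GABA",
                         hp_input={"CxHP8": 90, "CxHP4": 20}, extra_input=190,
                         module_output={2: 110, 4: 20}),
            PremotorSpec("pm_13B_1", "13B", "glutamate",
                         hp_input={"CxHP8": 40}, extra_input=160,
                         module_output={2: 60}),
            PremotorSpec("pm_3A_1", "3A", "acetylcholine",
                         hp_input={"CxHP4": 110}, extra_input=90,
                         module_output={2: 120, 4: 40}),
            PremotorSpec("pm_unk_1", "unknown", "unknown",
                         hp_input={"CxHP8": 30}, extra_input=70,
                         module_output={1: 25}),
        ],
        modules={1: ModuleSpec(3, 300), 2: ModuleSpec(4, 350),
                 3: ModuleSpec(3, 260), 4: ModuleSpec(2, 200)},
        mono_synapses={("CxHP8", 1): 160, ("CxHP8", 3): 24, ("CxHP4", 2): 140},
    )


def _even_split(total: int, n: int) -> list[int]:
    base, rem = divmod(int(total), n)
    return [base + (1 if i < rem else 0) for i in range(n)]


def generate_connectome(
    spec: CircuitSpec, seed: int = 0
) -> tuple[pd.DataFrame, list[NeuronRecord], pd.DataFrame]:
    """Realize a circuit spec as (synapse table, annotations, ground-truth
    impact matrix).

    The ground truth is the two-term signed impact computed directly from
    the spec's target counts; realized edge counts are Poisson about the
    targets (noise "poisson") or exactly the targets (noise "none"),
    with zero draws dropped.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    annotations: list[NeuronRecord] = []
    hp_cells = {}
    for hp, n in spec.hair_plates.items():
        hp_cells[hp] = [f"{hp}_s{i}" for i in range(n)]
        annotations += [
            NeuronRecord(c, "sensory", hair_plate=hp, neurotransmitter="acetylcholine")
            for c in hp_cells[hp]
        ]
    for p in spec.premotor:
        annotations.append(
            NeuronRecord(p.name, "premotor", hemilineage=p.hemilineage,
                         neurotransmitter=p.neurotransmitter)
        )
    motor_cells = {}
    for m, ms in spec.modules.items():
        motor_cells[m] = [f"mn{m}_{j}" for j in range(ms.n_motor)]
        annotations += [
            NeuronRecord(c, "motor", motor_module=m) for c in motor_cells[m]
        ]

    mean_edges: list[tuple[str, str, float]] = []
    for p in spec.premotor:
        for hp, c in p.hp_input.items():
            cells = hp_cells[hp]
            for cell, share in zip(cells, _even_split(c, len(cells))):
                mean_edges.append((cell, p.name, share))
        if p.extra_input > 0:
            bg = f"bg_{p.name}"
            annotations.append(NeuronRecord(bg, "other"))
            mean_edges.append((bg, p.name, p.extra_input))
        for m, c in p.module_output.items():
            cells = motor_cells[m]
            for cell, share in zip(cells, _even_split(c, len(cells))):
                mean_edges.append((p.name, cell, share))
    for (hp, m), c in spec.mono_synapses.items():
        pairs = [(s, t) for s in hp_cells[hp] for t in motor_cells[m]]
        for (s, t), share in zip(pairs, _even_split(c, len(pairs))):
            mean_edges.append((s, t, share))
    for m, ms in spec.modules.items():
        if ms.extra_input > 0:
            bg = f"bg_mod{m}"
            annotations.append(NeuronRecord(bg, "other"))
            for cell, share in zip(motor_cells[m], _even_split(ms.extra_input, len(motor_cells[m]))):
                mean_edges.append((bg, cell, share))

    # ground truth from target counts, before any noise
    sign = {"acetylcholine": 1, "GABA": -1, "glutamate": -1, "unknown": 0}
    t_mod = {
        m: sum(spec.mono_synapses.get((hp, m), 0) for hp in spec.hair_plates)
        + sum(p.module_output.get(m, 0) for p in spec.premotor)
        + ms.extra_input
        for m, ms in spec.modules.items()
    }
    rows = []
    for hp in spec.hair_plates:
        for m in spec.modules:
            if t_mod[m] == 0:
                raise SpecError(f"module {m} has zero target input")
            w1 = spec.mono_synapses.get((hp, m), 0) / t_mod[m]
            w2 = 0.0
            for p in spec.premotor:
                i_p = sum(p.hp_input.values()) + p.extra_input
                if i_p == 0 or hp not in p.hp_input:
                    continue
                w2 += (
                    sign[p.neurotransmitter]
                    * (p.hp_input[hp] / i_p)
                    * (p.module_output.get(m, 0) / t_mod[m])
                )
            rows.append({"hair_plate": hp, "module": m, "w1": w1, "w2": w2, "total": w1 + w2})
    truth = pd.DataFrame(rows)

    realized = []
    for pre, post, mean in mean_edges:
        if mean <= 0:
            continue
        n_syn = int(rng.poisson(mean)) if spec.noise == "poisson" else int(round(mean))
        if n_syn > 0:
            realized.append((pre, post, n_syn))
    edges = pd.DataFrame(realized, columns=["pre_id", "post_id", "n_synapses"])
    return edges, annotations, truth


# ---------------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------------

@dataclass
class GaitSpec:
    n_flies: int = 3
    steps_per_fly: int = 20
    step_frequency_hz: float = 10.0
    swing_duration_s: float = 0.03
    frame_rate_hz: float = 300.0
    aep_mm: dict = field(default_factory=lambda: dict(_DEF_AEP))
    pep_mm: dict = field(default_factory=lambda: dict(_DEF_PEP))
    swing_height_mm: float = 0.2
    phase_offsets: dict = field(default_factory=lambda: dict(TRIPOD_PHASES))
    noise_sd_mm: float = 0.0
    fly_sd_mm: float = 0.02           # between-fly SD of extreme positions
    aep_shift_mm: tuple = (0.0, 0.0, 0.0)   # cohort-level shift ("silenced")
    bow_mm: float = 0.0               # medial bow amplitude during swing
    bow_phase: float = 0.8            # swing phase of the bow peak
    bow_width: float = 0.12
    context: str = "treadmill"

    def validate(self):
        period = 1.0 / self.step_frequency_hz
        if not self.swing_duration_s < period:
            raise SpecError("swing duration must be shorter than the cycle period")
        if any(not (0 <= p < 1) for p in self.phase_offsets.values()):
            raise SpecError("phase offsets must lie in [0, 1)")
        if round(self.swing_duration_s * self.frame_rate_hz) < 3:
            raise SpecError(
                "frame rate too low to resolve the swing (< 3 frames per swing)"
            )


@dataclass
class FlyGait:
    """One synthetic fly: pose session, ground-truth labels and steps."""

    session: PoseSession
    labels: dict            # leg -> (n_frames,) bool, True = swing
    steps: pd.DataFrame     # ground-truth step cycles (pre-noise positions)


def generate_gait(spec: GaitSpec, seed: int = 0) -> list[FlyGait]:
    """Simulate tripod walking for ``spec.n_flies`` flies.

    Ground-truth swing labels cover frames [onset, onset + n_swing]
    inclusive of the touch-down frame; the recorded ground-truth AEP/PEP
    are the true extreme positions (at the touch-down frame and the next
    lift-off frame). Gaussian positional noise is added only after the
    ground truth is recorded.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rate = spec.frame_rate_hz
    ppf = rate / spec.step_frequency_hz          # frames per cycle
    n_sw = int(round(spec.swing_duration_s * rate))
    k_max = spec.steps_per_fly + 1
    n = int(math.ceil((k_max + 2) * ppf))
    med = {leg: (-1.0 if leg.startswith("L") else 1.0) for leg in LEGS}

    flies = []
    for fi in range(spec.n_flies):
        fly_id = f"fly{fi:02d}"
        fly_off = rng.normal(0.0, spec.fly_sd_mm, size=3)
        pos = {leg: np.zeros((n, 3)) for leg in LEGS}
        labels = {leg: np.zeros(n, dtype=bool) for leg in LEGS}
        step_rows = []
        for leg in LEGS:
            aep = np.asarray(spec.aep_mm[leg], float) + fly_off + np.asarray(spec.aep_shift_mm)
            pep = np.asarray(spec.pep_mm[leg], float) + fly_off
            phi = spec.phase_offsets[leg]
            onsets = [int(round((k + phi) * ppf)) for k in range(-1, k_max + 2)]
            for k in range(len(onsets) - 1):
                on, nxt = onsets[k], onsets[k + 1]
                sw_end = on + n_sw
                for i in range(max(on, 0), min(sw_end, n - 1) + 1):
                    s = (i - on) / n_sw
                    p = pep + (aep - pep) * s
                    p[1] += (
                        spec.bow_mm * med[leg]
                        * math.exp(-((s - spec.bow_phase) ** 2) / (2 * spec.bow_width**2))
                    )
                    p[2] += spec.swing_height_mm * math.sin(math.pi * s)
                    pos[leg][i] = p
                n_st = nxt - sw_end
                for i in range(max(sw_end, 0), min(nxt, n - 1) + 1):
                    j = (i - sw_end) / n_st
                    pos[leg][i] = aep + (pep - aep) * j
                lo, hi = max(on, 0), min(sw_end, n - 1)
                if lo <= hi:
                    labels[leg][lo:hi + 1] = True
                if on >= 1 and nxt <= n - 1:
                    # aep_*/pep_*: true extreme positions (touch-down and
                    # lift-off); aep_stance_*/pep_stance_*: positions at the
                    # analysis-convention frames (first stance frame, last
                    # stance frame before the swing), one frame of travel away
                    step_rows.append(
                        {
                            "fly_id": fly_id, "leg": leg,
                            "swing_onset": on, "first_stance": sw_end + 1,
                            "next_onset": nxt,
                            "aep_x": aep[0], "aep_y": pos[leg][sw_end][1],
                            "aep_z": pos[leg][sw_end][2],
                            "pep_x": pep[0], "pep_y": pep[1], "pep_z": pep[2],
                            "aep_stance_x": pos[leg][sw_end + 1][0],
                            "aep_stance_y": pos[leg][sw_end + 1][1],
                            "aep_stance_z": pos[leg][sw_end + 1][2],
                            "pep_stance_x": pos[leg][on - 1][0],
                            "pep_stance_y": pos[leg][on - 1][1],
                            "pep_stance_z": pos[leg][on - 1][2],
                            "swing_duration": (n_sw + 1) / rate,
                            "step_frequency": rate / (nxt - on),
                        }
                    )
        if spec.noise_sd_mm > 0:
            for leg in LEGS:
                pos[leg] = pos[leg] + rng.normal(0.0, spec.noise_sd_mm, size=(n, 3))
        keypoints = {f"tarsus_{leg}": pos[leg] for leg in LEGS}
        keypoints["thorax"] = np.tile([0.0, 0.0, 0.9], (n, 1))
        keypoints["head"] = np.tile([1.2, 0.0, 1.0], (n, 1))
        keypoints["abdomen"] = np.tile([-1.5, 0.0, 0.8], (n, 1))
        session = PoseSession(
            fly_id=fly_id, trial_id="t0", context=spec.context, frame_rate=rate,
            frames=np.arange(n, dtype=np.int64), time=np.arange(n) / rate,
            laser_state=np.full(n, "off", dtype=object),
            keypoints=keypoints, angles={},
        )
        flies.append(FlyGait(session=session, labels=labels, steps=pd.DataFrame(step_rows)))
    return flies


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

@dataclass
class TuningSpec:
    """Tonic limit-detector tuning with slow-indicator dynamics.

    The underlying firing-rate surface is a product of logistic limits:
    rate = max_rate * sigmoid(k_rot * (rot - theta0_rot))
                    * sigmoid(k_add * (add - theta0_add)),
    convolved with a single-exponential indicator kernel (time constant
    ``tau_s``). Both channels share a multiplicative log-normal AR(1)
    motion-artifact gain; only GCaMP carries the activity signal.
    """

    theta0_rot: float = 25.0      # deg, rotation limit angle
    theta0_add: float = 20.0      # deg, adduction limit angle
    k_rot: float = 0.4            # 1/deg
    k_add: float = 0.4
    max_rate: float = 1.0
    tau_s: float = 0.5            # indicator time constant
    gain_g: float = 1.0
    gain_r: float = 1.0
    f0: float = 0.2               # baseline GCaMP fluorescence
    artifact_sd: float = 0.1      # log-gain SD of the shared artifact
    artifact_ar: float = 0.98     # AR(1) coefficient at tracking rate
    noise_sd: float = 0.01        # per-volume photon noise SD
    volume_rate_hz: float = 8.26
    tracking_rate_hz: float = 300.0

    def validate(self):
        if self.max_rate <= 0 or self.tau_s <= 0:
            raise SpecError("max_rate and tau_s must be positive")
        if self.volume_rate_hz <= 0 or self.tracking_rate_hz <= 0:
            raise SpecError("rates must be positive")


def limit_detector_rate(spec: TuningSpec, rotation, adduction) -> np.ndarray:
    rot = np.asarray(rotation, float)
    add = np.asarray(adduction, float)
    return (
        spec.max_rate
        / (1.0 + np.exp(-spec.k_rot * (rot - spec.theta0_rot)))
        / (1.0 + np.exp(-spec.k_add * (add - spec.theta0_add)))
    )


def _exp_filter(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Causal single-exponential filter with unit steady-state gain."""
    a = math.exp(-dt / tau)
    y = np.empty_like(x)
    acc = x[0]
    for i, v in enumerate(x):
        acc = a * acc + (1 - a) * v
        y[i] = acc
    return y


def generate_calcium_session(
    spec: TuningSpec,
    rotation: np.ndarray,
    adduction: np.ndarray,
    seed: int = 0,
    behavior: Optional[np.ndarray] = None,
    fly_id: str = "fly00",
):
    """Two-channel fluorescence for a joint-angle trajectory.

    Returns (CalciumSession, ground-truth rate trace at tracking rate).
    GCaMP = gain_g * (f0 + rate (*) exp-kernel) * artifact + noise,
    tdTomato = gain_r * artifact + noise, both sampled at the volume rate
    (volume i timestamped at the middle of its acquisition interval).
    """
    from .calcium import CalciumSession

    spec.validate()
    rot = np.asarray(rotation, float)
    add = np.asarray(adduction, float)
    if np.nanmax(np.abs(rot)) > 180 or np.nanmax(np.abs(add)) > 180:
        raise ValueError("joint angles outside the plausible range (|theta| > 180 deg)")
    rng = np.random.default_rng(seed)
    n = len(rot)
    dt = 1.0 / spec.tracking_rate_hz

    rate_gt = limit_detector_rate(spec, rot, add)
    conv = _exp_filter(rate_gt, spec.tau_s, dt)

    b = np.empty(n)
    innov_sd = spec.artifact_sd * math.sqrt(max(1.0 - spec.artifact_ar**2, 1e-12))
    b[0] = rng.normal(0.0, spec.artifact_sd) if spec.artifact_sd > 0 else 0.0
    eps = rng.normal(0.0, innov_sd, size=n) if spec.artifact_sd > 0 else np.zeros(n)
    for i in range(1, n):
        b[i] = spec.artifact_ar * b[i - 1] + eps[i]
    artifact = np.exp(b)

    g_track = spec.gain_g * (spec.f0 + conv) * artifact
    r_track = spec.gain_r * artifact

    n_vol = int(n / spec.tracking_rate_hz * spec.volume_rate_hz)
    t_frame = np.arange(n) * dt
    t_vol = (np.arange(n_vol) + 0.5) / spec.volume_rate_hz
    gcamp = np.interp(t_vol, t_frame, g_track) + rng.normal(0, spec.noise_sd, n_vol)
    tdtom = np.interp(t_vol, t_frame, r_track) + rng.normal(0, spec.noise_sd, n_vol)

    session = CalciumSession(
        gcamp=gcamp, tdtom=tdtom,
        volume_rate=spec.volume_rate_hz, tracking_rate=spec.tracking_rate_hz,
        angles={"rotation": rot, "adduction": add},
        behavior=behavior, fly_id=fly_id,
    )
    return session, rate_gt


def angle_sweep(
    duration_s: float,
    tracking_rate_hz: float = 300.0,
    rot_limits: tuple = (-15.0, 29.0),
    add_limits: tuple = (-18.0, 24.0),
    rot_period_s: float = 9.0,
    add_period_s: float = 12.7,
    phase: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Slow sinusoidal joint-angle sweeps emulating passive platform
    movement: incommensurate periods cover the 2-D angle space, peak
    angular speed stays below ~20 deg/s, and the default ranges top out a
    few degrees past the default limit angles (a leg is driven to, not far
    beyond, its range limit)."""
    t = np.arange(int(duration_s * tracking_rate_hz)) / tracking_rate_hz
    rmid, ramp = np.mean(rot_limits), np.ptp(rot_limits) / 2
    amid, aamp = np.mean(add_limits), np.ptp(add_limits) / 2
    rot = rmid + ramp * np.sin(2 * np.pi * t / rot_period_s + phase)
    add = amid + aamp * np.sin(2 * np.pi * t / add_period_s + 0.7 + phase)
    return rot, add
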