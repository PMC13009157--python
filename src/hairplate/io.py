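"""Readers and writers for the delimited tables all pipeline stages consume.

All tables are UTF-8 comma-separated with a single header row. Identifiers
are opaque strings. Positions are mm in a right-handed body frame
(x anterior, y toward the animal's left, z up); angles are degrees; frames
are 0-based and intervals over frames are half-open [start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._errors import FormatError

log = logging.getLogger("hairplate")

CELL_CLASSES = ("sensory", "premotor", "motor", "glia", "other")
NEUROTRANSMITTERS = ("acetylcholine", "GABA", "glutamate", "unknown")
CONTEXTS = ("tethered_ball", "platform", "treadmill")

#: neurotransmitter -> functional sign. Cholinergic neurons are treated as
#: excitatory; GABAergic and glutamatergic neurons as inhibitory (glutamate
#: acts on inhibitory GluCl receptors in the fly nerve cord).
SIGN_MAP = {"acetylcholine": 1, "GABA": -1, "glutamate": -1, "unknown": 0}


@dataclass(frozen=True)
class NeuronRecord:
    """Annotation of one reconstructed neuron (or fragment)."""

    neuron_id: str
    cell_class: str
    hair_plate: Optional[str] = None
    hemilineage: Optional[str] = None
    neurotransmitter: str = "unknown"
    motor_module: Optional[int] = None

    def __post_init__(self):
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(
                f"unrecognized cell_class {self.cell_class!r} for neuron "
                f"{self.neuron_id!r}; expected one of {CELL_CLASSES}"
            )
        if self.neurotransmitter not in NEUROTRANSMITTERS:
            raise ValueError(
                f"unrecognized neurotransmitter {self.neurotransmitter!r} "
                f"for neuron {self.neuron_id!r}"
            )
        if self.motor_module is not None and self.cell_class != "motor":
            raise ValueError(
                f"motor_module set on non-motor neuron {self.neuron_id!r}"
            )

    @property
    def sign(self) -> int:
        return SIGN_MAP[self.neurotransmitter]


@dataclass
class LoadReport:
    """Per-file record counts and anomalies noticed while loading."""

    path: str = ""
    n_rows: int = 0
    n_records: int = 0
    duplicates_merged: int = 0
    frame_gaps: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_annotations(path) -> list[NeuronRecord]:
    """Load a neuron-annotation table.

    Required columns: neuron_id, cell_class. Optional: hair_plate,
    hemilineage, neurotransmitter, motor_module. The functional sign is
    derived from the neurotransmitter (see :data:`SIGN_MAP`), never stored.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("neuron_id", "cell_class"):
        if col not in df.columns:
            raise FormatError(f"annotation table {path} is missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        mm = _opt(row.get("motor_module"))
        records.append(
            NeuronRecord(
                neuron_id=str(row["neuron_id"]).strip(),
                cell_class=str(row["cell_class"]).strip(),
                hair_plate=_opt(row.get("hair_plate")),
                hemilineage=_opt(row.get("hemilineage")),
                neurotransmitter=_opt(row.get("neurotransmitter")) or "unknown",
                motor_module=int(mm) if mm is not None else None,
            )
        )
    log.info("read_annotations: %d neurons from %s", len(records), path)
    return records


def write_annotations(records, path) -> None:
    rows = [
        {
            "neuron_id": r.neuron_id,
            "cell_class": r.cell_class,
            "hair_plate": r.hair_plate or "",
            "hemilineage": r.hemilineage or "",
            "neurotransmitter": r.neurotransmitter,
            "motor_module": "" if r.motor_module is None else r.motor_module,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_synapse_table(path) -> tuple[pd.DataFrame, LoadReport]:
    """Load a directed synapse table (pre_id, post_id, n_synapses).

    Duplicate (pre, post) rows are summed. Counts must be positive integers.
    """
    df = pd.read_csv(path, dtype={"pre_id": str, "post_id": str})
    for col in ("pre_id", "post_id", "n_synapses"):
        if col not in df.columns:
            raise FormatError(f"synapse table {path} is missing required column {col!r}")
    report = LoadReport(path=str(path), n_rows=len(df))
    if len(df):
        counts = df["n_synapses"].to_numpy()
        bad = np.flatnonzero((counts != np.floor(counts)) | (counts <= 0))
        if bad.size:
            raise ValueError(
                f"synapse table {path}: n_synapses must be a positive integer "
                f"(data row {bad[0] + 1}: {counts[bad[0]]!r})"
            )
        n_before = len(df)
        df = (
            df.groupby(["pre_id", "post_id"], as_index=False, sort=False)["n_synapses"]
            .sum()
        )
        df["n_synapses"] = df["n_synapses"].astype(np.int64)
        report.duplicates_merged = n_before - len(df)
    else:
        df = df.astype({"n_synapses": np.int64})
    report.n_records = len(df)
    log.info(
        "read_synapse_table: %d edges (%d duplicate rows merged) from %s",
        report.n_records, report.duplicates_merged, path,
    )
    return df.reset_index(drop=True), report


def write_synapse_table(df: pd.DataFrame, path) -> None:
    df[["pre_id", "post_id", "n_synapses"]].to_csv(path, index=False)


@dataclass
class PoseSession:
    """3D keypoints and joint angles for one (fly, trial), time-indexed."""

    fly_id: str
    trial_id: str
    context: str
    frame_rate: float
    frames: np.ndarray                      # (n,) int, strictly increasing
    time: np.ndarray                        # (n,) seconds
    laser_state: np.ndarray                 # (n,) str "off"/"on"
    keypoints: dict                         # name -> (n, 3) float, mm
    angles: dict                            # name -> (n,) float, degrees

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def keypoint_names(self):
        return list(self.keypoints)


_POSE_META = ("frame", "time", "fly_id", "trial_id", "context", "laser_state", "frame_rate")


def read_pose_table(path) -> tuple[dict, LoadReport]:
    """Load a pose table into one :class:`PoseSession` per (fly_id, trial_id).

    Keypoint columns are ``<name>_x/_y/_z`` triplets; angle columns are
    ``angle_<name>``. Frames must be strictly increasing within a trial
    (gaps are allowed but flagged in the load report) and the time column
    must equal frame / frame_rate to within 1e-6 s.
    """
    df = pd.read_csv(path, dtype={"fly_id": str, "trial_id": str})
    for col in ("frame", "time", "fly_id", "trial_id", "context", "frame_rate"):
        if col not in df.columns:
            raise FormatError(f"pose table {path} is missing required column {col!r}")
    kp_names = sorted(
        {c[:-2] for c in df.columns if c.endswith("_x")
         if f"{c[:-2]}_y" in df.columns and f"{c[:-2]}_z" in df.columns}
    )
    angle_names = [c[len("angle_"):] for c in df.columns if c.startswith("angle_")]
    report = LoadReport(path=str(path), n_rows=len(df))
    sessions: dict[tuple, PoseSession] = {}
    for (fly, trial), g in df.groupby(["fly_id", "trial_id"], sort=False):
        frames = g["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) <= 0):
            raise FormatError(
                f"pose table {path}: frames not strictly increasing in trial "
                f"({fly}, {trial})"
            )
        rate = float(g["frame_rate"].iloc[0])
        if rate <= 0:
            raise FormatError(f"pose table {path}: frame_rate must be > 0")
        time = g["time"].to_numpy(dtype=float)
        if np.max(np.abs(time - frames / rate)) > 1e-6:
            raise FormatError(
                f"pose table {path}: time and frame/frame_rate disagree by "
                f"> 1e-6 s in trial ({fly}, {trial})"
            )
        gaps = np.flatnonzero(np.diff(frames) > 1)
        if gaps.size:
            report.frame_gaps.append((fly, trial, int(gaps.size)))
        context = str(g["context"].iloc[0])
        if context not in CONTEXTS:
            raise ValueError(
                f"pose table {path}: unknown context {context!r}; "
                f"expected one of {CONTEXTS}"
            )
        laser = (
            g["laser_state"].astype(str).to_numpy()
            if "laser_state" in g.columns
            else np.full(len(g), "off")
        )
        sessions[(fly, trial)] = PoseSession(
            fly_id=fly,
            trial_id=trial,
            context=context,
            frame_rate=rate,
            frames=frames,
            time=time,
            laser_state=laser,
            keypoints={
                n: g[[f"{n}_x", f"{n}_y", f"{n}_z"]].to_numpy(dtype=float)
                for n in kp_names
            },
            angles={n: g[f"angle_{n}"].to_numpy(dtype=float) for n in angle_names},
        )
    report.n_records = len(sessions)
    log.info(
        "read_pose_table: %d sessions, %d rows, %d trials with frame gaps (%s)",
        len(sessions), len(df), len(report.frame_gaps), path,
    )
    return sessions, report


def write_pose_table(sessions, path) -> None:
    """Write sessions (iterable of PoseSession) back to one CSV."""
    parts = []
    for s in sessions:
        d = {
            "frame": s.frames,
            "time": s.time,
            "fly_id": s.fly_id,
            "trial_id": s.trial_id,
            "context": s.context,
            "laser_state": s.laser_state,
            "frame_rate": s.frame_rate,
        }
        for name, xyz in s.keypoints.items():
            d[f"{name}_x"], d[f"{name}_y"], d[f"{name}_z"] = xyz.T
        for name, a in s.angles.items():
            d[f"angle_{name}"] = a
        parts.append(pd.DataFrame(d))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False, float_format="%.12g")
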