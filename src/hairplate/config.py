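"""Run configuration: every tunable parameter of the pipeline in one place.

Defaults follow the published analysis procedure where a value is printed
(velocity and turning thresholds, step filters, baseline fraction, filter
window, synapse threshold, Bonferroni factors); the remaining knobs
(smoothing scale, bin width, KDE bandwidth rule, peak threshold) are this
package's own documented choices.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, fields


@dataclass
class RunConfig:
    # swing/stance classification (tarsus velocity, mm/s)
    v_swing_fwd_mm_s: float = 5.0
    v_swing_back_mm_s: float = -25.0
    smoothing_sigma_frames: float = 2.0

    # behavior classification
    walk_fwd_min_mm_s: float = 5.0
    turn_rot_min_deg_s: float = 25.0
    turn_rot_max_deg_s: float = 50.0
    heading_limit_deg: float = 15.0
    rest_speed_max_mm_s: float = 5.0
    groom_proximity_mm: float = 0.5
    groom_speed_min_mm_s: float = 5.0

    # step filters
    step_freq_min_hz: float = 5.0
    step_freq_max_hz: float = 20.0
    swing_dur_min_s: float = 0.015
    swing_dur_max_s: float = 0.075
    stance_dur_max_s: float = 0.2

    # laser-aligned analysis window
    laser_baseline_s: float = 0.1
    traj_n_points: int = 100

    # calcium processing
    tracking_rate_hz: float = 300.0
    volume_rate_hz: float = 8.26
    baseline_fraction: float = 0.10
    ma_window_s: float = 0.2
    bin_width_deg: float = 5.0
    min_count_per_bin: int = 10
    peak_z_thresh: float = 2.0

    # connectome
    min_avg_synapses: float = 4.0

    # statistics
    alpha: float = 0.05
    bonferroni_step_params: int = 2
    bonferroni_phase: int = 5

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))
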