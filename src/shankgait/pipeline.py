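"""End-to-end reconstruction: IMU recording -> per-stride spatial parameters."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core_io import ImuRecording
from .gait_events import EventConfig, StrideSegmentation, detect_gait_events, tilt_angle_series
from .orientation import OrientationTrack, estimate_orientation
from .stride_parameters import (
    StrideResult,
    shank_vertical_displacement,
    stride_length,
    stride_timing,
)
from .trajectory_frames import (
    Trajectory,
    integrate_position,
    stride_frame_rotation,
    transform_stride,
)
from .velocity_drift import VelocityTrack, build_velocity_track

__all__ = ["PipelineResult", "reconstruct"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    """Stride parameters plus every intermediate track, for inspection."""

    strides: list[StrideResult]
    segmentation: StrideSegmentation
    orientation: OrientationTrack | None
    velocity: VelocityTrack | None
    trajectory: Trajectory | None


def reconstruct(
    rec: ImuRecording,
    r: float,
    method: str = "ipm",
    events_cfg: EventConfig | None = None,
) -> PipelineResult:
    """Run the full method on one recording.

    ``r`` is the sensor-to-malleolus distance in metres; ``method`` selects
    the mid-stance update velocity (``"ipm"`` or ``"zupt"``).
    """
    tilt = tilt_angle_series(rec)
    seg = detect_gait_events(rec, tilt, events_cfg)
    if len(seg.segments) == 0:
        return PipelineResult(
            strides=[], segmentation=seg, orientation=None, velocity=None, trajectory=None
        )

    orient = estimate_orientation(rec, seg.ms_idx)
    vel = build_velocity_track(rec, orient, seg.ms_idx, r, method=method)

    n = len(rec)
    p_e = np.full((n, 3), np.nan)
    start, stop = int(seg.ms_idx[0]), int(seg.ms_idx[-1])
    p_e[start : stop + 1] = integrate_position(
        vel.v_corr[start : stop + 1], rec.dt, np.zeros(3)
    )

    t0 = float(rec.t[0])
    strides: list[StrideResult] = []
    p_p_list: list[np.ndarray] = []
    for i, (a, b) in enumerate(seg.segments):
        frame = stride_frame_rotation(p_e, a, b)
        p_p = transform_stride(p_e, frame, (a, b))
        p_p_list.append(p_p)
        length = stride_length(p_p, (a, b))
        vert = shank_vertical_displacement(p_p, (a, b))

        hs_in = seg.hs_idx[(seg.hs_idx >= a) & (seg.hs_idx < b)]
        hs_next = seg.hs_idx[seg.hs_idx >= b]
        to_in = seg.to_idx[(seg.to_idx >= a) & (seg.to_idx < b)]
        hs_i = int(hs_in[0]) if hs_in.size else None
        hs_j = int(hs_next[0]) if hs_next.size else None
        to_i = int(to_in[0]) if to_in.size else None
        if hs_i is not None and hs_j is not None:
            duration, velocity = stride_timing(hs_i, hs_j, rec.dt, length)
        else:
            logger.warning("stride %d: missing heel-strike pair, timing undefined", i)
            duration, velocity = float("nan"), float("nan")

        strides.append(
            StrideResult(
                stride_index=i,
                stride_length_m=length,
                vertical_disp_m=vert,
                duration_s=duration,
                velocity_mps=velocity,
                ms_start_s=t0 + a * rec.dt,
                ms_end_s=t0 + b * rec.dt,
                hs_s=t0 + hs_i * rec.dt if hs_i is not None else float("nan"),
                to_s=t0 + to_i * rec.dt if to_i is not None else float("nan"),
                side=rec.side,
                ms_start_idx=a,
                ms_end_idx=b,
                hs_idx=hs_i,
                hs_next_idx=hs_j,
                to_idx=to_i,
            )
        )

    traj = Trajectory(p_e=p_e, p_p=p_p_list, segments=list(seg.segments))
    return PipelineResult(
        strides=strides, segmentation=seg, orientation=orient, velocity=vel, trajectory=traj
    )
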