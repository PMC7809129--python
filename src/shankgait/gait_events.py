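"""Gait event detection and mid-stance segmentation from sagittal angular velocity.

Events per gait cycle, all found on the gyroscope z channel ``w_z`` and its
integral, the sagittal shank tilt ``theta_z``:

* SMF — local maximum of ``theta_z`` (shank max forward)
* SMB — local minimum of ``theta_z`` (shank max backward)
* HS  — first local peak of ``w_z`` after SMF (heel strike)
* TO  — minimum of ``w_z`` before SMB (toe off)
* MS  — maximum of ``w_z`` strictly between HS and TO (mid-stance)

The stream is segmented into gait cycles as half-open windows
``[ms(i), ms(i+1))``.  For sensors mounted mirror-wise set ``flip_z`` to
negate ``w_z`` before detection.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import signal

from .core_io import ImuRecording

__all__ = [
    "TiltSeries",
    "EventConfig",
    "StrideSegmentation",
    "tilt_angle_series",
    "detect_gait_events",
    "segment_strides",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TiltSeries:
    """Sagittal shank tilt angle per sample, radians; ``theta_z(0) = 0``."""

    theta_z: np.ndarray


@dataclasses.dataclass
class EventConfig:
    """Tuning knobs for the extremum search.

    ``min_distance_s = None`` derives the peak separation as one quarter of
    the median cycle duration estimated from a first tilt-peak pass.
    ``detrend_tilt`` removes the linear trend gyro bias leaves in the
    integrated tilt before the extremum search.
    """

    prominence_rad_s: float = 0.2
    min_distance_s: float | None = None
    flip_z: bool = False
    detrend_tilt: bool = True


@dataclasses.dataclass
class StrideSegmentation:
    """Detected event indices and the mid-stance cycle windows.

    ``hs_idx`` may hold one trailing heel strike past the last mid-stance;
    it is kept because stride duration needs the next cycle's HS.
    """

    smf_idx: np.ndarray
    smb_idx: np.ndarray
    hs_idx: np.ndarray
    to_idx: np.ndarray
    ms_idx: np.ndarray
    segments: list[tuple[int, int]]

    @property
    def n_strides(self) -> int:
        return len(self.segments)


def tilt_angle_series(rec: ImuRecording) -> TiltSeries:
    """Cumulative trapezoidal integral of ``w_z`` from zero."""
    wz = rec.w_s[:, 2]
    theta = np.concatenate(([0.0], np.cumsum(0.5 * (wz[1:] + wz[:-1]) * rec.dt)))
    return TiltSeries(theta_z=theta)


def _empty_segmentation() -> StrideSegmentation:
    e = np.array([], dtype=int)
    return StrideSegmentation(e, e, e, e, e, [])


def detect_gait_events(
    rec: ImuRecording,
    tilt: TiltSeries | None = None,
    cfg: EventConfig | None = None,
) -> StrideSegmentation:
    """Detect SMF/SMB/HS/TO/MS and the mid-stance segmentation.

    Cycles whose event ordering cannot be satisfied are dropped and logged.
    Returns an empty segmentation (with a warning) when no tilt extrema are
    found, e.g. on a stationary recording.
    """
    cfg = cfg or EventConfig()
    if tilt is None:
        tilt = tilt_angle_series(rec)
    wz = rec.w_s[:, 2].astype(float)
    theta = tilt.theta_z.astype(float)
    if cfg.flip_z:
        wz = -wz
        theta = -theta
    if len(theta) != len(rec):
        raise ValueError("tilt series length does not match recording")
    if cfg.detrend_tilt and len(theta) > 2:
        theta = signal.detrend(theta, type="linear")

    prom_w = cfg.prominence_rad_s
    # tilt is in radians, not rad/s; half the rate knob works as a floor for
    # normal tilt ranges (~0.4-0.6 rad peak to peak)
    prom_t = 0.5 * cfg.prominence_rad_s

    smf0, _ = signal.find_peaks(theta, prominence=prom_t)
    if smf0.size < 2:
        warnings.warn("no gait cycles found (fewer than two tilt maxima)")
        return _empty_segmentation()

    if cfg.min_distance_s is not None:
        dist = max(1, int(round(cfg.min_distance_s / rec.dt)))
    else:
        est_cycle = float(np.median(np.diff(smf0)))
        dist = max(1, int(round(0.25 * est_cycle)))

    smf_idx, _ = signal.find_peaks(theta, prominence=prom_t, distance=dist)
    smb_idx, _ = signal.find_peaks(-theta, prominence=prom_t, distance=dist)
    # no distance constraint here: scipy culls by distance before prominence,
    # so noise micro-maxima could evict a true heel-strike peak
    w_peaks, _ = signal.find_peaks(wz, prominence=prom_w)
    if smf_idx.size < 2 or smb_idx.size == 0:
        warnings.warn("no gait cycles found (fewer than two tilt maxima)")
        return _empty_segmentation()

    smf_l, smb_l, hs_l, to_l, ms_l = [], [], [], [], []
    for c, smf in enumerate(smf_idx):
        nxt = smf_idx[c + 1] if c + 1 < smf_idx.size else len(wz)
        smb_cand = smb_idx[(smb_idx > smf) & (smb_idx < nxt)]
        hs_cand = w_peaks[w_peaks > smf]
        hs = int(hs_cand[0]) if hs_cand.size else None
        if smb_cand.size == 0:
            # incomplete trailing cycle: keep its HS for stride timing
            if hs is not None and hs < nxt:
                hs_l.append(hs)
                smf_l.append(int(smf))
            continue
        smb = int(smb_cand[0])
        if hs is None or hs >= smb:
            logger.info("cycle at sample %d dropped: no HS before SMB", smf)
            continue
        to = hs + 1 + int(np.argmin(wz[hs + 1 : smb + 1]))
        if to - hs < 2:
            logger.info("cycle at sample %d dropped: HS/TO too close", smf)
            continue
        ms = hs + 1 + int(np.argmax(wz[hs + 1 : to]))
        if not (smf < hs < ms < to <= smb):
            logger.info("cycle at sample %d dropped: event ordering violated", smf)
            continue
        smf_l.append(int(smf))
        smb_l.append(smb)
        hs_l.append(hs)
        to_l.append(to)
        ms_l.append(ms)

    seg = StrideSegmentation(
        smf_idx=np.array(smf_l, dtype=int),
        smb_idx=np.array(smb_l, dtype=int),
        hs_idx=np.array(hs_l, dtype=int),
        to_idx=np.array(to_l, dtype=int),
        ms_idx=np.array(ms_l, dtype=int),
        segments=[],
    )
    seg.segments = segment_strides(seg)
    return seg


def segment_strides(seg: StrideSegmentation) -> list[tuple[int, int]]:
    """Half-open cycle windows ``[ms(i), ms(i+1))`` from the MS indices."""
    ms = np.asarray(seg.ms_idx, dtype=int)
    if ms.size < 2:
        return []
    return [(int(ms[i]), int(ms[i + 1])) for i in range(ms.size - 1)]
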