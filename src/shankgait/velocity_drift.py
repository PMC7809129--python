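"""Velocity integration, inverted-pendulum update velocity, and drift removal.

Linear acceleration is trapezoid-integrated to a raw velocity per mid-stance
segment.  At each mid-stance the shank is modelled as rotating about the
stationary malleolus, so the sensor velocity there is the tangential
velocity ``w x r`` — the update velocity.  The mismatch between the raw
integral and the update velocities at the two segment ends defines a linear
drift model (slope + intercept per segment) that is subtracted from the raw
velocity.  The ZUPT baseline replaces the update velocity with zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import ImuRecording, Quaternion, quat_rotate
from .orientation import OrientationTrack

__all__ = [
    "VelocityTrack",
    "DriftModel",
    "integrate_velocity",
    "ipm_update_velocity",
    "zupt_update_velocity",
    "remove_drift",
    "build_velocity_track",
]


@dataclasses.dataclass
class DriftModel:
    """Per-segment linear velocity-error model ``e(k) = alpha*(k-k0) + beta``."""

    alpha: np.ndarray  # (3,) slope, m/s per sample
    beta: np.ndarray  # (3,) intercept, m/s
    seg: tuple[int, int]  # (ms_i, ms_j) global sample indices


@dataclasses.dataclass
class VelocityTrack:
    """Raw, update, and drift-corrected velocities.

    ``v_raw``/``v_corr`` are full recording length, NaN outside the covered
    span.  ``v_update[i]`` is the update velocity at ``ms_idx[i]``.
    """

    v_raw: np.ndarray
    v_update: np.ndarray
    v_corr: np.ndarray
    models: list[DriftModel]
    ms_idx: np.ndarray


def integrate_velocity(a_lin: np.ndarray, dt: float, v0) -> np.ndarray:
    """Trapezoidal cumulative integral of linear acceleration.

    ``v(k) = v(k-1) + (a(k) + a(k-1))/2 * dt`` with ``v(0) = v0``.
    """
    a = np.atleast_2d(np.asarray(a_lin, dtype=float))
    v0 = np.broadcast_to(np.asarray(v0, dtype=float), (a.shape[1],))
    inc = 0.5 * (a[1:] + a[:-1]) * dt
    return v0 + np.vstack([np.zeros(a.shape[1]), np.cumsum(inc, axis=0)])


def ipm_update_velocity(
    q_se_at_ms: Quaternion, w_s_at_ms, a_s_at_ms, r: float
) -> np.ndarray:
    """Tangential velocity of the sensor pivoting about the malleolus.

    The angular velocity is rotated into the lab frame; the lever arm is the
    sensor-to-malleolus distance ``r`` along the (lab-frame) accelerometer
    direction, which the mid-stance gravity alignment pins to the vertical.
    Returns ``w_lab x r_lab`` in m/s.
    """
    if r <= 0:
        raise ValueError("sensor-to-malleolus distance r must be positive")
    a = np.asarray(a_s_at_ms, dtype=float)
    n = np.linalg.norm(a)
    if n == 0.0:
        raise ValueError("zero-norm accelerometer sample at mid-stance")
    w_lab = quat_rotate(q_se_at_ms, np.asarray(w_s_at_ms, dtype=float))
    r_lab = r * quat_rotate(q_se_at_ms, a / n)
    return np.cross(w_lab, r_lab)


def zupt_update_velocity() -> np.ndarray:
    """Zero-velocity-update baseline: the mid-stance velocity is assumed zero."""
    return np.zeros(3)


def remove_drift(
    v_raw: np.ndarray,
    v_update_start,
    v_update_end,
    seg: tuple[int, int],
) -> tuple[np.ndarray, DriftModel]:
    """Subtract the linear drift model fitted to the segment endpoints.

    ``v_raw`` is the raw velocity over the closed window ``[ms_i, ms_j]``
    (``seg`` holds the global indices).  The corrected series equals the
    update velocities exactly at both ends.
    """
    v = np.atleast_2d(np.asarray(v_raw, dtype=float))
    m = v.shape[0]
    if m < 2:
        raise ValueError("drift removal needs a segment of at least 2 samples")
    vs = np.asarray(v_update_start, dtype=float)
    ve = np.asarray(v_update_end, dtype=float)
    beta = v[0] - vs
    alpha = ((v[-1] - ve) - beta) / (m - 1)
    k = np.arange(m)[:, None]
    corrected = v - alpha * k - beta
    return corrected, DriftModel(alpha=alpha, beta=beta, seg=(int(seg[0]), int(seg[1])))


def build_velocity_track(
    rec: ImuRecording,
    orient: OrientationTrack,
    ms_idx: np.ndarray,
    r: float,
    method: str = "ipm",
) -> VelocityTrack:
    """Integrate and drift-correct velocity over every mid-stance segment.

    ``method``: ``"ipm"`` (inverted pendulum update) or ``"zupt"`` (zero
    update).  Each segment's raw integral starts from the update velocity at
    its opening mid-stance, so the drift intercept measures accumulated
    drift relative to the model.
    """
    if method not in ("ipm", "zupt"):
        raise ValueError("method must be 'ipm' or 'zupt'")
    ms_idx = np.asarray(ms_idx, dtype=int)
    if ms_idx.size < 2:
        raise ValueError("need at least two mid-stances to build a velocity track")

    n = len(rec)
    v_raw = np.full((n, 3), np.nan)
    v_corr = np.full((n, 3), np.nan)
    v_update = np.zeros((ms_idx.size, 3))
    if method == "ipm":
        for i, m in enumerate(ms_idx):
            q_ms = Quaternion.from_array(orient.q_se[m])
            v_update[i] = ipm_update_velocity(q_ms, rec.w_s[m], rec.a_s[m], r)

    models: list[DriftModel] = []
    for i in range(ms_idx.size - 1):
        a, b = int(ms_idx[i]), int(ms_idx[i + 1])
        v_seg = integrate_velocity(orient.a_lin[a : b + 1], rec.dt, v_update[i])
        corrected, model = remove_drift(v_seg, v_update[i], v_update[i + 1], (a, b))
        # the closing sample is re-initialised by the next segment; both
        # assignments agree (endpoint exactness), later one wins
        v_raw[a : b + 1] = v_seg
        v_corr[a : b + 1] = corrected
        models.append(model)

    return VelocityTrack(
        v_raw=v_raw, v_update=v_update, v_corr=v_corr, models=models, ms_idx=ms_idx
    )
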