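"""Per-sample IMU orientation and lab-frame linear acceleration.

At each mid-stance the accelerometer is assumed to read pure gravity, so the
orientation there is the shortest-arc rotation mapping the normalised
accelerometer reading onto the lab gravity direction.  Within each
mid-stance window the orientation is propagated forward by first-order
quaternion integration of the gyroscope, renormalising every step.  No
smoothing or fusion filter is applied.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .core_io import (
    G_MAG,
    GRAVITY_LAB,
    ImuRecording,
    Quaternion,
    quat_array_rotate,
    quat_multiply,
)

__all__ = [
    "OrientationTrack",
    "quat_from_gravity",
    "propagate_orientation",
    "lab_linear_acceleration",
    "estimate_orientation",
]

logger = logging.getLogger(__name__)

#: ||a x g|| below this means the accelerometer is (anti)parallel to gravity
_DEGENERATE_AXIS_TOL = 1e-8

#: fallback rotation axis for the antipodal case (accelerometer exactly
#: opposite gravity): 180° about the lab/sensor y axis
_FALLBACK_AXIS = np.array([0.0, 1.0, 0.0])


@dataclasses.dataclass
class OrientationTrack:
    """Per-sample sensor→lab quaternions and accelerations.

    Arrays are full recording length; samples outside the covered
    ``[ms(0), ms(-1)]`` span are NaN.

    ``q_se`` : (N, 4) quaternion components ``[w, x, y, z]``
    ``a_lab`` : (N, 3) lab-frame acceleration, m/s²
    ``a_lin`` : (N, 3) lab-frame linear (gravity-free) acceleration, m/s²
    """

    q_se: np.ndarray
    a_lab: np.ndarray
    a_lin: np.ndarray
    start: int
    stop: int  # inclusive


def quat_from_gravity(a_s_at_ms, gravity_lab: np.ndarray | None = None) -> Quaternion:
    """Shortest-arc rotation mapping ``normalize(a_s)`` onto the gravity axis.

    The half-angle terms come from the dot product of the two unit vectors;
    the axis is their (normalised) cross product.  Antipodal input falls back
    to a 180° rotation about ``[0, 1, 0]``.
    """
    g = GRAVITY_LAB if gravity_lab is None else np.asarray(gravity_lab, dtype=float)
    a = np.asarray(a_s_at_ms, dtype=float)
    n = np.linalg.norm(a)
    if n == 0.0:
        raise ValueError("zero-norm accelerometer sample: orientation undefined")
    ahat = a / n
    c = float(ahat @ g)
    axis = np.cross(ahat, g)
    s = float(np.linalg.norm(axis))
    if s < _DEGENERATE_AXIS_TOL:
        if c > 0.0:
            return Quaternion.identity()
        return Quaternion(0.0, _FALLBACK_AXIS.copy())  # antipodal
    axis /= s
    half_cos = math.sqrt(max(0.0, 0.5 * (1.0 + c)))
    half_sin = math.sqrt(max(0.0, 0.5 * (1.0 - c)))
    return Quaternion(half_cos, half_sin * axis).normalized()


def propagate_orientation(
    q0: Quaternion, w_s: np.ndarray, dt: float
) -> list[Quaternion]:
    """Propagate ``q0`` through angular-velocity samples ``w_s``.

    ``w_s[k]`` is the gyroscope reading at the sample being produced, so

        q(k) = normalize(q(k-1) + 0.5 * q(k-1) ⊗ [0, w_s(k)] * dt)

    Returns one quaternion per row of ``w_s`` (``q0`` itself excluded).
    """
    w_s = np.atleast_2d(np.asarray(w_s, dtype=float))
    out: list[Quaternion] = []
    q = q0
    for wk in w_s:
        dq = quat_multiply(q, Quaternion(0.0, wk))
        q = Quaternion(q.w + 0.5 * dq.w * dt, q.v + 0.5 * dq.v * dt).normalized()
        out.append(q)
    return out


def lab_linear_acceleration(
    q_se: np.ndarray | list[Quaternion],
    a_s: np.ndarray,
    g_mag: float = G_MAG,
    gravity_lab: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate sensor accelerations into the lab frame and strip gravity.

    Returns ``(a_lab, a_lin)`` with ``a_lin = a_lab - g_mag * gravity_lab``.
    """
    g = GRAVITY_LAB if gravity_lab is None else np.asarray(gravity_lab, dtype=float)
    if isinstance(q_se, list):
        q_arr = np.array([q.as_array() for q in q_se])
    else:
        q_arr = np.asarray(q_se, dtype=float)
    a_s = np.asarray(a_s, dtype=float)
    if q_arr.shape[0] != a_s.shape[0]:
        raise ValueError("quaternion and acceleration series lengths differ")
    a_lab = quat_array_rotate(q_arr, a_s)
    a_lin = a_lab - g_mag * g
    return a_lab, a_lin


def estimate_orientation(rec: ImuRecording, ms_idx: np.ndarray) -> OrientationTrack:
    """Gravity-align at every mid-stance, gyro-propagate in between.

    The sample at each ``ms(i)`` takes the gravity-aligned quaternion;
    propagation runs over the open interval ``(ms(i), ms(i+1))``.  The final
    mid-stance is gravity-aligned as well.
    """
    ms_idx = np.asarray(ms_idx, dtype=int)
    if ms_idx.size < 1:
        raise ValueError("need at least one mid-stance index")
    n = len(rec)
    q_arr = np.full((n, 4), np.nan)

    for i, m in enumerate(ms_idx):
        a_ms = rec.a_s[m]
        mag = float(np.linalg.norm(a_ms))
        if abs(mag - G_MAG) > 0.2 * G_MAG:
            logger.warning(
                "accelerometer magnitude %.2f m/s² at mid-stance sample %d "
                "deviates from gravity by more than 20%%",
                mag,
                m,
            )
        q_ms = quat_from_gravity(a_ms)
        q_arr[m] = q_ms.as_array()
        if i + 1 < ms_idx.size:
            stop = int(ms_idx[i + 1])
            if stop > m + 1:
                qs = propagate_orientation(q_ms, rec.w_s[m + 1 : stop], rec.dt)
                q_arr[m + 1 : stop] = np.array([q.as_array() for q in qs])

    start, stop = int(ms_idx[0]), int(ms_idx[-1])
    a_lab = np.full((n, 3), np.nan)
    a_lin = np.full((n, 3), np.nan)
    sl = slice(start, stop + 1)
    a_lab[sl], a_lin[sl] = lab_linear_acceleration(q_arr[sl], rec.a_s[sl])
    return OrientationTrack(q_se=q_arr, a_lab=a_lab, a_lin=a_lin, start=start, stop=stop)
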