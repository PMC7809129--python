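"""Domain types, quaternion primitives, and delimited-text I/O.

Conventions
-----------
* Laboratory frame ``E``: ``x`` superior (vertical, against gravity), ``y``
  roughly the walking direction, ``z`` lateral.  The gravity *direction* is
  the fixed unit vector ``[1, 0, 0]``; wherever a gravity *vector* in m/s²
  is needed it is scaled by ``G_MAG``.
* Sensor frame ``S``: ``x`` along the shank (inferior/superior), ``y``
  posterior/anterior, ``z`` medial/lateral (perpendicular to the sagittal
  plane).
* Quaternions are stored ``[w, x, y, z]`` (scalar first, Hamilton
  convention); ``q`` and ``-q`` encode the same rotation and are
  canonicalised to ``w >= 0`` on output.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "G_MAG",
    "GRAVITY_LAB",
    "FrameConvention",
    "Quaternion",
    "ImuRecording",
    "quat_multiply",
    "quat_rotate",
    "read_imu_csv",
    "write_imu_csv",
    "read_stride_csv",
    "write_stride_csv",
    "STRIDE_CSV_COLUMNS",
]

#: standard gravity, m/s²
G_MAG = 9.80665

#: unit gravity direction in the laboratory frame (x = superior)
GRAVITY_LAB = np.array([1.0, 0.0, 0.0])


@dataclasses.dataclass(frozen=True)
class FrameConvention:
    """Fixed axis conventions shared by every pipeline stage."""

    gravity_lab: np.ndarray = dataclasses.field(
        default_factory=lambda: GRAVITY_LAB.copy()
    )
    g_mag: float = G_MAG

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity_lab, dtype=float)
        if g.shape != (3,):
            raise ValueError("gravity_lab must be a 3-vector")
        if abs(np.linalg.norm(g) - 1.0) > 1e-9:
            raise ValueError("gravity_lab must have unit norm")
        object.__setattr__(self, "gravity_lab", g)


# ---------------------------------------------------------------------------
# Quaternion
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Quaternion:
    """Unit-norm rotation quaternion, components ``[w, x, y, z]``."""

    w: float
    v: np.ndarray  # vector part, shape (3,)

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        if v.shape != (3,):
            raise ValueError("vector part must be a 3-vector")
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "w", float(self.w))

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "Quaternion":
        return cls(1.0, np.zeros(3))

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "Quaternion":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4,):
            raise ValueError("expected length-4 array [w, x, y, z]")
        return cls(arr[0], arr[1:])

    @classmethod
    def from_axis_angle(cls, axis: Sequence[float], angle: float) -> "Quaternion":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0.0:
            raise ValueError("axis must be non-zero")
        half = 0.5 * angle
        return cls(math.cos(half), math.sin(half) * axis / n)

    # -- basic algebra ------------------------------------------------------
    def as_array(self) -> np.ndarray:
        return np.concatenate(([self.w], self.v))

    @property
    def norm(self) -> float:
        return float(math.sqrt(self.w * self.w + float(self.v @ self.v)))

    def normalized(self) -> "Quaternion":
        n = self.norm
        if n == 0.0:
            raise ValueError("cannot normalise zero quaternion")
        return Quaternion(self.w / n, self.v / n)

    def canonical(self) -> "Quaternion":
        """Return the representative with non-negative scalar part."""
        if self.w < 0.0:
            return Quaternion(-self.w, -self.v)
        return self

    def conjugate(self) -> "Quaternion":
        return Quaternion(self.w, -self.v)

    def multiply(self, other: "Quaternion") -> "Quaternion":
        return quat_multiply(self, other)

    def rotate(self, u: Sequence[float]) -> np.ndarray:
        return quat_rotate(self, u)

    def to_rotation_matrix(self) -> np.ndarray:
        """3x3 rotation matrix R with ``R @ u == quat_rotate(q, u)``."""
        w, (x, y, z) = self.w, self.v
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )


def quat_multiply(p: Quaternion, q: Quaternion) -> Quaternion:
    """Hamilton product ``p ⊗ q``."""
    w = p.w * q.w - float(p.v @ q.v)
    v = p.w * q.v + q.w * p.v + np.cross(p.v, q.v)
    return Quaternion(w, v)


def quat_rotate(q: Quaternion, u: Sequence[float]) -> np.ndarray:
    """Rotate vector ``u`` by unit quaternion ``q``.

    Vector part of ``q ⊗ [0, u] ⊗ q*``.  Raises if ``q`` deviates from unit
    norm by more than 1e-6.
    """
    if abs(q.norm - 1.0) > 1e-6:
        raise ValueError(f"quat_rotate requires a unit quaternion, |q| = {q.norm}")
    u = np.asarray(u, dtype=float)
    # v' = u + 2 w (v x u) + 2 v x (v x u)  — expansion of the sandwich product
    t = np.cross(q.v, u)
    return u + 2.0 * q.w * t + 2.0 * np.cross(q.v, t)


def quat_array_rotate(q_arr: np.ndarray, u_arr: np.ndarray) -> np.ndarray:
    """Vectorised row-wise rotation: ``q_arr`` (N,4) applied to ``u_arr`` (N,3)."""
    w = q_arr[:, :1]
    v = q_arr[:, 1:]
    t = np.cross(v, u_arr)
    return u_arr + 2.0 * w * t + 2.0 * np.cross(v, t)


# ---------------------------------------------------------------------------
# IMU recording
# ---------------------------------------------------------------------------

_T_UNIFORM_TOL = 1e-9


@dataclasses.dataclass
class ImuRecording:
    """Uniformly sampled 6-axis IMU stream in the sensor frame.

    Attributes
    ----------
    t : (N,) seconds, strictly increasing, constant spacing ``dt``.
    a_s : (N, 3) specific force, m/s².
    w_s : (N, 3) angular velocity, rad/s.
    dt : sampling interval, seconds.
    side : ``"left"`` or ``"right"``.
    """

    t: np.ndarray
    a_s: np.ndarray
    w_s: np.ndarray
    dt: float
    side: str = "left"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a_s = np.asarray(self.a_s, dtype=float)
        self.w_s = np.asarray(self.w_s, dtype=float)
        n = self.t.shape[0]
        if self.a_s.shape != (n, 3) or self.w_s.shape != (n, 3):
            raise ValueError("a_s and w_s must be (N, 3) arrays matching len(t)")
        if n >= 2:
            dts = np.diff(self.t)
            bad = np.nonzero(np.abs(dts - self.dt) > _T_UNIFORM_TOL)[0]
            if bad.size:
                k = int(bad[0])
                raise ValueError(
                    f"non-uniform timestamps: interval t[{k}]→t[{k + 1}] is "
                    f"{dts[k]:.12g} s, expected {self.dt:.12g} s"
                )
        if not np.isfinite(self.a_s).all() or not np.isfinite(self.w_s).all():
            raise ValueError("recording contains non-finite sensor samples")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


def read_imu_csv(
    path: str | Path,
    dt_expected: float | None = None,
    gyro_units: str = "deg",
    side: str = "left",
) -> ImuRecording:
    """Read an IMU recording from a CSV with columns ``t,ax,ay,az,gx,gy,gz``.

    ``gyro_units``: ``"deg"`` (default, converted to rad/s) or ``"rad"``.
    Raises on NaN rows and on non-uniform timestamps (first offending row is
    named in the message).
    """
    if gyro_units not in ("deg", "rad"):
        raise ValueError("gyro_units must be 'deg' or 'rad'")
    df = pd.read_csv(path)
    required = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    data = df[required].to_numpy(dtype=float)
    nan_rows = np.nonzero(~np.isfinite(data).all(axis=1))[0]
    if nan_rows.size:
        raise ValueError(f"{path}: non-finite values at row {int(nan_rows[0])}")
    t = data[:, 0]
    if t.shape[0] >= 2:
        dts = np.diff(t)
        dt = float(dts[0]) if dt_expected is None else float(dt_expected)
        if dt <= 0:
            raise ValueError(f"{path}: non-increasing timestamps at row 1")
        bad = np.nonzero(np.abs(dts - dt) > max(_T_UNIFORM_TOL, 1e-6 * dt))[0]
        if bad.size:
            k = int(bad[0])
            raise ValueError(
                f"{path}: non-uniform timestamp at row {k + 1} "
                f"(interval {dts[k]:.12g} s, expected {dt:.12g} s)"
            )
    else:
        dt = float(dt_expected) if dt_expected is not None else 0.0
    w = data[:, 4:7]
    if gyro_units == "deg":
        w = np.deg2rad(w)
    return ImuRecording(t=t, a_s=data[:, 1:4], w_s=w, dt=dt, side=side)


def write_imu_csv(rec: ImuRecording, path: str | Path, gyro_units: str = "rad") -> None:
    """Write a recording back to the ``t,ax,ay,az,gx,gy,gz`` CSV layout."""
    w = rec.w_s if gyro_units == "rad" else np.rad2deg(rec.w_s)
    df = pd.DataFrame(
        {
            "t": rec.t,
            "ax": rec.a_s[:, 0],
            "ay": rec.a_s[:, 1],
            "az": rec.a_s[:, 2],
            "gx": w[:, 0],
            "gy": w[:, 1],
            "gz": w[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Stride-result CSV
# ---------------------------------------------------------------------------

STRIDE_CSV_COLUMNS = [
    "side",
    "stride_index",
    "ms_start_s",
    "ms_end_s",
    "hs_s",
    "to_s",
    "stride_length_m",
    "vertical_disp_m",
    "duration_s",
    "velocity_mps",
]


def write_stride_csv(results, path: str | Path) -> None:
    """Write per-stride parameters to CSV (see :data:`STRIDE_CSV_COLUMNS`)."""
    rows = []
    for r in results:
        rows.append(
            {
                "side": r.side,
                "stride_index": r.stride_index,
                "ms_start_s": r.ms_start_s,
                "ms_end_s": r.ms_end_s,
                "hs_s": r.hs_s,
                "to_s": r.to_s,
                "stride_length_m": r.stride_length_m,
                "vertical_disp_m": r.vertical_disp_m,
                "duration_s": r.duration_s,
                "velocity_mps": r.velocity_mps,
            }
        )
    pd.DataFrame(rows, columns=STRIDE_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_stride_csv(path: str | Path):
    """Read a stride-result CSV into a list of :class:`StrideResult`."""
    from .stride_parameters import StrideResult  # local import: avoid cycle

    df = pd.read_csv(path)
    missing = [c for c in STRIDE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            StrideResult(
                stride_index=int(row["stride_index"]),
                stride_length_m=float(row["stride_length_m"]),
                vertical_disp_m=float(row["vertical_disp_m"]),
                duration_s=float(row["duration_s"]),
                velocity_mps=float(row["velocity_mps"]),
                ms_start_s=float(row["ms_start_s"]),
                ms_end_s=float(row["ms_end_s"]),
                hs_s=float(row["hs_s"]),
                to_s=float(row["to_s"]),
                side=str(row["side"]),
            )
        )
    return out
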