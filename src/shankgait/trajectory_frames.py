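"""Position integration and per-stride frame transformation.

The corrected velocity is trapezoid-integrated to a lab-frame trajectory.
For each stride a right-handed frame ``P`` is built whose ``y`` axis is the
normalised displacement between the bounding mid-stances, ``z`` is the
normalised cross product of the lab vertical with ``y``, and ``x = y × z``.
The stride trajectory is rotated into that frame and re-origined at the
opening mid-stance, making the spatial parameters translation-invariant.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import GRAVITY_LAB
from .velocity_drift import integrate_velocity

__all__ = [
    "StrideFrame",
    "Trajectory",
    "integrate_position",
    "stride_frame_rotation",
    "transform_stride",
]

_ORTHO_TOL = 1e-9


@dataclasses.dataclass
class StrideFrame:
    """Rotation from the lab frame into one stride's aligned frame."""

    R_ep: np.ndarray  # (3, 3)
    x_e: np.ndarray
    y_e: np.ndarray
    z_e: np.ndarray


@dataclasses.dataclass
class Trajectory:
    """Lab-frame positions plus per-stride transformed trajectories."""

    p_e: np.ndarray  # (N, 3), NaN outside covered span
    p_p: list[np.ndarray]  # per stride, closed window, origin at ms(i)
    segments: list[tuple[int, int]]


def integrate_position(v_corr: np.ndarray, dt: float, p0) -> np.ndarray:
    """Trapezoidal cumulative integral of velocity from ``p0``."""
    return integrate_velocity(v_corr, dt, p0)


def stride_frame_rotation(p_e: np.ndarray, ms_i: int, ms_j: int) -> StrideFrame:
    """Build the stride-aligned frame from the inter-mid-stance displacement.

    Raises when the displacement vanishes or is parallel to the lab vertical
    (the lateral axis is then undefined).
    """
    d = np.asarray(p_e[ms_j], dtype=float) - np.asarray(p_e[ms_i], dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0.0:
        raise ValueError("zero displacement between mid-stances: frame undefined")
    y_e = d / nd
    c = np.cross(GRAVITY_LAB, y_e)
    nc = np.linalg.norm(c)
    if nc < 1e-9:
        raise ValueError(
            "stride displacement parallel to the vertical axis: frame undefined"
        )
    z_e = c / nc
    x_e = np.cross(y_e, z_e)
    basis = np.column_stack([x_e, y_e, z_e])
    # basis is orthonormal by construction, so its transpose inverts it
    err = np.abs(basis.T @ basis - np.eye(3)).max()
    if err > _ORTHO_TOL:
        raise ValueError(f"stride basis not orthonormal (max deviation {err:.3g})")
    return StrideFrame(R_ep=basis.T, x_e=x_e, y_e=y_e, z_e=z_e)


def transform_stride(
    p_e: np.ndarray, frame: StrideFrame, seg: tuple[int, int]
) -> np.ndarray:
    """Rotate one stride's trajectory into its aligned frame.

    Returns the closed window ``p_e[ms_i .. ms_j]`` shifted so the opening
    mid-stance is the origin, then rotated by ``R_ep``.
    """
    a, b = int(seg[0]), int(seg[1])
    window = np.asarray(p_e[a : b + 1], dtype=float) - np.asarray(p_e[a], dtype=float)
    return window @ frame.R_ep.T
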