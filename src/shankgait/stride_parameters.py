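"""Per-stride spatial parameters.

Stride length is the forward (stride-frame ``y``) displacement between the
bounding mid-stances; shank vertical displacement is the maximum vertical
(stride-frame ``x``) excursion above the opening mid-stance; stride duration
spans consecutive heel strikes; stride velocity is length over duration.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "StrideResult",
    "stride_length",
    "shank_vertical_displacement",
    "stride_timing",
]


@dataclasses.dataclass
class StrideResult:
    """Spatial parameters for one gait cycle."""

    stride_index: int
    stride_length_m: float
    vertical_disp_m: float
    duration_s: float
    velocity_mps: float
    ms_start_s: float = float("nan")
    ms_end_s: float = float("nan")
    hs_s: float = float("nan")
    to_s: float = float("nan")
    side: str = "left"
    ms_start_idx: int | None = None
    ms_end_idx: int | None = None
    hs_idx: int | None = None
    hs_next_idx: int | None = None
    to_idx: int | None = None


def stride_length(p_p: np.ndarray, seg: tuple[int, int]) -> float:
    """Forward displacement between the bounding mid-stances.

    ``p_p`` is the stride's transformed trajectory over the closed window
    ``[ms_i, ms_j]``; ``seg`` holds the global indices.
    """
    m = int(seg[1]) - int(seg[0])
    return float(p_p[m, 1] - p_p[0, 1])


def shank_vertical_displacement(p_p: np.ndarray, seg: tuple[int, int]) -> float:
    """Maximum vertical excursion strictly inside the stride window."""
    m = int(seg[1]) - int(seg[0])
    if m < 2:
        return 0.0
    return float(np.max(p_p[1:m, 0] - p_p[0, 0]))


def stride_timing(
    hs_i: int, hs_j: int, dt: float, length: float
) -> tuple[float, float]:
    """Stride duration from the heel-strike pair and the derived velocity."""
    if hs_j <= hs_i:
        raise ValueError("heel strikes must be strictly increasing")
    duration = (hs_j - hs_i) * dt
    return duration, length / duration
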