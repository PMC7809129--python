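"""Ground-truth walking-shank simulator.

Generates planar (sagittal) shank-IMU signals that satisfy the method's
model assumptions exactly where it needs them:

* during each stance window the malleolus is a fixed pivot and the IMU sits
  at distance ``r`` along the shank axis;
* the sagittal angular-rate profile is a C1 chain of half-cosine arcs whose
  nodes place every gait-event extremum (SMF, HS, MS, TO) at a known time,
  with zero angular acceleration at each node — so at mid-stance the IMU's
  linear acceleration reduces to the (small, logged) centripetal term and
  the accelerometer reads almost pure gravity;
* during each swing window the malleolus translates forward by the stride
  length on a C2 quintic path with a smooth vertical lift while the shank
  counter-rotates.

Positions, velocities and accelerations are evaluated in closed form, so
the emitted accelerometer/gyroscope channels are exactly consistent with
the recorded ground-truth trajectory.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .core_io import G_MAG, ImuRecording
from .stride_parameters import StrideResult

__all__ = [
    "GaitSimConfig",
    "GroundTruthEvents",
    "SyntheticTrial",
    "simulate_walk",
    "add_sensor_noise",
]

logger = logging.getLogger(__name__)

# Relative angular-rate node values over one cycle (scaled to the requested
# tilt amplitude).  Order: SMF, post-SMF dip, HS peak, early-stance dip,
# mid-stance, TO trough, swing peak (solved), next SMF.
_V_DIP1 = -1.0
_V_HS = -0.45
_V_DIP2 = -0.9
_V_MS = -0.2
_V_TO = -1.6

# Cycle-local timing fractions.
_F_HS = 0.10  # heel strike, fraction of cycle
_F_DIP1 = 0.04
_F_DIP2 = 0.25  # fraction of stance window after HS
_F_MS = 0.50
_F_SWINGPEAK = 0.45  # fraction of swing window after TO
_TAIL_STANCE_FRACTION = 0.9  # how far into the final partial cycle to simulate


def _smoothstep5(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quintic smoothstep and its first two derivatives (C2 at both ends)."""
    f = s**3 * (6.0 * s * s - 15.0 * s + 10.0)
    d1 = 30.0 * s * s * (s - 1.0) ** 2
    d2 = 60.0 * s * (2.0 * s - 1.0) * (s - 1.0)
    return f, d1, d2


def _bump(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit bump 64 s³(1-s)³ (max 1 at s=0.5, C2-flat at both ends)."""
    f = 64.0 * s**3 * (1.0 - s) ** 3
    d1 = 192.0 * s * s * (1.0 - s) ** 2 * (1.0 - 2.0 * s)
    d2 = 192.0 * (
        2.0 * s * (1.0 - s) ** 2 * (1.0 - 2.0 * s)
        - 2.0 * s * s * (1.0 - s) * (1.0 - 2.0 * s)
        - 2.0 * s * s * (1.0 - s) ** 2
    )
    return f, d1, d2


class _CosineNodeProfile:
    """Scalar C1 profile through (time, value) nodes via half-cosine arcs.

    Each segment runs monotonically from one node value to the next with
    zero slope at both nodes, so every node is a critical point and the
    curvature vanishes there.  Value, derivative and running integral all
    have closed forms.
    """

    def __init__(self, times: np.ndarray, values: np.ndarray):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("need matching 1-D node arrays with >= 2 nodes")
        if np.any(np.diff(t) <= 0):
            raise ValueError("node times must be strictly increasing")
        self.t = t
        self.v = v
        self.dt = np.diff(t)
        self.a = 0.5 * (v[:-1] + v[1:])
        self.b = 0.5 * (v[:-1] - v[1:])
        # integral of each full segment is a_k * dt_k (cosine term cancels)
        self.cum = np.concatenate(([0.0], np.cumsum(self.a * self.dt)))

    def _locate(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.clip(np.searchsorted(self.t, t, side="right") - 1, 0, self.dt.size - 1)
        return idx, t - self.t[idx]

    def value(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx, tau = self._locate(t)
        return self.a[idx] + self.b[idx] * np.cos(np.pi * tau / self.dt[idx])

    def derivative(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx, tau = self._locate(t)
        return -self.b[idx] * (np.pi / self.dt[idx]) * np.sin(np.pi * tau / self.dt[idx])

    def integral(self, t: np.ndarray) -> np.ndarray:
        """Running integral from the first node."""
        t = np.asarray(t, dtype=float)
        idx, tau = self._locate(t)
        return (
            self.cum[idx]
            + self.a[idx] * tau
            + self.b[idx] * self.dt[idx] / np.pi * np.sin(np.pi * tau / self.dt[idx])
        )


@dataclasses.dataclass
class GaitSimConfig:
    """Simulator parameters; all noise is off by default."""

    n_strides: int = 10
    stride_length_m: float = 1.2
    stride_duration_s: float = 1.1
    stance_fraction: float = 0.4
    r_m: float = 0.05
    shank_tilt_amplitude_rad: float = 0.45
    fs_hz: float = 100.0
    accel_sigma: float = 0.0
    gyro_sigma: float = 0.0
    accel_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    standing_s: float = 1.0
    swing_lift_m: float = 0.03
    sway_amplitude_m: float = 0.0
    still_at_midstance: bool = False
    ms_dwell_s: float = 0.05
    ms_rate_jitter: float = 0.0  # fractional stride-to-stride spread of the
    # mid-stance angular rate (real gait varies; ZUPT error then varies too)
    side: str = "left"

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.r_m <= 0:
            raise ValueError("r_m must be positive")
        if self.stride_duration_s <= 0 or self.stride_length_m <= 0:
            raise ValueError("stride duration and length must be positive")
        if self.accel_sigma < 0 or self.gyro_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        t_hs = _F_HS * self.stride_duration_s
        t_to = t_hs + self.stance_fraction * self.stride_duration_s
        if t_to >= 0.85 * self.stride_duration_s:
            raise ValueError(
                "stance_fraction leaves no room for a C1 swing profile "
                "(toe-off too close to the end of the cycle)"
            )


@dataclasses.dataclass
class GroundTruthEvents:
    """Constructed event sample indices (cycle-indexed arrays)."""

    smf: np.ndarray
    smb: np.ndarray
    hs: np.ndarray
    to: np.ndarray
    ms: np.ndarray


@dataclasses.dataclass
class SyntheticTrial:
    """Simulated recording plus full ground truth (truth is pre-noise)."""

    rec: ImuRecording
    truth_p: np.ndarray  # (N, 3) IMU lab-frame position, m
    truth_v: np.ndarray  # (N, 3) IMU lab-frame velocity, m/s
    truth_a: np.ndarray  # (N, 3) IMU lab-frame acceleration, m/s²
    truth_malleolus: np.ndarray  # (N, 3) malleolus lab-frame position, m
    truth_events: GroundTruthEvents
    truth_params: list[StrideResult]
    config: GaitSimConfig
    rec_clean: ImuRecording | None = None


def _build_cycle_nodes(
    cfg: GaitSimConfig, v_ms: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Node times/values for one cycle and the SMB (tilt-minimum) time.

    Returns raw (unscaled) values; the swing-peak value is solved so the
    angular rate integrates to zero over the cycle (periodic tilt).
    ``v_ms`` overrides the relative mid-stance rate (stride-to-stride
    jitter); ignored for still-at-mid-stance trials.
    """
    T = cfg.stride_duration_s
    t_hs = _F_HS * T
    stance = cfg.stance_fraction * T
    t_to = t_hs + stance
    t_ms = t_hs + _F_MS * stance
    times = [0.0, _F_DIP1 * T, t_hs, t_hs + _F_DIP2 * stance]
    values = [0.0, _V_DIP1, _V_HS, _V_DIP2]
    if cfg.still_at_midstance:
        d = 0.5 * cfg.ms_dwell_s
        if not (times[-1] < t_ms - d and t_ms + d < t_to):
            raise ValueError("ms_dwell_s too large for the stance window")
        times += [t_ms - d, t_ms + d]
        values += [0.0, 0.0]
    else:
        times.append(t_ms)
        values.append(_V_MS if v_ms is None else v_ms)
    t_sw = t_to + _F_SWINGPEAK * (T - t_to)
    times += [t_to, t_sw, T]
    values += [_V_TO, np.nan, 0.0]  # swing peak solved below
    times = np.asarray(times)
    values = np.asarray(values)

    # zero net integral: sum over segments of (v_k + v_{k+1})/2 * dt_k == 0
    dts = np.diff(times)
    iw = int(np.nonzero(np.isnan(values))[0][0])
    coef = 0.5 * (dts[iw - 1] + dts[iw])
    vals0 = np.where(np.isnan(values), 0.0, values)
    const = float(np.sum(0.5 * (vals0[:-1] + vals0[1:]) * dts))
    values[iw] = -const / coef
    if values[iw] <= 0:
        raise ValueError("degenerate profile: swing peak not positive")

    # SMB = zero crossing of the rate in the TO -> swing-peak segment
    prof = _CosineNodeProfile(times, values)
    k = iw - 1  # segment from TO to swing peak
    a, b = prof.a[k], prof.b[k]
    s_cross = prof.dt[k] / math.pi * math.acos(-a / b)
    t_smb = float(prof.t[k] + s_cross)
    return times, values, t_smb


def simulate_walk(cfg: GaitSimConfig) -> SyntheticTrial:
    """Generate a trial with ``cfg.n_strides`` complete mid-stance strides."""
    T = cfg.stride_duration_s
    fs = cfg.fs_hz
    dt = 1.0 / fs
    prefix = cfg.standing_s
    t_hs = _F_HS * T
    stance = cfg.stance_fraction * T
    t_to = t_hs + stance
    t_ms = t_hs + _F_MS * stance
    n = cfg.n_strides
    n_full = n + 1  # full cycles 0..n carry the n+1 mid-stances

    cyc_t, cyc_v, t_smb = _build_cycle_nodes(cfg)

    # amplitude scaling: raw tilt minimum over one cycle -> requested range
    raw = _CosineNodeProfile(cyc_t, cyc_v)
    psi_min = float(raw.integral(np.array([t_smb]))[0])
    if psi_min >= 0:
        raise ValueError("degenerate profile: tilt minimum not negative")
    lam = cfg.shank_tilt_amplitude_rad / (-psi_min)
    psi_ms = float(raw.integral(np.array([t_ms]))[0])

    # per-cycle mid-stance rate jitter (clipped so the event-detection
    # extremum ordering is preserved)
    jit = np.random.default_rng([cfg.seed, 17]).standard_normal(n_full + 1)
    if cfg.ms_rate_jitter > 0 and not cfg.still_at_midstance:
        v_ms_c = np.clip(_V_MS * (1.0 + cfg.ms_rate_jitter * jit), -0.34, -0.05)
    else:
        v_ms_c = np.full(n_full + 1, _V_MS)

    # global node list: flat standing prefix, a lead-in hump that rotates the
    # shank from vertical into the first SMF tilt (so the first tilt maximum
    # has prominence on both sides), then n_full+1 cycles (the last one is
    # only sampled through its early stance, far enough to detect its HS)
    t_lead = min(0.35 * T, 0.8 * prefix)
    if t_lead > 0:
        w_lead = cfg.shank_tilt_amplitude_rad / t_lead  # hump area = A/2
        times = [
            np.array([0.0, prefix - t_lead, prefix - 0.5 * t_lead, prefix])
        ]
        values = [np.array([0.0, 0.0, w_lead, 0.0])]
    else:
        times = [np.array([0.0, prefix])] if prefix > 0 else [np.array([0.0])]
        values = [np.zeros(len(times[0]))]
    t_smb_c = np.empty(n_full + 1)
    for c in range(n_full + 1):
        ct, cv, t_smb_c[c] = _build_cycle_nodes(cfg, v_ms=float(v_ms_c[c]))
        times.append(prefix + c * T + ct[1:])
        values.append(lam * cv[1:])
    profile = _CosineNodeProfile(np.concatenate(times), np.concatenate(values))

    t_end = prefix + n_full * T + t_hs + _TAIL_STANCE_FRACTION * stance
    n_samp = int(math.floor(t_end * fs)) + 1
    t = np.arange(n_samp) * dt

    # shank angle (rad, about lab z) and derivatives; offset chosen so the
    # shank is vertical at every mid-stance, making the model's lever arm
    # (along the accelerometer = gravity direction there) exact
    lead_area = 0.5 * cfg.shank_tilt_amplitude_rad if t_lead > 0 else 0.0
    phi0 = -(lead_area + lam * psi_ms)
    omega = profile.value(t)  # = d(phi)/dt, also the gyro z channel
    alpha_ang = profile.derivative(t)
    phi = phi0 + profile.integral(t)

    # malleolus trajectory: fixed during stance, quintic advance in swing
    L = cfg.stride_length_m
    dsw = T - t_to + t_hs  # swing window length
    tc = t - prefix
    u = tc - t_to
    sc = np.floor(u / T).astype(int)
    s_local = (u - sc * T) / dsw
    n_sw = n_full  # swings 0..n move the malleolus
    in_swing = (sc >= 0) & (sc < n_sw) & (s_local < 1.0)
    completed = np.where(
        sc < 0, 0, np.where(sc >= n_sw, n_sw, np.where(s_local >= 1.0, sc + 1, sc))
    )
    m_p = np.zeros((n_samp, 3))
    m_v = np.zeros((n_samp, 3))
    m_a = np.zeros((n_samp, 3))
    m_p[:, 1] = L * completed
    if np.any(in_swing):
        s = s_local[in_swing]
        f, d1, d2 = _smoothstep5(s)
        g0, g1, g2 = _bump(s)
        m_p[in_swing, 1] = L * (sc[in_swing] + f)
        m_v[in_swing, 1] = L * d1 / dsw
        m_a[in_swing, 1] = L * d2 / dsw**2
        m_p[in_swing, 0] = cfg.swing_lift_m * g0
        m_v[in_swing, 0] = cfg.swing_lift_m * g1 / dsw
        m_a[in_swing, 0] = cfg.swing_lift_m * g2 / dsw**2
        if cfg.sway_amplitude_m:
            m_p[in_swing, 2] = cfg.sway_amplitude_m * g0
            m_v[in_swing, 2] = cfg.sway_amplitude_m * g1 / dsw
            m_a[in_swing, 2] = cfg.sway_amplitude_m * g2 / dsw**2
        if cfg.sway_amplitude_m:
            # sway advances and stays: net zero handled by bump (returns to 0)
            pass

    # IMU kinematics: p = malleolus + r * u(phi), u = [cos, sin, 0]
    r = cfg.r_m
    cphi, sphi = np.cos(phi), np.sin(phi)
    shank = np.column_stack([cphi, sphi, np.zeros(n_samp)])
    shank_d = np.column_stack([-sphi, cphi, np.zeros(n_samp)])
    p = m_p + r * shank
    v = m_v + r * omega[:, None] * shank_d
    a = m_a + r * (alpha_ang[:, None] * shank_d - (omega**2)[:, None] * shank)

    # sensor channels: a_s = Rz(phi)^T (a + g x̂), w_s = [0, 0, d(phi)/dt]
    a_grav = a.copy()
    a_grav[:, 0] += G_MAG
    a_s = np.column_stack(
        [
            cphi * a_grav[:, 0] + sphi * a_grav[:, 1],
            -sphi * a_grav[:, 0] + cphi * a_grav[:, 1],
            a_grav[:, 2],
        ]
    )
    w_s = np.column_stack([np.zeros(n_samp), np.zeros(n_samp), omega])

    rec = ImuRecording(t=t, a_s=a_s, w_s=w_s, dt=dt, side=cfg.side)

    # ground-truth events (sample indices)
    def _idx(tt: float) -> int:
        return int(round(tt * fs))

    ev = GroundTruthEvents(
        smf=np.array([_idx(prefix + c * T) for c in range(n_full)]),
        smb=np.array([_idx(prefix + c * T + t_smb_c[c]) for c in range(n_full)]),
        hs=np.array([_idx(prefix + c * T + t_hs) for c in range(n_full + 1)]),
        to=np.array([_idx(prefix + c * T + t_to) for c in range(n_full)]),
        ms=np.array([_idx(prefix + c * T + t_ms) for c in range(n_full)]),
    )

    resid = r * profile.value(np.array([prefix + t_ms])) ** 2
    logger.debug(
        "mid-stance centripetal residual %.4g m/s² (accelerometer is not "
        "exactly pure gravity there)",
        float(resid[0]),
    )

    truth_params: list[StrideResult] = []
    for i in range(n):
        a_i, b_i = int(ev.ms[i]), int(ev.ms[i + 1])
        length = float(p[b_i, 1] - p[a_i, 1])
        vert = float(np.max(p[a_i + 1 : b_i, 0]) - p[a_i, 0])
        hs_i, hs_j = int(ev.hs[i + 1]), int(ev.hs[i + 2])
        duration = (hs_j - hs_i) * dt
        truth_params.append(
            StrideResult(
                stride_index=i,
                stride_length_m=length,
                vertical_disp_m=vert,
                duration_s=duration,
                velocity_mps=length / duration,
                ms_start_s=float(t[a_i]),
                ms_end_s=float(t[b_i]),
                hs_s=float(t[hs_i]),
                to_s=float(t[int(ev.to[i + 1])]) if i + 1 < ev.to.size else float("nan"),
                side=cfg.side,
                ms_start_idx=a_i,
                ms_end_idx=b_i,
                hs_idx=hs_i,
                hs_next_idx=hs_j,
                to_idx=int(ev.to[i + 1]) if i + 1 < ev.to.size else None,
            )
        )

    trial = SyntheticTrial(
        rec=rec,
        truth_p=p,
        truth_v=v,
        truth_a=a,
        truth_malleolus=m_p,
        truth_events=ev,
        truth_params=truth_params,
        config=cfg,
        rec_clean=rec,
    )
    if (
        cfg.accel_sigma > 0
        or cfg.gyro_sigma > 0
        or any(cfg.accel_bias)
        or any(cfg.gyro_bias)
    ):
        trial = add_sensor_noise(
            trial,
            accel_sigma=cfg.accel_sigma,
            gyro_sigma=cfg.gyro_sigma,
            accel_bias=cfg.accel_bias,
            gyro_bias=cfg.gyro_bias,
            seed=cfg.seed,
        )
    return trial


def add_sensor_noise(
    trial: SyntheticTrial,
    accel_sigma: float = 0.0,
    gyro_sigma: float = 0.0,
    accel_bias=None,
    gyro_bias=None,
    seed: int = 0,
) -> SyntheticTrial:
    """Return a copy of the trial with i.i.d. Gaussian noise plus constant
    bias on each sensor channel; ground-truth fields are untouched."""
    if accel_sigma < 0 or gyro_sigma < 0:
        raise ValueError("noise sigmas must be non-negative")
    base = trial.rec_clean if trial.rec_clean is not None else trial.rec
    rng = np.random.default_rng(seed)
    shape = base.a_s.shape
    a_noise = rng.standard_normal(shape)
    w_noise = rng.standard_normal(shape)
    a_s = base.a_s + accel_sigma * a_noise
    w_s = base.w_s + gyro_sigma * w_noise
    if accel_bias is not None:
        a_s = a_s + np.asarray(accel_bias, dtype=float)
    if gyro_bias is not None:
        w_s = w_s + np.asarray(gyro_bias, dtype=float)
    rec = ImuRecording(t=base.t.copy(), a_s=a_s, w_s=w_s, dt=base.dt, side=base.side)
    return dataclasses.replace(trial, rec=rec, rec_clean=base)
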