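"""Stride-matched agreement statistics and the IPM-vs-ZUPT comparison harness.

Strides from two sources are paired by nearest mid-stance time, then per
parameter the error (estimate minus reference), absolute error, relative
absolute error, Pearson correlation, and Bland–Altman bias with 1.96-SD
limits of agreement are computed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
from scipy import stats as sstats

from .gait_events import EventConfig
from .pipeline import reconstruct
from .stride_parameters import StrideResult
from .synthetic_gait import SyntheticTrial

__all__ = [
    "AgreementStats",
    "MethodComparison",
    "pair_strides",
    "agreement",
    "compare_methods",
    "PARAMETER_FIELDS",
]

logger = logging.getLogger(__name__)

_LOA_MULT = 1.96

PARAMETER_FIELDS = {
    "stride_length": "stride_length_m",
    "stride_velocity": "velocity_mps",
    "vertical_disp": "vertical_disp_m",
    "duration": "duration_s",
}


@dataclasses.dataclass
class AgreementStats:
    """Descriptive agreement between estimated and reference strides."""

    n: int
    mean_error: float
    sd_error: float
    mean_abs_error: float
    sd_abs_error: float
    mean_rel_abs_error_pct: float
    sd_rel_abs_error_pct: float
    pearson_r: float  # NaN when undefined (constant series)
    pearson_defined: bool
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    n_rel_excluded: int = 0


@dataclasses.dataclass
class MethodComparison:
    """Per-parameter agreement for both update-velocity modes."""

    ipm: dict[str, AgreementStats]
    zupt: dict[str, AgreementStats]


def pair_strides(
    est: list[StrideResult],
    ref: list[StrideResult],
    tol_s: float = 0.25,
) -> list[tuple[StrideResult, StrideResult]]:
    """Greedy nearest-mid-stance-time matching within ``tol_s`` seconds.

    Unmatched strides on either side are excluded and logged.
    """
    if not est or not ref:
        warnings.warn("pair_strides: empty stride list, nothing to match")
        return []
    cands = []
    for i, e in enumerate(est):
        for j, r in enumerate(ref):
            d = abs(e.ms_start_s - r.ms_start_s)
            if d <= tol_s:
                cands.append((d, i, j))
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    used_e: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[StrideResult, StrideResult]] = []
    for _, i, j in cands:
        if i in used_e or j in used_r:
            continue
        used_e.add(i)
        used_r.add(j)
        pairs.append((est[i], ref[j]))
    pairs.sort(key=lambda p: p[0].ms_start_s)
    n_excl = (len(est) - len(pairs)) + (len(ref) - len(pairs))
    if n_excl:
        logger.info("pair_strides: %d strides left unmatched (excluded)", n_excl)
    return pairs


def agreement(
    pairs: list[tuple[StrideResult, StrideResult]], field: str
) -> AgreementStats:
    """Agreement statistics for one parameter over matched stride pairs.

    ``field`` is a :class:`StrideResult` attribute name or one of the
    aliases in :data:`PARAMETER_FIELDS`.
    """
    attr = PARAMETER_FIELDS.get(field, field)
    if len(pairs) < 2:
        raise ValueError("agreement needs at least two matched pairs")
    est = np.array([float(getattr(e, attr)) for e, _ in pairs])
    ref = np.array([float(getattr(r, attr)) for _, r in pairs])
    err = est - ref
    abs_err = np.abs(err)

    nz = ref != 0.0
    n_excl = int(np.sum(~nz))
    if n_excl:
        logger.info("agreement(%s): %d pairs with zero reference excluded "
                    "from the relative metric", field, n_excl)
    if np.any(nz):
        rel = 100.0 * abs_err[nz] / np.abs(ref[nz])
        rel_mean, rel_sd = float(np.mean(rel)), float(np.std(rel, ddof=1)) if rel.size > 1 else 0.0
    else:
        rel_mean, rel_sd = float("nan"), float("nan")

    if np.ptp(est) == 0.0 or np.ptp(ref) == 0.0:
        pearson, defined = float("nan"), False
        logger.warning("agreement(%s): constant series, Pearson r undefined", field)
    else:
        pearson = float(sstats.pearsonr(est, ref).statistic)
        defined = True

    sd_err = float(np.std(err, ddof=1))
    bias = float(np.mean(err))
    return AgreementStats(
        n=len(pairs),
        mean_error=bias,
        sd_error=sd_err,
        mean_abs_error=float(np.mean(abs_err)),
        sd_abs_error=float(np.std(abs_err, ddof=1)),
        mean_rel_abs_error_pct=rel_mean,
        sd_rel_abs_error_pct=rel_sd,
        pearson_r=pearson,
        pearson_defined=defined,
        ba_bias=bias,
        ba_loa_low=bias - _LOA_MULT * sd_err,
        ba_loa_high=bias + _LOA_MULT * sd_err,
        n_rel_excluded=n_excl,
    )


def compare_methods(
    trial: SyntheticTrial,
    events_cfg: EventConfig | None = None,
    tol_s: float = 0.25,
    fields: tuple[str, ...] = ("stride_length", "stride_velocity", "vertical_disp"),
) -> MethodComparison:
    """Run the pipeline in both modes against the trial's ground truth."""
    out: dict[str, dict[str, AgreementStats]] = {}
    for method in ("ipm", "zupt"):
        res = reconstruct(trial.rec, r=trial.config.r_m, method=method, events_cfg=events_cfg)
        pairs = pair_strides(res.strides, trial.truth_params, tol_s=tol_s)
        out[method] = {f: agreement(pairs, f) for f in fields}
    return MethodComparison(ipm=out["ipm"], zupt=out["zupt"])
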