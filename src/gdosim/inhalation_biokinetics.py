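"""Whole-body and lung retention after acute inhalation of Gd oxide particles.

A reduced human-respiratory-tract model: deposited activity (fraction
``deposition_fraction`` of the inhaled intake, default 0.55 for a type-M
oxide aerosol of AMAD 2.2 um) splits into a fast lung pool (fraction f_r,
mechanical clearance rate s_r) and a slow pool (1 - f_r, rate s_s).  Both
pools also absorb to blood at rate s_b.  Mechanically cleared material is
swallowed and held in a 1.5-d plug-flow gut stage before excretion; of the
absorbed stream a bound fraction f_b is retained long-term while the
remainder is treated as promptly excreted (the unbound systemic stream is
below 2 % of intake in the first month and no excretion kinetics are
available for it).

R(t) is *biological* retention: physical decay of the inhaled isotope is
applied separately by the caller (the release-ratio chain), never inside R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError, UnmeasurableSignalError
from .nuclide_data import Nuclide, decay_factor


@dataclass(frozen=True)
class HRTMParams:
    """Reduced respiratory-tract model parameters (rates per day)."""

    deposition_fraction: float = 0.55
    f_r: float = 0.5     # fast-clearing fraction of deposited activity
    s_r: float = 0.3     # fast mechanical clearance rate, 1/d
    s_s: float = 0.002   # slow mechanical clearance rate, 1/d
    s_b: float = 0.021   # absorption-to-blood rate, 1/d
    f_b: float = 0.07    # bound (long-term retained) fraction of absorbed stream
    gi_transit_time: float = 1.5  # plug-flow gut stage for swallowed material, d

    def __post_init__(self) -> None:
        for name in ("s_r", "s_s", "s_b", "gi_transit_time"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name in ("deposition_fraction", "f_r", "f_b"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")


def _check_t(t: float) -> None:
    if t < 0:
        raise InvalidInputError(f"time must be >= 0, got {t}")


def retention_lung(t: float, params: HRTMParams = HRTMParams()) -> float:
    """Lung retention fraction of the inhaled intake (biological)."""
    _check_t(t)
    p = params
    return p.deposition_fraction * (
        p.f_r * math.exp(-(p.s_r + p.s_b) * t)
        + (1.0 - p.f_r) * math.exp(-(p.s_s + p.s_b) * t)
    )


def _pool_terms(p: HRTMParams) -> list[tuple[float, float, float]]:
    """(weight, mechanical rate, total rate) per lung pool."""
    return [
        (p.f_r, p.s_r, p.s_r + p.s_b),
        (1.0 - p.f_r, p.s_s, p.s_s + p.s_b),
    ]


def retention_whole_body(t: float, params: HRTMParams = HRTMParams()) -> float:
    """Whole-body retention fraction R(t) of the inhaled intake (biological).

    Lung pools + swallowed material still in gut transit + bound fraction of
    the absorbed stream.  R(0) = deposition_fraction; the long-term plateau
    is the bound share, well below 0.1 * deposition_fraction.
    """
    _check_t(t)
    p = params
    total = 0.0
    t_gut = max(0.0, t - p.gi_transit_time)
    for w, s_mech, s_tot in _pool_terms(p):
        lung = w * math.exp(-s_tot * t)
        # swallowed in (t - tau, t], i.e. still inside the plug-flow gut
        in_gut = w * (s_mech / s_tot) * (math.exp(-s_tot * t_gut) - math.exp(-s_tot * t))
        bound = p.f_b * w * (p.s_b / s_tot) * -math.expm1(-s_tot * t)
        total += lung + in_gut + bound
    return p.deposition_fraction * total


def retention_curve(
    times: np.ndarray, params: HRTMParams = HRTMParams()
) -> pd.DataFrame:
    """Retention time series (t_days, R_wholebody, R_lung)."""
    ts = np.asarray(times, dtype=float)
    return pd.DataFrame(
        {
            "t_days": ts,
            "R_wholebody": [retention_whole_body(float(t), params) for t in ts],
            "R_lung": [retention_lung(float(t), params) for t in ts],
        }
    )


def intake_from_measured_burden(
    q_measured: float,
    tracer: Nuclide,
    t: float,
    a_tracer_148_t0: float,
    params: HRTMParams = HRTMParams(),
    *,
    floor: float = 1e-12,
) -> float:
    """Invert a measured tracer body burden to the Gd-148 inhaled intake (Bq).

    The measured burden of the gamma emitter at ``t`` days post release is
    Q = I_inh * a(t0) * R(t) * exp(-lambda_tracer * t); physical decay is
    applied explicitly because R is not decay corrected.

    Raises :class:`UnmeasurableSignalError` when R(t) * decay underflows
    ``floor`` (the tracer signal carries no usable information).
    """
    _check_t(t)
    if q_measured < 0:
        raise InvalidInputError(f"measured burden must be >= 0, got {q_measured}")
    signal = retention_whole_body(t, params) * decay_factor(tracer, t)
    if signal < floor:
        raise UnmeasurableSignalError(
            f"tracer retention*decay = {signal:.3e} below floor {floor:.0e} at t={t} d"
        )
    return q_measured / (a_tracer_148_t0 * signal)
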