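"""Bi-exponential lesion growth model and event-time mathematics.

The structural model describes a treated lesion as a mixture of a
regressing (drug-sensitive) and a regrowing (resistant) cell population:

    V(t) = V0 * [F * exp(Kg*t) + (1 - F) * exp(-Kd*t)]

where ``V0`` is the baseline volume (mm^3), ``F`` the fraction of
non-responding cells, ``Kg`` the regrowth (progression) rate and ``Kd``
the regression (kill) rate, both in 1/day.  Volumetric response and
progression thresholds are evaluated on this curve: response when the
volume has dropped >= 20% from baseline, progression when it has risen
>= 30% or >= 200 mm^3 above the nadir.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthParams",
    "EventTime",
    "DEFAULT_AXIS_RATIO",
    "diameter_to_volume",
    "volume_to_diameter",
    "predict_volume",
    "nadir_time",
    "time_to_response",
    "time_to_progression",
]

#: Default ratio of tumor long axis to short axis used in the
#: ellipsoidal diameter-to-volume conversion.
DEFAULT_AXIS_RATIO = 1.31

_BISECT_TOL = 1e-6  # absolute tolerance on event times, days
_EXP_CAP = 500.0  # cap on exponents to avoid overflow in degenerate draws


@dataclass(frozen=True)
class GrowthParams:
    """Structural parameters of a single lesion's growth curve."""

    v0: float
    f: float
    kg: float
    kd: float

    def __post_init__(self) -> None:
        if not (self.v0 > 0 and math.isfinite(self.v0)):
            raise ValueError(f"V0 must be positive and finite, got {self.v0}")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"F must lie in [0, 1], got {self.f}")
        if self.kg < 0 or self.kd < 0 or not math.isfinite(self.kg) or not math.isfinite(self.kd):
            raise ValueError(f"rates must be finite and non-negative, got Kg={self.kg}, Kd={self.kd}")


@dataclass(frozen=True)
class EventTime:
    """A model-derived event time; ``reached=False`` marks a never-crossed threshold."""

    time: float
    reached: bool
    threshold_used: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.reached and not (math.isfinite(self.time) and self.time >= 0):
            raise ValueError("a reached event requires a finite non-negative time")


def diameter_to_volume(long_mm, axis_ratio: float = DEFAULT_AXIS_RATIO):
    """Convert longest diameter (mm) to ellipsoidal volume (mm^3).

    Uses V = long * short^2 / 2 with short = long / axis_ratio, the
    standard rotational-ellipsoid approximation for CT lesion measurements.
    Accepts scalars or arrays.
    """
    if axis_ratio <= 0:
        raise ValueError("axis_ratio must be positive")
    long_mm = np.asarray(long_mm, dtype=float)
    if np.any(long_mm < 0):
        raise ValueError("diameter must be non-negative")
    vol = long_mm * (long_mm / axis_ratio) ** 2 / 2.0
    return float(vol) if vol.ndim == 0 else vol


def volume_to_diameter(volume_mm3, axis_ratio: float = DEFAULT_AXIS_RATIO):
    """Exact inverse of :func:`diameter_to_volume`."""
    if axis_ratio <= 0:
        raise ValueError("axis_ratio must be positive")
    volume_mm3 = np.asarray(volume_mm3, dtype=float)
    if np.any(volume_mm3 < 0):
        raise ValueError("volume must be non-negative")
    diam = np.cbrt(2.0 * volume_mm3 * axis_ratio**2)
    return float(diam) if diam.ndim == 0 else diam


def predict_volume(params: GrowthParams, t):
    """Evaluate V(t) = V0[F e^{Kg t} + (1-F) e^{-Kd t}] at time(s) ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    grow = np.exp(np.minimum(params.kg * t, _EXP_CAP))
    decay = np.exp(np.maximum(-params.kd * t, -_EXP_CAP))
    v = params.v0 * (params.f * grow + (1.0 - params.f) * decay)
    return float(v) if v.ndim == 0 else v


def nadir_time(params: GrowthParams) -> float:
    """Time of the curve's minimum.

    Interior minimum exists when both populations are present and the
    initial slope is negative, i.e. Kd(1-F) > Kg*F; then

        t* = ln[Kd(1-F) / (Kg F)] / (Kg + Kd).

    Returns 0.0 when the curve is non-decreasing from baseline and
    ``inf`` for pure monotone decay (F == 0 or Kg == 0 with F < 1 and
    Kd > 0), whose infimum is approached but never attained.
    """
    f, kg, kd = params.f, params.kg, params.kd
    if f >= 1.0 or (kd == 0.0 and kg == 0.0):
        return 0.0
    if f == 0.0 or kg == 0.0:
        return math.inf if kd > 0.0 else 0.0
    num = kd * (1.0 - f)
    den = kg * f
    if num <= den:
        return 0.0  # slope non-negative at t=0: baseline is the nadir
    return math.log(num / den) / (kg + kd)


def nadir_volume(params: GrowthParams) -> float:
    """Volume at the nadir (``V0*F`` asymptote when the nadir is at infinity)."""
    tn = nadir_time(params)
    if math.isinf(tn):
        return params.v0 * params.f  # = 0 when F == 0
    return predict_volume(params, tn)


def _bisect(fun, lo: float, hi: float, tol: float = _BISECT_TOL) -> float:
    """Bisection for fun(lo) <= 0 <= fun(hi) (or the reverse), monotone fun."""
    flo = fun(lo)
    if flo == 0.0:
        return lo
    increasing = flo < 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = fun(mid)
        if (fm < 0) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def time_to_response(params: GrowthParams, response_fraction: float = 0.20) -> EventTime:
    """Smallest t > 0 with V(t) <= (1 - response_fraction) * V0.

    Not reached when the curve never drops that far below baseline
    (in particular whenever F >= 1 - response_fraction, since
    V(t) >= F*V0 for all t).
    """
    if not (0.0 < response_fraction < 1.0):
        raise ValueError("response_fraction must lie in (0, 1)")
    thr = (1.0 - response_fraction) * params.v0
    f, kd = params.f, params.kd
    if f == 0.0:
        # single decaying exponential: V0 e^{-Kd t} = thr
        if kd == 0.0:
            return EventTime(math.nan, False, thr)
        return EventTime(math.log(1.0 / (1.0 - response_fraction)) / kd, True, thr)
    if f == 1.0:
        return EventTime(math.nan, False, thr)
    tn = nadir_time(params)
    if tn == 0.0 or nadir_volume(params) > thr:
        return EventTime(math.nan, False, thr)
    hi = min(tn, 1e7) if math.isfinite(tn) else 1e7
    # V is strictly decreasing on (0, tn); bracket [0, hi] is guaranteed
    t = _bisect(lambda s: predict_volume(params, s) - thr, 0.0, hi)
    return EventTime(t, True, thr)


def time_to_progression(
    params: GrowthParams,
    rel: float = 0.30,
    abs_mm3: float = 200.0,
    rule: str = "or",
) -> EventTime:
    """Smallest t >= nadir with V(t) >= threshold above the nadir volume.

    Under the default ``rule="or"`` either criterion triggers progression,
    so the effective threshold is min((1+rel)*Vn, Vn + abs_mm3); with
    ``rule="and"`` both must hold (max of the two), mirroring RECIST 1.1.
    Never reached when the curve has no regrowth component (F == 0 or
    Kg == 0).
    """
    if rel <= 0:
        raise ValueError("rel must be positive")
    if abs_mm3 < 0:
        raise ValueError("abs_mm3 must be non-negative")
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    f, kg = params.f, params.kg
    if f == 0.0 or kg == 0.0:
        return EventTime(math.nan, False, math.nan)
    tn = nadir_time(params)
    vn = nadir_volume(params)
    pick = min if rule == "or" else max
    thr = pick((1.0 + rel) * vn, vn + abs_mm3)
    if f == 1.0:
        # pure exponential growth from baseline: V0 e^{Kg t} = thr
        return EventTime(math.log(thr / params.v0) / kg, True, thr)
    # bracket: V(t) >= V0 F e^{Kg t}, so the crossing is below
    # t_hi solving V0 F e^{Kg t_hi} = thr
    hi = math.log(max(thr / (params.v0 * f), 1.0)) / kg + 1.0
    lo = tn
    if predict_volume(params, lo) >= thr:  # nadir itself already past threshold (thr<=Vn impossible, safety)
        return EventTime(lo, True, thr)
    while predict_volume(params, hi) < thr:  # safety widening; analytically unnecessary
        hi *= 2.0
        if hi > 1e9:
            return EventTime(math.nan, False, thr)
    t = _bisect(lambda s: predict_volume(params, s) - thr, lo, hi)
    return EventTime(t, True, thr)
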