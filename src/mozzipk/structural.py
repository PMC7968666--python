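"""Deterministic individual amount-time curves and exposure metrics.

Three candidate elimination types are supported for the whole-body amount
A(t) of a drug after a bolus blood meal of absorbed amount D, each with an
initial lag phase during which the amount stays at D:

* zero_order:        A(t) = max(D - k_el (t - T_lag), 0)
* first_order:       A(t) = D exp(-k (t - T_lag))
* michaelis_menten:  dA/dt = -Vmax A / (Km + A), solved implicitly

for t > T_lag.  Amounts are physical quantities and never negative; the
zero-order curve is clipped at exactly 0 after depletion.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .datamodel import StructuralParams

__all__ = ["amount_at", "depletion_time", "auc", "auc_ratio"]


def _mm_inverse(D: float, vmax: float, km: float, tau: float) -> float:
    """Amount remaining tau hours after elimination onset for the
    Michaelis-Menten model: the root A in (0, D] of
    tau = (D - A)/Vmax + (Km/Vmax) ln(D/A).

    The implicit time solution is strictly decreasing in A, so bisection
    (brentq) on (eps*D, D] is robust; the curve decays asymptotically and 0
    is never returned.
    """
    if tau <= 0:
        return D

    def implied_time(a: float) -> float:
        return (D - a) / vmax + (km / vmax) * math.log(D / a) - tau

    lo = 1e-12 * D
    # expand the bracket downwards in the (extreme) case the root is tinier
    while implied_time(lo) < 0 and lo > 1e-300:
        lo *= 1e-12
    return brentq(implied_time, lo, D, rtol=1e-12, maxiter=200)


def amount_at(params: StructuralParams, t) -> float | np.ndarray:
    """Whole-body amount (ng) at time(s) ``t`` hours post feeding."""
    params.validate()
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    tau = np.maximum(t_arr - params.tlag_h, 0.0)
    D = params.dose_ng
    if params.model_kind == "zero_order":
        out = np.maximum(D - params.kel_ng_per_h * tau, 0.0)
    elif params.model_kind == "first_order":
        out = D * np.exp(-params.k_per_h * tau)
    else:
        out = np.vectorize(
            lambda x: _mm_inverse(D, params.vmax_ng_per_h, params.km_ng, x)
        )(tau).astype(float)
    return out if t_arr.ndim else float(out)


def depletion_time(params: StructuralParams) -> float:
    """Time at which the amount first reaches 0 (finite only for zero-order:
    T_lag + D/k_el; exponential and Michaelis-Menten decay never reach 0)."""
    params.validate()
    if params.model_kind != "zero_order":
        return math.inf
    return params.tlag_h + params.dose_ng / params.kel_ng_per_h


def auc(params: StructuralParams, t_end: float = math.inf) -> float:
    """Area under the amount-time curve (ng*h) from 0 to ``t_end``.

    Closed forms for zero- and first-order (to infinity:
    D*T_lag + D^2/(2 k_el) and D*T_lag + D/k); the Michaelis-Menten integral
    to infinity is (Km*D + D^2/2)/Vmax, finite horizons by adaptive
    quadrature.
    """
    params.validate()
    if t_end <= 0:
        if t_end == 0:
            return 0.0
        raise ValueError("t_end must be > 0")
    D, tlag = params.dose_ng, params.tlag_h
    plateau = D * min(t_end, tlag)
    tau = t_end - tlag
    if tau <= 0:
        return plateau
    if params.model_kind == "zero_order":
        k = params.kel_ng_per_h
        tau_dep = D / k
        if tau >= tau_dep:
            return plateau + D * D / (2.0 * k)
        return plateau + D * tau - k * tau * tau / 2.0
    if params.model_kind == "first_order":
        k = params.k_per_h
        if math.isinf(tau):
            return plateau + D / k
        return plateau + (D / k) * (1.0 - math.exp(-k * tau))
    vmax, km = params.vmax_ng_per_h, params.km_ng
    if math.isinf(tau):
        return plateau + (km * D + D * D / 2.0) / vmax
    val, _ = quad(lambda x: _mm_inverse(D, vmax, km, x), 0.0, tau,
                  limit=200, epsabs=1e-12, epsrel=1e-10)
    return plateau + val


def auc_ratio(base: StructuralParams, modified: StructuralParams,
              t_end: float = math.inf) -> float:
    """Exposure ratio auc(modified)/auc(base) over a shared horizon."""
    denom = auc(base, t_end)
    if denom == 0:
        raise ValueError("base AUC is zero")
    return auc(modified, t_end) / denom
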