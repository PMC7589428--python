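"""Time-activity-curve models, fitting, and time-integrated activity.

The time-integrated activity (TIA, MBq.h) of a source region is the
integral of its time-activity curve on (0, inf); dividing by the injected
activity A0 gives the time-integrated activity coefficient (TIAC, hours).
Clinical platforms integrate TACs in a handful of ways, all implemented
here:

``monoexp``
    least-squares fit of A exp(-lambda t); TIA = A / lambda.
``biexp``
    damped least-squares (Levenberg-Marquardt-style) fit of
    A1 exp(-l1 t) + A2 exp(-l2 t), initialized from a mono-exponential
    peel; TIA = A1/l1 + A2/l2.
``powerexp``
    fit of f(t) = A t^b exp(-c t^d) with c, d > 0 and b > -1 for
    integrability; TIA by adaptive quadrature.
``trapezoid_tail``
    piecewise-linear integration between sampled points with a
    configurable head rule before the first point (a straight line from
    zero, or constant at the first sample) and a mono-exponential tail
    after the last point at the physical decay rate by default.

Goodness of fit is reported as the Spearman rank correlation between
observed and fitted values, plus the residual sum of squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, optimize, stats

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    IntegrabilityError,
    InvalidInputError,
)

#: Default tail extrapolation rate: physical decay of Lu-177 (T1/2 = 159.53 h).
LU177_LAMBDA_PHYS_PER_H = math.log(2.0) / 159.53

FIT_FAMILIES = ("monoexp", "biexp", "powerexp", "trapezoid_tail")
HEAD_RULES = ("zero_line", "constant")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-organ (time, activity) samples with the injected activity A0."""

    label: int
    name: str
    times_h: np.ndarray
    activities_MBq: np.ndarray
    a0_MBq: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.activities_MBq, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "activities_MBq", a)
        if t.ndim != 1 or t.shape != a.shape or t.size < 1:
            raise InvalidInputError("times and activities must be matched 1-D, length >= 1")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(a < 0):
            raise InvalidInputError("activities must be >= 0")
        if not self.a0_MBq > 0:
            raise InvalidInputError("A0 must be > 0 MBq")

    def __len__(self) -> int:
        return int(self.times_h.size)


@dataclass(frozen=True)
class FitModel:
    """A fit-family choice plus its head/tail options (trapezoid only)."""

    family: str
    head_rule: str = "zero_line"
    tail_rate_per_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FIT_FAMILIES:
            raise ConfigurationError(f"unknown fit family {self.family!r}")
        if self.head_rule not in HEAD_RULES:
            raise ConfigurationError(f"unknown head rule {self.head_rule!r}")
        if self.tail_rate_per_h is not None and not self.tail_rate_per_h > 0:
            raise InvalidInputError("tail rate must be > 0 per hour")


@dataclass(frozen=True)
class FitResult:
    """A fitted TAC: parameters, TIA/TIAC, goodness, convergence."""

    model: FitModel
    parameters: Dict[str, float]
    tia_MBqh: float
    tiac_h: float
    goodness_spearman: float
    rss: float
    converged: bool
    n_points: int
    n_params: int
    warnings: Tuple[str, ...] = ()
    fitted_values: Tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "model": self.model.family,
            "head_rule": self.model.head_rule if self.model.family == "trapezoid_tail" else None,
            "parameters": dict(self.parameters),
            "TIA_MBqh": self.tia_MBqh,
            "TIAC_h": self.tiac_h,
            "goodness_spearman": self.goodness_spearman,
            "rss": self.rss,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


def _spearman(observed: np.ndarray, fitted: np.ndarray) -> float:
    if observed.size < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(observed, fitted).statistic
    return float(rho)


def _result(
    model: FitModel,
    tac: TimeActivityCurve,
    params: Dict[str, float],
    tia: float,
    fitted: np.ndarray,
    converged: bool,
    n_params: int,
    warn: Sequence[str] = (),
) -> FitResult:
    resid = tac.activities_MBq - fitted
    return FitResult(
        model=model,
        parameters=params,
        tia_MBqh=float(tia),
        tiac_h=float(tia) / tac.a0_MBq,
        goodness_spearman=_spearman(tac.activities_MBq, fitted),
        rss=float((resid * resid).sum()),
        converged=converged,
        n_points=len(tac),
        n_params=n_params,
        warnings=tuple(warn),
        fitted_values=tuple(float(v) for v in fitted),
    )


# ---------------------------------------------------------------------------
# mono-exponential
# ---------------------------------------------------------------------------

def fit_monoexp(tac: TimeActivityCurve) -> FitResult:
    """Least-squares fit of A exp(-lambda t); TIA = A / lambda."""
    t, y = tac.times_h, tac.activities_MBq
    if len(tac) < 2:
        raise InsufficientDataError("mono-exponential fit needs >= 2 points")
    if np.any(y <= 0):
        raise InvalidInputError("mono-exponential fit needs positive activities")
    warn = []
    slope, intercept = np.polyfit(t, np.log(y), 1)
    lam0, a0 = -slope, math.exp(intercept)
    if lam0 <= 0:
        warn.append("non-decaying data: decay rate clamped at lower bound")
        lam0 = 1e-9

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - y

    sol = optimize.least_squares(
        resid, x0=[a0, lam0], bounds=([0.0, 1e-12], [np.inf, np.inf]),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    amp, lam = sol.x
    fitted = amp * np.exp(-lam * t)
    params = {"A_MBq": float(amp), "lambda_per_h": float(lam)}
    return _result(
        FitModel("monoexp"), tac, params, amp / lam, fitted,
        converged=bool(sol.success) and not warn, n_params=2, warn=warn,
    )


# ---------------------------------------------------------------------------
# bi-exponential
# ---------------------------------------------------------------------------

def _biexp_init(t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float]:
    """Peel the slow component off the late points, the fast off the residual."""
    lam_s = math.log(max(y[-2] / y[-1], 1.0 + 1e-9)) / (t[-1] - t[-2])
    lam_s = max(lam_s, 1e-6)
    a_s = y[-1] * math.exp(lam_s * t[-1])
    resid = y - a_s * np.exp(-lam_s * t)
    if np.max(np.abs(resid)) <= 1e-10 * np.max(y):
        # the slow component already explains the curve (degenerate case)
        return 0.0, 2.0 * lam_s, a_s, lam_s
    if resid[0] > 0 and resid[1] > 0 and resid[0] > resid[1]:
        lam_f = math.log(resid[0] / resid[1]) / (t[1] - t[0])
        a_f = resid[0] * math.exp(lam_f * t[0])
    else:
        lam_f, a_f = 10.0 * lam_s, 0.5 * a_s
    return a_f, max(lam_f, 2.0 * lam_s), a_s, lam_s


def fit_biexp(tac: TimeActivityCurve, allow_washin: bool = False) -> FitResult:
    """Damped least-squares fit of A1 exp(-l1 t) + A2 exp(-l2 t).

    Initialized from a mono-exponential peel of the curve so the fit is
    deterministic.  Both rates are constrained positive; both amplitudes
    too unless ``allow_washin`` frees A1's sign to represent uptake.
    TIA = A1/l1 + A2/l2.
    """
    t, y = tac.times_h, tac.activities_MBq
    if len(tac) < 4:
        raise InsufficientDataError("bi-exponential fit needs >= 4 points")
    x0 = np.array(_biexp_init(t, y))
    lo_a1 = -np.inf if allow_washin else 0.0

    def resid(p):
        return p[0] * np.exp(-p[1] * t) + p[2] * np.exp(-p[3] * t) - y

    sol = optimize.least_squares(
        resid, x0=x0,
        bounds=([lo_a1, 1e-12, 0.0, 1e-12], [np.inf, np.inf, np.inf, np.inf]),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
    )
    a1, l1, a2, l2 = sol.x
    # canonical order: fast component first
    if l1 < l2:
        a1, l1, a2, l2 = a2, l2, a1, l1
    fitted = a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t)
    params = {
        "A1_MBq": float(a1), "lambda1_per_h": float(l1),
        "A2_MBq": float(a2), "lambda2_per_h": float(l2),
    }
    tia = a1 / l1 + a2 / l2
    warn = [] if sol.success else ["bi-exponential fit did not converge"]
    return _result(
        FitModel("biexp"), tac, params, tia, fitted,
        converged=bool(sol.success), n_params=4, warn=warn,
    )


# ---------------------------------------------------------------------------
# power-exponential  f(t) = A t^b exp(-c t^d)
# ---------------------------------------------------------------------------

def _powerexp(t, a, b, c, d):
    return a * np.power(t, b) * np.exp(-c * np.power(t, d))


def powerexp_tia(a: float, b: float, c: float, d: float, t_split: float) -> float:
    """Integral of A t^b exp(-c t^d) on (0, inf) by adaptive quadrature."""
    if b <= -1.0:
        raise IntegrabilityError("power-exponential with b <= -1 is not integrable at 0")
    f = lambda t: _powerexp(t, a, b, c, d)
    head, _ = integrate.quad(f, 0.0, t_split, epsabs=0.0, epsrel=1e-10, limit=200)
    tail, _ = integrate.quad(f, t_split, np.inf, epsabs=0.0, epsrel=1e-10, limit=200)
    return float(head + tail)


def fit_powerexp(tac: TimeActivityCurve) -> FitResult:
    """Least-squares fit of the four-parameter power-exponential family.

    Initialized from the mono-exponential fit (b=0, d=1), which the family
    nests exactly.  Rejects optima with b <= -1 (divergent integral).
    """
    t, y = tac.times_h, tac.activities_MBq
    if len(tac) < 4:
        raise InsufficientDataError("power-exponential fit needs >= 4 points")
    if np.any(t <= 0):
        raise InvalidInputError("power-exponential fit needs strictly positive times")
    mono = fit_monoexp(tac)
    x0 = np.array([mono.parameters["A_MBq"], 0.0, mono.parameters["lambda_per_h"], 1.0])

    def resid(p):
        return _powerexp(t, *p) - y

    sol = optimize.least_squares(
        resid, x0=x0,
        bounds=([0.0, -1.0, 1e-12, 1e-6], [np.inf, np.inf, np.inf, np.inf]),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
    )
    a, b, c, d = (float(v) for v in sol.x)
    if b <= -1.0 + 1e-9:
        raise IntegrabilityError("fitted b <= -1: TIA integral diverges")
    fitted = _powerexp(t, a, b, c, d)
    tia = powerexp_tia(a, b, c, d, t_split=float(t[-1]))
    params = {"A": a, "b": b, "c_per_h": c, "d": d}
    warn = [] if sol.success else ["power-exponential fit did not converge"]
    return _result(
        FitModel("powerexp"), tac, params, tia, fitted,
        converged=bool(sol.success), n_params=4, warn=warn,
    )


# ---------------------------------------------------------------------------
# trapezoid + mono-exponential tail
# ---------------------------------------------------------------------------

def integrate_trapezoid_tail(
    tac: TimeActivityCurve,
    head_rule: str = "zero_line",
    tail_rate_per_h: Optional[float] = None,
) -> FitResult:
    """Piecewise-linear TIA: head rule + trapezoids + physical-decay tail.

    head: 0.5 * t1 * A1 (``zero_line``: straight line from the origin) or
    t1 * A1 (``constant``: activity held at the first sample since t=0);
    tail: A_last / tail_rate (analytic integral of the mono-exponential
    extrapolation).  The default tail rate is the Lu-177 physical decay
    constant.
    """
    model = FitModel("trapezoid_tail", head_rule=head_rule, tail_rate_per_h=tail_rate_per_h)
    lam = tail_rate_per_h if tail_rate_per_h is not None else LU177_LAMBDA_PHYS_PER_H
    t, y = tac.times_h, tac.activities_MBq
    head = (0.5 if head_rule == "zero_line" else 1.0) * t[0] * y[0]
    body = float(np.trapezoid(y, t)) if len(tac) > 1 else 0.0
    tail = y[-1] / lam
    tia = head + body + tail
    params = {"head_MBqh": float(head), "body_MBqh": body, "tail_MBqh": float(tail),
              "tail_rate_per_h": float(lam)}
    return _result(model, tac, params, tia, fitted=y.copy(), converged=True, n_params=0)


# ---------------------------------------------------------------------------
# automatic model selection
# ---------------------------------------------------------------------------

def _criterion(res: FitResult) -> float:
    """Small-sample-corrected information criterion (AICc, denominator clamped).

    RSS is floored at n * (1e-12 * max|y|)^2 so exact fits compare by
    parameter count rather than by floating-point noise.
    """
    n, k = res.n_points, res.n_params
    scale = max(abs(v) for v in res.fitted_values) if res.fitted_values else 1.0
    floor = n * (1e-12 * max(scale, 1e-300)) ** 2
    rss = max(res.rss, floor)
    correction = 2.0 * k * (k + 1) / max(n - k - 1, 1)
    return n * math.log(rss / n) + 2.0 * k + correction


_FITTERS: Dict[str, Callable[[TimeActivityCurve], FitResult]] = {
    "monoexp": fit_monoexp,
    "biexp": fit_biexp,
    "powerexp": fit_powerexp,
}


def auto_select(
    tac: TimeActivityCurve,
    candidates: Sequence[FitModel] = (FitModel("monoexp"), FitModel("biexp")),
    head_rule: str = "zero_line",
    tail_rate_per_h: Optional[float] = None,
) -> FitResult:
    """Best-fitting model per VOI by clamped AICc; parsimony breaks ties.

    Parametric candidates that are inapplicable (too few points) or fail to
    converge are dropped; if none survive, the trapezoid+tail integral is
    returned with a warning (it is always applicable).
    """
    scored = []
    for cand in candidates:
        if cand.family == "trapezoid_tail":
            continue  # fallback, not a competing parametric model
        fitter = _FITTERS[cand.family]
        try:
            res = fitter(tac)
        except (InsufficientDataError, InvalidInputError, IntegrabilityError):
            continue
        if res.converged:
            scored.append((res, _criterion(res)))
    if scored:
        best, _ = min(scored, key=lambda rc: (rc[1], rc[0].n_params))
        return best
    fallback = integrate_trapezoid_tail(tac, head_rule=head_rule, tail_rate_per_h=tail_rate_per_h)
    warn = fallback.warnings + ("no parametric candidate converged; trapezoid+tail used",)
    return FitResult(**{**fallback.__dict__, "warnings": warn})


# ---------------------------------------------------------------------------
# voxel-level trapezoid+tail integration (TIA maps)
# ---------------------------------------------------------------------------

def voxel_tia_map(
    activity_maps: Sequence,  # Sequence[ImageVolume] with kind activity_MBq
    head_rule: str = "zero_line",
    tail_rate_per_h: Optional[float] = None,
):
    """Trapezoid+tail TIA per voxel on a series of activity maps.

    Returns a TIA ImageVolume (MBq.h).  This is the voxel-level analogue of
    :func:`integrate_trapezoid_tail`, as done by platforms that integrate
    voxel-wise before kernel convolution.
    """
    from .volumes import ImageVolume  # local import to keep module layering

    if head_rule not in HEAD_RULES:
        raise ConfigurationError(f"unknown head rule {head_rule!r}")
    if not activity_maps:
        raise InvalidInputError("at least one activity map is required")
    times = [v.time_post_injection_h for v in activity_maps]
    if any(t is None for t in times) or np.any(np.diff(times) <= 0):
        raise InvalidInputError("activity maps need strictly increasing times")
    for v in activity_maps:
        if v.kind != "activity_MBq":
            raise ConfigurationError("voxel_tia_map expects activity volumes")
    lam = tail_rate_per_h if tail_rate_per_h is not None else LU177_LAMBDA_PHYS_PER_H
    stack = np.stack([v.data for v in activity_maps])
    t = np.asarray(times, dtype=float)
    head = (0.5 if head_rule == "zero_line" else 1.0) * t[0] * stack[0]
    body = np.trapezoid(stack, t, axis=0) if len(activity_maps) > 1 else 0.0
    tail = stack[-1] / lam
    ref = activity_maps[0]
    return ImageVolume(head + body + tail, ref.spacing, "TIA_MBqh")
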