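"""Deterministic mean dynamics, noise decomposition, and optimal-regulation
closed forms.

All variance formulas here are derived in the step (H -> infinity) limit of
the regulation function, where the deterministic target dynamics are
piecewise linear: xbar(t) = 0 before the regulator crosses its threshold K
at time t0, and alpha*(t - t0) afterwards, with alpha = x*/(t* - t0) fixed
by xbar(t*) = x*.  The timing variance splits into a regulator term
(uncertainty in when y crosses K, propagated through the slope of ybar)
and a target term (uncertainty in the target's own Poisson accumulation):

    sigma_t^2 ~ sigma_y^2 (dybar/dt)^-2 |_t0  +  sigma_x^2 (dxbar/dt)^-2 |_t*

For the pure activator (Poisson, variance k t0) and the pure repressor
(binomial, variance N e^{-mu t0}(1 - e^{-mu t0})) this yields the scaled
variances

    activator:  K x*/(k t*)^2 + (1 - K/(k t*))^2
    repressor:  (N - K) x* / (N K (mu t*)^2) + (1 - ln(N/K)/(mu t*))^2

whose minimization gives the descent path / optimum formulas below.  The
linearity index rho = (2/(x* t*)) \int_0^{t*} x dt equals 1 - t0/t* for the
piecewise-linear mean, which links the variance formulas to measurable
(rho, cost) coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, InfeasibleTargetError, UnreachableThresholdError
from .model import ACTIVATOR, REPRESSOR, RegulatorSpec, SystemSpec

__all__ = [
    "DeterministicCurves",
    "AnalyticSummary",
    "mean_regulator",
    "threshold_time_t0",
    "mean_target",
    "variance_decomposition",
    "activator_scaled_variance",
    "repressor_scaled_variance",
    "activator_descent",
    "repressor_optimum",
    "regulator_cost",
    "variance_vs_rho",
    "repressor_variance_vs_rho_at_N",
    "rho_step",
]


def mean_regulator(reg: RegulatorSpec, t):
    """Deterministic mean regulator count ybar(t).

    k*t for the pure activator, N e^{-mu t} for the pure repressor, and the
    exponential relaxation (k/mu) + (n0 - k/mu) e^{-mu t} in general.
    """
    return reg.mean(t)


def threshold_time_t0(reg: RegulatorSpec, K: float) -> float:
    """Time t0 at which the deterministic mean crosses the regulation
    threshold, ybar(t0) = K.

    Closed forms: K/k (pure activator from 0), ln(N/K)/mu (pure repressor),
    and -ln[(K - k/mu)/(n0 - k/mu)]/mu for the birth-death extension.
    Raises :class:`UnreachableThresholdError` when the mean never attains K
    (e.g. a steady state on the wrong side of the threshold).
    """
    if K < 0:
        raise ConfigurationError(f"K must be >= 0, got {K}")
    if reg.mu == 0.0:
        if reg.n0 >= K:
            return 0.0
        if reg.k == 0.0:
            raise UnreachableThresholdError(f"static regulator n0={reg.n0} never reaches K={K}")
        return (K - reg.n0) / reg.k
    ss = reg.k / reg.mu
    num, den = K - ss, reg.n0 - ss
    if den == 0.0:
        if K == ss:
            return 0.0
        raise UnreachableThresholdError(
            f"regulator fixed at steady state {ss} never reaches K={K}"
        )
    ratio = num / den
    if ratio > 1.0:
        return 0.0  # already past the threshold at t = 0
    if ratio <= 0.0:
        raise UnreachableThresholdError(
            f"regulator relaxing from n0={reg.n0} to steady state {ss} never reaches K={K}"
        )
    return -math.log(ratio) / reg.mu


def rho_step(t0: float, t_star: float) -> float:
    """Linearity index of the piecewise-linear (step-limit) mean: 1 - t0/t*."""
    if not t_star > 0:
        raise ConfigurationError("t_star must be > 0")
    return 1.0 - t0 / t_star


def mean_target(spec: SystemSpec, t, mode: str):
    """Deterministic mean target count xbar(t).

    ``mode='step'``: the piecewise-linear step-limit form — 0 for t < t0,
    alpha (t - t0) after.  ``mode='hill1'``: the H = 1 closed forms obtained
    by separation of variables,

        activator:  alpha t - (alpha K / k) ln[(k t + K)/K]
        repressor:  (alpha/mu) ln[(N + K e^{mu t})/(N + K)]

    Uses the alpha currently stored in ``spec.regulation``.
    """
    reg = spec.regulator
    regu = spec.regulation
    alpha, K = regu.alpha, regu.K
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ConfigurationError("time must be nonnegative")
    if mode == "step":
        t0 = threshold_time_t0(reg, K)
        out = np.where(t_arr < t0, 0.0, alpha * (t_arr - t0))
    elif mode == "hill1":
        if regu.H != 1:
            raise ConfigurationError(f"mode 'hill1' requires H = 1, got H = {regu.H}")
        if regu.sign == ACTIVATOR:
            if not reg.is_pure_birth:
                raise ConfigurationError("hill1 activator form requires a pure-birth regulator")
            k = reg.k
            if K == 0.0:
                out = alpha * t_arr
            else:
                out = alpha * t_arr - (alpha * K / k) * np.log((k * t_arr + K) / K)
        else:
            if not reg.is_pure_death:
                raise ConfigurationError("hill1 repressor form requires a pure-death regulator")
            N, mu = reg.n0, reg.mu
            out = (alpha / mu) * np.log((N + K * np.exp(mu * t_arr)) / (N + K))
    else:
        raise ConfigurationError(f"mode must be 'step' or 'hill1', got {mode!r}")
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DeterministicCurves:
    """Bundle of deterministic mean curves for a calibrated system."""

    regulator_mean: Callable
    target_mean: Callable
    t0: float
    mode: str

    @classmethod
    def for_system(cls, spec: SystemSpec, mode: str = "step") -> "DeterministicCurves":
        t0 = threshold_time_t0(spec.regulator, spec.regulation.K)
        return cls(
            regulator_mean=lambda t: mean_regulator(spec.regulator, t),
            target_mean=lambda t: mean_target(spec, t, mode),
            t0=t0,
            mode=mode,
        )


def activator_scaled_variance(k_t_star: float, K: float, x_star: int) -> float:
    """Step-limit scaled timing variance for the pure activator:
    K x*/(k t*)^2 + (1 - K/(k t*))^2."""
    if k_t_star <= 0:
        raise ConfigurationError("k*t_star must be > 0")
    return K * x_star / k_t_star**2 + (1.0 - K / k_t_star) ** 2


def repressor_scaled_variance(mu_t_star: float, K: float, N: int, x_star: int) -> float:
    """Step-limit scaled timing variance for the pure repressor:
    (N - K) x* / (N K (mu t*)^2) + (1 - ln(N/K)/(mu t*))^2."""
    if mu_t_star <= 0 or not (0 < K <= N):
        raise ConfigurationError("require mu*t_star > 0 and 0 < K <= N")
    return (N - K) * x_star / (N * K * mu_t_star**2) + (
        1.0 - math.log(N / K) / mu_t_star
    ) ** 2


def variance_decomposition(spec: SystemSpec) -> Tuple[float, float, float]:
    """Step-limit decomposition of the scaled timing variance into
    (regulator term, target term, total).

    Built from the molecule-number variances and mean-curve slopes: the
    activator count at t0 is Poisson (variance k t0), the repressor count
    binomial (variance N e^{-mu t0}(1-e^{-mu t0})), the target count Poisson
    (variance alpha (t* - t0)), with alpha = x*/(t* - t0).  Only the pure
    activator and pure repressor are supported — the decomposition is not
    derived for the birth-death extension.
    """
    reg, K = spec.regulator, spec.regulation.K
    x_star, t_star = spec.x_star, spec.t_star
    t0 = threshold_time_t0(reg, K)
    if t0 >= t_star:
        raise InfeasibleTargetError(
            f"deterministic switch time t0={t0:.4g} >= t_star={t_star}: "
            "no production rate can reach the threshold in time"
        )
    scale = x_star / t_star**2
    if spec.regulation.sign == ACTIVATOR and reg.is_pure_birth and reg.n0 == 0:
        if K == 0.0:
            reg_term = 0.0
        else:
            sigma_y2 = reg.k * t0  # Poisson
            reg_term = sigma_y2 / reg.k**2 * scale
    elif spec.regulation.sign == REPRESSOR and reg.is_pure_death:
        if K >= reg.n0:
            reg_term = 0.0  # threshold crossed at t = 0 with certainty
        else:
            p = math.exp(-reg.mu * t0)  # = K/N
            sigma_y2 = reg.n0 * p * (1.0 - p)  # binomial
            slope = reg.mu * reg.n0 * p  # |dybar/dt| at t0
            reg_term = sigma_y2 / slope**2 * scale
    else:
        raise ConfigurationError(
            "variance decomposition is defined only for the pure activator "
            "and pure repressor"
        )
    alpha = x_star / (t_star - t0)
    sigma_x2 = alpha * (t_star - t0)  # Poisson
    target_term = sigma_x2 / alpha**2 * scale
    return reg_term, target_term, reg_term + target_term


def activator_descent(k_t_star: float, x_star: int) -> Tuple[float, float]:
    """Optimal K and scaled variance along the activator descent path.

    Minimizing the activator variance over K at fixed k t* gives
    K = k t* - x*/2 where that is nonnegative (else K = 0, unregulated),
    with variance (x*/(k t*)) (1 - x*/(4 k t*)) on the path and 1 off it.
    """
    if k_t_star <= 0:
        raise ConfigurationError("k*t_star must be > 0")
    if k_t_star < x_star / 2.0:
        return 0.0, 1.0
    K = k_t_star - x_star / 2.0
    var = (x_star / k_t_star) * (1.0 - x_star / (4.0 * k_t_star))
    return K, var


_EQ24_ROOT = None  # cached root of (1/2) ln(1/s) = 1 - s, s = K/N


def _transcendental_ratio() -> float:
    """Nontrivial root s* of (1/2) ln(N/K) = 1 - K/N in s = K/N.

    The equation depends on K and N only through their ratio; besides the
    trivial root s = 1 it has a single root in (0, 1/2)."""
    global _EQ24_ROOT
    if _EQ24_ROOT is None:
        _EQ24_ROOT = brentq(lambda s: 0.5 * math.log(1.0 / s) - (1.0 - s), 1e-12, 0.5)
    return _EQ24_ROOT


def repressor_optimum(
    N: int, x_star: int, mode: str = "approximate"
) -> Tuple[float, float, float]:
    """Optimal (K, mu t*, scaled variance) for the pure repressor.

    ``mode='approximate'`` uses the K/N << 1 closed forms
    K = e^{-2} N, mu t* = e^2 x*/(2N) + 2, variance = x*/(x* + 4 e^{-2} N).
    ``mode='transcendental'`` solves the exact stationarity condition
    (1/2) ln(N/K) = 1 - K/N numerically and back-substitutes
    mu t* = ln(N/K) + x*/(2K) into the repressor variance formula.
    """
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    if mode == "approximate":
        K = math.exp(-2.0) * N
        mu_t = math.exp(2.0) * x_star / (2.0 * N) + 2.0
        var = x_star / (x_star + 4.0 * math.exp(-2.0) * N)
        return K, mu_t, var
    if mode == "transcendental":
        s = _transcendental_ratio()
        K = s * N
        mu_t = math.log(N / K) + x_star / (2.0 * K)
        var = repressor_scaled_variance(mu_t, K, N, x_star)
        return K, mu_t, var
    raise ConfigurationError(f"mode must be 'approximate' or 'transcendental', got {mode!r}")


def regulator_cost(reg: RegulatorSpec, t_star: float) -> float:
    """Time-averaged regulator copy number over [0, t*].

    <a> = k t*/2 for the pure activator, <r> = N (1 - e^{-mu t*})/(mu t*)
    for the pure repressor; the birth-death extension averages the
    exponential relaxation analytically.
    """
    if not t_star > 0:
        raise ConfigurationError("t_star must be > 0")
    if reg.mu == 0.0:
        return reg.n0 + 0.5 * reg.k * t_star
    ss = reg.k / reg.mu
    u = reg.mu * t_star
    return ss + (reg.n0 - ss) * (1.0 - math.exp(-u)) / u


def repressor_variance_vs_rho_at_N(
    rho: float, cost: float, x_star: int, N: float
) -> float:
    """Repressor scaled variance at linearity rho, cost <r> and explicit N,
    before optimizing over N:

        x* (e^{N(1-rho)/<r>} - 1) <r>^2 / N^3 + rho^2

    The -1 in the bracket is kept at rho = 1 (where the exponent vanishes
    and the regulator term is exactly zero) and retained generally; for
    rho < 1 it is negligible at the optimum.
    """
    if not (0.0 < rho <= 1.0):
        raise ConfigurationError("rho must lie in (0, 1]")
    if cost <= 0 or N <= 0:
        raise ConfigurationError("cost and N must be > 0")
    return x_star * (math.expm1(N * (1.0 - rho) / cost)) * cost**2 / N**3 + rho**2


def variance_vs_rho(regime: str, rho: float, cost: float, x_star: int) -> float:
    """Minimal scaled timing variance at linearity index rho and regulator
    cost (time-averaged copy number).

        activator:  x* (1 - rho) / (2 <a>) + rho^2
        repressor:  (e^3/27) (x*/<r>) (1 - rho)^3 + rho^2

    The repressor form applies the optimal initial number
    N = 3 <r> / (1 - rho) internally (any rho at rho = 1, where the
    regulator term vanishes).  Both endpoints satisfy variance = 1 at
    rho = 1, the unregulated limit.
    """
    if not (0.0 < rho <= 1.0):
        raise ConfigurationError("rho must lie in (0, 1]")
    if cost <= 0:
        raise ConfigurationError("cost must be > 0")
    if regime == ACTIVATOR:
        return x_star * (1.0 - rho) / (2.0 * cost) + rho**2
    if regime == REPRESSOR:
        return (math.exp(3.0) / 27.0) * (x_star / cost) * (1.0 - rho) ** 3 + rho**2
    raise ConfigurationError(f"regime must be 'activator' or 'repressor', got {regime!r}")


@dataclass(frozen=True)
class AnalyticSummary:
    """Step-limit analytic summary of a calibrated system."""

    rho: float
    cost: float
    scaled_var_approx: float
    regulator_term: float
    target_term: float
    t0: float

    @classmethod
    def for_system(cls, spec: SystemSpec) -> "AnalyticSummary":
        t0 = threshold_time_t0(spec.regulator, spec.regulation.K)
        reg_term, tgt_term, total = variance_decomposition(spec)
        return cls(
            rho=rho_step(t0, spec.t_star),
            cost=regulator_cost(spec.regulator, spec.t_star),
            scaled_var_approx=total,
            regulator_term=reg_term,
            target_term=tgt_term,
            t0=t0,
        )
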