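"""Exact first-passage-time statistics from the two-species master equation.

The joint probability P_yx(t) of (regulator count y, target count x < x*)
evolves under a linear generator M with the level x = x* absorbing: the
production transition x*-1 -> x* has no reverse and its destination lies
outside the state space, so probability leaks over time and every
eigenvalue of M has negative real part.  States are enumerated as
s = x*(Y+1) + y (regulator index fastest), giving M a block
lower-bidiagonal layout: diagonal blocks hold the regulator birth-death
moves and all outflows, subdiagonal blocks hold the target production
rates f±(y) moving x -> x+1.

The FPT density is the probability flux into the absorbing level,
F(t) = sum_y f±(y) P_{y,x*-1}(t), and its moments reduce, by integration
by parts, to

    <t^m> = (-1)^{m+1} m! V^T (M^{-1})^{m+1} P(0),

with V the flux row vector.  The moments are computed with m+1 sequential
sparse triangular solves against one LU factorization of M — never an
explicit inverse.

The activator's state space is unbounded; it is truncated at
a_max = ceil(k t_max + 10 sqrt(k t_max)) (Poisson mean plus ten standard
deviations at the largest time probed), and production out of a_max is
suppressed so no probability leaks through the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from .analytics import threshold_time_t0
from .errors import (
    ConfigurationError,
    FPTimingError,
    InfeasibleTargetError,
    UnreachableThresholdError,
)
from .model import FPTResult, SystemSpec, regulation_rate

__all__ = [
    "StateSpace",
    "build_generator",
    "fpt_moments",
    "fpt_moment",
    "fpt_density",
    "calibrate_alpha",
    "calibrated_system",
    "scan_variance",
]

#: multiple of t_star used as the default largest time probed when sizing
#: the activator truncation.
DEFAULT_T_MAX_FACTOR = 3.0


@dataclass(frozen=True)
class StateSpace:
    """Truncated state space for the master equation.

    ``Y`` is the maximal regulator index (N for a pure repressor, a_max for
    an activator); target levels run over 0 .. x*-1.  State index
    ``s = x*(Y+1) + y``.
    """

    Y: int
    x_star: int

    def __post_init__(self) -> None:
        if self.Y < 0:
            raise ConfigurationError(f"Y must be >= 0, got {self.Y}")
        if self.x_star < 1:
            raise ConfigurationError(f"x_star must be >= 1, got {self.x_star}")

    @property
    def dim(self) -> int:
        return self.x_star * (self.Y + 1)

    def index(self, y: int, x: int) -> int:
        return x * (self.Y + 1) + y

    @classmethod
    def for_system(cls, spec: SystemSpec, t_max: Optional[float] = None) -> "StateSpace":
        """Choose a truncation adequate for ``spec``.

        For a bounded regulator (no production) ``Y = n0``.  Otherwise ``Y``
        covers the largest deterministic mean over [0, t_max] plus ten
        Poisson standard deviations, and always exceeds K so that step
        regulation stays reachable.
        """
        reg = spec.regulator
        if t_max is None:
            t_max = DEFAULT_T_MAX_FACTOR * spec.t_star
        if reg.k == 0.0:
            Y = reg.n0
        else:
            m = max(reg.mean(0.0), reg.mean(t_max), float(reg.n0))
            Y = math.ceil(m + 10.0 * math.sqrt(max(m, 1.0)))
            K = spec.regulation.K
            Y = max(Y, math.ceil(K + 10.0 * math.sqrt(K + 1.0)))
        return cls(Y=int(Y), x_star=int(spec.x_star))


def build_generator(spec: SystemSpec, truncation: Optional[StateSpace] = None) -> sp.csc_matrix:
    """Assemble the sparse absorbing-boundary generator M.

    Within each target level the regulator performs its birth-death moves
    (production suppressed at y = Y); target production f±(y) couples level
    x to x+1; the outflow at x = x*-1 has no destination, making x* the
    absorbing level.
    """
    if truncation is None:
        truncation = StateSpace.for_system(spec)
    Y, x_star = truncation.Y, truncation.x_star
    Yp1 = Y + 1
    reg = spec.regulator
    y = np.arange(Yp1)
    f = np.asarray(regulation_rate(spec.regulation, y), dtype=float).reshape(Yp1)

    rows, cols, vals = [], [], []
    base = np.arange(x_star)[:, None] * Yp1  # block offsets

    # diagonal: total outflow (k suppressed at the truncation boundary)
    birth_out = np.where(y < Y, reg.k, 0.0)
    diag = -(birth_out + reg.mu * y + f)
    idx = (base + y).ravel()
    rows.append(idx)
    cols.append(idx)
    vals.append(np.tile(diag, x_star))

    if reg.k > 0 and Y >= 1:  # regulator production y -> y+1
        src = (base + y[:-1]).ravel()
        dst = (base + y[1:]).ravel()
        rows.append(dst)
        cols.append(src)
        vals.append(np.full(src.size, reg.k))

    if reg.mu > 0 and Y >= 1:  # regulator degradation y -> y-1 at rate mu*y
        src = (base + y[1:]).ravel()
        dst = (base + y[:-1]).ravel()
        rows.append(dst)
        cols.append(src)
        vals.append(np.tile(reg.mu * y[1:], x_star))

    if x_star >= 2:  # target production x -> x+1 at rate f(y)
        base_lo = np.arange(x_star - 1)[:, None] * Yp1
        src = (base_lo + y).ravel()
        dst = (base_lo + Yp1 + y).ravel()
        rows.append(dst)
        cols.append(src)
        vals.append(np.tile(f, x_star - 1))

    M = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(truncation.dim, truncation.dim),
    )
    return M


def _initial_vector(spec: SystemSpec, truncation: StateSpace) -> np.ndarray:
    """P(0): all mass at x = 0, y = n0."""
    n0 = spec.regulator.n0
    if n0 > truncation.Y:
        raise ConfigurationError(f"initial regulator count n0={n0} exceeds truncation Y={truncation.Y}")
    p0 = np.zeros(truncation.dim)
    p0[truncation.index(n0, 0)] = 1.0
    return p0


def _flux_vector(spec: SystemSpec, truncation: StateSpace) -> np.ndarray:
    """V: flux f±(y) out of the x = x*-1 level, preceded by zeros."""
    Yp1 = truncation.Y + 1
    f = np.asarray(regulation_rate(spec.regulation, np.arange(Yp1)), dtype=float).reshape(Yp1)
    v = np.zeros(truncation.dim)
    v[(truncation.x_star - 1) * Yp1 :] = f
    return v


def _factorize(M: sp.csc_matrix) -> spla.SuperLU:
    try:
        return spla.splu(M)
    except RuntimeError as exc:  # singular: some reachable column has no outflow
        raise UnreachableThresholdError(
            "generator is singular: the regulator can never reach a state with "
            "nonzero target production (threshold unreachable)"
        ) from exc


def fpt_moments(
    spec: SystemSpec,
    truncation: Optional[StateSpace] = None,
    *,
    _lu: Optional[spla.SuperLU] = None,
) -> FPTResult:
    """Mean and variance of the first-passage time to x = x*.

    Solves the linear systems of the moment formula block-free against a
    single sparse LU factorization of M.
    """
    if truncation is None:
        truncation = StateSpace.for_system(spec)
    lu = _lu if _lu is not None else _factorize(build_generator(spec, truncation))
    p0 = _initial_vector(spec, truncation)
    v = _flux_vector(spec, truncation)
    if not np.any(v):
        raise UnreachableThresholdError("target production rate vanishes at every regulator state")
    u1 = lu.solve(p0)
    u2 = lu.solve(u1)
    u3 = lu.solve(u2)
    mean = float(v @ u2)
    second = float(-2.0 * (v @ u3))
    var = second - mean * mean
    if not (math.isfinite(mean) and math.isfinite(var)) or mean <= 0:
        raise UnreachableThresholdError(
            f"moment solve produced non-physical moments (mean={mean}, var={var}); "
            "the threshold is unreachable or the truncation is inadequate"
        )
    return FPTResult(mean_t=mean, var_t=var, x_star=spec.x_star, t_star=spec.t_star)


def fpt_moment(spec: SystemSpec, truncation: Optional[StateSpace] = None, m: int = 1) -> float:
    """Raw moment <t^m> of the first-passage time, m in {1, 2}."""
    if m not in (1, 2):
        raise ConfigurationError(f"moment order m must be 1 or 2, got {m}")
    res = fpt_moments(spec, truncation)
    if m == 1:
        return res.mean_t
    return res.var_t + res.mean_t**2


def fpt_density(
    spec: SystemSpec,
    t_grid: Sequence[float],
    truncation: Optional[StateSpace] = None,
) -> np.ndarray:
    """FPT density F(t) = sum_y f±(y) P_{y,x*-1}(t) on an increasing grid.

    The state vector is propagated exactly between grid points with the
    action of the matrix exponential (Krylov evaluation, no dense expm).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ConfigurationError("t_grid must be a nonempty 1-D array")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ConfigurationError("t_grid must be nonnegative and strictly increasing")
    if truncation is None:
        truncation = StateSpace.for_system(spec, t_max=float(t[-1]))
    M = build_generator(spec, truncation)
    v = _flux_vector(spec, truncation)
    if not np.any(v):
        raise UnreachableThresholdError("target production rate vanishes at every regulator state")
    p = _initial_vector(spec, truncation)
    out = np.empty(t.size)
    t_prev = 0.0
    for i, ti in enumerate(t):
        dt = ti - t_prev
        if dt > 0:
            p = spla.expm_multiply(M * dt, p)
        out[i] = v @ p
        t_prev = ti
    return out


def calibrate_alpha(
    spec: SystemSpec,
    truncation: Optional[StateSpace] = None,
    rtol: float = 1e-8,
) -> float:
    """Maximal production rate alpha such that the mean FPT equals t_star.

    The mean FPT is strictly decreasing in alpha with infimum t_min (the
    mean time for the regulator to first permit production), so the root is
    unique whenever t_min < t_star.  Bracketed root finding on alpha starts
    from the unregulated rate x*/t* (always a lower bound on alpha) and a
    step-limit guess 10*x*/(t* - t0_det).
    """
    if truncation is None:
        truncation = StateSpace.for_system(spec)
    x_star, t_star = spec.x_star, spec.t_star

    # Precompute alpha-independent structure: M(alpha) = A + alpha * B.
    probe = spec.with_alpha(1.0)
    B = build_generator(probe, truncation) - build_generator(probe.with_alpha(0.0), truncation)
    A = build_generator(probe.with_alpha(0.0), truncation)
    p0 = _initial_vector(spec, truncation)
    h = np.asarray(
        regulation_rate(spec.regulation.with_alpha(1.0), np.arange(truncation.Y + 1)), dtype=float
    ).reshape(truncation.Y + 1)
    if not np.any(h):
        raise UnreachableThresholdError("target production rate vanishes at every regulator state")

    def mean_at(alpha: float) -> float:
        lu = _factorize((A + alpha * B).tocsc())
        v = np.zeros(truncation.dim)
        v[(truncation.x_star - 1) * (truncation.Y + 1) :] = alpha * h
        u2 = lu.solve(lu.solve(p0))
        m = float(v @ u2)
        if not math.isfinite(m) or m <= 0:
            raise UnreachableThresholdError("mean FPT solve failed during calibration")
        return m

    lo = x_star / t_star
    m_lo = mean_at(lo)
    if abs(m_lo - t_star) <= rtol * t_star:
        return lo
    if m_lo < t_star:  # cannot happen for a pure delay process; guard anyway
        raise ConfigurationError("mean FPT below t_star at the unregulated rate")

    # step-limit deterministic switch time, used only to seed the bracket
    try:
        t0_det = threshold_time_t0(spec.regulator, spec.regulation.K)
    except FPTimingError:
        t0_det = None
    if t0_det is not None and t0_det < t_star:
        hi = 10.0 * x_star / (t_star - t0_det)
    else:
        hi = 100.0 * x_star / t_star
    hi = max(hi, 2.0 * lo)
    for _ in range(60):
        if mean_at(hi) < t_star:
            break
        hi *= 10.0
    else:
        raise InfeasibleTargetError(
            f"mean FPT stays above t_star={t_star} for alpha up to {hi:.3g}: "
            "the regulator cannot permit crossing by the target time"
        )
    alpha = brentq(lambda a: mean_at(a) - t_star, lo, hi, rtol=1e-13, maxiter=200)
    if abs(mean_at(alpha) - t_star) > rtol * t_star:
        raise InfeasibleTargetError("calibration did not converge to the requested tolerance")
    return float(alpha)


def calibrated_system(spec: SystemSpec, truncation: Optional[StateSpace] = None) -> SystemSpec:
    """Copy of ``spec`` with alpha set so the mean FPT equals t_star."""
    return spec.with_alpha(calibrate_alpha(spec, truncation))


def scan_variance(
    template: SystemSpec,
    K_values: Iterable[float],
    rate_values: Iterable[float],
    rate_kind: Optional[str] = None,
    errors: str = "raise",
) -> pd.DataFrame:
    """Scaled timing variance over a (K, dimensionless rate) grid.

    ``rate_values`` are k*t_star for an activator template or mu*t_star for
    a repressor template (``rate_kind`` overrides the inference).  Each grid
    point is calibrated so its mean FPT equals t_star before the variance
    is evaluated.  ``errors='nan'`` records failed points as NaN instead of
    raising.
    """
    import dataclasses as _dc

    if rate_kind is None:
        rate_kind = "mu_t_star" if template.regulator.is_pure_death else "k_t_star"
    if rate_kind not in ("k_t_star", "mu_t_star"):
        raise ConfigurationError(f"rate_kind must be 'k_t_star' or 'mu_t_star', got {rate_kind!r}")
    if errors not in ("raise", "nan"):
        raise ConfigurationError("errors must be 'raise' or 'nan'")

    rows = []
    failures = []
    for K in K_values:
        for rate in rate_values:
            if rate_kind == "k_t_star":
                regulator = _dc.replace(template.regulator, k=rate / template.t_star)
            else:
                regulator = _dc.replace(template.regulator, mu=rate / template.t_star)
            spec = _dc.replace(
                template,
                regulator=regulator,
                regulation=template.regulation.with_K(K),
            )
            try:
                trunc = StateSpace.for_system(spec)
                alpha = calibrate_alpha(spec, trunc)
                res = fpt_moments(spec.with_alpha(alpha), trunc)
                rows.append((K, rate, alpha, res.mean_t, res.var_t, res.scaled_var))
            except FPTimingError as exc:
                if errors == "raise":
                    raise type(exc)(f"grid point K={K}, {rate_kind}={rate}: {exc}") from exc
                failures.append((K, rate))
                rows.append((K, rate, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["K", rate_kind, "alpha", "mean_t", "var_t", "scaled_var"]
    )
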