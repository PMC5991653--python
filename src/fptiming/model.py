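"""Domain types and the Hill regulation function.

The model: a target species X is produced at a rate set by a single
regulator Y, which is either an accumulating activator A (pure birth at
rate k from a(0) = 0) or a diminishing repressor R (pure first-order decay
at rate mu from r(0) = N).  A birth-death extension allows both k > 0 and
mu > 0, relaxing toward the steady state k/mu.  The event of interest is
the first time the target count x reaches a threshold ``x_star``; the
maximal production rate ``alpha`` is calibrated so the mean first-passage
time equals a target time ``t_star``.

Regulation is a Hill function of the regulator copy number y:

    activator:  f+(y) = alpha * y^H / (y^H + K^H)
    repressor:  f-(y) = alpha * K^H / (y^H + K^H)

with half-maximal number K and cooperativity H >= 1.  ``H = math.inf``
selects the step (infinite-cooperativity) limit: the rate is 0 below the
threshold (activator, y < K) or above it (repressor, y > K) and alpha
otherwise.  A tie y == K counts as active for both signs, consistent with
defining the deterministic switch time t0 by the equality ybar(t0) = K.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ACTIVATOR",
    "REPRESSOR",
    "RegulationSpec",
    "RegulatorSpec",
    "SystemSpec",
    "BurstSpec",
    "DivisionSpec",
    "FPTResult",
    "regulation_rate",
    "unregulated_system",
]

ACTIVATOR = "activator"
REPRESSOR = "repressor"


@dataclass(frozen=True)
class RegulationSpec:
    """Hill regulation of target production by the regulator copy number.

    Parameters
    ----------
    sign : {"activator", "repressor"}
    alpha : float
        Maximal production rate of the target (molecules per unit time).
    K : float
        Half-maximal regulator number (molecules); real-valued, ``>= 0``.
    H : float
        Cooperativity, ``>= 1``; ``math.inf`` selects the step limit.
    """

    sign: str
    alpha: float
    K: float
    H: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATOR, REPRESSOR):
            raise ConfigurationError(f"sign must be 'activator' or 'repressor', got {self.sign!r}")
        if not self.alpha >= 0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha}")
        if not self.K >= 0:
            raise ConfigurationError(f"K must be >= 0, got {self.K}")
        if not (self.H >= 1):
            raise ConfigurationError(f"H must be >= 1 (or math.inf), got {self.H}")

    @property
    def is_step(self) -> bool:
        return math.isinf(self.H)

    def rate(self, y):
        return regulation_rate(self, y)

    def with_alpha(self, alpha: float) -> "RegulationSpec":
        return dataclasses.replace(self, alpha=alpha)

    def with_K(self, K: float) -> "RegulationSpec":
        return dataclasses.replace(self, K=K)


def regulation_rate(reg: RegulationSpec, y):
    """Target production rate f±(y) at regulator count ``y``.

    ``y`` may be a nonnegative scalar or array.  Finite ``H`` evaluates the
    Hill forms; ``H = inf`` evaluates the step forms (tie ``y == K`` active).
    ``K == 0`` is treated as the step limit at threshold zero so that the
    activator is constitutively active (the unregulated limit ``K -> 0``)
    and the repressor produces only at ``y == 0``.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ConfigurationError("regulator count y must be nonnegative")
    alpha, K, H = reg.alpha, reg.K, reg.H
    if math.isinf(H) or K == 0.0:
        if reg.sign == ACTIVATOR:
            out = np.where(y_arr >= K, alpha, 0.0)
        else:
            out = np.where(y_arr <= K, alpha, 0.0)
    else:
        # ratio form alpha / (1 + (K/y)^H) stays finite for any H: the
        # power may overflow to inf, which correctly drives the rate to 0
        with np.errstate(divide="ignore", over="ignore"):
            if reg.sign == ACTIVATOR:
                ratio = np.where(y_arr > 0, K / np.maximum(y_arr, 1e-300), np.inf)
            else:
                ratio = y_arr / K
            out = alpha / (1.0 + ratio**H)
    if np.isscalar(y) or np.ndim(y) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class RegulatorSpec:
    """Birth-death dynamics of the regulator.

    ``k`` is the zeroth-order production rate, ``mu`` the per-molecule
    degradation rate, ``n0`` the initial copy number.  The pure activator is
    ``(k > 0, mu = 0, n0 = 0)``; the pure repressor is ``(k = 0, mu > 0,
    n0 = N > 0)``.  ``n0_poisson`` draws the initial count from a Poisson
    law of mean ``n0`` (stochastic simulation only).
    """

    k: float = 0.0
    mu: float = 0.0
    n0: int = 0
    n0_poisson: bool = False

    def __post_init__(self) -> None:
        if not self.k >= 0:
            raise ConfigurationError(f"k must be >= 0, got {self.k}")
        if not self.mu >= 0:
            raise ConfigurationError(f"mu must be >= 0, got {self.mu}")
        if not (isinstance(self.n0, (int, np.integer)) and self.n0 >= 0):
            raise ConfigurationError(f"n0 must be an integer >= 0, got {self.n0!r}")

    @property
    def is_pure_birth(self) -> bool:
        return self.mu == 0.0

    @property
    def is_pure_death(self) -> bool:
        return self.k == 0.0

    def mean(self, t):
        """Deterministic mean copy number ybar(t)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ConfigurationError("time must be nonnegative")
        if self.mu == 0.0:
            out = self.n0 + self.k * t_arr
        else:
            ss = self.k / self.mu
            out = ss + (self.n0 - ss) * np.exp(-self.mu * t_arr)
        if np.isscalar(t) or np.ndim(t) == 0:
            return float(out)
        return out


@dataclass(frozen=True)
class SystemSpec:
    """Full specification of a threshold-crossing system."""

    regulator: RegulatorSpec
    regulation: RegulationSpec
    x_star: int
    t_star: float

    def __post_init__(self) -> None:
        if not (isinstance(self.x_star, (int, np.integer)) and self.x_star >= 1):
            raise ConfigurationError(f"x_star must be an integer >= 1, got {self.x_star!r}")
        if not self.t_star > 0:
            raise ConfigurationError(f"t_star must be > 0, got {self.t_star}")

    def with_alpha(self, alpha: float) -> "SystemSpec":
        return dataclasses.replace(self, regulation=self.regulation.with_alpha(alpha))

    @property
    def is_unregulated(self) -> bool:
        """True when target production is constitutive at rate alpha for every
        reachable regulator state (the K -> 0 activator limit)."""
        return self.regulation.sign == ACTIVATOR and self.regulation.K == 0.0


def unregulated_system(x_star: int, t_star: float, alpha: Optional[float] = None) -> SystemSpec:
    """Constitutive production at rate ``alpha`` (default x*/t*, the rate
    that sets the mean first-passage time of the gamma law to t*)."""
    if alpha is None:
        alpha = x_star / t_star
    return SystemSpec(
        regulator=RegulatorSpec(k=0.0, mu=0.0, n0=0),
        regulation=RegulationSpec(sign=ACTIVATOR, alpha=alpha, K=0.0, H=1.0),
        x_star=x_star,
        t_star=t_star,
    )


@dataclass(frozen=True)
class BurstSpec:
    """Geometric production bursts for the regulator: each production event
    adds a number of molecules drawn from the geometric law on {1, 2, ...}
    with mean ``b``; ``b = 1`` degenerates to single-molecule events.

    Bursts are flux-preserving: production events fire at rate ``k/b`` so
    the mean regulator trajectory ``kt`` is unchanged and only its noise
    grows with ``b``.  This keeps the burst curves comparable at a common
    ``k t*`` axis, which is how burstiness is benchmarked against the
    Poisson baseline.
    """

    b: float = 1.0

    def __post_init__(self) -> None:
        if not self.b >= 1:
            raise ConfigurationError(f"burst mean b must be >= 1, got {self.b}")


@dataclass(frozen=True)
class DivisionSpec:
    """One cell division per trajectory at a Gaussian random time.

    At division both molecule counts are binomially partitioned (each
    molecule kept with probability 1/2) and the half-maximal number K is
    scaled by ``volume_factor`` because K = K_d * V for dissociation
    constant K_d and cell volume V.
    """

    t_d_mean: float
    t_d_sd: float = 0.0
    volume_factor: float = 0.5

    def __post_init__(self) -> None:
        if not self.t_d_mean > 0:
            raise ConfigurationError(f"t_d_mean must be > 0, got {self.t_d_mean}")
        if not self.t_d_sd >= 0:
            raise ConfigurationError(f"t_d_sd must be >= 0, got {self.t_d_sd}")
        if not 0 < self.volume_factor <= 1:
            raise ConfigurationError(f"volume_factor must be in (0, 1], got {self.volume_factor}")


@dataclass(frozen=True)
class FPTResult:
    """First-passage-time statistics.

    ``scaled_var`` is the nondimensionalized variance sigma_t^2 * x* / t*^2,
    equal to 1 for the unregulated (gamma) process calibrated to t*.
    """

    mean_t: float
    var_t: float
    x_star: int
    t_star: float
    density: Optional[Tuple[np.ndarray, np.ndarray]] = None
    mean_se: Optional[float] = None
    var_se: Optional[float] = None
    n_crossed: Optional[int] = None
    n_censored: Optional[int] = None

    def __post_init__(self) -> None:
        if self.var_t < 0:
            raise ConfigurationError(f"variance must be >= 0, got {self.var_t}")

    @property
    def scaled_var(self) -> float:
        return self.var_t * self.x_star / self.t_star**2

    @property
    def scaled_var_se(self) -> Optional[float]:
        if self.var_se is None:
            return None
        return self.var_se * self.x_star / self.t_star**2
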