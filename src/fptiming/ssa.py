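"""Exact stochastic simulation (Gillespie direct method) of the
threshold-crossing reaction scheme, with the robustness extensions:
geometric production bursts, a Poisson-distributed initial repressor count,
regulator birth-death dynamics, and a single cell division with symmetric
binomial partitioning and halving of the regulation threshold K.

Reproducibility: run ``i`` of an ensemble uses an independent
``random.Random`` stream seeded with the ``i``-th 64-bit word of
``numpy.random.SeedSequence(seed).generate_state(n_runs, uint64)``;
auxiliary vectorized draws (Poisson initial counts) use a generator spawned
from the same master ``SeedSequence``.  Identical (spec, seed, n_runs)
therefore reproduce identical ensembles bit-for-bit, independent of run
order.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigurationError, NoCrossingsError
from .model import (
    ACTIVATOR,
    BurstSpec,
    DivisionSpec,
    FPTResult,
    RegulationSpec,
    SystemSpec,
)

__all__ = [
    "TrajectoryEnsemble",
    "simulate",
    "draw_burst",
    "apply_division",
    "ensemble_fpt_stats",
    "calibrate_alpha_by_simulation",
]


@dataclass
class TrajectoryEnsemble:
    """Seeded ensemble of stochastic trajectories and their FPT samples.

    ``fpt_samples[i]`` is NaN when run ``i`` did not cross ``x_star`` by
    ``t_max`` (censored, never silently dropped).  ``final_y``/``final_x``
    hold the state at termination (threshold crossing, or ``t_max`` when
    ``stop_at_threshold`` is off).
    """

    spec: SystemSpec
    n_runs: int
    seed: int
    t_max: float
    fpt_samples: np.ndarray
    final_y: np.ndarray
    final_x: np.ndarray
    mean_curve_grid: Optional[np.ndarray] = None
    mean_y: Optional[np.ndarray] = None
    mean_x: Optional[np.ndarray] = None
    trajectories: Optional[List[Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None

    @property
    def crossed(self) -> np.ndarray:
        return ~np.isnan(self.fpt_samples)


def draw_burst(b: float, rng) -> int:
    """One geometric burst size on {1, 2, ...} with mean ``b`` (inverse-CDF
    draw from ``rng.random()``; ``b = 1`` always returns 1)."""
    if b < 1:
        raise ConfigurationError(f"burst mean b must be >= 1, got {b}")
    if b == 1.0:
        return 1
    # P(X = n) = (1-p)^{n-1} p with p = 1/b
    return int(math.log(1.0 - rng.random()) / math.log(1.0 - 1.0 / b)) + 1


def _binomial_half(n: int, rng: random.Random) -> int:
    """Binomial(n, 1/2) via a popcount of n random bits."""
    if n <= 0:
        return 0
    return rng.getrandbits(n).bit_count()


def apply_division(
    state: Tuple[int, int],
    regulation: RegulationSpec,
    division: DivisionSpec,
    rng: random.Random,
) -> Tuple[Tuple[int, int], RegulationSpec]:
    """Binomially partition both molecule counts (each molecule kept with
    probability 1/2) and scale K by the post-division volume fraction."""
    y, x = state
    if division.volume_factor == 0.5:
        y2, x2 = _binomial_half(y, rng), _binomial_half(x, rng)
    else:
        # asymmetric volume fraction: keep each molecule w.p. volume_factor
        p = division.volume_factor
        y2 = sum(1 for _ in range(y) if rng.random() < p)
        x2 = sum(1 for _ in range(x) if rng.random() < p)
    return (y2, x2), regulation.with_K(regulation.K * division.volume_factor)


def _run_one(
    rnd: random.Random,
    spec: SystemSpec,
    y0: int,
    burst_b: float,
    division: Optional[DivisionSpec],
    t_max: float,
    stop_at_threshold: bool,
    sample_times: Optional[np.ndarray],
    sample_y: Optional[np.ndarray],
    sample_x: Optional[np.ndarray],
    record: bool,
):
    """Simulate one trajectory; returns (fpt, y_final, x_final, traj)."""
    reg = spec.regulator
    # flux-preserving bursts: event rate k/b with geometric(b) increments
    k, mu = reg.k / burst_b, reg.mu
    regu = spec.regulation
    sign_act = regu.sign == ACTIVATOR
    alpha, H = regu.alpha, regu.H
    step = math.isinf(H)
    Kc = regu.K
    KH = 0.0 if step else Kc**H
    x_star = spec.x_star

    td = math.inf
    vol = 0.5
    if division is not None:
        vol = division.volume_factor
        td = rnd.gauss(division.t_d_mean, division.t_d_sd)
        while td <= 0.0:
            td = rnd.gauss(division.t_d_mean, division.t_d_sd)
    divided = division is None

    expovariate = rnd.expovariate
    uniform = rnd.random
    log = math.log
    log1mp = 0.0 if burst_b <= 1.0 else math.log(1.0 - 1.0 / burst_b)

    t = 0.0
    y = y0
    x = 0
    fpt = math.nan
    si = 0
    ns = 0 if sample_times is None else sample_times.size
    traj_t, traj_y, traj_x = ([0.0], [y], [x]) if record else (None, None, None)

    while True:
        # propensities
        if step or Kc == 0.0:
            active = (y >= Kc) if sign_act else (y <= Kc)
            f = alpha if active else 0.0
        else:
            yH = float(y) ** H
            f = alpha * (yH / (yH + KH)) if sign_act else alpha * (KH / (yH + KH))
        total = k + mu * y + f
        t_next = t + expovariate(total) if total > 0.0 else math.inf

        if not divided and t_next >= td:
            # division fires before the next reaction
            if td > t_max:
                t_next = math.inf  # fall through to censoring below
            else:
                while si < ns and sample_times[si] <= td:
                    sample_y[si] += y
                    sample_x[si] += x
                    si += 1
                t = td
                y = _binomial_half(y, rnd) if vol == 0.5 else sum(
                    1 for _ in range(y) if rnd.random() < vol
                )
                x = _binomial_half(x, rnd) if vol == 0.5 else sum(
                    1 for _ in range(x) if rnd.random() < vol
                )
                Kc *= vol
                if not step:
                    KH = Kc**H
                divided = True
                if record:
                    traj_t.append(t)
                    traj_y.append(y)
                    traj_x.append(x)
                continue

        if t_next > t_max:
            while si < ns and sample_times[si] <= t_max:
                sample_y[si] += y
                sample_x[si] += x
                si += 1
            t = t_max
            break

        while si < ns and sample_times[si] <= t_next:
            sample_y[si] += y
            sample_x[si] += x
            si += 1
        t = t_next

        u = uniform() * total
        if u < k:
            if burst_b > 1.0:
                y += int(log(1.0 - uniform()) / log1mp) + 1
            else:
                y += 1
        elif u < k + mu * y:
            y -= 1
        else:
            x += 1
            if x >= x_star and math.isnan(fpt):
                fpt = t
                if stop_at_threshold:
                    if record:
                        traj_t.append(t)
                        traj_y.append(y)
                        traj_x.append(x)
                    break
        if record:
            traj_t.append(t)
            traj_y.append(y)
            traj_x.append(x)

    traj = None
    if record:
        traj = (np.asarray(traj_t), np.asarray(traj_y), np.asarray(traj_x))
    return fpt, y, x, traj


def simulate(
    spec: SystemSpec,
    burst: Optional[BurstSpec] = None,
    division: Optional[DivisionSpec] = None,
    n_runs: int = 1000,
    seed: int = 0,
    t_max: Optional[float] = None,
    stop_at_threshold: bool = True,
    record_trajectories: bool = False,
    mean_curve_grid: Optional[np.ndarray] = None,
) -> TrajectoryEnsemble:
    """Gillespie ensemble of the regulated threshold-crossing scheme.

    Events: regulator production (single molecules at rate k, or — when
    ``burst`` is given — geometric bursts of mean b at rate k/b, which
    preserves the mean flux k while amplifying the noise), regulator
    degradation at rate mu*y, target production at rate f±(y).  The FPT of each run is the first time
    x reaches ``x_star``; by default the run terminates there (absorbing
    convention), otherwise it continues to ``t_max`` (used for mean curves
    and cross-sectional observation).  ``division`` inserts one binomial
    partitioning event at a truncated-Gaussian random time.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    if t_max is None:
        t_max = 20.0 * spec.t_star
    if t_max <= spec.t_star:
        raise ConfigurationError("t_max must exceed t_star")
    b = burst.b if burst is not None else 1.0
    if b > 1.0 and spec.regulator.k == 0.0:
        raise ConfigurationError("bursts apply to regulator production, which requires k > 0")

    master = np.random.SeedSequence(seed)
    run_seeds = master.generate_state(n_runs, dtype=np.uint64)
    if spec.regulator.n0_poisson:
        aux = np.random.default_rng(master.spawn(1)[0])
        y0s = aux.poisson(spec.regulator.n0, size=n_runs)
    else:
        y0s = np.full(n_runs, spec.regulator.n0, dtype=np.int64)

    grid = None
    sum_y = sum_x = None
    if mean_curve_grid is not None:
        grid = np.asarray(mean_curve_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ConfigurationError("mean_curve_grid must be strictly increasing")
        sum_y = np.zeros(grid.size)
        sum_x = np.zeros(grid.size)
        if stop_at_threshold:
            raise ConfigurationError(
                "mean curves require stop_at_threshold=False so every run "
                "spans the full grid"
            )

    fpts = np.empty(n_runs)
    final_y = np.empty(n_runs, dtype=np.int64)
    final_x = np.empty(n_runs, dtype=np.int64)
    trajs: Optional[list] = [] if record_trajectories else None

    for i in range(n_runs):
        rnd = random.Random(int(run_seeds[i]))
        fpt, y_f, x_f, traj = _run_one(
            rnd,
            spec,
            int(y0s[i]),
            b,
            division,
            t_max,
            stop_at_threshold,
            grid,
            sum_y,
            sum_x,
            record_trajectories,
        )
        fpts[i] = fpt
        final_y[i] = y_f
        final_x[i] = x_f
        if record_trajectories:
            trajs.append(traj)

    ens = TrajectoryEnsemble(
        spec=spec,
        n_runs=n_runs,
        seed=seed,
        t_max=t_max,
        fpt_samples=fpts,
        final_y=final_y,
        final_x=final_x,
        trajectories=trajs,
    )
    if grid is not None:
        ens.mean_curve_grid = grid
        ens.mean_y = sum_y / n_runs
        ens.mean_x = sum_x / n_runs
    return ens


def ensemble_fpt_stats(ensemble: TrajectoryEnsemble) -> FPTResult:
    """Sample mean and unbiased variance of the crossed FPT samples, with
    asymptotic standard errors; censored runs are counted separately."""
    samples = ensemble.fpt_samples[ensemble.crossed]
    n = samples.size
    n_censored = ensemble.n_runs - n
    if n == 0:
        raise NoCrossingsError("no run crossed the threshold by t_max")
    if n < 2:
        raise NoCrossingsError("need at least 2 crossed runs to estimate a variance")
    mean = float(np.mean(samples))
    var = float(np.var(samples, ddof=1))
    mean_se = math.sqrt(var / n)
    m4 = float(np.mean((samples - mean) ** 4))
    var_of_var = (m4 - var**2 * (n - 3) / (n - 1)) / n
    var_se = math.sqrt(max(var_of_var, 0.0))
    return FPTResult(
        mean_t=mean,
        var_t=var,
        x_star=ensemble.spec.x_star,
        t_star=ensemble.spec.t_star,
        mean_se=mean_se,
        var_se=var_se,
        n_crossed=n,
        n_censored=n_censored,
    )


def calibrate_alpha_by_simulation(
    spec: SystemSpec,
    burst: Optional[BurstSpec] = None,
    division: Optional[DivisionSpec] = None,
    n_runs: int = 20000,
    seed: int = 0,
    rtol: float = 1e-3,
    max_iter: int = 20,
    t_max: Optional[float] = None,
) -> float:
    """Adjust alpha until the ensemble-mean FPT equals t_star within
    ``rtol * t_star``, for variants (bursts, division) the exact solver
    does not cover.  Common random numbers (a fixed ensemble seed) make the
    target function deterministic, so a secant iteration converges fast.
    """
    t_star = spec.t_star

    def mean_at(alpha: float) -> float:
        ens = simulate(
            spec.with_alpha(alpha),
            burst=burst,
            division=division,
            n_runs=n_runs,
            seed=seed,
            t_max=t_max,
        )
        return ensemble_fpt_stats(ens).mean_t

    a0 = spec.regulation.alpha
    if a0 <= 0:
        a0 = spec.x_star / t_star
    m0 = mean_at(a0)
    if abs(m0 - t_star) <= rtol * t_star:
        return a0
    a1 = a0 * (1.3 if m0 > t_star else 0.7)
    m1 = mean_at(a1)
    for _ in range(max_iter):
        if abs(m1 - t_star) <= rtol * t_star:
            return a1
        denom = m1 - m0
        if denom == 0.0:
            break
        a2 = a1 - (m1 - t_star) * (a1 - a0) / denom
        if a2 <= 0:
            a2 = 0.5 * a1
        a0, m0 = a1, m1
        a1, m1 = a2, mean_at(a2)
    if abs(m1 - t_star) <= 3 * rtol * t_star:
        return a1
    raise ConfigurationError(
        f"simulation-based calibration did not converge (last mean {m1:.5g} vs t_star {t_star})"
    )
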