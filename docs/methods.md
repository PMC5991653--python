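# Methods

## Model

A target species X is produced one molecule at a time at a rate set by a
single regulator Y and crosses a threshold count `x_star`; the crossing
triggers a downstream event (the motivating system is *mig-1* expression
terminating neuroblast migration in *C. elegans*, where the count is mRNA
copies per cell). The regulator is either

- an **activator** A produced at a zeroth-order rate `k` from `a(0) = 0`
  (mean `ā(t) = kt`), or
- a **repressor** R degraded at a first-order per-molecule rate `mu` from
  `r(0) = N` (mean `r̄(t) = N e^{-mu t}`),

so that in both cases the production rate of X rises with time. Production
is a Hill function of the regulator count with maximal rate `alpha`,
half-maximal number `K` and cooperativity `H >= 1`; `H = inf` is the step
limit (rate 0 strictly below/above threshold, `alpha` otherwise, the tie
`y == K` counted as active so that the deterministic switch time `t0`
defined by `ȳ(t0) = K` is consistent). A birth–death extension allows
`k > 0` and `mu > 0` simultaneously (relaxation toward `k/mu`).

`alpha` is never a free parameter: it is calibrated so the *mean*
first-passage time (FPT) equals a target time `t_star`. Precision is
quantified by the scaled FPT variance `sigma_t^2 x*/t*^2`, which equals 1
for constitutive production (the gamma law with shape `x_star`), so values
below 1 mean regulation beats the unregulated strategy.

## Exact FPT statistics

The joint law `P_yx(t)` for `x < x_star` evolves under a sparse generator
with the level `x = x_star` absorbing; the FPT density is the flux
`F(t) = sum_y f±(y) P_{y,x*-1}(t)` and its moments reduce to
`<t^m> = (-1)^{m+1} m! V^T (M^{-1})^{m+1} P(0)`, evaluated with `m+1`
sequential solves against one sparse LU factorization (`scipy.sparse`),
never an explicit inverse. Orders `m <= 2` are exposed; higher orders are
not needed for any reported quantity.

Numerical choices:

- **Truncation.** The repressor state space is finite (`Y = N`). The
  activator is truncated at `a_max = ceil(k t_max + 10 sqrt(k t_max))`
  (Poisson mean plus ten standard deviations at the largest time probed,
  default `t_max = 3 t_star`), extended to exceed `K` so step regulation
  stays reachable. Production out of the boundary state is suppressed
  rather than leaked, so total probability is conserved up to absorption.
  Tests assert the moments are insensitive (rel. 1e-8) to doubling `a_max`.
- **Calibration.** The mean FPT is strictly decreasing in `alpha` with
  infimum equal to the mean time for the regulator to first permit
  production, so the root of `mean(alpha) = t_star` is unique whenever it
  exists. Bracketed Brent iteration starts from the unregulated rate
  `x*/t*` (a lower bound) and a step-limit guess `10 x*/(t* - t0)`;
  failure to bracket after expanding 60 decades raises an infeasibility
  error. Convergence tolerance: relative 1e-8 on the mean.
- **Density.** `F(t)` is evaluated by propagating the state with the
  action of the matrix exponential between grid points (Krylov
  `expm_multiply`); conservation (`integral F = 1`) is verified in tests.
- **Degenerate inputs.** A regulator that can never reach a producing
  state yields a singular generator; this is detected and raised as an
  "unreachable threshold" error rather than returned as NaN.

`K = 0` with finite `H` is treated as constitutive production. This is a
genuine modeling choice: for any `K > 0` the Hill rate at `y = 0` is zero,
so the `K -> 0+` limit of an activator still waits ~Exp(k) for the first
regulator molecule and is *not* the unregulated process (its scaled
variance is the step-limit formula with K replaced by 1, confirmed in
tests). The `K = 0` convention makes the unregulated corner of parameter
scans exact.

## Step-limit analytics

In the step limit the deterministic target dynamics are piecewise linear
(0 until `t0`, slope `alpha = x*/(t* - t0)` after), and the timing
variance splits into a regulator term (count noise at `t0` divided by the
squared regulator slope) and a target term (Poisson accumulation noise
divided by `alpha^2`). The scaled variances are

    activator:  K x*/(k t*)^2 + (1 - K/(k t*))^2
    repressor:  (N - K) x*/(N K (mu t*)^2) + (1 - ln(N/K)/(mu t*))^2

For the step **activator** these formulas are *exact* once `alpha` is
calibrated: the FPT is the independent sum of an Erlang(K, k) regulator
waiting time and a Gamma(x*, alpha) accumulation time. For the repressor
they are approximate (binomial crossing-time propagation); the solver
agrees with them to <1% at `H = inf`. At the `H = 3` used in parameter
scans, the formulas overestimate the numeric variance by roughly 13–16%
across the beneficial region of a fixed-`K = 10` slice — the smoother Hill
switch starts production earlier and genuinely reduces the variance below
the step-limit prediction. This gap is physics, not numerics (the solver
matches 50,000-run Gillespie ensembles within statistical error), and it
is reported honestly by the acceptance machinery.

Minimizing the activator formula over `K` at fixed `k t*` gives the
descent path `K = k t* - x*/2` (or `K = 0`, variance 1, below
`k t* = x*/2`), with variance `(x*/(k t*)) (1 - x*/(4 k t*))` on the path.
Minimizing the repressor formula over both parameters leads to the
transcendental stationarity condition `(1/2) ln(N/K) = 1 - K/N`, whose
nontrivial root is `K/N ≈ 0.2032` for *every* `N` (the equation depends on
the ratio only); back-substitution gives `mu t* = ln(N/K) + x*/(2K)`. The
widely quoted small-`K/N` forms `K = e^{-2} N`,
`mu t* = e^2 x*/(2N) + 2`, variance `x*/(x* + 4 e^{-2} N)` follow from
dropping the `K/N` term, which is only marginally justified (`e^{-2} =
0.135` vs the exact ratio `0.203` — a ~50% difference in `K`, though the
variance at the two points differs by only ~7% because the optimum is
flat). Both modes are exposed (`repressor_optimum(mode=...)`); note that
the `H = 3` numeric landscape has its minimum near the *exact* stationary
point, not the small-`K/N` one.

The linearity index `rho = (2/(x* t*)) \int_0^{t*} x dt` equals
`1 - t0/t*` for piecewise-linear means. Writing the variance formulas in
terms of `rho` and the regulator cost (time-averaged copy number,
`<a> = k t*/2` or `<r> = N (1 - e^{-mu t*})/(mu t*)`) gives the envelopes

    activator:  x* (1 - rho)/(2 <a>) + rho^2
    repressor:  (e^3/27) (x*/<r>) (1 - rho)^3 + rho^2

the repressor after optimizing the initial number, `N = 3<r>/(1 - rho)`.
In the intermediate expression `x*(e^{N(1-rho)/<r>} - 1)<r>^2/N^3 + rho^2`
the `-1` is retained (it is what makes the regulator term vanish exactly
at `rho = 1`); dropping it, as the envelope derivation does for `rho < 1`,
shifts the optimal `N` by a few percent and the minimum by <1%.

## Stochastic simulation

The Gillespie direct method with events: regulator production, regulator
degradation (`mu y`), target production (`f±(y)`). The FPT is the first
time `x` reaches `x_star`; by default the run then terminates (matching
the absorbing convention of the solver), but trajectories can continue to
`t_max` for mean curves and cross-sectional observation. Extensions:

- **Bursts.** Production events fire at rate `k/b` and add a
  geometric(mean `b`) number of molecules, preserving the mean flux `k`
  while amplifying regulator noise; `b = 1` reproduces the plain process
  on the identical random stream.
- **Poisson initial condition.** The repressor's initial count can be
  drawn Poisson with mean `n0` across runs.
- **Cell division.** At most one division per run, at a Gaussian time
  (mean `t_d_mean`, SD `t_d_sd`, redrawn if nonpositive — a negative
  division time is unphysical). Both counts are partitioned binomially
  (each molecule kept with probability 1/2, drawn as a popcount of random
  bits) and `K` is scaled by the post-division volume fraction (default
  1/2) because `K = K_d V`. Division times default to
  `t_d_mean = 0.8 t_star`, `t_d_sd = 0.05 t_star`: late in the process but
  before the terminal expression rise, the configuration in which the
  measured division times of the motivating experiment fall. Division can
  *lower* as well as raise the timing variance (halving `K` changes the
  effective regulation strategy), so "insensitive to division" is assessed
  on the absolute scaled-variance scale, where deviations stay well under
  a tenth of the unregulated baseline.

Reproducibility: run `i` uses an independent `random.Random` stream seeded
by the `i`-th 64-bit word of `SeedSequence(seed).generate_state(n_runs)`;
vectorized auxiliary draws use a generator spawned from the same master
sequence. Identical `(spec, seed, n_runs)` give bit-identical ensembles
regardless of run order. For variants the exact solver cannot treat
(division, bursts), `alpha` can be recalibrated by a common-random-numbers
secant iteration on the ensemble mean (tolerance `1e-3 t_star`).

## Cross-sectional scatter analysis

Single-molecule FISH is destructive, so real data are one `(t, x)` point
per cell. The synthetic generator emulates this: each cell is an
independent trajectory observed once at a uniform random time in
`[0, 1.3 t_star]` (constant migration speed makes the experimental time
axis uniformly populated; 200 cells by default, 500 in the end-to-end
recovery check). Trajectories continue past the threshold; an optional
flag freezes production at `x_star` to mimic saturating expression.

Estimation mirrors the published procedure: for every combination of a
candidate threshold `x*` in 10..25 and a bin width `dx` in {3, 6, 9, 12},
the observation times of the cells with `x` in `[x* - dx/2, x* + dx/2]`
give a mean (estimating `t*`), an unbiased variance (estimating
`sigma_t^2`), and `var·x*/mean^2` (the scaled variance); estimates are
averaged over the grid and the spread across combinations is the reported
uncertainty. `rho` is computed per combination by a trapezoidal sum over
the time-sorted points with `(0,0)` prepended and interpolation to that
combination's `t*`, then averaged likewise.

Known biases, accepted because they are part of the procedure being
emulated: the binned time variance of a noiseless linear trajectory is not
zero but the bin-width term `(dx/alpha)^2/12`; for trajectories nonlinear
in time the cross-sectional variance is a biased estimator of the true FPT
variance. The end-to-end recovery tolerance (25%) absorbs both. The
generator does not emulate measurement noise in the count itself, cell-to-
cell parameter variability, or non-uniform observation times; passing
tests therefore validate the estimator pipeline, not those aspects of real
data.

## Problem sizes

Parameter scans use 30×30 grids (repressor `K` in [0.5, 8] ×
`mu t*` in [1, 12]; activator corner and descent-path probes); slice
comparisons use 20 log-spaced points per slice spanning one decade
centered on the closed-form optimal parameters; simulator cross-checks use
50,000-run ensembles compared within three standard errors; the end-to-end
scatter check uses 500 cells. These sizes make every check reproducible on
a single CPU in minutes while keeping Monte-Carlo error well below the
tolerances tested.

## Limitations

- No auto-regulation/feedback on the target, no regulator cascades, no
  transcriptional delay, at most one regulator species.
- The variance decomposition is derived only for the pure activator and
  pure repressor in the step limit; the birth–death extension is handled
  by the exact solver and simulator only.
- At most one division per run; asymmetric volume fractions are exposed
  but exercised only at 1/2.
- The exact solver's generator is time-independent; division is handled
  only by the simulator.
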