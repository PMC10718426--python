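# Methods

## Models

**State space.** Two species share a fixed total population `N`. The state
is the abundance `n` of species 1 (relative fitness `w = 1 + s > 0`); `n = 0`
and `n = N` are absorbing (extinction / fixation).

**Moran model (baseline).** Per event, a fitness-weighted individual
divides while a uniformly chosen individual dies:
`T+(n) = [wn/((N-n)+wn)](N-n)/N`, `T-(n) = [(N-n)/((N-n)+wn)] n/N`.
Events fire at rate `r N`, so one time unit is one generation and the ratio
`T+/T-` is `w` at every interior state. The basal rate `r` (default 1)
rescales time identically in both models; it is the only free time scale.

**Spatial exclusion model.** `N` cells single file in a channel open at
both ends, species segregated so a single inter-species boundary exists.
The divider is chosen with probability `w/D` (species 1) or `1/D` (species
2), `D = (N-n) + wn`; the daughter pushes the cells between the divider and
one opening outward, expelling the terminal cell. The push direction is
right with probability `(i-1)/(N-1)` for a divider at position `i` (the
linear minimal-bias law: proportional to the cells it does *not* have to
push). Summing per-cell rates gives the boundary rates `r±(n)` quoted in the
README. The total division rate is exactly `r (N-1)` independent of the
composition, which the simulator exploits (a single exponential clock).
`N >= 3` is required: at `N = 2` both boundary rates vanish at `n = 1` and
the `(N-1)` direction normalisation degenerates, so the constructor rejects
it rather than regularising.

**Conventions.** Positions are 1-based; species 1 occupies the prefix
`1..n`. Divisions whose push would expel the divider's own daughter (e.g.
position 1 dividing left) are null events for the composition but still
consume time, consistently with the constant total rate.

## Exact first-passage solvers

Absorption probabilities use the gambler's-ruin product form with rate
ratios `gamma_j = r-(j)/r+(j)` accumulated in log space; the products span
`~ e^{N ln 2}`, so log accumulation keeps the recursion stable to `N ~ 1e4`.
Structural zeros (`r+(1) = 0`, `r-(N-1) = 0` in the spatial chain) are
short-circuited exactly: states cut off from one end get probability 0 or 1,
never an epsilon-regularised rate. An interior state with both rates zero is
reported as a frozen-state error.

MFPTs solve the tridiagonal backward system
`r+(n)[tau(n+1)-tau(n)] + r-(n)[tau(n-1)-tau(n)] = -1` by one banded solve
(O(N), partial pivoting). Conditional MFPTs use the standard construction:
solve the same system with source `-P_target(n)` and divide by `P_target`;
where `P_target = 0` the conditional time is NaN (undefined), never 0 or
infinity, and CSV export writes those fields empty. Averages over initial
conditions exclude the absorbing states.

## Continuum (Fokker-Planck) solvers

Drift `A = r+ - r-` and diffusion `B = r+ + r-` in the continuum limit give
the backward operator `(A/N) d/df + (B/2N^2) d^2/df^2`. The potential
`U(f) = -2N ∫ A/B` is evaluated in closed form (the integrand is rational;
partial fractions plus an arctan term), normalised so `max U = 0`
(`U(f_eq) = 0` for the spatial model). For neutral competition
`U = -N ln(2(2f^2-2f+1))`, `U''(f_eq) = -8N`; generally
`U''(f_eq) = -2N(1+sqrt(w))^2/sqrt(w)`.

Fixation probability and MFPT use the classical scale/speed-density
quadratures. All integrals of `e^{±U}` are carried in log space (values span
`O(N)`), with per-segment integration assuming the *log*-integrand is linear
across the segment -- exact for exponentials and accurate where the speed
density rises by many e-folds per grid step near the channel ends; a plain
trapezoid rule there overshoots the MFPT by ~20% at `N = 4000`. The default
uniform grid has `max(2001, 2N+1)` nodes, keeping the quadrature within
0.1% of the exact discrete MFPT up to `N ~ 1e4` at negligible cost.

**Deterministic time.** Outside the tug-of-war region the MFPT obeys
`-1 = (A/N) tau'`, solved exactly by
`tau_det(f) = -(1/r)(ln|(w-1)f^2+2f-1| - Theta(f - f_eq) ln w)`.
The Heaviside step is placed at `f - f_eq`: the unique choice with
`tau_det(0) = tau_det(1) = 0` and continuity in `w` at `w = 1`. `tau_det`
diverges at `f_eq` and is reported as +inf there.

**Tug-of-war region.** The boundaries `f_t±` solve
`|U'(f_t)| = sqrt(|U''(f_eq)|/pi)` by bracketed root finding (xtol 1e-10).
The square root is deliberate: balancing `|U'|` directly against `U''/pi`
is dimensionally inconsistent (`U'` ~ 1/f, `U''` ~ 1/f^2) and would give an
N-independent region, contradicting the diffusive picture; the square-root
criterion gives a half-width `~ (pi |U''|)^(-1/2)`, i.e. `1/sqrt(8 pi N)`
for neutral competition, and with it the `(1/2) ln(pi N)` growth of the
maximal MFPT.

**tau_dif.** Defined operationally as the residual
`tau_exact(n_eq) - (1/2) ln(pi N)` with `n_eq = round(N f_eq)`, computed
from the exact discrete solver over a ladder of sizes (default
500..4000) and averaged; the per-N residuals are returned so flatness can
be asserted. Measured values: 0.411-0.423 for `w = 1` (mean 0.416),
0.52-0.58 for `w = 10`. Note the additive convention inside the logarithm
matters: using `2 pi N` instead of `pi N` shifts the residual by
`(1/2) ln 2 ≈ 0.35`; this package uses `pi N` throughout. The approximate
maximal MFPT is assembled as `tau_a = tau_det(f_t±) + tau_dif` with
`tau_det` averaged over the two boundaries (they coincide for `w = 1`);
at `N = 1000` this is within 8% (`w = 1`) and 3% (`w = 10`) of the exact
maximum.

## Invasion model

Segments `(a, b)` with `1 <= a <= b <= N` enumerate the invader's extent;
`(1, N)` is the FIXED outcome and `m = 0` EXTINCT. The four transition
families (README) are assembled into a sparse generator; null self-loop
events are omitted, which leaves continuous-time first-passage laws
unchanged. Absorption probabilities and success-conditioned times come from
sparse LU solves of `(diag(outflow) - Q) h = exit_rates` -- `N = 100` means
5049 transient unknowns and runs in well under a second.

Two structural identities gate the re-derived rate table and are enforced in
tests: (i) a segment pinned at `a = 1` reproduces the single-boundary chain
exactly (agreement to 1e-15 with the 1D solver), and (ii) for a neutral
invader the success probabilities over all insertion sites sum to exactly 1
(exactly one founder lineage inherits the channel), which also forces the
uniform average to be `1/N`.

## Simulator

The cell-level simulator implements only the microscopic rules (labels
array, fitness-weighted divider choice by inverse-CDF, linear direction
bias, shift-and-expel) and never the mesoscopic rates, so ensemble
agreement with the solvers is a genuine cross-validation of the two
descriptions. Waiting times are exponential with the constant total rate
`r (N-1)`. Hot loops are numba-compiled with a pure-Python fallback.
Per-replicate 32-bit seeds are spawned from the master seed with
`numpy.random.SeedSequence`; identical seeds reproduce identical event
sequences. Ensemble summaries report Wilson intervals for win fractions
(non-degenerate at 0 and 1) and normal-approximation intervals for mean
times (NaN for a single replicate).

## Numerical choices and defaults

| quantity | default | rationale |
|---|---|---|
| `r` | 1 /generation | makes spatial and Moran time axes directly comparable |
| FP grid | `max(2001, 2N+1)` uniform nodes | resolves the `~1/(2N)` e-folding of the speed density at the ends |
| root-finding xtol | 1e-10 in `f` | region boundaries well below grid resolution |
| `tau_dif` ladder | N = 500, 1000, 2000, 4000 | asymptotic regime (residual spread < 0.02) at < 1 s of tridiagonal solves |
| simulator step cap | 1e9 events | diagnostic guard; untriggered for N <= 1e3 |

## What the tests do and do not show

All inputs are generated internally; the exact solvers, the continuum
approximations and the agent simulator validate one another (dense
brute-force solves at small N, closed forms for the Moran chain, 4-SE
Monte-Carlo agreement at `N = 20` with 1e5 replicates). Passing tests
demonstrate internal consistency of this idealised lattice model -- they say
nothing about mechanical effects absent from it: cell size variability and
forces, growth-rate coupling to pressure, wall adhesion, position-dependent
basal rates, multi-lane channels, or sub/super-linear direction-bias laws.
The linear bias is stronger than what has been measured in microfluidic
experiments; alternative bias strengths are deliberately out of scope.

Known quantitative caveats, measured and asserted in the test suite: the
MFPT peak approaches `f_eq` only like `N^(-1/2)` for `w > 1`; the
success-conditioned advantage of a fitter species reverses for rare-minority
starts (`n < ~0.17 N` at `w = 10`); and the N-collapse of MFPT curves away
from the peak reaches the 5% level only from `N ~ 100` upward.
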