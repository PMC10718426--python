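"""Exact first-passage solvers for birth-death chains with absorbing ends.

Given tabulated one-step rates on states ``0..N`` with 0 and N absorbing,
these routines compute, for every initial state:

* the probability of absorption at each end (fixation of species 1 at
  ``n = N``, extinction at ``n = 0``),
* the unconditional mean first-passage time (MFPT) to absorption, and
* MFPTs conditioned on which end wins.

Absorption probabilities use the gambler's-ruin product recursion with the
rate ratios accumulated in log space, which stays stable up to N ~ 1e4 where
the products span thousands of orders of magnitude.  MFPTs solve the
tridiagonal backward system directly (one banded solve, O(N)).

Structural zeros -- interior states with a vanishing up- or down-rate, such
as ``n = 1`` and ``n = N - 1`` in the spatial exclusion chain, which can
only exit in one direction -- are handled exactly, not by regularisation.
A conditional MFPT from a state that can never reach the conditioning end is
reported as NaN (undefined), never as 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .model_core import BirthDeathChain

__all__ = [
    "FirstPassageSolution",
    "fixation_probability",
    "mfpt_unconditional",
    "mfpt_conditional",
    "average_over_initials",
    "solve_chain",
]


@dataclass(frozen=True)
class FirstPassageSolution:
    """First-passage functionals of a birth-death chain, per initial state.

    All vectors are indexed by the initial abundance ``n = 0..N``.  Times are
    in units of ``1/r``.  Conditional MFPTs are NaN where the conditioning
    outcome has zero probability.
    """

    N: int
    p_fix_high: np.ndarray
    p_fix_low: np.ndarray
    mfpt: np.ndarray
    mfpt_cond_high: np.ndarray
    mfpt_cond_low: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = np.arange(self.N + 1)
        return pd.DataFrame(
            {
                "n": n,
                "f": n / self.N,
                "p_fix_high": self.p_fix_high,
                "p_fix_low": self.p_fix_low,
                "mfpt": self.mfpt,
                "mfpt_cond_high": self.mfpt_cond_high,
                "mfpt_cond_low": self.mfpt_cond_low,
            }
        )

    def to_csv(self, path) -> None:
        # NaN conditional entries serialize as empty fields
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def _structure(chain: BirthDeathChain) -> tuple[int, int]:
    """Locate structural zeros of the interior rates.

    Returns ``(j_low, j_high)``: states ``n <= j_low`` can never reach N
    (some up-rate at or above them vanishes) and states ``n >= j_high`` can
    never reach 0.  For a chain with strictly positive interior rates this is
    ``(0, N)``.
    """
    up, down, N = chain.up, chain.down, chain.N
    interior = np.arange(1, N)
    frozen = interior[(up[1:N] == 0) & (down[1:N] == 0)]
    if frozen.size:
        raise ValueError(
            f"frozen interior state(s) {frozen.tolist()}: both rates vanish "
            "but the state is not absorbing"
        )
    up_zero = interior[up[1:N] == 0]
    down_zero = interior[down[1:N] == 0]
    j_low = int(up_zero.max()) if up_zero.size else 0
    j_high = int(down_zero.min()) if down_zero.size else N
    if j_low >= j_high:
        raise ValueError(
            "inconsistent rate structure: no state can reach both absorbing ends"
        )
    return j_low, j_high


def fixation_probability(chain: BirthDeathChain) -> np.ndarray:
    """Probability of absorption at N (species-1 fixation) per initial state.

    Solves the backward harmonic equation by the gambler's-ruin closed form

        P1(n) = sum_{k<n} prod_{j<=k} gamma_j / sum_{k<N} prod_{j<=k} gamma_j,

    with ``gamma_j = down[j]/up[j]`` accumulated in log space.  States cut
    off from one end by a structural zero are short-circuited to 0 or 1.
    """
    N = chain.N
    j_low, j_high = _structure(chain)
    p = np.empty(N + 1)
    p[: j_low + 1] = 0.0
    p[j_high:] = 1.0
    if j_high - j_low >= 2:
        j = np.arange(j_low + 1, j_high)
        log_gamma = np.log(chain.down[j]) - np.log(chain.up[j])
        # log of prod_{j<=k} gamma_j for k = j_low..j_high-1 (empty product = 1)
        log_terms = np.concatenate([[0.0], np.cumsum(log_gamma)])
        log_cum = np.logaddexp.accumulate(log_terms)
        # P1(n) for n = j_low+1 .. j_high-1
        p[j_low + 1 : j_high] = np.exp(log_cum[:-1] - log_cum[-1])
    return p


def _backward_solve(chain: BirthDeathChain, rhs: np.ndarray) -> np.ndarray:
    """Solve the interior tridiagonal backward system  L g = -rhs, g(0)=g(N)=0.

    ``L g (n) = up[n] (g(n+1) - g(n)) + down[n] (g(n-1) - g(n))``.
    """
    N = chain.N
    up = chain.up[1:N]
    down = chain.down[1:N]
    m = N - 1
    ab = np.zeros((3, m))
    ab[0, 1:] = up[:-1]  # superdiagonal
    ab[1, :] = -(up + down)  # diagonal
    ab[2, :-1] = down[1:]  # subdiagonal
    g = solve_banded((1, 1), ab, -np.asarray(rhs, dtype=float))
    out = np.zeros(N + 1)
    out[1:N] = g
    return out


def mfpt_unconditional(chain: BirthDeathChain) -> np.ndarray:
    """Mean first-passage time to either absorbing end, per initial state."""
    _structure(chain)  # raise on frozen states
    return _backward_solve(chain, np.ones(chain.N - 1))


def mfpt_conditional(
    chain: BirthDeathChain, target: str = "high"
) -> tuple[np.ndarray, np.ndarray]:
    """Absorption probability and MFPT conditioned on absorbing at one end.

    Returns ``(P_target, tau_target)`` where ``tau_target`` solves the
    backward system with source ``-P_target`` divided by ``P_target``
    pointwise; it is NaN wherever ``P_target = 0``.
    """
    if target not in ("high", "low"):
        raise ValueError("target must be 'high' or 'low'")
    p_high = fixation_probability(chain)
    p = p_high if target == "high" else 1.0 - p_high
    g = _backward_solve(chain, p[1 : chain.N])
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(p > 0, g / np.where(p > 0, p, 1.0), np.nan)
    # absorbing ends: time zero where the condition is satisfiable
    tau[0] = 0.0 if target == "low" else tau[0]
    tau[chain.N] = 0.0 if target == "high" else tau[chain.N]
    return p, tau


def average_over_initials(values: np.ndarray) -> float:
    """Uniform average over the interior initial states ``n = 1..N-1``.

    The absorbing states are excluded: a competition that starts decided is
    not a competition.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least one interior state")
    return float(values[1:-1].mean())


def solve_chain(chain: BirthDeathChain) -> FirstPassageSolution:
    """All first-passage functionals of one chain in a single object."""
    p_high = fixation_probability(chain)
    mfpt = mfpt_unconditional(chain)
    _, tau_high = mfpt_conditional(chain, "high")
    _, tau_low = mfpt_conditional(chain, "low")
    return FirstPassageSolution(
        N=chain.N,
        p_fix_high=p_high,
        p_fix_low=1.0 - p_high,
        mfpt=mfpt,
        mfpt_cond_high=tau_high,
        mfpt_cond_low=tau_low,
    )
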