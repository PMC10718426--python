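"""Two-boundary invasion model: a single invader inside a fixated channel.

An invader placed at position ``x`` of a full channel of ``N`` native cells
creates a contiguous invader segment ``[a, b]`` (initially ``a = b = x``)
bounded by *two* inter-species boundaries.  The birth/death rules are the
same as in the single-boundary spatial exclusion model -- fitness-weighted
choice of the dividing cell (invader weight ``w``, native weight 1,
normaliser ``D = (N - m) + w m`` with segment size ``m = b - a + 1``),
linear direction bias, shift-and-expel pushing -- but the state space is now
the two-dimensional set of segments ``1 <= a <= b <= N``.

Summing per-cell division rates gives the transitions out of ``(a, b)``:

* left native divides right,  rate ``r (a-1)(a-2) / 2D``:
  segment shifts right to ``(a+1, b+1)``; if ``b = N`` the invader's
  rightmost cell is expelled instead, shrinking it to ``(a+1, N)``;
* right native divides left,  rate ``r (N-b)(N-b-1) / 2D``:
  mirror image, to ``(a-1, b-1)`` or ``(1, b-1)``;
* invader divides right,  rate ``r w m (a+b-2) / 2D``:
  grows to ``(a, b+1)``; null if ``b = N`` (its own cell is expelled);
* invader divides left,   rate ``r w m (2N-a-b) / 2D``:
  grows to ``(a-1, b)``; null if ``a = 1``.

Native divisions that push only natives out are null events.  Null
(self-loop) events are omitted from the continuous-time generator -- they do
not alter first-passage laws.  Absorption: EXTINCT when ``m`` reaches 0,
FIXED at ``(a, b) = (1, N)``.

Two structural identities gate the derivation and are enforced in the test
suite: a segment pinned at an edge (``a = 1``) reduces exactly to the
single-boundary chain, and for neutral invaders the success probabilities
sum to exactly 1 over insertion positions (exactly one of the N founder
lineages takes over).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .model_core import CompetitionParams

__all__ = [
    "InvasionChain",
    "build_invasion_chain",
    "invasion_probability_profile",
    "average_invasion_probability",
    "conditional_invasion_mfpt",
    "invasion_summary",
]

EXTINCT = -1
FIXED = -2


@dataclass(frozen=True)
class InvasionChain:
    """Sparse continuous-time generator of the two-boundary invasion process.

    Transient states are all segments ``(a, b)`` with ``1 <= a <= b <= N``
    except ``(1, N)``, enumerated row-major in ``a`` then ``b``.  ``Q`` holds
    the transient-to-transient rates, ``to_fixed`` / ``to_extinct`` the exit
    rates into the two absorbing outcomes.
    """

    N: int
    w: float
    r: float
    states: np.ndarray  # (n_transient, 2) array of (a, b)
    index: dict  # (a, b) -> row
    Q: sp.csr_matrix  # off-diagonal transient rates
    out_rate: np.ndarray  # total outflow per transient state
    to_fixed: np.ndarray
    to_extinct: np.ndarray

    @property
    def n_transient(self) -> int:
        return self.states.shape[0]


def _transitions(N: int, w: float, r: float, a: int, b: int):
    """Yield (rate, destination) for one segment state; dest is (a', b') or a label."""
    m = b - a + 1
    D = (N - m) + w * m
    # left native divides right
    rate = r * (a - 1) * (a - 2) / (2.0 * D)
    if rate > 0:
        if b < N:
            yield rate, (a + 1, b + 1)
        else:
            yield rate, (a + 1, N) if a + 1 <= N else EXTINCT
    # right native divides left
    rate = r * (N - b) * (N - b - 1) / (2.0 * D)
    if rate > 0:
        if a > 1:
            yield rate, (a - 1, b - 1)
        else:
            yield rate, (1, b - 1) if b - 1 >= 1 else EXTINCT
    # invader divides right
    if b < N:
        rate = r * w * m * (a + b - 2) / (2.0 * D)
        if rate > 0:
            yield rate, (a, b + 1)
    # invader divides left
    if a > 1:
        rate = r * w * m * (2 * N - a - b) / (2.0 * D)
        if rate > 0:
            yield rate, (a - 1, b)


def build_invasion_chain(params: CompetitionParams) -> InvasionChain:
    """Enumerate the segment state space and assemble the sparse generator."""
    if params.N < 3:
        raise ValueError("invasion model requires N >= 3")
    N, w, r = params.N, params.w, params.r
    states = [(a, b) for a in range(1, N + 1) for b in range(a, N + 1) if (a, b) != (1, N)]
    index = {s: k for k, s in enumerate(states)}
    n_tr = len(states)
    rows, cols, vals = [], [], []
    out_rate = np.zeros(n_tr)
    to_fixed = np.zeros(n_tr)
    to_extinct = np.zeros(n_tr)
    for k, (a, b) in enumerate(states):
        for rate, dest in _transitions(N, w, r, a, b):
            out_rate[k] += rate
            if dest == EXTINCT:
                to_extinct[k] += rate
            elif dest == (1, N):
                to_fixed[k] += rate
            else:
                da, db = dest
                if db - da + 1 <= 0:
                    to_extinct[k] += rate
                else:
                    rows.append(k)
                    cols.append(index[dest])
                    vals.append(rate)
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n_tr, n_tr))
    return InvasionChain(
        N=N,
        w=w,
        r=r,
        states=np.asarray(states, dtype=int),
        index=index,
        Q=Q,
        out_rate=out_rate,
        to_fixed=to_fixed,
        to_extinct=to_extinct,
    )


def _linear_solve(chain: InvasionChain, rhs: np.ndarray) -> np.ndarray:
    """Solve (diag(out_rate) - Q) h = rhs over the transient states."""
    A = sp.diags(chain.out_rate) - chain.Q
    h = spsolve(A.tocsc(), rhs)
    if not np.all(np.isfinite(h)):
        raise RuntimeError(
            "invasion linear solve returned non-finite values; the generator "
            f"may be ill-conditioned (N={chain.N}, w={chain.w})"
        )
    return h


def _fixation_vector(chain: InvasionChain) -> np.ndarray:
    """P(absorb at FIXED) for every transient segment state."""
    return _linear_solve(chain, chain.to_fixed)


def invasion_probability_profile(params: CompetitionParams) -> np.ndarray:
    """Probability that an invader inserted at x = 1..N takes over the channel.

    Index 0 of the returned vector is position ``x = 1``.  Edge insertions
    never succeed: an edge invader cannot divide inward and any native push
    expels it.
    """
    chain = build_invasion_chain(params)
    h = _fixation_vector(chain)
    return np.array([h[chain.index[(x, x)]] for x in range(1, params.N + 1)])


def average_invasion_probability(params: CompetitionParams) -> float:
    """Uniform average of the success probability over insertion positions.

    Equals exactly 1/N for a neutral invader: one of the N founder lineages
    takes over the channel.
    """
    return float(invasion_probability_profile(params).mean())


def conditional_invasion_mfpt(
    params: CompetitionParams,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Success-conditioned invasion MFPT per insertion position.

    Returns ``(p_success, tau_cond, weighted_average)`` over ``x = 1..N``;
    ``tau_cond`` is NaN where success is impossible (the channel edges) and
    the average is weighted by the success probability,
    ``sum_x P(x) tau_c(x) / sum_x P(x)``.
    """
    chain = build_invasion_chain(params)
    h = _fixation_vector(chain)
    g = _linear_solve(chain, h)  # g = P_fix * tau_cond per transient state
    idx = [chain.index[(x, x)] for x in range(1, params.N + 1)]
    p = h[idx]
    gx = g[idx]
    if not np.any(p > 0):
        raise RuntimeError("no insertion position has positive success probability")
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(p > 0, gx / np.where(p > 0, p, 1.0), np.nan)
    avg = float(gx.sum() / p.sum())
    return p, tau, avg


def invasion_summary(params: CompetitionParams) -> tuple[pd.DataFrame, dict]:
    """Profile table and JSON-ready summary of one invasion computation."""
    p, tau, avg_tau = conditional_invasion_mfpt(params)
    table = pd.DataFrame(
        {"x": np.arange(1, params.N + 1), "p_success": p, "mfpt_cond": tau}
    )
    summary = {
        "N": params.N,
        "w": float(params.w),
        "avg_probability": float(p.mean()),
        "avg_cond_mfpt": avg_tau,
    }
    return table, summary
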