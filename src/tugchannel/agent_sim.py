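"""Event-driven cell-level simulator of the channel and of the Moran model.

This is the stochastic oracle for the exact solvers: it implements the
microscopic rules directly -- fitness-weighted choice of the dividing cell,
linear direction bias, shift-and-expel pushing -- without ever referencing
the mesoscopic boundary rates, so agreement between simulated ensembles and
the birth-death solvers validates that the two descriptions are the same
process.

Dynamics are continuous-time: every cell divides with exponential clocks,
giving a constant total event rate ``r (N - 1)`` (division propensities are
normalised over the channel), and each event picks a cell with probability
proportional to its fitness weight and a direction by the linear bias.
Divisions whose push expels the divider's own terminal lineage cell (e.g. a
leftmost cell dividing left) are null events for the species composition but
still consume simulated time, consistent with the rate normalisation.

Hot loops are compiled with numba when available and fall back to pure
Python otherwise; both paths draw from the same legacy NumPy RNG stream so
results are identical.  Replicate seeds are derived from a master seed via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import BirthDeathChain, CompetitionParams, moran_rates

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


__all__ = [
    "ChannelConfig",
    "SimulationEnsemble",
    "step",
    "run_to_fixation",
    "run_moran",
    "run_ensemble",
    "estimate_first_passage",
]

SPECIES1 = 1  # focal species / invader (fitness w)
SPECIES2 = 2  # competitor / native (fitness 1)


@dataclass
class ChannelConfig:
    """Cell labels over channel positions 1..N plus parameters and seed.

    ``mode`` is ``"single_boundary"`` (species-1 block must be a prefix) or
    ``"invasion"`` (single species-1 segment anywhere in the channel).
    """

    cells: np.ndarray
    params: CompetitionParams
    rng_seed: int = 0
    mode: str = "single_boundary"

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.size != self.params.N:
            raise ValueError("cells must have length N")
        if not np.all(np.isin(self.cells, (SPECIES1, SPECIES2))):
            raise ValueError("labels must be SPECIES1 (1) or SPECIES2 (2)")
        if self.mode not in ("single_boundary", "invasion"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "single_boundary":
            n = int(np.sum(self.cells == SPECIES1))
            if not np.all(self.cells[:n] == SPECIES1):
                raise ValueError(
                    "single-boundary mode requires the species-1 block to be a prefix"
                )

    @property
    def n1(self) -> int:
        return int(np.sum(self.cells == SPECIES1))

    @classmethod
    def segregated(cls, params: CompetitionParams, n0: int, seed: int = 0) -> "ChannelConfig":
        """Species 1 occupying positions 1..n0, species 2 the rest."""
        if not (0 <= n0 <= params.N):
            raise ValueError("n0 must be in [0, N]")
        cells = np.full(params.N, SPECIES2, dtype=np.int8)
        cells[:n0] = SPECIES1
        return cls(cells=cells, params=params, rng_seed=seed)

    @classmethod
    def invasion(cls, params: CompetitionParams, x: int, seed: int = 0) -> "ChannelConfig":
        """A single invader at position x (1-based) in a native channel."""
        if not (1 <= x <= params.N):
            raise ValueError("x must be in 1..N")
        cells = np.full(params.N, SPECIES2, dtype=np.int8)
        cells[x - 1] = SPECIES1
        return cls(cells=cells, params=params, rng_seed=seed, mode="invasion")


def step(config: ChannelConfig, rng: np.random.Generator):
    """Advance the channel by one division event.

    Returns ``(new_config, waiting_time, event)`` where ``event`` records the
    1-based position ``i`` of the dividing cell, its ``label`` and the push
    ``direction`` ("left"/"right").  Pure-Python reference implementation
    used for unit-level checks; ensembles use the compiled kernel.
    """
    cells = config.cells
    N, w, r = config.params.N, config.params.w, config.params.r
    weights = np.where(cells == SPECIES1, w, 1.0)
    D = weights.sum()
    u = rng.random() * D
    j = int(np.searchsorted(np.cumsum(weights), u, side="right"))
    j = min(j, N - 1)
    i = j + 1
    right = rng.random() < (i - 1) / (N - 1)
    dt = rng.exponential(1.0 / (r * (N - 1)))
    lab = cells[j]
    new = cells.copy()
    if right:
        # daughter at j+1, cells beyond shift right, last cell expelled
        if j + 1 <= N - 1:
            new[j + 1 :] = cells[j:-1]
            new[j + 1] = lab
        # j == N-1: daughter inserted then immediately expelled (null event)
    else:
        # daughter at j, cells before shift left, first cell expelled
        new[: j] = cells[1 : j + 1]
        if j > 0:
            new[j - 1] = lab
        # j == 0: daughter inserted then immediately expelled (null event)
    event = {"i": i, "label": int(lab), "direction": "right" if right else "left"}
    return (
        ChannelConfig(cells=new, params=config.params, rng_seed=config.rng_seed, mode=config.mode),
        float(dt),
        event,
    )


@njit(cache=False)
def _channel_kernel(cells, w, r, seed, max_steps):  # pragma: no cover - compiled
    np.random.seed(seed)
    N = cells.size
    n1 = 0
    for k in range(N):
        if cells[k] == 1:
            n1 += 1
    t = 0.0
    total_rate = r * (N - 1)
    steps = 0
    while 0 < n1 < N:
        if steps >= max_steps:
            return -1, t, steps
        steps += 1
        D = (N - n1) + w * n1
        u = np.random.random() * D
        acc = 0.0
        j = 0
        for k in range(N):
            acc += w if cells[k] == 1 else 1.0
            if u < acc:
                j = k
                break
        i = j + 1
        right = np.random.random() < (i - 1.0) / (N - 1.0)
        t += np.random.exponential(1.0 / total_rate)
        lab = cells[j]
        if right:
            expelled = cells[N - 1]
            for k in range(N - 1, j + 1, -1):
                cells[k] = cells[k - 1]
            if j + 1 <= N - 1:
                cells[j + 1] = lab
            n1 += (1 if lab == 1 else 0) - (1 if expelled == 1 else 0)
        else:
            expelled = cells[0]
            for k in range(0, j - 1):
                cells[k] = cells[k + 1]
            if j - 1 >= 0:
                cells[j - 1] = lab
            n1 += (1 if lab == 1 else 0) - (1 if expelled == 1 else 0)
    winner = 1 if n1 == N else 2
    return winner, t, steps


@njit(cache=False)
def _bd_kernel(up, down, n0, seed, max_steps):  # pragma: no cover - compiled
    np.random.seed(seed)
    N = up.size - 1
    n = n0
    t = 0.0
    steps = 0
    while 0 < n < N:
        if steps >= max_steps:
            return -1, t, steps
        steps += 1
        rate = up[n] + down[n]
        t += np.random.exponential(1.0 / rate)
        if np.random.random() * rate < up[n]:
            n += 1
        else:
            n -= 1
    winner = 1 if n == N else 2
    return winner, t, steps


MAX_STEPS = 10**9


def run_to_fixation(config: ChannelConfig) -> tuple[int, float]:
    """Run the cell-level channel until one species occupies all N positions.

    Returns ``(winner_label, absorption_time)``.
    """
    cells = config.cells.copy()
    winner, t, steps = _channel_kernel(
        cells, float(config.params.w), float(config.params.r),
        np.uint32(config.rng_seed), MAX_STEPS,
    )
    if winner < 0:
        raise RuntimeError(f"no fixation within {MAX_STEPS} events (N={config.params.N})")
    return int(winner), float(t)


def run_moran(params: CompetitionParams, n0: int, seed: int) -> tuple[int, float]:
    """Gillespie simulation of the Moran chain from abundance n0."""
    if not (0 < n0 < params.N):
        raise ValueError("n0 must be an interior abundance")
    chain = moran_rates(params)
    winner, t, steps = _bd_kernel(
        chain.up, chain.down, int(n0), np.uint32(seed), MAX_STEPS
    )
    if winner < 0:
        raise RuntimeError("no fixation within the step cap")
    return int(winner), float(t)


@dataclass(frozen=True)
class SimulationEnsemble:
    """Replicate outcomes of repeated first-passage simulations."""

    params: CompetitionParams
    model: str
    initial: int  # n0 (abundance) or x (invasion position)
    master_seed: int
    winners: np.ndarray  # species labels, one per replicate
    times: np.ndarray

    @property
    def count(self) -> int:
        return self.winners.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "replicate_id": np.arange(self.count),
                "winner": self.winners,
                "time": self.times,
            }
        )


def _replicate_seeds(master_seed: int, reps: int) -> np.ndarray:
    """Per-replicate 32-bit seeds spawned from the master seed."""
    return np.random.SeedSequence(master_seed).generate_state(reps, dtype=np.uint32)


def run_ensemble(
    params: CompetitionParams,
    reps: int,
    master_seed: int,
    model: str = "spatial",
    n0: int | None = None,
    x0: int | None = None,
) -> SimulationEnsemble:
    """Simulate ``reps`` independent first-passage replicates.

    ``model``: "spatial" (segregated channel started at abundance ``n0``),
    "invasion" (single invader at position ``x0``), or "moran" (well-mixed,
    abundance ``n0``).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seeds = _replicate_seeds(master_seed, reps)
    winners = np.empty(reps, dtype=np.int8)
    times = np.empty(reps)
    if model == "moran":
        if n0 is None:
            raise ValueError("moran model requires n0")
        chain = moran_rates(params)
        for k in range(reps):
            wnr, t, st = _bd_kernel(chain.up, chain.down, int(n0), seeds[k], MAX_STEPS)
            if wnr < 0:
                raise RuntimeError("step cap exceeded")
            winners[k], times[k] = wnr, t
        initial = n0
    elif model in ("spatial", "invasion"):
        if model == "spatial":
            if n0 is None:
                raise ValueError("spatial model requires n0")
            template = ChannelConfig.segregated(params, n0)
            initial = n0
        else:
            if x0 is None:
                raise ValueError("invasion model requires x0")
            template = ChannelConfig.invasion(params, x0)
            initial = x0
        for k in range(reps):
            cells = template.cells.copy()
            wnr, t, st = _channel_kernel(
                cells, float(params.w), float(params.r), seeds[k], MAX_STEPS
            )
            if wnr < 0:
                raise RuntimeError("step cap exceeded")
            winners[k], times[k] = wnr, t
    else:
        raise ValueError(f"unknown model {model!r}")
    return SimulationEnsemble(
        params=params,
        model=model,
        initial=int(initial),
        master_seed=int(master_seed),
        winners=winners,
        times=times,
    )


def _wilson_interval(successes: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (non-degenerate at 0/1)."""
    phat = successes / n
    denom = 1.0 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


def estimate_first_passage(ensemble: SimulationEnsemble, winner: int = SPECIES1) -> dict:
    """Summarise an ensemble: win probability and mean time with intervals.

    Probability gets a 95% Wilson interval; the mean absorption time a
    normal-approximation interval (NaN half-width for a single replicate).
    Conditional mean times per winner are NaN when that outcome never
    occurred.
    """
    if ensemble.count == 0:
        raise ValueError("empty ensemble")
    n = ensemble.count
    wins = int(np.sum(ensemble.winners == winner))
    lo, hi = _wilson_interval(wins, n)
    times = ensemble.times
    mean_t = float(times.mean())
    se_t = float(times.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    def _cond_mean(label):
        sel = ensemble.winners == label
        return float(times[sel].mean()) if np.any(sel) else float("nan")

    return {
        "n": n,
        "p_win": wins / n,
        "p_win_ci": (lo, hi),
        "mean_time": mean_t,
        "mean_time_se": se_t,
        "mean_time_ci": (mean_t - 1.96 * se_t, mean_t + 1.96 * se_t),
        "cond_mean_time": {SPECIES1: _cond_mean(SPECIES1), SPECIES2: _cond_mean(SPECIES2)},
    }
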