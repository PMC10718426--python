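"""Parameters, transition rates, and continuum fields for two-species
competition in a one-dimensional open microchannel.

Two birth-death processes over the abundance ``n`` of species 1 (the focal
species, carrying relative fitness ``w``) share a common chain interface:

* **Moran model** -- the classical well-mixed baseline.  At each event one
  individual is chosen to divide (fitness-weighted) while another is chosen
  uniformly to die, keeping the total population ``N`` fixed.

* **Spatial exclusion model** -- ``N`` cells packed single file in a channel
  open at both ends.  A dividing cell pushes its neighbours toward one
  opening and the terminal cell on that side is expelled.  The probability
  that the cell at position ``i`` (1-based) divides to the right is
  ``(i - 1)/(N - 1)`` -- proportional to the number of cells it would *not*
  have to push -- and to the left ``(N - i)/(N - 1)``.  With the two species
  segregated, the state reduces to the position ``n`` of the single
  inter-species boundary, moving right at rate

      r+ (n) = r w n (n - 1) / (2 [(N - n) + w n])

  and left at rate

      r- (n) = r (N - n)(N - n - 1) / (2 [(N - n) + w n]).

The basal rate ``r`` (default 1) sets the time unit to roughly one
generation in both models: the total division rate of the channel is
``r (N - 1)`` and the Moran model performs ``N`` birth-death events per unit
time.

The continuum (Fokker-Planck) limit of either chain is characterised by a
drift field ``A(f)``, a diffusion field ``B(f)`` and the effective potential

    U(f) = -2 N \int^f A(y) / B(y) dy,

which for the spatial model is unimodal with an unstable maximum at the
equiprobable takeover abundance ``f_eq = 1 / (1 + sqrt(w))``, the initial
fraction from which both species win with equal probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import yaml

__all__ = [
    "CompetitionParams",
    "BirthDeathChain",
    "DirectionBias",
    "ContinuumFields",
    "spatial_rates",
    "moran_rates",
    "drift",
    "diffusion",
    "equiprobable_abundance",
    "potential",
    "potential_curvature_at_peak",
    "continuum_fields",
    "direction_bias",
    "params_from_config",
    "params_to_config",
]

_MODELS = ("spatial", "moran")


@dataclass(frozen=True)
class CompetitionParams:
    """Model parameters for a two-species competition in a channel of size N.

    Parameters
    ----------
    N:
        Total population / channel length in cells.  The Moran model needs
        ``N >= 2``; the spatial model needs ``N >= 3`` (at ``N = 2`` both
        boundary rates vanish at ``n = 1`` and the process freezes).
    w:
        Relative fitness of species 1, ``w = 1 + s`` with selection
        coefficient ``s``.
    r:
        Basal division rate (1/time).  ``r = 1`` makes one unit of time
        roughly one generation in both models.
    """

    N: int
    w: float = 1.0
    r: float = 1.0

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        object.__setattr__(self, "N", int(self.N))
        if not (self.w > 0):
            raise ValueError(f"relative fitness w must be > 0, got {self.w!r}")
        if not (self.r > 0):
            raise ValueError(f"basal rate r must be > 0, got {self.r!r}")

    @property
    def s(self) -> float:
        """Selection coefficient s = w - 1."""
        return self.w - 1.0


@dataclass(frozen=True)
class BirthDeathChain:
    """Tabulated one-step rates of a birth-death chain on states 0..N.

    ``up[n]`` is the rate of ``n -> n + 1`` and ``down[n]`` of
    ``n -> n - 1`` (units 1/time).  The end states 0 and N are absorbing, so
    all four boundary rates are forced to zero.
    """

    N: int
    up: np.ndarray
    down: np.ndarray

    def __post_init__(self) -> None:
        up = np.asarray(self.up, dtype=float)
        down = np.asarray(self.down, dtype=float)
        if up.shape != (self.N + 1,) or down.shape != (self.N + 1,):
            raise ValueError("rate vectors must have length N + 1")
        if not (np.all(np.isfinite(up)) and np.all(np.isfinite(down))):
            raise ValueError("rates must be finite")
        if np.any(up < 0) or np.any(down < 0):
            raise ValueError("rates must be non-negative")
        for v in (up, down):
            if v[0] != 0 or v[-1] != 0:
                raise ValueError("states 0 and N must be absorbing (zero rates)")
        up.setflags(write=False)
        down.setflags(write=False)
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)

    @property
    def absorbing(self) -> tuple[int, int]:
        return (0, self.N)


@dataclass(frozen=True)
class DirectionBias:
    """Linear division-direction bias over channel positions i = 1..N.

    ``p_right(i) = (i - 1)/(N - 1)``: a cell divides toward the opening for
    which it has to push fewer neighbours.
    """

    N: int

    def p_right(self, i):
        i = np.asarray(i, dtype=float)
        return (i - 1.0) / (self.N - 1.0)

    def p_left(self, i):
        return 1.0 - self.p_right(i)


def spatial_rates(params: CompetitionParams) -> BirthDeathChain:
    """Boundary-motion rates of the spatial exclusion model.

    The boundary at abundance ``n`` moves right when any of the ``n``
    species-1 cells divides to the right; summing the per-cell rates
    ``r (N-1) * w/[(N-n)+wn] * (i-1)/(N-1)`` over ``i = 1..n`` gives
    ``r+ = r w n(n-1) / (2[(N-n)+wn])`` and, mirror-wise,
    ``r- = r (N-n)(N-n-1) / (2[(N-n)+wn])``.
    """
    if params.N < 3:
        raise ValueError(
            "spatial exclusion model requires N >= 3: at N = 2 both boundary "
            "rates vanish at n = 1 (frozen state) and the (N - 1) direction "
            "normalization degenerates"
        )
    N, w, r = params.N, params.w, params.r
    n = np.arange(N + 1, dtype=float)
    D = (N - n) + w * n
    up = r * w * n * (n - 1.0) / (2.0 * D)
    down = r * (N - n) * (N - n - 1.0) / (2.0 * D)
    up[0] = up[N] = 0.0
    down[0] = down[N] = 0.0
    return BirthDeathChain(N=N, up=up, down=down)


def moran_rates(params: CompetitionParams) -> BirthDeathChain:
    """Moran-model transition rates with fitness-weighted birth selection.

    Per event, ``T+(n) = [wn/((N-n)+wn)] (N-n)/N`` and
    ``T-(n) = [(N-n)/((N-n)+wn)] n/N``; with ``N`` events per unit time the
    rates are ``r N T+-`` so one unit of time is one generation.  The ratio
    ``T+/T-`` equals ``w`` at every interior state.
    """
    N, w, r = params.N, params.w, params.r
    n = np.arange(N + 1, dtype=float)
    D = (N - n) + w * n
    Tp = (w * n / D) * ((N - n) / N)
    Tm = ((N - n) / D) * (n / N)
    up = r * N * Tp
    down = r * N * Tm
    up[0] = up[N] = 0.0
    down[0] = down[N] = 0.0
    return BirthDeathChain(N=N, up=up, down=down)


def direction_bias(N: int) -> DirectionBias:
    if N < 2:
        raise ValueError("direction bias needs N >= 2")
    return DirectionBias(N=N)


def _check_model(model: str) -> None:
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")


def drift(params: CompetitionParams, f, model: str = "spatial"):
    """Continuum drift field A(f) = r+(f) - r-(f), units 1/time.

    Spatial model: ``A(f) = r N [(w-1) f^2 + 2 f - 1] / (2 [1 + (w-1) f])``
    -- non-zero even for neutral competition, vanishing only at ``f_eq``.
    Moran model: ``A(f) = r N (w-1) f (1-f) / [1 + (w-1) f]`` (identically
    zero when neutral).
    """
    _check_model(model)
    f = np.asarray(f, dtype=float)
    N, w, r = params.N, params.w, params.r
    denom = 1.0 + (w - 1.0) * f
    if model == "spatial":
        out = r * N * ((w - 1.0) * f**2 + 2.0 * f - 1.0) / (2.0 * denom)
    else:
        out = r * N * (w - 1.0) * f * (1.0 - f) / denom
    return out if out.ndim else float(out)


def diffusion(params: CompetitionParams, f, model: str = "spatial"):
    """Continuum diffusion field B(f) = r+(f) + r-(f), units 1/time.

    Spatial: ``B(f) = r N [w f^2 + (1-f)^2] / (2 [1 + (w-1) f])`` (strictly
    positive on [0, 1]).  Moran: ``B(f) = r N (w+1) f (1-f) / [1 + (w-1) f]``
    (vanishing at the ends).
    """
    _check_model(model)
    f = np.asarray(f, dtype=float)
    N, w, r = params.N, params.w, params.r
    denom = 1.0 + (w - 1.0) * f
    if model == "spatial":
        out = r * N * (w * f**2 + (1.0 - f) ** 2) / (2.0 * denom)
    else:
        out = r * N * (w + 1.0) * f * (1.0 - f) / denom
    return out if out.ndim else float(out)


def equiprobable_abundance(w: float) -> float:
    """Initial fraction from which both species take over with probability 1/2.

    The zero of the spatial drift, i.e. the positive root of
    ``(w - 1) f^2 + 2 f - 1 = 0``:  ``f_eq = 1 / (1 + sqrt(w))``.  Equals 1/2
    for neutral competition and decreases monotonically with the fitness of
    species 1.
    """
    if not (w > 0):
        raise ValueError("w must be > 0")
    return 1.0 / (1.0 + np.sqrt(w))


def potential(params: CompetitionParams, f, model: str = "spatial"):
    """Fokker-Planck potential U(f) = -2N ∫^f A(y)/B(y) dy (dimensionless).

    Evaluated in closed form (the integrand is a rational function; ``r``
    cancels).  The integration constant is fixed so that ``max U = 0``:
    ``U(f_eq) = 0`` for the spatial model, ``U = 0`` at the end favoured by
    drift for the Moran model.  Values at the channel ends are O(-N), so
    ratios of ``exp(U)`` should always be formed in log space.
    """
    _check_model(model)
    f = np.asarray(f, dtype=float)
    N, w = params.N, params.w
    if model == "moran":
        # A/B = (w-1)/(w+1) is constant; normalized so max over [0,1] is 0.
        k = 2.0 * N * (w - 1.0) / (w + 1.0)
        out = -k * f if w >= 1 else -k * (f - 1.0)
        return out if out.ndim else float(out)
    # spatial: A/B = [(w-1)y^2 + 2y - 1] / [(w+1)y^2 - 2y + 1]
    #        = a + (b D'(y) + c) / D(y) with D(y) = (w+1)y^2 - 2y + 1
    a = (w - 1.0) / (w + 1.0)
    b = 2.0 * w / (w + 1.0) ** 2
    c = 2.0 * w * (1.0 - w) / (w + 1.0) ** 2
    feq = equiprobable_abundance(w)

    def F(y):
        Dy = (w + 1.0) * y**2 - 2.0 * y + 1.0
        atan = np.arctan(((w + 1.0) * y - 1.0) / np.sqrt(w)) / np.sqrt(w)
        return a * y + b * np.log(Dy) + c * atan

    out = -2.0 * N * (F(f) - F(feq))
    return out if out.ndim else float(out)


def potential_curvature_at_peak(params: CompetitionParams) -> float:
    """U''(f_eq) = -2N (1 + sqrt(w))^2 / sqrt(w) for the spatial model."""
    sw = np.sqrt(params.w)
    return -2.0 * params.N * (1.0 + sw) ** 2 / sw


@dataclass(frozen=True)
class ContinuumFields:
    """Bundle of continuum-limit fields for one model and parameter set."""

    params: CompetitionParams
    model: str
    drift: Callable = field(repr=False)
    diffusion: Callable = field(repr=False)
    potential: Callable = field(repr=False)
    f_eq: float | None = None


def continuum_fields(params: CompetitionParams, model: str = "spatial") -> ContinuumFields:
    """Construct drift/diffusion/potential callables plus ``f_eq``.

    ``f_eq`` is the interior zero of the drift; it exists for the spatial
    model at any ``w`` but only degenerately for the Moran model (whose drift
    never changes sign), where it is reported as ``None``.
    """
    _check_model(model)
    return ContinuumFields(
        params=params,
        model=model,
        drift=lambda f: drift(params, f, model),
        diffusion=lambda f: diffusion(params, f, model),
        potential=lambda f: potential(params, f, model),
        f_eq=equiprobable_abundance(params.w) if model == "spatial" else None,
    )


def params_from_config(path) -> tuple[CompetitionParams, str]:
    """Read ``(params, model)`` from a flat key-value YAML config.

    Recognised keys: ``N`` (required), ``w``, ``r``, ``model``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    unknown = set(cfg) - {"N", "w", "r", "model"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "N" not in cfg:
        raise ValueError("config must define N")
    model = cfg.get("model", "spatial")
    _check_model(model)
    params = CompetitionParams(
        N=int(cfg["N"]), w=float(cfg.get("w", 1.0)), r=float(cfg.get("r", 1.0))
    )
    return params, model


def params_to_config(params: CompetitionParams, model: str, path) -> None:
    _check_model(model)
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"N": params.N, "w": float(params.w), "r": float(params.r), "model": model},
            fh,
            default_flow_style=False,
        )
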