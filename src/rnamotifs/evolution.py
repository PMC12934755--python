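"""Drift-diffusion (Fokker-Planck) model of pairwise-similarity evolution.

The density f(s, t) of pairwise RNA similarity s evolves under

    df/dt = -d/ds [A(s) f] + D d2f/ds2

where the drift A(s) models systematic similarity change (motif swapping)
and the diffusion coefficient D models random change (mutation).  At steady
state the zero-flux solution is f(s) = C exp( (1/D) \\int A(s) ds ); the
drift A(s) = -D / (2 s) yields the power law f(s) proportional to s^(-1/2),
and conversely a stationary density determines the drift through
A(s) = D f'(s) / f(s).

The similarity domain is truncated to [s_min, 1] (default s_min = 0.01)
with reflecting boundaries: s^(-1/2) is integrable at 0 but the matching
drift diverges there, and similarity is bounded by 1.  Time units are
arbitrary; only the steady state is compared with data.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.stats import linregress

from .errors import ContractError, ModelError


def sqrt_inverse_drift(D: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """The drift A(s) = -D / (2 s) whose stationary density is ~ s^(-1/2)."""
    return lambda s: -D / (2.0 * np.asarray(s, dtype=float))


def _default_grid() -> np.ndarray:
    return np.linspace(0.01, 1.0, 1000)


@dataclass
class EvolutionModel:
    D: float = 1.0
    drift: Callable[[np.ndarray], np.ndarray] = field(default=None)
    grid: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self):
        if self.D <= 0:
            raise ContractError("diffusion coefficient D must be positive")
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.size < 10 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
            raise ContractError("grid must be strictly increasing with min > 0")
        self.grid = grid
        if self.drift is None:
            self.drift = sqrt_inverse_drift(self.D)


@dataclass
class DensityEstimate:
    s_values: np.ndarray
    density: np.ndarray
    alpha: float | None = None  # fitted power-law exponent
    alpha_se: float | None = None


def stationary_density(model: EvolutionModel) -> DensityEstimate:
    """Zero-flux steady state on the grid, normalized to unit mass."""
    s = model.grid
    phi = cumulative_trapezoid(np.asarray(model.drift(s), dtype=float) / model.D, s, initial=0.0)
    f = np.exp(phi - phi.max())
    mass = trapezoid(f, s)
    if not np.isfinite(mass) or mass <= 0:
        raise ModelError("stationary density is not normalizable on the grid")
    return DensityEstimate(s_values=s, density=f / mass)


def fit_power_law(
    s_or_samples,
    density=None,
    n_bins: int = 50,
    tail_fraction: float = 0.05,
):
    """Least-squares log-log slope of a density (or of binned samples).

    With one argument, the input is a sample of similarities that is binned
    into logarithmically spaced bins; with two, a density table (s, f).
    Support points whose s falls in the lowest or highest ``tail_fraction``
    of the s-range are excluded to avoid boundary-layer bias.  Returns
    (alpha, standard error).
    """
    if density is None:
        samples = np.asarray(s_or_samples, dtype=float)
        if samples.size < 10:
            raise ContractError("need at least 10 samples")
        if np.any(samples <= 0):
            raise ContractError("samples must be positive")
        edges = np.geomspace(samples.min(), samples.max(), n_bins + 1)
        hist, _ = np.histogram(samples, bins=edges, density=True)
        s = np.sqrt(edges[:-1] * edges[1:])
        f = hist
        keep = f > 0
        s, f = s[keep], f[keep]
    else:
        s = np.asarray(s_or_samples, dtype=float)
        f = np.asarray(density, dtype=float)
    if s.size < 10:
        raise ContractError("need at least 10 positive support points")
    lo = s.min() + tail_fraction * (s.max() - s.min())
    hi = s.max() - tail_fraction * (s.max() - s.min())
    mask = (s >= lo) & (s <= hi)
    s, f = s[mask], f[mask]
    if np.any(f <= 0):
        raise ModelError("nonpositive density values inside the fit range")
    fit = linregress(np.log(s), np.log(f))
    return float(fit.slope), float(fit.stderr)


def drift_from_density(f, D: float, s=None) -> np.ndarray:
    """Invert the stationary condition: A(s) = D f'(s) / f(s).

    ``f`` may be a :class:`DensityEstimate` or an array (then ``s`` is
    required).  Central differences on the grid.
    """
    if isinstance(f, DensityEstimate):
        s = f.s_values
        f = f.density
    s = np.asarray(s, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ContractError("density must be strictly positive to invert the drift")
    return D * np.gradient(f, s) / f


def simulate(
    model: EvolutionModel,
    n_walkers: int = 100_000,
    n_steps: int = 10_000,
    dt: float = 1e-4,
    seed: int = 0,
    s_min: float | None = None,
) -> np.ndarray:
    """Euler-Maruyama simulation with reflecting boundaries at s_min and 1.

    Each step: s <- s + A(s) dt + sqrt(2 D dt) xi.  Walkers start uniform on
    [s_min, 1]; the final positions are returned.  Raises a step-size error
    when the deterministic step exceeds the domain width.
    """
    s_min = float(model.grid[0]) if s_min is None else float(s_min)
    width = 1.0 - s_min
    if width <= 0:
        raise ContractError("s_min must be below 1")
    rng = np.random.default_rng(seed)
    s = rng.uniform(s_min, 1.0, size=n_walkers)
    sigma = np.sqrt(2.0 * model.D * dt)
    max_drift = np.max(np.abs(np.asarray(model.drift(np.array([s_min, 1.0])), dtype=float)))
    if max_drift * dt >= width:
        raise ModelError(
            f"divergent step: |A| dt = {max_drift * dt:.3g} exceeds the domain width {width:.3g}"
        )
    for _ in range(n_steps):
        s = s + np.asarray(model.drift(s), dtype=float) * dt + sigma * rng.standard_normal(n_walkers)
        # reflect into [s_min, 1] (at most a few folds per step)
        while True:
            below = s < s_min
            above = s > 1.0
            if not (below.any() or above.any()):
                break
            s = np.where(below, 2.0 * s_min - s, s)
            s = np.where(above, 2.0 - s, s)
    return s
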