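"""Sigma-profile representation and self-consistent sigma-potentials.

The sigma-profile p(sigma) of a compound is the histogram of its COSMO
screening-charge density over the molecular surface.  The sigma-potential
mu_S(sigma) of a liquid S is the affinity of that phase for surface of
polarity sigma and follows from the segment self-consistency equation

    ln G_S(sigma_m) = -ln sum_n p_S(sigma_n) G_S(sigma_n)
                          exp(-dW(sigma_m, sigma_n) / RT)

with the exchange energy

    dW(m, n) = (alpha'/2) (sigma_m + sigma_n)^2
               + c_hb * max(0, sigma_acc - sigma_hb)
                      * min(0, sigma_don + sigma_hb)

(sigma_acc = max(m, n), sigma_don = min(m, n)); the potential per unit
area is mu_S(sigma) = RT ln G_S(sigma) / a_eff.  The equation is solved
by damped fixed-point iteration.  Relative solute-solvent potentials,
the descriptor family used downstream, are the pointwise difference
mu_solute - mu_solvent at a common temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EngineConfig, R_KJ
from .systems import SolventSystem

SIGMA_MIN = -0.03
SIGMA_MAX = 0.03
SIGMA_STEP = 0.001
N_SIGMA = 61


class ConvergenceError(RuntimeError):
    """Raised when the segment fixed point fails to converge."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"sigma-potential fixed point did not converge in "
            f"{iterations} iterations (final residual {residual:.3e})"
        )


@dataclass(frozen=True)
class SigmaGrid:
    """Uniform grid of screening-charge densities, e/A^2."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two points")
        d = np.diff(v)
        if not np.all(d > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=0, atol=1e-12):
            raise ValueError("grid must be uniformly spaced")
        object.__setattr__(self, "values", v)

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def bounds(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, SigmaGrid) and np.array_equal(
            self.values, other.values
        )


def make_grid() -> SigmaGrid:
    """The canonical 61-point grid from -0.03 to +0.03 e/A^2, step 0.001."""
    return SigmaGrid(np.linspace(SIGMA_MIN, SIGMA_MAX, N_SIGMA))


@dataclass(frozen=True)
class SigmaProfile:
    """Surface-area histogram of one compound on a sigma grid.

    ``areas[i]`` is the surface area (A^2) with screening-charge density
    ``grid.values[i]``.
    """

    compound_id: str
    grid: SigmaGrid
    areas: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.areas, dtype=float)
        if a.shape != (len(self.grid),):
            raise ValueError("areas must match grid length")
        if np.any(a < 0):
            raise ValueError("negative surface area")
        object.__setattr__(self, "areas", a)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def p(self) -> np.ndarray:
        """Normalised probability over segments."""
        total = self.total_area
        if total <= 0:
            raise ValueError(f"profile {self.compound_id!r} has zero area")
        return self.areas / total


@dataclass(frozen=True)
class SigmaPotential:
    """Per-grid-point potential mu(sigma), kJ/(mol A^2), at temperature T."""

    grid: SigmaGrid
    mu: np.ndarray
    temperature: float
    source: str = "pure-compound"

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (len(self.grid),):
            raise ValueError("mu must match grid length")
        if not np.all(np.isfinite(mu)):
            raise ValueError("non-finite sigma-potential")
        object.__setattr__(self, "mu", mu)


@dataclass(frozen=True)
class RelativePotential:
    """Pointwise solute-minus-solvent sigma-potential, kJ/(mol A^2)."""

    grid: SigmaGrid
    delta_mu: np.ndarray
    solute_id: str
    system_id: str
    temperature: float

    def __post_init__(self) -> None:
        d = np.asarray(self.delta_mu, dtype=float)
        if d.shape != (len(self.grid),):
            raise ValueError("delta_mu must match grid length")
        object.__setattr__(self, "delta_mu", d)


def exchange_energy(grid: SigmaGrid, config: EngineConfig | None = None) -> np.ndarray:
    """Segment exchange-energy matrix dW(m, n) in kJ/mol."""
    cfg = config or EngineConfig()
    c = cfg.interactions
    s = grid.values
    sm = s[:, None]
    sn = s[None, :]
    misfit = 0.5 * c.alpha_prime * (sm + sn) ** 2
    s_acc = np.maximum(sm, sn)
    s_don = np.minimum(sm, sn)
    hb = c.c_hb * np.maximum(0.0, s_acc - c.sigma_hb) * np.minimum(
        0.0, s_don + c.sigma_hb
    )
    return misfit + hb


_KERNEL_CACHE: dict = {}


def _boltzmann_kernel(grid: SigmaGrid, T: float, config: EngineConfig) -> np.ndarray:
    """exp(-dW/RT), cached per (grid, T, constants)."""
    key = (grid.values.tobytes(), round(T, 9), config.interactions)
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = np.exp(
            -exchange_energy(grid, config) / (R_KJ * T)
        )
    return _KERNEL_CACHE[key]


def _solve_ln_gamma(
    p: np.ndarray,
    grid: SigmaGrid,
    T: float,
    config: EngineConfig,
    ln_gamma0: np.ndarray | None = None,
) -> np.ndarray:
    """Damped fixed-point solve of the segment self-consistency equation.

    Returns ln G(sigma) for the phase with segment probabilities ``p``.
    ``ln_gamma0`` warm-starts the iteration (e.g. from a nearby
    composition); the fixed point itself does not depend on it.
    """
    conv = config.convergence
    K = _boltzmann_kernel(grid, T, config)
    ln_gamma = np.zeros(len(grid)) if ln_gamma0 is None else ln_gamma0.copy()
    for it in range(conv.max_iter):
        ln_new = -np.log(K @ (p * np.exp(ln_gamma)))
        residual = float(np.max(np.abs(ln_new - ln_gamma)))
        ln_gamma = (1.0 - conv.damping) * ln_new + conv.damping * ln_gamma
        if residual < conv.tol:
            return ln_new
    raise ConvergenceError(residual, conv.max_iter)


def _mixed_p(
    profiles: list[SigmaProfile], mole_fractions: list[float]
) -> tuple[np.ndarray, SigmaGrid]:
    if not profiles:
        raise ValueError("empty profile list")
    x = np.asarray(mole_fractions, dtype=float)
    if x.shape != (len(profiles),):
        raise ValueError("one mole fraction per profile required")
    if np.any(x < 0) or not np.isclose(x.sum(), 1.0, atol=1e-8):
        raise ValueError("mole fractions must be nonnegative and sum to 1")
    grid = profiles[0].grid
    for pr in profiles[1:]:
        if pr.grid != grid:
            raise ValueError("all profiles must share one grid")
    areas = np.stack([pr.areas for pr in profiles])
    weighted = x @ areas
    total = weighted.sum()
    if total <= 0:
        raise ValueError("mixture has zero surface area")
    return weighted / total, grid


def sigma_potential(
    profiles: list[SigmaProfile],
    mole_fractions: list[float],
    T: float,
    config: EngineConfig | None = None,
) -> SigmaPotential:
    """Self-consistent sigma-potential of a liquid phase at ``T`` (K).

    For a multi-profile call the phase is the area-and-mole-fraction
    weighted combination of the component surfaces.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    cfg = config or EngineConfig()
    p, grid = _mixed_p(profiles, mole_fractions)
    ln_gamma = _solve_ln_gamma(p, grid, T, cfg)
    mu = R_KJ * T * ln_gamma / cfg.interactions.a_eff
    source = "pure-compound" if len(profiles) == 1 else "mixture"
    return SigmaPotential(grid, mu, T, source)


def mixture_potential(
    system: SolventSystem,
    profiles: dict[str, SigmaProfile],
    T: float,
    config: EngineConfig | None = None,
) -> SigmaPotential:
    """Sigma-potential of a (possibly multicomponent) solvent system.

    Default convention: mole-fraction-weighted linear combination of the
    pure-component sigma-potentials at ``T``, using the system's
    solute-free fractions.  With ``config.mix_profiles_not_potentials``
    the profiles are combined first and the self-consistency solved once.
    """
    cfg = config or EngineConfig()
    missing = [c for c in system.components if c not in profiles]
    if missing:
        raise KeyError(
            f"no sigma-profile for component(s) {', '.join(missing)} "
            f"of system {system.system_id!r}"
        )
    comps = [profiles[c] for c in system.components]
    if cfg.mix_profiles_not_potentials:
        pot = sigma_potential(comps, list(system.fractions), T, cfg)
        return SigmaPotential(pot.grid, pot.mu, T, "mixture")
    mu = np.zeros(len(comps[0].grid))
    for frac, prof in zip(system.fractions, comps):
        if frac == 0.0:
            continue
        mu = mu + frac * sigma_potential([prof], [1.0], T, cfg).mu
    return SigmaPotential(comps[0].grid, mu, T, "mixture")


def relative_potential(
    solute: SigmaPotential, solvent: SigmaPotential, solute_id: str = "",
    system_id: str = "",
) -> RelativePotential:
    """Pointwise solute-minus-solvent potential at a common temperature."""
    if solute.grid != solvent.grid:
        raise ValueError("potentials defined on different grids")
    if not np.isclose(solute.temperature, solvent.temperature):
        raise ValueError(
            f"temperature mismatch: solute at {solute.temperature} K, "
            f"solvent at {solvent.temperature} K"
        )
    return RelativePotential(
        solute.grid,
        solute.mu - solvent.mu,
        solute_id,
        system_id,
        solute.temperature,
    )


def ln_activity_coefficient(
    solute: SigmaProfile,
    solvent_profiles: list[SigmaProfile],
    solvent_fractions: list[float],
    x_solute: float,
    T: float,
    config: EngineConfig | None = None,
    ln_g_pure: np.ndarray | None = None,
    warm_start: np.ndarray | None = None,
) -> float:
    """Segment (residual) ln gamma of a solute in a solvent at ``x_solute``.

    ln gamma = (A_solute / a_eff) * sum_sigma p_solute(sigma)
               [ln G_mix(sigma) - ln G_solute(sigma)],
    where the mixture contains the solute at mole fraction ``x_solute``
    and the solvent components at (1 - x_solute) times their solute-free
    fractions.  The Staverman-Guggenheim combinatorial part is omitted;
    see the methods note.
    """
    cfg = config or EngineConfig()
    x = np.asarray(solvent_fractions, dtype=float)
    x = x / x.sum()
    all_profiles = [solute] + list(solvent_profiles)
    all_x = [x_solute] + list((1.0 - x_solute) * x)
    p_mix, grid = _mixed_p(all_profiles, all_x)
    ln_g_mix = _solve_ln_gamma(p_mix, grid, T, cfg, ln_gamma0=warm_start)
    if ln_g_pure is None:
        ln_g_pure = _solve_ln_gamma(solute.p, grid, T, cfg)
    if warm_start is not None:
        warm_start[:] = ln_g_mix
    return float(
        solute.total_area
        / cfg.interactions.a_eff
        * np.sum(solute.p * (ln_g_mix - ln_g_pure))
    )
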