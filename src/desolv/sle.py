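"""Solid-liquid equilibrium solubility from fusion data.

Saturation of a crystalline solute in a liquid satisfies

    ln(x_sat * gamma(x_sat, T)) = ln x_ideal(T)

where the ideal solubility follows the Schroeder-van Laar form

    ln x_ideal = -(dH_m / R) (1/T - 1/T_m)
                 [+ (dCp/R) (T_m/T - 1 - ln(T_m/T)) when dCp is known].

The saturation mole fraction is obtained by a bracketed root solve on
(0, 1] rather than successive substitution, which oscillates or
diverges for highly soluble solutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from scipy.optimize import brentq

from .config import R_J

#: gamma(x, T) -> activity coefficient of the solute at mole fraction x.
ActivityModel = Callable[[float, float], float]


@dataclass(frozen=True)
class FusionData:
    """Melting temperature (K), fusion enthalpy (kJ/mol), optional dCp."""

    compound_id: str
    T_m: float
    dH_m: float
    dCp: float | None = None

    def __post_init__(self) -> None:
        if self.T_m <= 0:
            raise ValueError("melting temperature must be positive")
        if self.dH_m <= 0:
            raise ValueError("fusion enthalpy must be positive")


#: Literature mean fusion data for the study compounds.
FUSION_TABLE: dict[str, FusionData] = {
    "ibuprofen": FusionData("ibuprofen", 348.64, 26.69),
    "dexibuprofen": FusionData("dexibuprofen", 348.64, 26.69),
    "ketoprofen": FusionData("ketoprofen", 367.99, 25.52),
    "flurbiprofen": FusionData("flurbiprofen", 387.34, 27.86),
}


@dataclass(frozen=True)
class SaturationResult:
    """Outcome of an SLE solve."""

    x_sat: float
    gamma_at_sat: float
    converged: bool
    residual: float


def ideal_solubility(fusion: FusionData, T: float) -> float:
    """Ideal (gamma = 1) saturation mole fraction at ``T`` kelvin.

    Equals 1 at and above the melting point; strictly increasing in T.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if T >= fusion.T_m:
        return 1.0
    ln_x = -(fusion.dH_m * 1e3 / R_J) * (1.0 / T - 1.0 / fusion.T_m)
    if fusion.dCp is not None:
        ln_x += (fusion.dCp * 1e3 / R_J) * (
            fusion.T_m / T - 1.0 - math.log(fusion.T_m / T)
        )
    return min(math.exp(ln_x), 1.0)


def solve_sle(
    fusion: FusionData,
    activity: ActivityModel,
    T: float,
    x_min: float = 1e-300,
    tol: float = 1e-8,
) -> SaturationResult:
    """Saturation mole fraction by bracketed root solve on (0, 1].

    Finds x with ln x + ln gamma(x, T) = ln x_ideal(T) using Brent's
    method between ``x_min`` and 1.  Returns a non-converged result with
    diagnostics when the residual has no sign change on the bracket.
    """
    ln_x_ideal = math.log(ideal_solubility(fusion, T))

    def f(t: float) -> float:
        # residual in t = ln x; roots of t + ln gamma - ln x_ideal
        g = activity(math.exp(t), T)
        if not math.isfinite(g) or g <= 0:
            raise ValueError(
                f"activity model returned non-positive gamma at x={math.exp(t)}"
            )
        return t + math.log(g) - ln_x_ideal

    f_one = f(0.0)
    if f_one <= 0:
        # saturated liquid is the pure melt: x_sat = 1
        return SaturationResult(1.0, activity(1.0, T), True, abs(f_one))
    # dilute-limit estimate x0 = x_ideal / gamma_inf seeds the bracket;
    # ln x -> -inf ensures a sign change exists unless gamma blows up
    t_floor = math.log(x_min)
    gamma_inf = activity(max(x_min, 1e-12), T)
    t0 = min(ln_x_ideal - math.log(gamma_inf), -1e-8)
    lo = hi = t0
    f0 = f(t0)
    step = 1.0
    if f0 > 0:
        f_lo = f0
        while f_lo > 0:
            lo -= step
            step *= 2.0
            if lo < t_floor:
                return SaturationResult(math.nan, math.nan, False, f_lo)
            f_lo = f(lo)
    else:
        f_hi = f0
        while f_hi <= 0 and hi < 0.0:
            hi = min(hi + step, 0.0)
            step *= 2.0
            f_hi = f(hi)
    t_sat = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    x_sat = math.exp(t_sat)
    residual = abs(f(t_sat))
    return SaturationResult(x_sat, activity(x_sat, T), residual < tol, residual)


def ideal_activity(x: float, T: float) -> float:
    """gamma = 1 for all compositions; for testing and the ideal model."""
    return 1.0


def constant_activity(c: float) -> ActivityModel:
    """Composition-independent activity coefficient gamma = c."""
    if c <= 0:
        raise ValueError("gamma must be positive")
    return lambda x, T: c


def cosmo_activity(
    solute_profile,
    system,
    profiles: dict,
    config=None,
) -> ActivityModel:
    """COSMO-RS-style activity model from the sigma engine.

    gamma(x, T) from the solute's segment chemical potential in the
    saturated mixture minus in its own pure liquid.
    """
    import numpy as np

    from .sigma import _solve_ln_gamma, ln_activity_coefficient

    solvent_profiles = [profiles[c] for c in system.components]
    fractions = list(system.fractions)
    pure_cache: dict[float, object] = {}
    warm = {"start": None}

    def gamma(x: float, T: float) -> float:
        if T not in pure_cache:
            from .config import EngineConfig

            cfg = config or EngineConfig()
            pure_cache[T] = _solve_ln_gamma(
                solute_profile.p, solute_profile.grid, T, cfg
            )
            warm["start"] = np.zeros(len(solute_profile.grid))
        ln_g = ln_activity_coefficient(
            solute_profile,
            solvent_profiles,
            fractions,
            x,
            T,
            config,
            ln_g_pure=pure_cache[T],
            warm_start=warm["start"],
        )
        return math.exp(ln_g)

    return gamma
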