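"""Wet-lab data reduction for shake-flask solubility measurements.

Covers UV calibration (OLS line, R2, ICH 3.3*sigma and 10*sigma
detection/quantification limits), conversion of a measured absorbance
to a saturation mole fraction via the sample density, triplicate
aggregation, and classification of DES-water cosolvency curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import molar_mass
from .records import SolubilityRecord
from .systems import SolventSystem, enumerate_des_grid  # noqa: F401 (re-export)

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear UV calibration A = slope * C + intercept, C in mg/mL."""

    slope: float
    intercept: float
    r2: float
    lod: float
    loq: float
    n_levels: int
    residual_sd: float

    def concentration(self, absorbance: float, dilution: float = 1.0) -> float:
        """Invert the line: mg/mL in the undiluted sample."""
        return dilution * (absorbance - self.intercept) / self.slope


def fit_calibration(levels: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """OLS fit of absorbance on concentration with ICH limits.

    LOD = 3.3 s / slope and LOQ = 10 s / slope where s is the residual
    standard deviation of the fit (n - 2 degrees of freedom), so
    LOQ / LOD = 10 / 3.3 by construction.
    """
    if len(levels) < 3:
        raise ValueError("at least 3 calibration levels required")
    conc = np.array([c for c, _ in levels], dtype=float)
    absb = np.array([a for _, a in levels], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("calibration levels have zero concentration range")
    fit = stats.linregress(conc, absb)
    resid = absb - (fit.slope * conc + fit.intercept)
    s = float(np.sqrt(np.sum(resid**2) / (len(conc) - 2)))
    r2 = float(fit.rvalue**2)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        lod=LOD_FACTOR * s / fit.slope,
        loq=LOQ_FACTOR * s / fit.slope,
        n_levels=len(conc),
        residual_sd=s,
    )


def absorbance_to_mole_fraction(
    absorbance: float,
    curve: CalibrationCurve,
    dilution: float,
    density_g_mL: float,
    system: SolventSystem,
    molar_masses: dict[str, float] | None = None,
) -> float:
    """Saturation mole fraction from a diluted-sample absorbance.

    The solute concentration C (mg per mL of saturated solution) comes
    from the calibration line and the dilution factor; 1 mL of solution
    weighs 1000*density mg, of which C mg are solute; the remaining
    solvent mass is apportioned into moles by the system's solute-free
    composition.
    """
    if density_g_mL <= 0:
        raise ValueError("density must be positive")
    conc = curve.concentration(absorbance, dilution)
    if conc <= 0:
        raise ValueError(
            f"absorbance {absorbance} at or below the intercept: "
            "nonpositive concentration"
        )
    return concentration_to_mole_fraction(conc, density_g_mL, system, molar_masses)


def concentration_to_mole_fraction(
    conc_mg_mL: float,
    density_g_mL: float,
    system: SolventSystem,
    molar_masses: dict[str, float] | None = None,
    solute_mw: float | None = None,
) -> float:
    """Mole fraction from mg/mL of solute in the saturated solution."""
    mm = molar_masses or {}

    def mw(cid: str) -> float:
        return mm[cid] if cid in mm else molar_mass(cid)

    if solute_mw is None:
        if "solute" not in mm:
            raise KeyError("provide the solute molar mass as molar_masses['solute']")
        solute_mw = mm["solute"]
    n_solute = conc_mg_mL / solute_mw  # mmol per mL of solution
    solvent_mass = 1000.0 * density_g_mL - conc_mg_mL  # mg per mL
    if solvent_mass <= 0:
        raise ValueError(
            "solute concentration exceeds the sample mass implied by density"
        )
    # mean molar mass of the solute-free solvent
    mean_mw = sum(f * mw(c) for c, f in zip(system.components, system.fractions))
    n_solvent = solvent_mass / mean_mw  # mmol per mL
    return n_solute / (n_solute + n_solvent)


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (ddof=1); SD is 0 for one value."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("at least one replicate required")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd


@dataclass(frozen=True)
class CosolvencyResult:
    x_star_opt: float
    classification: str  # "apparent cosolvency" | "none"
    x_max: float
    x_neat: float


def cosolvency_analysis(
    series: Sequence[tuple[float, float]]
) -> CosolvencyResult:
    """Locate the optimal DES-water composition on the measured grid.

    ``series`` is (x*_DES, solubility) pairs including the neat DES
    point x*_DES = 1.  Classified as "apparent cosolvency" when the
    maximum strictly exceeds the neat-DES solubility; ties (flat
    series) resolve toward x*_DES = 1 and classify as "none".
    """
    if len(series) < 3:
        raise ValueError("at least 3 compositions required")
    comps = [c for c, _ in series]
    if len(set(comps)) != len(comps):
        raise ValueError("duplicate compositions in cosolvency series")
    if not any(math.isclose(c, 1.0) for c in comps):
        raise ValueError("series must include the neat DES point x*_DES = 1")
    x_neat = next(x for c, x in series if math.isclose(c, 1.0))
    # argmax; ties broken toward the largest composition (neat DES)
    best_c, best_x = max(series, key=lambda p: (p[1], p[0]))
    classification = "apparent cosolvency" if best_x > x_neat else "none"
    return CosolvencyResult(best_c, classification, best_x, x_neat)


def reduce_raw_measurements(
    raw: Sequence[dict],
    curve: CalibrationCurve,
    systems: dict[str, SolventSystem],
    solute: str,
    solute_mw: float | None = None,
) -> list[SolubilityRecord]:
    """Triplicate raw absorbance rows -> averaged SolubilityRecords.

    ``raw`` rows carry sample_id, system_id, T_K, absorbance, dilution,
    density_g_mL; rows sharing (system_id, T_K) are replicates.
    """
    mw = solute_mw if solute_mw is not None else molar_mass(solute)
    groups: dict[tuple[str, float], list[float]] = {}
    for row in raw:
        x = absorbance_to_mole_fraction(
            row["absorbance"],
            curve,
            row["dilution"],
            row["density_g_mL"],
            systems[row["system_id"]],
            molar_masses={"solute": mw},
        )
        groups.setdefault((row["system_id"], row["T_K"]), []).append(x)
    out = []
    for (system_id, T), xs in groups.items():
        mean, sd = aggregate_replicates(xs)
        out.append(
            SolubilityRecord(
                f"{solute}@{system_id}@{T:g}K",
                solute,
                systems[system_id],
                T,
                mean,
                sd,
                len(xs),
            )
        )
    return out
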