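"""Descriptor assembly and R2-threshold sigma-point selection.

Each solubility record is featurised as (i) the log10 saturation mole
fraction computed by fully solving the SLE with the sigma-engine
activity model, (ii) the temperature, and (iii) the relative
solute-solvent sigma-potential at a selected subset of grid points.

The subset is chosen by regressing log10 experimental solubility on the
relative potential at every sigma point, separately for the non-DES and
the DES records, and keeping the points whose univariate R2 exceeds a
threshold (default 0.4) in either subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EngineConfig
from .records import SolubilityRecord
from .sigma import (
    RelativePotential,
    SigmaProfile,
    make_grid,
    mixture_potential,
    relative_potential,
    sigma_potential,
)
from .sle import FusionData, cosmo_activity, solve_sle
from .systems import SolventSystem

R2_THRESHOLD = 0.4


class DescriptorEngine:
    """Caches sigma-potentials and SLE solves for a compound/profile store."""

    def __init__(
        self,
        profiles: dict[str, SigmaProfile],
        fusion: dict[str, FusionData],
        config: EngineConfig | None = None,
    ):
        self.profiles = profiles
        self.fusion = fusion
        self.config = config or EngineConfig()
        self._pure_cache: dict[tuple[str, float], object] = {}
        self._mix_cache: dict[tuple[str, float], object] = {}
        self._sle_cache: dict[tuple[str, str, float], float] = {}

    def pure_potential(self, compound_id: str, T: float):
        key = (compound_id, T)
        if key not in self._pure_cache:
            if compound_id not in self.profiles:
                raise KeyError(f"no sigma-profile for compound {compound_id!r}")
            self._pure_cache[key] = sigma_potential(
                [self.profiles[compound_id]], [1.0], T, self.config
            )
        return self._pure_cache[key]

    def solvent_potential(self, system: SolventSystem, T: float):
        key = (system.system_id, T)
        if key not in self._mix_cache:
            self._mix_cache[key] = mixture_potential(
                system, self.profiles, T, self.config
            )
        return self._mix_cache[key]

    def relative_potential(
        self, solute: str, system: SolventSystem, T: float
    ) -> RelativePotential:
        return relative_potential(
            self.pure_potential(solute, T),
            self.solvent_potential(system, T),
            solute,
            system.system_id,
        )

    def log10_x_computed(
        self, solute: str, system: SolventSystem, T: float
    ) -> float:
        """log10 saturation mole fraction from the full SLE solve."""
        key = (solute, system.system_id, T)
        if key not in self._sle_cache:
            if solute not in self.fusion:
                raise KeyError(
                    f"no fusion data for solute {solute!r}; SLE solubility "
                    "requires melting temperature and fusion enthalpy"
                )
            gamma = cosmo_activity(
                self.profiles[solute], system, self.profiles, self.config
            )
            res = solve_sle(self.fusion[solute], gamma, T)
            if not res.converged or not res.x_sat > 0:
                raise RuntimeError(
                    f"SLE solve failed for {solute} in {system.system_id} "
                    f"at {T} K (residual {res.residual:.3e})"
                )
            self._sle_cache[key] = math.log10(res.x_sat)
        return self._sle_cache[key]


@dataclass(frozen=True)
class SelectionReport:
    """Per-sigma R2 profiles for both subsets and the selected indices."""

    sigma: np.ndarray
    r2_non_des: np.ndarray
    r2_des: np.ndarray
    selected_indices: tuple[int, ...]
    threshold: float = R2_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        sel = np.zeros(len(self.sigma), dtype=bool)
        sel[list(self.selected_indices)] = True
        return pd.DataFrame(
            {
                "sigma": self.sigma,
                "r2_nonDES": self.r2_non_des,
                "r2_DES": self.r2_des,
                "selected": sel,
            }
        )


def _univariate_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R2 of a simple linear regression of y on x; 0 for a constant x."""
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def r2_profile(
    records: list[SolubilityRecord],
    relpots: dict[str, RelativePotential] | np.ndarray,
    log_scale: bool = True,
) -> np.ndarray:
    """Per-sigma-point R2 of log10 solubility against the relative potential.

    ``relpots`` maps record_id to that record's RelativePotential (or is
    an (n_records, n_sigma) array in record order).
    """
    if len(records) < 3:
        raise ValueError("at least 3 records required for an R2 profile")
    if isinstance(relpots, np.ndarray):
        dmu = np.asarray(relpots, dtype=float)
    else:
        dmu = np.stack([relpots[r.record_id].delta_mu for r in records])
    if dmu.shape[0] != len(records):
        raise ValueError("one relative potential per record required")
    y = np.array(
        [math.log10(r.x_exp) if log_scale else r.x_exp for r in records]
    )
    return np.array([_univariate_r2(dmu[:, j], y) for j in range(dmu.shape[1])])


def select_sigma_points(
    r2_non_des: np.ndarray,
    r2_des: np.ndarray,
    threshold: float = R2_THRESHOLD,
    sigma: np.ndarray | None = None,
) -> SelectionReport:
    """Keep sigma points with R2 strictly above the threshold in either subset."""
    r2_non_des = np.asarray(r2_non_des, dtype=float)
    r2_des = np.asarray(r2_des, dtype=float)
    if r2_non_des.shape != r2_des.shape:
        raise ValueError("subset R2 profiles must share the grid")
    if sigma is None:
        sigma = make_grid().values
    selected = np.flatnonzero((r2_non_des > threshold) | (r2_des > threshold))
    return SelectionReport(
        np.asarray(sigma, dtype=float),
        r2_non_des,
        r2_des,
        tuple(int(i) for i in selected),
        threshold,
    )


def sigma_feature_names(selection: SelectionReport) -> list[str]:
    return [
        f"dmu_{selection.sigma[i]:+.3f}" for i in selection.selected_indices
    ]


def build_feature_table(
    records: list[SolubilityRecord],
    engine: DescriptorEngine,
    selection: SelectionReport,
) -> pd.DataFrame:
    """One descriptor row per record, deterministic column order.

    Columns: ``log10_x_computed``, ``T_K``, then the relative-potential
    values at the selected sigma points; the index is the record_id.
    """
    idx = list(selection.selected_indices)
    names = sigma_feature_names(selection)
    rows = []
    for rec in records:
        dmu = engine.relative_potential(rec.solute, rec.system, rec.T).delta_mu
        row = {
            "log10_x_computed": engine.log10_x_computed(
                rec.solute, rec.system, rec.T
            ),
            "T_K": rec.T,
        }
        row.update({name: dmu[i] for name, i in zip(names, idx)})
        rows.append(row)
    table = pd.DataFrame(
        rows,
        index=pd.Index([r.record_id for r in records], name="record_id"),
        columns=["log10_x_computed", "T_K", *names],
    )
    if table.isna().any().any():
        raise ValueError("missing values in feature table")
    return table


def target_vector(records: list[SolubilityRecord]) -> pd.Series:
    """log10 experimental mole-fraction solubility, indexed by record_id."""
    return pd.Series(
        [math.log10(r.x_exp) for r in records],
        index=pd.Index([r.record_id for r in records], name="record_id"),
        name="log10_x_exp",
    )
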