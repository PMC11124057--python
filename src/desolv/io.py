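"""CSV readers and writers for the pipeline's file formats.

Formats (all plain CSV):
  profiles/<compound>.csv : sigma,area           (e/A^2, A^2)
  fusion.csv              : compound_id,Tm_K,dHm_kJ_mol[,dCp_kJ_molK]
  systems.csv             : system_id,components,fractions,is_DES,hba,hbd,ratio,x_star_DES
  records.csv             : record_id,solute,system_id,is_DES,T_K,x_exp,sd
  calibration.csv         : conc_mg_mL,absorbance
  selection.csv           : sigma,r2_nonDES,r2_DES,selected
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .features import SelectionReport
from .records import SolubilityRecord
from .sigma import SigmaProfile, make_grid
from .sle import FusionData
from .systems import SolventSystem


# -- sigma-profiles ---------------------------------------------------------

def write_profile(profile: SigmaProfile, path: str | Path) -> None:
    pd.DataFrame({"sigma": profile.grid.values, "area": profile.areas}).to_csv(
        path, index=False
    )


def read_profile(path: str | Path, compound_id: str | None = None) -> SigmaProfile:
    df = pd.read_csv(path)
    values = df["sigma"].to_numpy(dtype=float)
    canonical = make_grid()
    if values.shape != canonical.values.shape or not np.allclose(
        values, canonical.values, atol=1e-9, rtol=0
    ):
        raise ValueError(f"{path}: sigma grid is not the canonical 61-point grid")
    cid = compound_id or Path(path).stem
    # snap to the canonical grid so round-tripped profiles compare equal
    return SigmaProfile(cid, canonical, df["area"].to_numpy(dtype=float))


def write_profiles(profiles: dict[str, SigmaProfile], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cid, prof in profiles.items():
        write_profile(prof, directory / f"{cid}.csv")


def read_profiles(directory: str | Path) -> dict[str, SigmaProfile]:
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("*.csv")):
        out[path.stem] = read_profile(path)
    if not out:
        raise FileNotFoundError(f"no profile CSVs in {directory}")
    return out


# -- fusion data ------------------------------------------------------------

def write_fusion(fusion: dict[str, FusionData], path: str | Path) -> None:
    rows = [
        {
            "compound_id": f.compound_id,
            "Tm_K": f.T_m,
            "dHm_kJ_mol": f.dH_m,
            "dCp_kJ_molK": f.dCp if f.dCp is not None else "",
        }
        for f in fusion.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fusion(path: str | Path) -> dict[str, FusionData]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        dcp = row.get("dCp_kJ_molK")
        dcp = None if dcp is None or (isinstance(dcp, float) and math.isnan(dcp)) else float(dcp)
        out[row["compound_id"]] = FusionData(
            row["compound_id"], float(row["Tm_K"]), float(row["dHm_kJ_mol"]), dcp
        )
    return out


# -- solvent systems --------------------------------------------------------

def write_systems(systems: list[SolventSystem], path: str | Path) -> None:
    rows = [
        {
            "system_id": s.system_id,
            "components": ";".join(s.components),
            "fractions": ";".join(f"{f!r}" for f in s.fractions),
            "is_DES": s.is_des,
            "hba": s.hba or "",
            "hbd": s.hbd or "",
            "ratio": s.ratio if s.ratio is not None else "",
            "x_star_DES": s.x_star_des if s.x_star_des is not None else "",
        }
        for s in systems
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _opt_float(v) -> float | None:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_systems(path: str | Path) -> dict[str, SolventSystem]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        s = SolventSystem(
            row["system_id"],
            tuple(row["components"].split(";")),
            tuple(float(f) for f in str(row["fractions"]).split(";")),
            bool(row["is_DES"]),
            hba=row["hba"] if isinstance(row["hba"], str) and row["hba"] else None,
            hbd=row["hbd"] if isinstance(row["hbd"], str) and row["hbd"] else None,
            ratio=_opt_float(row.get("ratio")),
            x_star_des=_opt_float(row.get("x_star_DES")),
        )
        out[s.system_id] = s
    return out


# -- solubility records -----------------------------------------------------

def write_records(records: list[SolubilityRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "solute": r.solute,
            "system_id": r.system.system_id,
            "is_DES": r.is_des,
            "T_K": r.T,
            "x_exp": r.x_exp,
            "sd": r.sd,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records(
    path: str | Path, systems: dict[str, SolventSystem]
) -> list[SolubilityRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            SolubilityRecord(
                str(row["record_id"]),
                row["solute"],
                systems[row["system_id"]],
                float(row["T_K"]),
                float(row["x_exp"]),
                float(row.get("sd", 0.0) or 0.0),
            )
        )
    return out


# -- calibration series and selection reports ------------------------------

def write_calibration(levels: list[tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(levels, columns=["conc_mg_mL", "absorbance"]).to_csv(
        path, index=False
    )


def read_calibration(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return list(zip(df["conc_mg_mL"].astype(float), df["absorbance"].astype(float)))


def write_selection(report: SelectionReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, index=False)


def read_selection(path: str | Path) -> SelectionReport:
    df = pd.read_csv(path)
    selected = tuple(int(i) for i in np.flatnonzero(df["selected"].to_numpy()))
    return SelectionReport(
        df["sigma"].to_numpy(),
        df["r2_nonDES"].to_numpy(),
        df["r2_DES"].to_numpy(),
        selected,
    )
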