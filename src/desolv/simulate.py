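"""Synthetic study data: profiles, fusion data, solubility surfaces.

The real solubility dataset behind this kind of study is typically not
deposited, so every pipeline stage here is exercised on synthetic data
with known ground truth.  The generator emulates:

* sigma-profiles as mixtures of Gaussians on the canonical grid —
  apolar drug-like solutes (most surface near sigma = 0 plus a small
  carboxylic donor/acceptor pair), HBD-rich polyols (donor surface at
  negative sigma), HBA salts (acceptor-heavy) and water;
* fusion data in the range of small-molecule drugs;
* a solubility surface that is a known function of the ideal
  solubility plus a linear-and-mildly-quadratic map of relative
  sigma-potentials at planted grid indices, with Gaussian noise in dex;
* linear UV calibration series with Gaussian absorbance noise;
* unimodal DES-water cosolvency curves with a controllable peak.

Every generator is a pure function of its seed and config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EngineConfig
from .features import DescriptorEngine
from .records import SolubilityRecord
from .sigma import SigmaProfile, make_grid
from .sle import FusionData, ideal_solubility
from .systems import HBA_IDS, HBD_IDS, SolventSystem


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic dataset."""

    seed: int = 0
    n_records: int = 600
    n_solutes: int = 6
    noise_sd_dex: float = 0.1
    planted_sigma_indices: tuple[int, ...] = (16, 44)
    effect_sizes_dex: tuple[float, ...] = (0.6, -0.6)
    quadratic_dex: float = 0.15
    cosolvency_peak: float = 0.9
    calib_noise_sd: float = 0.002
    temperatures: tuple[float, ...] = (298.15, 303.15, 308.15, 313.15)
    #: global offset of the synthetic surface in dex (keeps the noisy
    #: observations well below x = 1, like real sub-saturation data)
    baseline_dex: float = -1.5
    #: fraction of records drawn from conventional (non-DES) solvents
    non_des_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd_dex < 0 or self.calib_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if len(self.planted_sigma_indices) != len(self.effect_sizes_dex):
            raise ValueError("one effect size per planted index required")
        if any(not 0 <= i < 61 for i in self.planted_sigma_indices):
            raise ValueError("planted indices must lie on the 61-point grid")


# ---------------------------------------------------------------------------
# sigma-profiles
# ---------------------------------------------------------------------------


def _gauss_profile(
    grid_values: np.ndarray,
    peaks: list[tuple[float, float, float]],
    total_area: float,
) -> np.ndarray:
    """Mixture of Gaussians (centre, width, weight) scaled to total_area."""
    dens = np.zeros_like(grid_values)
    for centre, width, weight in peaks:
        dens += weight * np.exp(-0.5 * ((grid_values - centre) / width) ** 2)
    dens = np.clip(dens, 0.0, None)
    return dens / dens.sum() * total_area


def gen_sigma_profiles(config: GeneratorConfig) -> dict[str, SigmaProfile]:
    """Archetype profiles for solutes, DES components, water and organics."""
    rng = np.random.default_rng(config.seed)
    grid = make_grid()
    g = grid.values
    profiles: dict[str, SigmaProfile] = {}

    def add(name: str, peaks, total):
        profiles[name] = SigmaProfile(name, grid, _gauss_profile(g, peaks, total))

    # drug-like apolar solutes: bulk near sigma=0, small COOH donor/acceptor.
    # The solutes emulate a close analog family: nearly identical surface
    # polarity (shared scaffold) but distinct fusion data, as for the
    # profen analogs, so lattice effects are not readable off the profile.
    for i in range(config.n_solutes):
        centre = rng.normal(0.0, 0.0001)
        donor = 0.014 + rng.normal(0.0, 0.0002)
        area = rng.uniform(270.0, 290.0)
        add(
            f"solute{i}",
            [
                (centre, 0.0020, 0.86),
                (-donor, 0.0015, 0.08 + 0.004 * rng.uniform()),
                (+donor * 0.9, 0.0015, 0.06 + 0.003 * rng.uniform()),
            ],
            area,
        )

    # HBAs: acceptor-heavy (screening charge of the anion), some donor OH
    add("ChCl", [(0.0, 0.002, 0.45), (0.017, 0.003, 0.38), (-0.012, 0.002, 0.17)], 220.0)
    add("BI", [(0.0, 0.002, 0.50), (0.015, 0.003, 0.33), (-0.011, 0.002, 0.17)], 200.0)
    # polyols: alkyl backbone + hydroxyl donor (negative sigma) and acceptor
    polyol_donor = {
        "ETG": 0.013, "DEG": 0.0125, "TEG": 0.012,
        "GLY": 0.014, "P2D": 0.0125, "B3D": 0.012,
    }
    polyol_area = {
        "ETG": 120.0, "DEG": 180.0, "TEG": 240.0,
        "GLY": 140.0, "P2D": 140.0, "B3D": 160.0,
    }
    for name in HBD_IDS:
        d = polyol_donor[name]
        add(
            name,
            [(0.0, 0.0025, 0.55), (-d, 0.0018, 0.25), (d * 0.85, 0.0018, 0.20)],
            polyol_area[name],
        )
    add("water", [(-0.016, 0.0022, 0.40), (0.016, 0.0022, 0.40), (0.0, 0.003, 0.20)], 110.0)
    # conventional organic solvents for the non-DES subset
    add("alcohol", [(0.0, 0.0025, 0.70), (-0.013, 0.0018, 0.15), (0.012, 0.0018, 0.15)], 150.0)
    add("apolar_org", [(0.0, 0.0018, 0.97), (-0.006, 0.002, 0.03)], 180.0)
    add("ketone", [(0.0, 0.002, 0.80), (0.013, 0.002, 0.20)], 160.0)
    return profiles


def gen_fusion_data(config: GeneratorConfig) -> dict[str, FusionData]:
    """Drug-like melting data: T_m in 330-400 K, dH_m in 20-30 kJ/mol."""
    rng = np.random.default_rng(config.seed + 1)
    out = {}
    for i in range(config.n_solutes):
        name = f"solute{i}"
        out[name] = FusionData(
            name,
            T_m=float(rng.uniform(330.0, 400.0)),
            dH_m=float(rng.uniform(20.0, 30.0)),
        )
    return out


# ---------------------------------------------------------------------------
# solvent systems
# ---------------------------------------------------------------------------


def gen_systems(config: GeneratorConfig) -> list[SolventSystem]:
    """DES-water ternaries plus neat and binary conventional solvents."""
    systems: list[SolventSystem] = []
    for hba in HBA_IDS:
        for hbd in HBD_IDS:
            for ratio in (1.0, 2.0):
                for x_star in (0.6, 0.8, 0.9, 1.0):
                    systems.append(SolventSystem.des(hba, hbd, ratio, x_star))
    for neat in ("water", "alcohol", "apolar_org", "ketone"):
        systems.append(SolventSystem.neat(neat))
    for x in (0.25, 0.5, 0.75):
        systems.append(SolventSystem.binary("alcohol", "water", x))
        systems.append(SolventSystem.binary("ketone", "water", x))
    return systems


# ---------------------------------------------------------------------------
# solubility surface with planted structure
# ---------------------------------------------------------------------------


def gen_solubility_dataset(
    config: GeneratorConfig,
    profiles: dict[str, SigmaProfile] | None = None,
    fusion: dict[str, FusionData] | None = None,
    engine_config: EngineConfig | None = None,
) -> tuple[list[SolubilityRecord], pd.DataFrame]:
    """Records with known ground truth.

    log10 x = log10 x_ideal(T) + sum_i beta_i * z_i + q * (z_0^2 - 1)
              + N(0, noise_sd_dex),
    where z_i is the relative sigma-potential at planted index i,
    standardised by its population SD over the dataset so that the
    betas are in dex.  The truth table (noise-free surface) is returned
    alongside the records.
    """
    rng = np.random.default_rng(config.seed + 2)
    profiles = profiles if profiles is not None else gen_sigma_profiles(config)
    fusion = fusion if fusion is not None else gen_fusion_data(config)
    systems = gen_systems(config)
    engine = DescriptorEngine(profiles, fusion, engine_config)

    solutes = sorted(fusion)
    n = config.n_records
    des_pool = [i for i, s in enumerate(systems) if s.is_des]
    non_des_pool = [i for i, s in enumerate(systems) if not s.is_des]
    choice_solute = rng.integers(0, len(solutes), size=n)
    pick_non_des = rng.uniform(size=n) < config.non_des_fraction
    choice_system = np.where(
        pick_non_des,
        rng.choice(non_des_pool, size=n),
        rng.choice(des_pool, size=n),
    )
    choice_T = rng.integers(0, len(config.temperatures), size=n)

    idx = list(config.planted_sigma_indices)
    dmu = np.zeros((n, len(idx)))
    log_ideal = np.zeros(n)
    for k in range(n):
        solute = solutes[choice_solute[k]]
        system = systems[choice_system[k]]
        T = config.temperatures[choice_T[k]]
        dmu[k] = engine.relative_potential(solute, system, T).delta_mu[idx]
        log_ideal[k] = math.log10(ideal_solubility(fusion[solute], T))

    scale = dmu.std(axis=0)
    scale[scale == 0] = 1.0
    z = (dmu - dmu.mean(axis=0)) / scale
    beta = np.asarray(config.effect_sizes_dex)
    truth_log10 = config.baseline_dex + log_ideal + z @ beta
    if len(idx):
        truth_log10 = truth_log10 + config.quadratic_dex * (z[:, 0] ** 2 - 1.0)
    noise = rng.normal(0.0, config.noise_sd_dex, size=n)
    obs_log10 = np.minimum(truth_log10 + noise, 0.0)

    records, rows = [], []
    for k in range(n):
        solute = solutes[choice_solute[k]]
        system = systems[choice_system[k]]
        T = config.temperatures[choice_T[k]]
        rec_id = f"r{k:04d}"
        records.append(
            SolubilityRecord(rec_id, solute, system, T, 10.0 ** obs_log10[k])
        )
        rows.append(
            {
                "record_id": rec_id,
                "solute": solute,
                "system_id": system.system_id,
                "is_DES": system.is_des,
                "T_K": T,
                "log10_x_truth": truth_log10[k],
                "log10_x_obs": obs_log10[k],
                "log10_x_ideal": log_ideal[k],
            }
        )
    return records, pd.DataFrame(rows).set_index("record_id")


# ---------------------------------------------------------------------------
# decorrelated planted features (selection-rule stress test)
# ---------------------------------------------------------------------------


def gen_planted_features(
    config: GeneratorConfig,
    n_sigma: int = 61,
    target_r2: float = 0.7,
) -> tuple[list[SolubilityRecord], np.ndarray]:
    """Per-sigma features i.i.d. except a shared factor at planted indices.

    Physically derived relative potentials are smooth in sigma, so
    neighbouring points are collinear and exact index recovery is not
    defined; this mode decorrelates the grid points to exercise the
    R2-threshold selection rule in isolation.  Planted columns share a
    latent factor and reach a per-point R2 of ~``target_r2`` against
    the response; all other columns are independent noise.

    Returns pseudo-records (DES and non-DES labels alternating) and the
    (n_records, n_sigma) feature matrix.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_records
    Z = rng.normal(size=(n, n_sigma))
    latent = rng.normal(size=n)
    eps = 0.25
    for i in config.planted_sigma_indices:
        Z[:, i] = latent + eps * rng.normal(size=n)
    # choose noise so that corr(z_i, y)^2 ~= target_r2
    var_z = 1.0 + eps**2
    sigma2 = var_z * (1.0 / (target_r2 * var_z) - 1.0)
    y = latent + math.sqrt(sigma2) * rng.normal(size=n)
    log10_x = -3.0 + y  # plausible dex range, x well inside (0, 1)
    des_sys = SolventSystem.des("ChCl", "TEG", 2.0, 0.9)
    non_des_sys = SolventSystem.neat("water")
    records = [
        SolubilityRecord(
            f"p{k:04d}",
            "solute0",
            des_sys if k % 2 else non_des_sys,
            298.15,
            10.0 ** min(log10_x[k], 0.0),
        )
        for k in range(n)
    ]
    return records, Z


# ---------------------------------------------------------------------------
# calibration and cosolvency curves
# ---------------------------------------------------------------------------


def gen_calibration_series(
    slope: float = 27.268,
    intercept: float = 0.001,
    noise: float = 0.002,
    n_levels: int = 11,
    seed: int = 0,
    conc_range: tuple[float, float] = (0.0126, 0.0504),
) -> list[tuple[float, float]]:
    """Evenly spaced calibration levels with Gaussian absorbance noise."""
    if n_levels < 3:
        raise ValueError("at least 3 levels required")
    rng = np.random.default_rng(seed)
    conc = np.linspace(conc_range[0], conc_range[1], n_levels)
    absb = slope * conc + intercept + rng.normal(0.0, noise, size=n_levels)
    return list(zip(conc.tolist(), absb.tolist()))


def gen_cosolvency_curve(
    peak: float = 0.9,
    amplitude: float = 0.05,
    grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.7, 0.8, 0.9, 1.0),
    x_neat: float = 0.35,
    x_water: float = 1e-4,
) -> list[tuple[float, float]]:
    """Unimodal DES-water solubility series peaking at ``peak``.

    The maximum sits exactly at the requested grid point and exceeds
    the neat-DES value by ``amplitude``; amplitude 0 gives a monotone
    series peaking at the neat DES.
    """
    if peak not in grid:
        raise ValueError("peak must be a grid point")
    base = [x_water + (x_neat - x_water) * c**0.7 for c in grid]
    series = []
    for c, b in zip(grid, base):
        bump = amplitude * math.exp(-0.5 * ((c - peak) / 0.06) ** 2)
        series.append((c, b + bump))
    if amplitude > 0:
        # pin the maximum to the requested grid point and the neat DES
        # point to x_neat, so max - neat == amplitude exactly
        vals = dict(series)
        vals[peak] = x_neat + amplitude
        vals[1.0] = x_neat
        series = [(c, vals[c]) for c in grid]
    return series
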