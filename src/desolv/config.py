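"""Versioned physical constants and run configuration.

All energies are in kJ/mol, surface charge densities (sigma) in e/A^2,
surface areas in A^2 and temperatures in K throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

#: Gas constant, kJ/(mol K).
R_KJ = 8.31446e-3

#: Gas constant, J/(mol K) — used where fusion enthalpies enter in J.
R_J = 8.31446

KCAL_TO_KJ = 4.184


@dataclass(frozen=True)
class InteractionConstants:
    """Segment interaction constants of the simplified COSMO-RS model.

    The misfit constant ``alpha_prime`` and the hydrogen-bond constant
    ``c_hb`` carry units of kJ A^4/(mol e^2) so that, multiplied by a
    squared screening charge density (e^2/A^4), they yield kJ/mol per
    segment contact.  ``sigma_hb`` is the donor/acceptor polarity
    threshold beyond which the hydrogen-bond term switches on, and
    ``a_eff`` the effective contact segment area.  Defaults are the
    widely used published segment-model parametrisation.
    """

    alpha_prime: float = 16466.72 * KCAL_TO_KJ
    c_hb: float = 85580.0 * KCAL_TO_KJ
    sigma_hb: float = 0.0084
    a_eff: float = 7.5
    version: str = "segment-2002"


@dataclass(frozen=True)
class ConvergenceControls:
    """Damped fixed-point controls for the segment self-consistency loop."""

    damping: float = 0.5
    tol: float = 1e-10
    max_iter: int = 10_000


@dataclass(frozen=True)
class EngineConfig:
    """Bundle of sigma-engine settings.

    ``mix_profiles_not_potentials`` switches the multicomponent-solvent
    convention from mole-fraction weighting of pure-component
    sigma-potentials (default) to weighting the sigma-profiles first and
    solving the mixture self-consistency once.
    """

    interactions: InteractionConstants = field(default_factory=InteractionConstants)
    convergence: ConvergenceControls = field(default_factory=ConvergenceControls)
    mix_profiles_not_potentials: bool = False


# ---------------------------------------------------------------------------
# Molecular structures of the study compounds.  Average molar masses are
# derived from these with rdkit; the two drug values round to the printed
# 206.28 and 254.28 g/mol.
# ---------------------------------------------------------------------------

SMILES: dict[str, str] = {
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "dexibuprofen": "CC(C)Cc1ccc(cc1)[C@@H](C)C(=O)O",
    "ketoprofen": "CC(c1cccc(c1)C(=O)c1ccccc1)C(=O)O",
    "flurbiprofen": "CC(C(=O)O)c1ccc(-c2ccccc2)c(F)c1",
    "felbinac": "OC(=O)Cc1ccc(-c2ccccc2)cc1",
    "phenylacetic_acid": "OC(=O)Cc1ccccc1",
    "diphenylacetic_acid": "OC(=O)C(c1ccccc1)c1ccccc1",
    "ChCl": "C[N+](C)(C)CCO.[Cl-]",
    "BI": "C[N+](C)(C)CC(=O)[O-]",
    "ETG": "OCCO",
    "DEG": "OCCOCCO",
    "TEG": "OCCOCCOCCO",
    "GLY": "OCC(O)CO",
    "P2D": "CC(O)CO",
    "B3D": "CC(O)CCO",
    "water": "O",
    "methanol": "CO",
}


@lru_cache(maxsize=None)
def molar_mass(compound_id: str) -> float:
    """Average molar mass in g/mol, computed from the stored structure."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    try:
        smi = SMILES[compound_id]
    except KeyError:
        raise KeyError(f"no structure registered for compound {compound_id!r}")
    return Descriptors.MolWt(Chem.MolFromSmiles(smi))
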