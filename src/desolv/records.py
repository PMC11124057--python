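"""Observation unit of the pipeline: one saturation measurement."""

from __future__ import annotations

from dataclasses import dataclass

from .systems import SolventSystem


@dataclass(frozen=True)
class SolubilityRecord:
    """(solute, solvent system, temperature, mole-fraction solubility).

    ``x_exp`` is the saturation mole fraction of the solute, ``sd`` the
    standard deviation over replicates (0 for a single measurement).
    """

    record_id: str
    solute: str
    system: SolventSystem
    T: float
    x_exp: float
    sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_exp <= 1.0:
            raise ValueError(f"x_exp out of [0, 1]: {self.x_exp}")
        if self.sd < 0:
            raise ValueError("negative standard deviation")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def is_des(self) -> bool:
        return self.system.is_des
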