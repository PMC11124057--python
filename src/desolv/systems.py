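"""Solvent systems: neat solvents, binary mixtures and DES-water ternaries.

A DES is described by its hydrogen-bond acceptor (HBA), hydrogen-bond
donor (HBD) and molar ratio 1:k; an HBA:HBD ratio of 1:k contributes
component fractions (1/(1+k), k/(1+k)) within the DES.  Choline chloride
is treated as a single component (ion pair).  Water enters through
``x_star_des``, the solute-free mole fraction of the DES in the aqueous
mixture, so the solute-free component fractions of a ternary are
(x*/(1+k), k x*/(1+k), 1-x*).
"""

from __future__ import annotations

from dataclasses import dataclass

HBA_IDS = ("ChCl", "BI")
HBD_IDS = ("ETG", "DEG", "TEG", "GLY", "P2D", "B3D")
STUDY_RATIOS = (1.0, 2.0, 4.0)


@dataclass(frozen=True)
class SolventSystem:
    """A solvent phase with solute-free component mole fractions.

    Parameters
    ----------
    system_id
        Unique identifier, e.g. ``"ChCl-TEG-1:2-w0.9"``.
    components
        Component compound ids, in fixed order.
    fractions
        Solute-free mole fractions; renormalised to sum to 1.
    is_des
        Whether the system contains a deep eutectic solvent.
    """

    system_id: str
    components: tuple[str, ...]
    fractions: tuple[float, ...]
    is_des: bool = False
    hba: str | None = None
    hbd: str | None = None
    ratio: float | None = None
    x_star_des: float | None = None

    def __post_init__(self) -> None:
        if len(self.components) != len(self.fractions):
            raise ValueError("components and fractions length mismatch")
        if any(f < 0 for f in self.fractions):
            raise ValueError("negative mole fraction")
        total = sum(self.fractions)
        if total <= 0:
            raise ValueError("fractions sum to zero")
        object.__setattr__(
            self, "fractions", tuple(f / total for f in self.fractions)
        )

    @classmethod
    def neat(cls, compound_id: str) -> "SolventSystem":
        return cls(compound_id, (compound_id,), (1.0,))

    @classmethod
    def binary(
        cls, a: str, b: str, x_a: float, system_id: str | None = None
    ) -> "SolventSystem":
        if not 0.0 <= x_a <= 1.0:
            raise ValueError("x_a must lie in [0, 1]")
        sid = system_id or f"{a}-{b}-x{a[:1]}{x_a:g}"
        return cls(sid, (a, b), (x_a, 1.0 - x_a))

    @classmethod
    def des(
        cls,
        hba: str,
        hbd: str,
        ratio: float,
        x_star_des: float = 1.0,
        system_id: str | None = None,
    ) -> "SolventSystem":
        """DES-water system from the HBA:HBD molar ratio 1:``ratio``.

        ``x_star_des = 1`` is the neat DES.
        """
        if ratio <= 0:
            raise ValueError("HBA:HBD ratio must be positive")
        if not 0.0 < x_star_des <= 1.0:
            raise ValueError("x_star_des must lie in (0, 1]")
        f_hba = x_star_des / (1.0 + ratio)
        f_hbd = x_star_des * ratio / (1.0 + ratio)
        f_water = 1.0 - x_star_des
        if f_water > 0:
            components = (hba, hbd, "water")
            fractions = (f_hba, f_hbd, f_water)
        else:
            components = (hba, hbd)
            fractions = (f_hba, f_hbd)
        sid = system_id or f"{hba}-{hbd}-1:{ratio:g}-w{x_star_des:g}"
        return cls(
            sid,
            components,
            fractions,
            is_des=True,
            hba=hba,
            hbd=hbd,
            ratio=ratio,
            x_star_des=x_star_des,
        )


def enumerate_des_grid(
    hba_list: list[str] = list(HBA_IDS),
    hbd_list: list[str] = list(HBD_IDS),
    ratios: list[float] = list(STUDY_RATIOS),
) -> list[SolventSystem]:
    """Cartesian product of HBAs, HBDs and molar ratios, deduplicated.

    The study grid (2 HBAs x 6 HBDs x 3 ratios) yields 36 neat DESs.
    """
    if not hba_list or not hbd_list or not ratios:
        raise ValueError("empty component list")
    seen: dict[tuple[str, str, float], SolventSystem] = {}
    for hba in hba_list:
        for hbd in hbd_list:
            for ratio in ratios:
                key = (hba, hbd, float(ratio))
                if key not in seen:
                    seen[key] = SolventSystem.des(hba, hbd, float(ratio))
    return list(seen.values())
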