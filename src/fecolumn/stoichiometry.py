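"""Electron-balance stoichiometry linking Fe(III) reduction to toluene oxidation.

Complete anaerobic mineralization of toluene with ferric iron as the terminal
electron acceptor transfers 36 electrons per toluene:

    C7H8 + 36 Fe(III) + 21 H2O  →  7 HCO3⁻ + 36 Fe(II) + 43 H⁺

Each Fe(III)→Fe(II) accepts one electron, so 36 mol Fe(II) accumulate per mol
toluene mineralized.  Measured Fe(II) mass therefore converts to
toluene-equivalents degraded, the core quantity of the solid-phase
natural-attenuation audit.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, Field

__all__ = [
    "MOLAR_MASS_FE",
    "MOLAR_MASS_TOLUENE",
    "MOLAR_MASS_FE_HYDROXIDE",
    "StoichiometryModel",
    "toluene_mass_concentration",
    "toluene_equivalent",
    "round_sig",
]

MOLAR_MASS_FE = 55.845  # g/mol
MOLAR_MASS_TOLUENE = 92.14  # g/mol
MOLAR_MASS_FE_HYDROXIDE = 106.867  # Fe(OH)3, g/mol


class StoichiometryModel(BaseModel):
    """Stoichiometric constants of the Fe(II)↔toluene coupling.

    ``electrons_per_toluene`` defaults to 36 (complete mineralization); lower
    values model partial oxidation stopping at intermediates.
    """

    model_config = {"frozen": True, "extra": "forbid"}

    electrons_per_toluene: int = Field(default=36, gt=0)
    molar_mass_fe: float = Field(default=MOLAR_MASS_FE, gt=0)
    molar_mass_toluene: float = Field(default=MOLAR_MASS_TOLUENE, gt=0)
    electrons_per_fe: int = Field(default=1, gt=0)

    @property
    def fe_mass_per_toluene_mass(self) -> float:
        """mg Fe(II) produced per mg toluene fully degraded (≈ 21.8 for 36 e⁻)."""
        return (
            self.electrons_per_toluene
            / self.electrons_per_fe
            * self.molar_mass_fe
            / self.molar_mass_toluene
        )


_DEFAULT = StoichiometryModel()


def toluene_mass_concentration(
    c_mmol_per_l: float, stoich: StoichiometryModel = _DEFAULT
) -> float:
    """Convert a molar toluene concentration (mmol/L) to mg/L.

    0.1 mmol/L → 9.214 mg/L (the feed concentration of the column design).
    """
    if c_mmol_per_l < 0:
        raise ValueError(f"concentration must be >= 0, got {c_mmol_per_l}")
    return c_mmol_per_l * stoich.molar_mass_toluene


def toluene_equivalent(m_fe2_mg: float, stoich: StoichiometryModel = _DEFAULT) -> float:
    """Toluene mass (mg) whose complete degradation produces ``m_fe2_mg`` of Fe(II).

    Electron balance: mol toluene = mol Fe(II) × e⁻/Fe ÷ e⁻/toluene.  With the
    default 36-electron coupling, 42 mg Fe(II) → 1.92 mg toluene and
    38 mg → 1.74 mg.
    """
    if m_fe2_mg < 0:
        raise ValueError(f"Fe(II) mass must be >= 0, got {m_fe2_mg}")
    mol_fe = m_fe2_mg / stoich.molar_mass_fe
    mol_tol = mol_fe * stoich.electrons_per_fe / stoich.electrons_per_toluene
    return mol_tol * stoich.molar_mass_toluene


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
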