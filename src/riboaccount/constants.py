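"""Physical constants used by the cellular censuses.

Values are the conversion factors of the resource-accounting model: an
average mammalian protein of 472 amino acids at 110 Da per residue, a
proteome tryptophan mass fraction of 0.69%, and the molar masses of the
small- and large-subunit rRNAs used to convert rRNA mass to ribosomal
subunit copy numbers.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator

_RRNA_SPECIES = ("mouse_18S", "mouse_28S", "human_18S", "human_28S")


class PhysicalConstants(BaseModel):
    """Conversion constants for the protein and ribosome censuses.

    All values are overridable; the defaults are the standard literature
    values used throughout the accounting chain.
    """

    avg_protein_length_aa: float = 472.0
    avg_aa_mass_da: float = 110.0
    trp_mass_fraction: float = 0.0069
    dalton_g: float = 1.66054e-24
    avogadro: float = 6.02214076e23
    rrna_molar_mass_g_per_mol: dict[str, float] = Field(
        default_factory=lambda: {
            "mouse_18S": 6.40e5,
            "mouse_28S": 1.60e6,
            "human_18S": 6.40e5,
            "human_28S": 1.70e6,
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "PhysicalConstants":
        for name in (
            "avg_protein_length_aa",
            "avg_aa_mass_da",
            "trp_mass_fraction",
            "dalton_g",
            "avogadro",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if set(self.rrna_molar_mass_g_per_mol) != set(_RRNA_SPECIES):
            raise ValueError(
                "rrna_molar_mass_g_per_mol must have exactly the keys "
                f"{_RRNA_SPECIES}"
            )
        if any(v <= 0 for v in self.rrna_molar_mass_g_per_mol.values()):
            raise ValueError("rRNA molar masses must be positive")
        return self

    @property
    def avg_protein_mass_g(self) -> float:
        """Mass of one average protein in grams (length x residue mass x Da)."""
        return self.avg_protein_length_aa * self.avg_aa_mass_da * self.dalton_g


DEFAULT_CONSTANTS = PhysicalConstants()

SECONDS_PER_HOUR = 3600.0
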