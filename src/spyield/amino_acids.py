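"""Amino-acid reference data: alphabet, essentiality, biosynthetic precursors, masses.

The essential set is the nine classical human essential amino acids
(phenylalanine, histidine, isoleucine, lysine, leucine, methionine,
threonine, valine, tryptophan) — amino acids a human cell line cannot
synthesize and must obtain from the culture medium.  Histidine is included.
The precursor map records which non-essential amino acids are made from
which others: serine is the precursor of cysteine and glycine, aspartate of
asparagine, and glutamate of glutamine, proline and arginine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from types import MappingProxyType
from typing import Mapping

#: The 20 proteinogenic one-letter codes, alphabetical.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: The nine essential amino acids for human cells.
ESSENTIAL: frozenset[str] = frozenset("FHIKLMTVW")

#: NEAA precursor -> NEAA products synthesized from it (human biosynthesis).
PRECURSOR_PRODUCTS: Mapping[str, frozenset[str]] = MappingProxyType(
    {
        "S": frozenset("CG"),
        "D": frozenset("N"),
        "E": frozenset("QPR"),
    }
)

#: Average molar mass of the free amino acid (with water), g/mol.
MOLAR_MASS_G_PER_MOL: Mapping[str, float] = MappingProxyType(
    {
        "A": 89.09,
        "C": 121.16,
        "D": 133.10,
        "E": 147.13,
        "F": 165.19,
        "G": 75.07,
        "H": 155.15,
        "I": 131.17,
        "K": 146.19,
        "L": 131.17,
        "M": 149.21,
        "N": 132.12,
        "P": 115.13,
        "Q": 146.14,
        "R": 174.20,
        "S": 105.09,
        "T": 119.12,
        "V": 117.15,
        "W": 204.23,
        "Y": 181.19,
    }
)

#: Avogadro's number, molecules per mole.
AVOGADRO: float = 6.02214e23


@dataclass(frozen=True)
class AminoAcidTable:
    """Reference table binding alphabet, essentiality, precursors and masses.

    All analyses take a table argument so the essential set and precursor
    pairing stay configurable; the defaults encode standard human biology.
    """

    alphabet: str = ALPHABET
    essential_set: frozenset[str] = ESSENTIAL
    precursor_map: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: PRECURSOR_PRODUCTS
    )
    molar_mass: Mapping[str, float] = field(default_factory=lambda: MOLAR_MASS_G_PER_MOL)

    def __post_init__(self) -> None:
        letters = set(self.alphabet)
        if len(self.alphabet) != 20 or len(letters) != 20:
            raise ValueError("alphabet must contain 20 distinct one-letter codes")
        if len(self.essential_set) != 9:
            raise ValueError(
                f"essential_set must have exactly 9 members, got {len(self.essential_set)}"
            )
        if not self.essential_set <= letters:
            raise ValueError("essential_set must be a subset of the alphabet")
        neaa = self.nonessential_set
        for precursor, products in self.precursor_map.items():
            if precursor not in neaa:
                raise ValueError(f"precursor {precursor!r} is not a NEAA")
            if not set(products) <= neaa:
                raise ValueError(f"products of {precursor!r} include a non-NEAA")
        for aa, mass in self.molar_mass.items():
            if mass <= 0:
                raise ValueError(f"molar mass of {aa!r} must be positive")

    @property
    def nonessential_set(self) -> frozenset[str]:
        return frozenset(self.alphabet) - self.essential_set

    def is_essential(self, aa: str) -> bool:
        return aa in self.essential_set

    def validate_sequence(self, seq: str, name: str = "sequence") -> str:
        """Upper-case ``seq`` and reject any letter outside the alphabet."""
        seq = seq.upper()
        letters = set(self.alphabet)
        for ch in seq:
            if ch not in letters:
                raise ValueError(f"{name}: invalid amino-acid letter {ch!r}")
        return seq


#: Shared default table.
DEFAULT_TABLE = AminoAcidTable()


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (display convention for reports)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
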