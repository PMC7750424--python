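"""Culture-media amino-acid supply versus per-protein demand.

Treats antibody synthesis as pure stoichiometry: the medium supplies a
finite molecule count of each free amino acid, each antibody copy consumes
a fixed residue count of each, and the achievable number of copies is
capped by the scarcest amino acid (Liebig's law of the minimum).  Reports
the per-amino-acid capacity, the limiting essential amino acid, amino
acids absent from the medium, and non-essential amino acids whose
biosynthetic precursor is also missing.

No uptake kinetics or growth coupling is modelled; supply/demand ratios
only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .amino_acids import (
    AVOGADRO,
    DEFAULT_TABLE,
    AminoAcidTable,
    round_half_up,
)


def molecules_from_concentration(
    conc_g_per_l: float, volume_l: float, molar_mass_g_per_mol: float
) -> float:
    """Molecule count of a dissolved amino acid: c·V/M · N_A."""
    if volume_l <= 0:
        raise ValueError(f"volume must be positive, got {volume_l}")
    if molar_mass_g_per_mol <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass_g_per_mol}")
    if conc_g_per_l < 0:
        raise ValueError(f"concentration must be non-negative, got {conc_g_per_l}")
    return conc_g_per_l * volume_l / molar_mass_g_per_mol * AVOGADRO


@dataclass(frozen=True)
class MediaFormulation:
    """Per-amino-acid molecule supply of a culture medium.

    ``molecules`` holds raw molecule counts; amino acids missing from the
    mapping read as zero supply.  Construct from concentrations with
    :meth:`from_concentrations` or from a CSV with :meth:`from_csv`.
    """

    molecules: Mapping[str, float]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        for aa, n in self.molecules.items():
            if n < 0:
                raise ValueError(f"negative molecule count for {aa!r}")

    def supply(self, aa: str) -> float:
        return float(self.molecules.get(aa, 0.0))

    def scaled(self, factor: float) -> "MediaFormulation":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return MediaFormulation(
            molecules={aa: n * factor for aa, n in self.molecules.items()},
            source=self.source,
        )

    @classmethod
    def from_concentrations(
        cls,
        conc_g_per_l: Mapping[str, float],
        volume_l: float = 1.0,
        table: AminoAcidTable = DEFAULT_TABLE,
        source: str = "unspecified",
    ) -> "MediaFormulation":
        molecules = {
            aa: molecules_from_concentration(c, volume_l, table.molar_mass[aa])
            for aa, c in conc_g_per_l.items()
        }
        return cls(molecules=molecules, source=source)

    @classmethod
    def from_csv(
        cls,
        path,
        volume_l: float = 1.0,
        table: AminoAcidTable = DEFAULT_TABLE,
        source: str | None = None,
    ) -> "MediaFormulation":
        """Read columns ``amino_acid`` plus ``molecules`` or ``conc_g_per_L``.

        ``molecules`` takes precedence when both are present.
        """
        df = pd.read_csv(path)
        if "amino_acid" not in df.columns:
            raise ValueError("media CSV requires an 'amino_acid' column")
        molecules: dict[str, float] = {}
        for _, row in df.iterrows():
            aa = str(row["amino_acid"]).strip().upper()
            if "molecules" in df.columns and not pd.isna(row.get("molecules")):
                molecules[aa] = float(row["molecules"])
            elif "conc_g_per_L" in df.columns and not pd.isna(row.get("conc_g_per_L")):
                molecules[aa] = molecules_from_concentration(
                    float(row["conc_g_per_L"]), volume_l, table.molar_mass[aa]
                )
            else:
                raise ValueError(f"{aa}: need one of 'molecules' or 'conc_g_per_L'")
        return cls(molecules=molecules, source=source or str(path))


@dataclass(frozen=True)
class DemandProfile:
    """Residues of each amino acid consumed per protein copy."""

    counts: Mapping[str, float]
    protein: str = "antibody"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("demand counts must be non-negative")
        if not any(v > 0 for v in self.counts.values()):
            raise ValueError("demand must have at least one positive entry")

    def demand(self, aa: str) -> float:
        return float(self.counts.get(aa, 0.0))

    @classmethod
    def from_csv(cls, path, protein: str | None = None) -> "DemandProfile":
        df = pd.read_csv(path)
        if not {"amino_acid", "count"} <= set(df.columns):
            raise ValueError("demand CSV requires 'amino_acid' and 'count' columns")
        counts = {
            str(r["amino_acid"]).strip().upper(): float(r["count"])
            for _, r in df.iterrows()
        }
        return cls(counts=counts, protein=protein or str(path))


@dataclass(frozen=True)
class CapacityReport:
    """Per-amino-acid maximum protein copies and the limiting amino acids.

    ``max_copies`` is supply/demand in raw copies (+inf where demand is 0);
    ``limiting_eaa`` restricts the argmin to essential amino acids (the
    medium's headline bottleneck), ``limiting_overall`` ranges over every
    demanded amino acid.  ``zero_supply`` lists demanded amino acids absent
    from the medium; ``precursor_gaps`` are (product, precursor) pairs where
    a missing non-essential amino acid cannot be made because its precursor
    is missing too.
    """

    max_copies: Mapping[str, float]
    limiting_eaa: tuple[str, float]
    limiting_overall: tuple[str, float]
    zero_supply: tuple[str, ...]
    precursor_gaps: tuple[tuple[str, str], ...]

    def max_copies_1e18(self, aa: str) -> float:
        """Display convention: copies in units of 1e18, 2 decimals, half-up."""
        v = self.max_copies[aa]
        return math.inf if math.isinf(v) else round_half_up(v / 1e18, 2)

    def to_dict(self) -> dict:
        return {
            "max_copies_1e18": {
                aa: (None if math.isinf(v) else round_half_up(v / 1e18, 2))
                for aa, v in sorted(self.max_copies.items())
            },
            "limiting_eaa": {
                "amino_acid": self.limiting_eaa[0],
                "max_copies_1e18": round_half_up(self.limiting_eaa[1] / 1e18, 2),
            },
            "limiting_overall": {
                "amino_acid": self.limiting_overall[0],
                "max_copies_1e18": round_half_up(self.limiting_overall[1] / 1e18, 2),
            },
            "zero_supply": list(self.zero_supply),
            "precursor_gaps": [list(pair) for pair in self.precursor_gaps],
        }

    def to_json(self, handle) -> None:
        json.dump(self.to_dict(), handle, indent=2, sort_keys=False)
        handle.write("\n")


def precursor_gaps(
    media: MediaFormulation, table: AminoAcidTable = DEFAULT_TABLE
) -> list[tuple[str, str]]:
    """(product, precursor) pairs where both are absent from the medium.

    A non-essential amino acid missing from the medium is only a problem
    if the cell also cannot make it — i.e. its biosynthetic precursor is
    missing as well.  Pairs are ordered by product letter.
    """
    gaps = []
    for precursor, products in table.precursor_map.items():
        if media.supply(precursor) > 0:
            continue
        for product in sorted(products):
            if media.supply(product) == 0:
                gaps.append((product, precursor))
    gaps.sort()
    return gaps


def capacity(
    media: MediaFormulation,
    demand: DemandProfile,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> CapacityReport:
    """Maximum protein copies supported by each amino acid alone.

    ``max_copies[a] = supply[a] / demand[a]`` (+inf when a is not
    demanded); the limiting amino acid is the argmin, reported both over
    essential amino acids only and over all demanded amino acids.
    """
    max_copies: dict[str, float] = {}
    for aa in table.alphabet:
        d = demand.demand(aa)
        max_copies[aa] = media.supply(aa) / d if d > 0 else math.inf

    demanded = [aa for aa in table.alphabet if demand.demand(aa) > 0]
    if not demanded:
        raise ValueError("demand profile is all zero")

    def argmin(scope):
        # ties broken alphabetically for deterministic reports
        return min(scope, key=lambda aa: (max_copies[aa], aa))

    eaa_scope = [aa for aa in demanded if table.is_essential(aa)]
    if not eaa_scope:
        raise ValueError("no essential amino acid is demanded")
    lim_eaa = argmin(eaa_scope)
    lim_all = argmin(demanded)
    zero = tuple(sorted(aa for aa in demanded if media.supply(aa) == 0))
    return CapacityReport(
        max_copies=max_copies,
        limiting_eaa=(lim_eaa, max_copies[lim_eaa]),
        limiting_overall=(lim_all, max_copies[lim_all]),
        zero_supply=zero,
        precursor_gaps=tuple(precursor_gaps(media, table)),
    )
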