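"""Signal-peptide parsing, composition profiling and per-family consensus.

A signal peptide (SP) is the short N-terminal tag that routes an antibody
chain into the secretory pathway.  This module reads SP (or full-length
protein) sequences from FASTA, counts residues, summarizes essential
amino-acid (EAA) usage as a variety/total pair, and derives the
position-wise consensus of a pre-aligned family.
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .amino_acids import DEFAULT_TABLE, AminoAcidTable, round_half_up

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignalPeptide:
    """A named, family-tagged amino-acid sequence.

    ``family`` is the V-gene family label (Vκ1–Vκ6 for light chains,
    VH1–VH7 for heavy chains) or a free label such as ``IgE``; ``chain``
    is ``heavy``, ``light`` or ``other``.
    """

    name: str
    sequence: str
    family: str = "unknown"
    chain: str = "other"
    table: AminoAcidTable = field(default=DEFAULT_TABLE, repr=False, compare=False)

    def __post_init__(self) -> None:
        seq = self.table.validate_sequence(self.sequence, name=self.name)
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.name}: sequence must be non-empty")
        if seq[0] != "M":
            raise ValueError(f"{self.name}: signal peptide must start with M, got {seq[0]!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CompositionProfile:
    """Per-amino-acid residue counts of a sequence (or mean of a set).

    ``counts`` holds every alphabet letter (integers for a single sequence,
    reals for averaged profiles); ``length`` is the total residue count.
    """

    counts: Mapping[str, float]
    length: float

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("composition counts must be non-negative")
        if abs(total - self.length) > 1e-9:
            raise ValueError(f"counts sum to {total}, expected length {self.length}")

    def __getitem__(self, aa: str) -> float:
        return self.counts[aa]

    def rounded(self) -> "CompositionProfile":
        """Half-up integer view, used when building demand profiles."""
        counts = {aa: float(round_half_up(v, 0)) for aa, v in self.counts.items()}
        return CompositionProfile(counts=counts, length=sum(counts.values()))

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype=float)


@dataclass(frozen=True)
class EAAProfile:
    """Essential amino-acid usage summary: ``variety`` distinct EAA types
    present and ``total_eaa`` EAA residues, out of ``length`` residues."""

    variety: int
    total_eaa: int
    length: int

    def __post_init__(self) -> None:
        if not (0 <= self.variety <= 9):
            raise ValueError("variety must lie in [0, 9]")
        if not (self.variety <= self.total_eaa <= self.length):
            raise ValueError("expected variety <= total_eaa <= length")

    def __str__(self) -> str:  # the "variety/No." convention of SP reports
        return f"{self.variety}/{self.total_eaa}"


def parse_sp_fasta(
    text: str, table: AminoAcidTable = DEFAULT_TABLE
) -> list[SignalPeptide]:
    """Parse FASTA text into signal peptides, preserving record order.

    Headers may carry metadata as ``name|family|chain``; missing fields
    default to ``unknown`` family and ``other`` chain.  A sequence letter
    outside the 20-letter alphabet raises ``ValueError`` naming the record
    and the offending character.
    """
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        parts = rec.description.split("|")
        name = parts[0].strip() or rec.id
        family = parts[1].strip() if len(parts) > 1 and parts[1].strip() else "unknown"
        chain = parts[2].strip() if len(parts) > 2 and parts[2].strip() else "other"
        records.append(
            SignalPeptide(
                name=name, sequence=str(rec.seq), family=family, chain=chain, table=table
            )
        )
    return records


def write_sp_fasta(peptides: Iterable[SignalPeptide], handle) -> None:
    """Write signal peptides in the ``>name|family|chain`` header dialect."""
    for sp in peptides:
        handle.write(f">{sp.name}|{sp.family}|{sp.chain}\n{sp.sequence}\n")


def composition(
    seq: str, table: AminoAcidTable = DEFAULT_TABLE
) -> CompositionProfile:
    """Residue counts of ``seq`` over the full 20-letter alphabet."""
    seq = table.validate_sequence(seq)
    tally = Counter(seq)
    counts = {aa: float(tally.get(aa, 0)) for aa in table.alphabet}
    return CompositionProfile(counts=counts, length=float(len(seq)))


def eaa_profile(seq: str, table: AminoAcidTable = DEFAULT_TABLE) -> EAAProfile:
    """Essential amino-acid variety and total for ``seq``."""
    seq = table.validate_sequence(seq)
    essential = [aa for aa in seq if table.is_essential(aa)]
    return EAAProfile(
        variety=len(set(essential)), total_eaa=len(essential), length=len(seq)
    )


def consensus(seqs: Sequence[str], table: AminoAcidTable = DEFAULT_TABLE) -> str:
    """Position-wise most frequent residue of pre-aligned, equal-length sequences.

    Ties are broken toward the alphabetically smaller residue and logged,
    so a downstream audit can see where the consensus was ambiguous.
    """
    if not seqs:
        raise ValueError("consensus requires at least one sequence")
    seqs = [table.validate_sequence(s) for s in seqs]
    lengths = sorted({len(s) for s in seqs})
    if len(lengths) > 1:
        raise ValueError(f"consensus requires equal-length sequences, got lengths {lengths}")
    out = []
    for pos in range(lengths[0]):
        tally = Counter(s[pos] for s in seqs)
        top = max(tally.values())
        tied = sorted(aa for aa, n in tally.items() if n == top)
        if len(tied) > 1:
            logger.info("consensus tie at position %d among %s; taking %s", pos + 1, tied, tied[0])
        out.append(tied[0])
    return "".join(out)


def average_composition(
    seqs: Sequence[str], table: AminoAcidTable = DEFAULT_TABLE
) -> CompositionProfile:
    """Arithmetic mean of per-sequence compositions (real-valued counts).

    This is the "unified representative average" used to build an
    amino-acid demand profile from a set of full-length chains; use
    ``.rounded()`` for the half-up integer view.
    """
    if not seqs:
        raise ValueError("average_composition requires at least one sequence")
    profiles = [composition(s, table) for s in seqs]
    n = len(profiles)
    counts = {
        aa: sum(p.counts[aa] for p in profiles) / n for aa in table.alphabet
    }
    length = sum(p.length for p in profiles) / n
    return CompositionProfile(counts=counts, length=length)


def profile_table(
    peptides: Iterable[SignalPeptide], table: AminoAcidTable = DEFAULT_TABLE
) -> pd.DataFrame:
    """Per-SP report: family, sequence, length, EAA variety and total."""
    rows = []
    for sp in peptides:
        prof = eaa_profile(sp.sequence, table)
        rows.append(
            {
                "name": sp.name,
                "family": sp.family,
                "chain": sp.chain,
                "sequence": sp.sequence,
                "length": len(sp),
                "variety": prof.variety,
                "total_eaa": prof.total_eaa,
            }
        )
    return pd.DataFrame(rows)
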