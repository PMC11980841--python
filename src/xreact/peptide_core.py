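"""Peptide and proteome primitives.

Fixed-length epitope peptides, protein records, k-mer window enumeration
and FASTA ingestion. All residue positions are 1-based and intervals are
closed, matching the residue numbering conventions of epitope mapping
(position 1 = N-terminal residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET: frozenset[str] = frozenset(STANDARD_AA)

#: Ambiguity / non-standard codes tolerated in proteome sequences but never
#: in epitope queries. Selenocysteine (U) is deliberately treated as an
#: ambiguity code rather than mapped to C.
AMBIGUITY_AA: frozenset[str] = frozenset("XBZUJO")


class PeptideError(ValueError):
    """Malformed peptide or protein input."""


@dataclass(frozen=True)
class EpitopePeptide:
    """A validated fixed-length peptide over the 20 standard residues.

    The canonical use is a 9-mer MHC class I epitope such as the CD22-derived
    HLA-A*02:01 ligand FLSNDTVQL.
    """

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideError("epitope peptide must be nonempty")
        bad = set(self.sequence) - STANDARD_AA_SET
        if bad:
            raise PeptideError(
                f"non-standard residue(s) {sorted(bad)} in epitope {self.sequence!r}"
            )

    @property
    def k(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.k:
            raise IndexError(f"position {position} outside 1..{self.k}")
        return self.sequence[position - 1]


def validate_peptide(raw: str) -> EpitopePeptide:
    """Validate and case-normalize an epitope peptide string.

    Raises :class:`PeptideError` on empty input or any character outside the
    20-letter standard alphabet (ambiguity codes are rejected for queries).
    """
    if not raw:
        raise PeptideError("epitope peptide must be nonempty")
    return EpitopePeptide(raw.upper())


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: accession, free-text description, sequence.

    Sequences may contain ambiguity codes (X, B, Z, U, ...); windows covering
    them are skipped during enumeration.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise PeptideError("protein id must be nonempty")
        if not self.sequence:
            raise PeptideError(f"protein {self.id!r} has empty sequence")
        bad = set(self.sequence) - STANDARD_AA_SET - AMBIGUITY_AA
        if bad:
            raise PeptideError(
                f"protein {self.id!r} contains unknown character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideWindow:
    """A length-k window of a protein, with 1-based start offset."""

    peptide: str
    protein_id: str
    offset: int

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise PeptideError(f"window offset {self.offset} must be >= 1")


def enumerate_windows(protein: ProteinRecord, k: int) -> Iterator[PeptideWindow]:
    """Yield every contiguous length-``k`` window of ``protein`` in offset order.

    Windows containing any ambiguity code are skipped. ``k`` longer than the
    protein yields nothing (not an error). For an unambiguous protein of
    length L >= k this yields exactly L - k + 1 windows.
    """
    if k < 1:
        raise PeptideError(f"window length k={k} must be >= 1")
    seq = protein.sequence
    n = len(seq)
    for start in range(n - k + 1):
        pep = seq[start : start + k]
        if STANDARD_AA_SET.issuperset(pep):
            yield PeptideWindow(peptide=pep, protein_id=protein.id, offset=start + 1)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into records; sequences are uppercased.

    The id is the first whitespace-delimited header token; the remainder is
    kept as the description. Duplicate ids are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise PeptideError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), description=desc)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as multi-record FASTA (id + optional description headers)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")
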