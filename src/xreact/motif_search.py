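"""Proteome motif searches.

Search 1 scans a proteome for every k-mer sharing the exact TCR-contact
motif of the query epitope. Search 2 relaxes each constrained motif position
to the physicochemical similarity class(es) of its allowed residues, since a
cross-reactive peptide need not conserve contact residues exactly — a
chemically similar side chain may suffice. Both searches emit deduplicated
peptide hits with full window provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .peptide_core import (
    STANDARD_AA_SET,
    EpitopePeptide,
    PeptideError,
    PeptideWindow,
    ProteinRecord,
    enumerate_windows,
)
from .scan_interpret import RecognitionMotif

#: Default physicochemical grouping of the 20 standard residues: small
#: (A/G), aliphatic hydrophobic (I/L/M/V), aromatic (F/W/Y), basic (K/R/H),
#: acidic (D/E), amide (N/Q), hydroxyl (S/T), and cysteine / proline as
#: singletons for their distinctive chemistry.
DEFAULT_CLASS_GROUPS: dict[str, frozenset[str]] = {
    "small": frozenset("AG"),
    "aliphatic": frozenset("ILMV"),
    "aromatic": frozenset("FWY"),
    "basic": frozenset("KRH"),
    "acidic": frozenset("DE"),
    "amide": frozenset("NQ"),
    "hydroxyl": frozenset("ST"),
    "cysteine": frozenset("C"),
    "proline": frozenset("P"),
}


@dataclass(frozen=True)
class SimilarityClasses:
    """A partition of the 20 standard residues into named classes."""

    groups: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        covered: set[str] = set()
        for name, members in self.groups.items():
            if not members:
                raise PeptideError(f"similarity class {name!r} is empty")
            overlap = covered & members
            if overlap:
                raise PeptideError(
                    f"residue(s) {sorted(overlap)} assigned to multiple classes"
                )
            covered |= members
        missing = STANDARD_AA_SET - covered
        if missing:
            raise PeptideError(
                f"residue(s) {sorted(missing)} not assigned to any class"
            )
        extra = covered - STANDARD_AA_SET
        if extra:
            raise PeptideError(f"non-standard residue(s) {sorted(extra)} in classes")

    def expand(self, residue: str) -> frozenset[str]:
        """The class containing ``residue`` (always includes the residue)."""
        for members in self.groups.values():
            if residue in members:
                return members
        raise PeptideError(f"residue {residue!r} not in any class")

    @classmethod
    def default(cls) -> "SimilarityClasses":
        return cls(groups=dict(DEFAULT_CLASS_GROUPS))

    @classmethod
    def identity(cls) -> "SimilarityClasses":
        """Each residue its own class; expansion becomes a no-op."""
        return cls(groups={aa: frozenset(aa) for aa in sorted(STANDARD_AA_SET)})


@dataclass(frozen=True)
class PeptideHit:
    """A distinct proteome peptide with provenance across searches.

    ``windows`` lists every (protein, offset) occurrence; ``found_by`` names
    the searches that produced it; ``scores`` accumulates downstream
    annotations (alignment score, binding score/rank). ``is_self`` marks
    hits identical to the query epitope, which are reported but never
    counted as cross-reactivity candidates.
    """

    peptide: str
    windows: tuple[PeptideWindow, ...]
    found_by: frozenset[str]
    scores: Mapping[str, float] = field(default_factory=dict)
    is_self: bool = False

    def __post_init__(self) -> None:
        if not self.windows:
            raise PeptideError(f"hit {self.peptide!r} has no window provenance")
        if not self.found_by:
            raise PeptideError(f"hit {self.peptide!r} has empty found_by")
        for w in self.windows:
            if w.peptide != self.peptide:
                raise PeptideError(
                    f"window peptide {w.peptide!r} != hit peptide {self.peptide!r}"
                )

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(sorted({w.protein_id for w in self.windows}))


def expand_motif(
    motif: RecognitionMotif, classes: SimilarityClasses | None = None
) -> RecognitionMotif:
    """Relax each constrained motif position to its similarity class(es).

    Positions already allowing the full alphabet are unchanged. The expanded
    motif's language is always a superset of the input's (classes are
    reflexive), so Search 2 hits always include Search 1 hits.
    """
    if classes is None:
        classes = SimilarityClasses.default()
    n_alpha = len(STANDARD_AA_SET)
    allowed = []
    for s in motif.allowed:
        if len(s) == n_alpha:
            allowed.append(s)
        else:
            expanded: frozenset[str] = frozenset()
            for residue in s:
                expanded |= classes.expand(residue)
            allowed.append(expanded)
    return RecognitionMotif(allowed=tuple(allowed))


def _merge_windows_to_hits(
    windows: Iterable[PeptideWindow],
    found_by: str,
    query: EpitopePeptide | None,
) -> list[PeptideHit]:
    by_peptide: dict[str, list[PeptideWindow]] = {}
    for w in windows:
        by_peptide.setdefault(w.peptide, []).append(w)
    hits = []
    for pep in sorted(by_peptide):
        wins = tuple(
            sorted(by_peptide[pep], key=lambda w: (w.protein_id, w.offset))
        )
        hits.append(
            PeptideHit(
                peptide=pep,
                windows=wins,
                found_by=frozenset({found_by}),
                is_self=(query is not None and pep == query.sequence),
            )
        )
    return hits


def scan_proteome(
    proteome: Sequence[ProteinRecord],
    motif: RecognitionMotif,
    k: int | None = None,
    query: EpitopePeptide | None = None,
    search_name: str = "search1",
) -> list[PeptideHit]:
    """Scan a proteome for k-mers matching a recognition motif (Search 1/2).

    Returns one :class:`PeptideHit` per distinct matching peptide, window
    provenance merged across proteins and offsets, deterministically ordered
    by peptide (windows by protein id, then offset). Hits equal to ``query``
    are flagged self.
    """
    if k is None:
        k = motif.k
    if k != motif.k:
        raise PeptideError(f"k={k} does not match motif length {motif.k}")
    allowed = motif.allowed
    matching: list[PeptideWindow] = []
    for protein in proteome:
        for w in enumerate_windows(protein, k):
            pep = w.peptide
            ok = True
            for res, allow in zip(pep, allowed):
                if res not in allow:
                    ok = False
                    break
            if ok:
                matching.append(w)
    return _merge_windows_to_hits(matching, search_name, query)
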