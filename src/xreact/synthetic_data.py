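"""Seeded generators for synthetic proteomes and positional-scan tables.

Every input the screening pipeline consumes can be generated here with
planted ground truth, so each stage is testable without downloading a real
proteome or running a wet-lab scan:

* **proteomes** — i.i.d.-background protein sequences with peptides planted
  at recorded, non-overlapping coordinates. Plant labels describe which
  stage should find (or remove) them: ``exact_motif`` windows match the
  contact motif verbatim, ``class_variant`` windows match only the
  similarity-expanded motif, ``align_decoy`` windows score highly under
  local alignment without matching either motif, and ``nonbinder_decoy``
  windows match the motif but destroy both MHC anchors so the binding
  filter must remove them;
* **scan tables** — single-substitution response/binding tables in which
  designated positions show abrogated response (contacts) or abrogated
  predicted binding (anchors), under multiplicative log-normal noise.

All generation is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .align_search import SubstitutionMatrix
from .motif_search import SimilarityClasses
from .peptide_core import (
    STANDARD_AA,
    EpitopePeptide,
    PeptideError,
    ProteinRecord,
)
from .scan_interpret import (
    PositionalScanTable,
    PositionClassification,
    ScanError,
    ScanVariant,
)

PlantLabel = Literal["exact_motif", "class_variant", "align_decoy", "nonbinder_decoy"]


class SyntheticError(ValueError):
    """Invalid synthetic-data specification."""


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Specification of a background proteome with planted peptides.

    Defaults give ~10^4 background residues (40 proteins of 200-300
    residues), a scale at which exhaustive alignment and brute-force oracles
    are still fast while leaving ample non-overlapping insertion space.
    """

    n_proteins: int = 40
    length_range: tuple[int, int] = (200, 300)
    background_freqs: tuple[float, ...] | None = None  # None = uniform
    planted: tuple[tuple[str, PlantLabel, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SyntheticError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise SyntheticError(f"bad length_range {self.length_range}")
        if self.background_freqs is not None:
            f = np.asarray(self.background_freqs, dtype=float)
            if f.shape != (20,):
                raise SyntheticError("background_freqs must have 20 entries")
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise SyntheticError(
                    "background_freqs must be nonnegative and sum to 1"
                )
        lengths = {len(p) for p, _, _ in self.planted}
        if len(lengths) > 1:
            raise SyntheticError(f"planted peptides have mixed lengths {lengths}")
        for pep, label, copies in self.planted:
            EpitopePeptide(pep)  # validates alphabet
            if copies < 1:
                raise SyntheticError(f"plant {pep!r} has copies={copies} < 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted-peptide labels and coordinates, keyed by peptide sequence."""

    entries: Mapping[str, tuple[PlantLabel, tuple[tuple[str, int], ...]]]

    def peptides(self, label: PlantLabel | None = None) -> frozenset[str]:
        if label is None:
            return frozenset(self.entries)
        return frozenset(p for p, (lab, _) in self.entries.items() if lab == label)

    def occurrences(self, peptide: str) -> tuple[tuple[str, int], ...]:
        return self.entries[peptide][1]


def generate_proteome(
    spec: SyntheticProteomeSpec,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate a seeded background proteome with planted peptides.

    Background residues are drawn i.i.d. from ``background_freqs`` (uniform
    by default). Each plant copy overwrites a randomly chosen window that
    overlaps neither a protein boundary nor any previous plant; exhaustion
    of insertion space raises :class:`SyntheticError`. Identical spec and
    seed give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    freqs = (
        np.full(20, 1 / 20)
        if spec.background_freqs is None
        else np.asarray(spec.background_freqs, dtype=float)
    )
    alphabet = np.array(list(STANDARD_AA))
    lengths = rng.integers(lo, hi + 1, size=spec.n_proteins)
    chars = [
        rng.choice(alphabet, size=length, p=freqs).tolist() for length in lengths
    ]
    ids = [f"SYN{i + 1:05d}" for i in range(spec.n_proteins)]

    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_proteins)}
    truth: dict[str, tuple[PlantLabel, list[tuple[str, int]]]] = {}
    for pep, label, copies in spec.planted:
        k = len(pep)
        coords = truth.setdefault(pep, (label, []))[1]
        for _ in range(copies):
            placed = False
            for _attempt in range(1000):
                pi = int(rng.integers(0, spec.n_proteins))
                if lengths[pi] < k:
                    continue
                start = int(rng.integers(0, lengths[pi] - k + 1))
                span = (start, start + k)
                if any(span[0] < e and s < span[1] for s, e in occupied[pi]):
                    continue
                chars[pi][span[0] : span[1]] = list(pep)
                occupied[pi].append(span)
                coords.append((ids[pi], start + 1))
                placed = True
                break
            if not placed:
                raise SyntheticError(
                    f"could not place plant {pep!r}: insertion space exhausted"
                )
    records = [
        ProteinRecord(id=pid, sequence="".join(c), description="synthetic")
        for pid, c in zip(ids, chars)
    ]
    frozen = {
        pep: (label, tuple(sorted(coords))) for pep, (label, coords) in truth.items()
    }
    return records, SyntheticTruth(entries=frozen)


# ---------------------------------------------------------------------------
# Plant construction helpers
# ---------------------------------------------------------------------------

def class_variant_peptide(
    query: EpitopePeptide,
    contacts: frozenset[int] | Sequence[int],
    classes: SimilarityClasses | None = None,
    which: int = 0,
) -> str:
    """A peptide matching the class-expanded motif but not the exact motif.

    Substitutes one contact residue by another member of its similarity
    class. ``which`` indexes the available substitutions deterministically
    (ordered by position, then residue). Raises if every contact residue's
    class is a singleton.
    """
    if classes is None:
        classes = SimilarityClasses.default()
    options: list[tuple[int, str]] = []
    for p in sorted(contacts):
        wt = query.residue(p)
        for res in sorted(classes.expand(wt) - {wt}):
            options.append((p, res))
    if not options:
        raise SyntheticError("all contact residues are in singleton classes")
    p, res = options[which % len(options)]
    seq = list(query.sequence)
    seq[p - 1] = res
    return "".join(seq)


def align_decoy_peptide(
    query: EpitopePeptide,
    avoid_positions: frozenset[int] | Sequence[int],
    matrix: SubstitutionMatrix | None = None,
    classes: SimilarityClasses | None = None,
    which: int = 0,
) -> str:
    """A high-alignment-score decoy invisible to both motif searches.

    Substitutes one residue at a position in ``avoid_positions`` (typically
    the contact set) by the best-scoring replacement under the substitution
    matrix that lies *outside* the wild-type residue's similarity class, so
    the decoy matches neither the exact nor the class-expanded motif yet
    keeps its local-alignment self-score deficit minimal.
    """
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    if classes is None:
        classes = SimilarityClasses.default()
    positions = sorted(avoid_positions)
    if not positions:
        raise SyntheticError("avoid_positions must be nonempty")
    p = positions[which % len(positions)]
    wt = query.residue(p)
    forbidden = classes.expand(wt)
    best = max(
        (res for res in STANDARD_AA if res not in forbidden),
        key=lambda res: (matrix.score(wt, res), res),
    )
    seq = list(query.sequence)
    seq[p - 1] = best
    return "".join(seq)


def nonbinder_decoy_peptide(
    query: EpitopePeptide,
    anchors: frozenset[int] | Sequence[int],
    destructive_residue: str = "P",
) -> str:
    """A motif-matching peptide with both MHC anchors destroyed.

    Replaces every anchor residue by ``destructive_residue`` (proline by
    default — incompatible with the HLA-A*02:01 B and F pockets). Contact
    residues are untouched, so the peptide is found by Search 1 and must be
    removed by the binding filter.
    """
    if not anchors:
        raise SyntheticError("anchors must be nonempty")
    seq = list(query.sequence)
    for p in sorted(anchors):
        seq[p - 1] = destructive_residue
    return "".join(seq)


# ---------------------------------------------------------------------------
# Scan-table generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticScanSpec:
    """Specification of a synthetic positional-scan table.

    Response magnitudes emulate an overnight-coculture IFN-γ ELISA readout:
    wild type ~1000 pg/ml, contact substitutions collapsing to ~2% of wild
    type, tolerant substitutions retaining ~90%. Anchor substitutions worsen
    the predicted affinity 100-fold (affinity-like orientation, lower =
    stronger) and also suppress the response, since a peptide that is no
    longer presented cannot stimulate. Noise is multiplicative log-normal.
    """

    wild_type: EpitopePeptide
    contact_positions: frozenset[int]
    anchor_positions: frozenset[int]
    wt_response: float = 1000.0
    wt_predicted_binding: float = 20.0
    contact_response_frac: float = 0.02
    tolerant_response_frac: float = 0.9
    anchor_binding_fold: float = 100.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.wild_type.k
        for p in self.contact_positions | self.anchor_positions:
            if not 1 <= p <= k:
                raise SyntheticError(f"position {p} outside 1..{k}")
        if self.contact_positions & self.anchor_positions:
            raise SyntheticError("contact and anchor position sets must be disjoint")
        for name, frac in (
            ("contact_response_frac", self.contact_response_frac),
            ("tolerant_response_frac", self.tolerant_response_frac),
        ):
            if not 0 < frac < 1:
                raise SyntheticError(f"{name} {frac} must be in (0,1)")
        if self.contact_response_frac >= self.tolerant_response_frac:
            raise SyntheticError(
                "contact_response_frac must be below tolerant_response_frac"
            )
        if self.anchor_binding_fold <= 1:
            raise SyntheticError("anchor_binding_fold must be > 1")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")


def generate_scan_table(spec: SyntheticScanSpec) -> PositionalScanTable:
    """Generate a seeded positional-scan table with planted position classes.

    Each position gets an alanine substitution (glycine where the wild-type
    residue already is alanine). Responses and predicted-binding values are
    multiplied by independent log-normal noise factors exp(N(0, noise_sd)).
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.wild_type.k

    def noise() -> float:
        if spec.noise_sd == 0:
            return 1.0
        return float(np.exp(rng.normal(0.0, spec.noise_sd)))

    variants = []
    for p in range(1, k + 1):
        wt_res = spec.wild_type.residue(p)
        sub = "G" if wt_res == "A" else "A"
        if p in spec.anchor_positions:
            binding = spec.wt_predicted_binding * spec.anchor_binding_fold * noise()
            response = spec.contact_response_frac * spec.wt_response * noise()
        elif p in spec.contact_positions:
            binding = spec.wt_predicted_binding * noise()
            response = spec.contact_response_frac * spec.wt_response * noise()
        else:
            binding = spec.wt_predicted_binding * noise()
            response = spec.tolerant_response_frac * spec.wt_response * noise()
        variants.append(
            ScanVariant(
                position=p,
                substituted_residue=sub,
                response=response,
                predicted_binding=binding,
            )
        )
    return PositionalScanTable(
        wild_type=spec.wild_type,
        wt_response=spec.wt_response,
        wt_predicted_binding=spec.wt_predicted_binding,
        variants=tuple(variants),
        orientation="affinity",
    )


def truth_tsv(truth: SyntheticTruth) -> str:
    """Render a truth table as TSV text (peptide, label, protein_id, offset)."""
    lines = ["peptide\tlabel\tprotein_id\toffset"]
    for pep in sorted(truth.entries):
        label, coords = truth.entries[pep]
        for protein_id, offset in coords:
            lines.append(f"{pep}\t{label}\t{protein_id}\t{offset}")
    return "\n".join(lines) + "\n"
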