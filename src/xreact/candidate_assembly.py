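"""Candidate-set assembly, export and the end-to-end screening pipeline.

The three searches (exact contact motif, similarity-class-expanded motif,
exhaustive local alignment) are merged into one deduplicated candidate list
with complete provenance: which searches found each peptide, at which
proteome coordinates, with which scores. A provenance snapshot (thresholds,
classes, matrix, predictor, seeds, proteome digest) is recorded so a run
can be reproduced bit-identically. Candidate counts are outputs to be
reported with provenance, never validated against any particular screen's
published count, since they depend on the proteome version and parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import align_search, hla_filter, motif_search, scan_interpret
from .align_search import SubstitutionMatrix
from .hla_filter import AnchorPSSM, BindingPredictor
from .motif_search import PeptideHit, SimilarityClasses
from .peptide_core import (
    EpitopePeptide,
    PeptideError,
    PeptideWindow,
    ProteinRecord,
    write_fasta,
)
from .scan_interpret import PositionalScanTable


class AssemblyError(ValueError):
    """Inconsistent inputs to candidate assembly."""


@dataclass(frozen=True)
class CandidateSet:
    """Deduplicated cross-reactivity candidates with provenance.

    ``candidates`` excludes self-flagged peptides (the query's own proteome
    occurrence is by construction not a cross-reactivity candidate); these
    are kept separately in ``self_hits`` for reporting.
    """

    candidates: tuple[PeptideHit, ...]
    query: EpitopePeptide
    provenance: Mapping[str, object] = field(default_factory=dict)
    self_hits: tuple[PeptideHit, ...] = ()

    def __post_init__(self) -> None:
        peptides = [h.peptide for h in self.candidates]
        if len(peptides) != len(set(peptides)):
            raise AssemblyError("duplicate peptide sequences in candidate set")
        for h in self.candidates:
            if h.is_self:
                raise AssemblyError(
                    f"self-flagged peptide {h.peptide!r} in candidates"
                )

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def merge_searches(
    s1: Sequence[PeptideHit],
    s2: Sequence[PeptideHit],
    s3: Sequence[PeptideHit],
    query: EpitopePeptide,
    provenance: Mapping[str, object] | None = None,
) -> CandidateSet:
    """Union the three searches' hits by peptide sequence.

    ``found_by`` sets, window provenance and score annotations are merged;
    self-hits are set aside; output is deterministically ordered by peptide.
    Identical (protein, offset) coordinates claiming different peptides
    signal inconsistent inputs and raise :class:`AssemblyError`.
    """
    coord_claim: dict[tuple[str, int], str] = {}
    merged: dict[str, dict] = {}
    for hit in [*s1, *s2, *s3]:
        for w in hit.windows:
            key = (w.protein_id, w.offset)
            prior = coord_claim.get(key)
            if prior is not None and prior != w.peptide:
                raise AssemblyError(
                    f"window {w.protein_id}:{w.offset} claimed by both "
                    f"{prior!r} and {w.peptide!r}: inconsistent search inputs"
                )
            coord_claim[key] = w.peptide
        entry = merged.setdefault(
            hit.peptide,
            {"windows": set(), "found_by": set(), "scores": {}, "is_self": False},
        )
        entry["windows"].update(hit.windows)
        entry["found_by"].update(hit.found_by)
        entry["scores"].update(hit.scores)
        entry["is_self"] = entry["is_self"] or hit.is_self
    candidates = []
    self_hits = []
    for pep in sorted(merged):
        e = merged[pep]
        hit = PeptideHit(
            peptide=pep,
            windows=tuple(sorted(e["windows"], key=lambda w: (w.protein_id, w.offset))),
            found_by=frozenset(e["found_by"]),
            scores=dict(e["scores"]),
            is_self=e["is_self"],
        )
        (self_hits if hit.is_self else candidates).append(hit)
    return CandidateSet(
        candidates=tuple(candidates),
        query=query,
        provenance=dict(provenance or {}),
        self_hits=tuple(self_hits),
    )


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "peptide",
    "found_by",
    "n_windows",
    "protein_ids",
    "windows",
    "align_score",
    "binding_score",
    "binding_rank",
)


def _fmt_score(hit: PeptideHit, key: str) -> str:
    val = hit.scores.get(key)
    return "" if val is None else repr(float(val))


def hits_to_tsv(hits: Sequence[PeptideHit], path: str | Path) -> None:
    """Write hits as TSV (deterministic, peptide-sorted)."""
    lines = ["\t".join(_TSV_COLUMNS)]
    for h in sorted(hits, key=lambda h: h.peptide):
        windows = ";".join(f"{w.protein_id}:{w.offset}" for w in h.windows)
        lines.append(
            "\t".join(
                [
                    h.peptide,
                    ",".join(sorted(h.found_by)),
                    str(h.n_windows),
                    ";".join(h.protein_ids),
                    windows,
                    _fmt_score(h, "align_score"),
                    _fmt_score(h, "binding_score"),
                    _fmt_score(h, "binding_rank"),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def hits_from_tsv(path: str | Path, query: EpitopePeptide | None = None) -> list[PeptideHit]:
    """Read hits back from the TSV written by :func:`hits_to_tsv`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != list(_TSV_COLUMNS):
        raise AssemblyError(f"unrecognized hits TSV header in {path}")
    hits = []
    for line in lines[1:]:
        if not line.strip():
            continue
        pep, found_by, _, _, windows, a, b, r = line.split("\t")
        wins = []
        for token in windows.split(";"):
            protein_id, _, offset = token.rpartition(":")
            wins.append(
                PeptideWindow(peptide=pep, protein_id=protein_id, offset=int(offset))
            )
        scores = {}
        for key, raw in (("align_score", a), ("binding_score", b), ("binding_rank", r)):
            if raw:
                scores[key] = float(raw)
        hits.append(
            PeptideHit(
                peptide=pep,
                windows=tuple(wins),
                found_by=frozenset(found_by.split(",")),
                scores=scores,
                is_self=(query is not None and pep == query.sequence),
            )
        )
    return hits


def export_candidates(
    cset: CandidateSet, path: str | Path, format: str = "tsv"
) -> None:
    """Export the candidate list as TSV or FASTA.

    TSV carries the full per-candidate provenance; FASTA headers carry the
    candidate index and the searches that found it.
    """
    if format == "tsv":
        hits_to_tsv(cset.candidates, path)
    elif format == "fasta":
        records = [
            ProteinRecord(
                id=f"candidate_{i + 1}",
                sequence=h.peptide,
                description=f"found_by={','.join(sorted(h.found_by))}",
            )
            for i, h in enumerate(cset.candidates)
        ]
        write_fasta(records, path)
    else:
        raise AssemblyError(f"unknown export format {format!r}")


def write_provenance(cset: CandidateSet, path: str | Path) -> None:
    """Write the provenance snapshot as a YAML sidecar."""
    Path(path).write_text(
        yaml.safe_dump(dict(cset.provenance), sort_keys=True, default_flow_style=False)
    )


def proteome_digest(proteome: Sequence[ProteinRecord]) -> str:
    """SHA-256 digest over (id, sequence) pairs, order-sensitive."""
    h = hashlib.sha256()
    for rec in proteome:
        h.update(rec.id.encode())
        h.update(b"\x00")
        h.update(rec.sequence.encode())
        h.update(b"\x00")
    return h.hexdigest()


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_screen(
    proteome: Sequence[ProteinRecord],
    scan: PositionalScanTable,
    response_threshold: float = scan_interpret.DEFAULT_RESPONSE_THRESHOLD,
    binding_fold_threshold: float = scan_interpret.DEFAULT_BINDING_FOLD_THRESHOLD,
    classes: SimilarityClasses | None = None,
    matrix: SubstitutionMatrix | None = None,
    min_score: int | None = None,
    predictor: BindingPredictor | None = None,
    rank_threshold: float = hla_filter.DEFAULT_RANK_THRESHOLD,
    background_size: int = hla_filter.DEFAULT_BACKGROUND_SIZE,
    background_seed: int = 0,
    apply_binding_filter: bool = True,
) -> CandidateSet:
    """Full cross-reactivity screen: scan interpretation through candidates.

    Classifies scan positions, builds and expands the recognition motif,
    runs all three proteome searches, merges them, and (by default) filters
    the merged set by HLA-binding percentile rank against a seeded proteome
    background. The returned provenance snapshot is sufficient to reproduce
    the run bit-identically.
    """
    if classes is None:
        classes = SimilarityClasses.default()
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    if predictor is None:
        predictor = AnchorPSSM()
    query = scan.wild_type
    if min_score is None:
        min_score = align_search.default_min_score(query, matrix)

    classification = scan_interpret.classify_positions(
        scan, response_threshold, binding_fold_threshold
    )
    motif = scan_interpret.build_motif(classification, query)
    expanded = motif_search.expand_motif(motif, classes)
    s1 = motif_search.scan_proteome(proteome, motif, query=query, search_name="search1")
    s2 = motif_search.scan_proteome(
        proteome, expanded, query=query, search_name="search2"
    )
    s3 = align_search.search_by_similarity(
        query, proteome, matrix=matrix, min_score=min_score
    )
    provenance = {
        "query": query.sequence,
        "k": query.k,
        "response_threshold": response_threshold,
        "binding_fold_threshold": binding_fold_threshold,
        "contacts": sorted(classification.contacts),
        "anchors": sorted(classification.anchors),
        "motif": motif.to_regex(),
        "expanded_motif": expanded.to_regex(),
        "similarity_classes": {
            name: "".join(sorted(members)) for name, members in classes.groups.items()
        },
        "matrix": matrix.name,
        "gap_open": matrix.gap_open,
        "gap_extend": matrix.gap_extend,
        "min_score": min_score,
        "predictor": predictor.name,
        "rank_threshold": rank_threshold if apply_binding_filter else None,
        "background_size": background_size if apply_binding_filter else None,
        "background_seed": background_seed if apply_binding_filter else None,
        "proteome_sha256": proteome_digest(proteome),
        "n_proteins": len(proteome),
    }
    cset = merge_searches(s1, s2, s3, query, provenance=provenance)
    if apply_binding_filter:
        background = hla_filter.sample_background(
            proteome, k=query.k, n=background_size, seed=background_seed
        )
        filtered = hla_filter.filter_candidates(
            cset.candidates, predictor, background, rank_threshold
        )
        cset = CandidateSet(
            candidates=tuple(filtered),
            query=query,
            provenance=provenance,
            self_hits=cset.self_hits,
        )
    return cset
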