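"""Similarity search by exhaustive local alignment (Search 3).

The third search strategy looks for proteome peptides similar to the query
epitope without requiring any shared motif residue. At 9-mer query scale a
heuristic seeded search is unnecessary: the query is aligned against every
proteome window by full Smith-Waterman local alignment (Gotoh affine-gap
recurrences) under a substitution matrix, which is exact and reproducible.
Gap costs follow the NCBI convention: a gap of length L costs
``gap_open + gap_extend * L``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .peptide_core import (
    STANDARD_AA,
    EpitopePeptide,
    PeptideError,
    PeptideWindow,
    ProteinRecord,
    enumerate_windows,
)
from .motif_search import PeptideHit, _merge_windows_to_hits

DEFAULT_GAP_OPEN: int = 11
DEFAULT_GAP_EXTEND: int = 1
#: Default alignment-score acceptance threshold, as a fraction of the query
#: self-alignment score (rounded down).
DEFAULT_MIN_SCORE_FRACTION: float = 0.6

_AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_AA)}


class AlignmentError(ValueError):
    """Invalid alignment input (e.g. residue absent from the matrix)."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution matrix with affine gap penalties.

    Asserted at load: symmetry, and every diagonal entry being the maximum
    of its row (true for BLOSUM62), which guarantees a same-length window
    can never outscore the query's self-alignment.
    """

    name: str
    scores: Mapping[tuple[str, str], int]
    gap_open: int = DEFAULT_GAP_OPEN
    gap_extend: int = DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignmentError("gap penalties must be nonnegative")
        for a in STANDARD_AA:
            for b in STANDARD_AA:
                if (a, b) not in self.scores:
                    raise AlignmentError(f"matrix {self.name!r} missing pair ({a},{b})")
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise AlignmentError(f"matrix {self.name!r} asymmetric at ({a},{b})")
        for a in STANDARD_AA:
            row_max = max(self.scores[(a, b)] for b in STANDARD_AA)
            if self.scores[(a, a)] != row_max:
                raise AlignmentError(
                    f"matrix {self.name!r}: diagonal ({a},{a}) is not its row maximum"
                )

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise AlignmentError(
                f"residue pair ({a!r},{b!r}) absent from matrix {self.name!r}"
            ) from None

    def as_array(self) -> np.ndarray:
        """20x20 integer array indexed by :data:`STANDARD_AA` order."""
        arr = np.empty((20, 20), dtype=np.int32)
        for a, i in _AA_INDEX.items():
            for b, j in _AA_INDEX.items():
                arr[i, j] = self.scores[(a, b)]
        return arr

    @classmethod
    def blosum62(
        cls,
        gap_open: int = DEFAULT_GAP_OPEN,
        gap_extend: int = DEFAULT_GAP_EXTEND,
    ) -> "SubstitutionMatrix":
        mat = substitution_matrices.load("BLOSUM62")
        scores = {
            (a, b): int(mat[a, b]) for a in STANDARD_AA for b in STANDARD_AA
        }
        return cls(
            name="BLOSUM62", scores=scores, gap_open=gap_open, gap_extend=gap_extend
        )


@dataclass(frozen=True)
class AlignmentHit:
    """Optimal local alignment of the query against one target window.

    ``aligned_pairs`` holds 1-based (query_pos, target_pos) tuples; a gap is
    marked by None in the unconsumed slot.
    """

    window: PeptideWindow
    score: int
    aligned_pairs: tuple[tuple[int | None, int | None], ...]


def self_score(query: EpitopePeptide, matrix: SubstitutionMatrix) -> int:
    """Ungapped self-alignment score: the sum of diagonal matrix entries."""
    return sum(matrix.score(c, c) for c in query.sequence)


def default_min_score(query: EpitopePeptide, matrix: SubstitutionMatrix) -> int:
    return math.floor(DEFAULT_MIN_SCORE_FRACTION * self_score(query, matrix))


def local_align(
    query: EpitopePeptide,
    target: str,
    matrix: SubstitutionMatrix,
    window: PeptideWindow | None = None,
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment of ``query`` against ``target``.

    Affine gaps via the Gotoh three-state recurrence; cell scores clamped at
    zero per local-alignment semantics. One optimal traceback is returned,
    ties broken by preferring diagonal moves, then up (query-consuming),
    then left (target-consuming); within a gap state, closing the gap is
    preferred over extending it.
    """
    if not target:
        raise AlignmentError("target must be nonempty")
    q = query.sequence
    m, n = len(q), len(target)
    oc = matrix.gap_open + matrix.gap_extend  # cost of opening (first gap residue)
    ge = matrix.gap_extend
    NEG = -(10**9)
    # M: ends in an aligned pair; Ix: gap in target (consumes query);
    # Iy: gap in query (consumes target).
    M = [[0] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = matrix.score(qi, target[j - 1])
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0)
            M[i][j] = max(0, diag + s)
            Ix[i][j] = max(M[i - 1][j] - oc, Ix[i - 1][j] - ge)
            Iy[i][j] = max(M[i][j - 1] - oc, Iy[i][j - 1] - ge)
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    pairs: list[tuple[int | None, int | None]] = []
    if best > 0:
        i, j, state = bi, bj, "M"
        while i > 0 and j > 0:
            if state == "M":
                if M[i][j] == 0:
                    break
                pairs.append((i, j))
                s = matrix.score(q[i - 1], target[j - 1])
                prev = M[i][j] - s
                # tie-break: diagonal (M), then up (Ix), then left (Iy), then stop
                if prev == M[i - 1][j - 1] and M[i - 1][j - 1] > 0:
                    state = "M"
                elif prev == Ix[i - 1][j - 1]:
                    state = "Ix"
                elif prev == Iy[i - 1][j - 1]:
                    state = "Iy"
                else:
                    i, j = i - 1, j - 1
                    break
                i, j = i - 1, j - 1
            elif state == "Ix":
                pairs.append((i, None))
                state = "M" if Ix[i][j] == M[i - 1][j] - oc else "Ix"
                i -= 1
            else:  # Iy
                pairs.append((None, j))
                state = "M" if Iy[i][j] == M[i][j - 1] - oc else "Iy"
                j -= 1
    pairs.reverse()
    if window is None:
        window = PeptideWindow(peptide=target, protein_id="target", offset=1)
    return AlignmentHit(window=window, score=best, aligned_pairs=tuple(pairs))


def _encode_windows(windows: Sequence[PeptideWindow]) -> np.ndarray:
    """(n_windows, k) int8 array of alphabet indices."""
    k = len(windows[0].peptide)
    arr = np.empty((len(windows), k), dtype=np.int8)
    for r, w in enumerate(windows):
        for c, res in enumerate(w.peptide):
            arr[r, c] = _AA_INDEX[res]
    return arr


def score_windows(
    query: EpitopePeptide,
    windows: Sequence[PeptideWindow],
    matrix: SubstitutionMatrix,
) -> np.ndarray:
    """Optimal local-alignment score of ``query`` against each window.

    Vectorized Gotoh recurrence across windows (score only, no traceback);
    exact, identical to :func:`local_align` scores.
    """
    if not windows:
        return np.zeros(0, dtype=np.int32)
    codes = _encode_windows(windows)
    nw, k = codes.shape
    m = query.k
    sub = matrix.as_array()
    qidx = np.array([_AA_INDEX[c] for c in query.sequence])
    oc = matrix.gap_open + matrix.gap_extend
    ge = matrix.gap_extend
    NEG = np.int32(-(10**9) // 2)
    zeros = np.zeros(nw, dtype=np.int32)
    M_prev = np.zeros((k + 1, nw), dtype=np.int32)   # row i-1 of M, per j
    Ix_prev = np.full((k + 1, nw), NEG, dtype=np.int32)
    Iy_prev = np.full((k + 1, nw), NEG, dtype=np.int32)
    best = np.zeros(nw, dtype=np.int32)
    for i in range(1, m + 1):
        M_cur = np.zeros((k + 1, nw), dtype=np.int32)
        Ix_cur = np.full((k + 1, nw), NEG, dtype=np.int32)
        Iy_cur = np.full((k + 1, nw), NEG, dtype=np.int32)
        srow = sub[qidx[i - 1]]  # scores of q_i against each alphabet index
        for j in range(1, k + 1):
            s = srow[codes[:, j - 1]]
            diag = np.maximum(
                np.maximum(M_prev[j - 1], Ix_prev[j - 1]),
                np.maximum(Iy_prev[j - 1], zeros),
            )
            M_cur[j] = np.maximum(0, diag + s)
            Ix_cur[j] = np.maximum(M_prev[j] - oc, Ix_prev[j] - ge)
            Iy_cur[j] = np.maximum(M_cur[j - 1] - oc, Iy_cur[j - 1] - ge)
            np.maximum(best, M_cur[j], out=best)
        M_prev, Ix_prev, Iy_prev = M_cur, Ix_cur, Iy_cur
    return best


def search_by_similarity(
    query: EpitopePeptide,
    proteome: Sequence[ProteinRecord],
    matrix: SubstitutionMatrix | None = None,
    min_score: int | None = None,
    k: int | None = None,
) -> list[PeptideHit]:
    """Exhaustive local-alignment search of the query against all k-mer windows.

    Keeps windows whose optimal Smith-Waterman score reaches ``min_score``
    (default: 60% of the query self-score, rounded down) and merges them into
    deduplicated :class:`PeptideHit` records with ``found_by={'search3'}``
    and the alignment score annotated. Self-hits are flagged.
    """
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    if min_score is None:
        min_score = default_min_score(query, matrix)
    if min_score <= 0:
        raise AlignmentError(f"min_score {min_score} must be > 0")
    if k is None:
        k = query.k
    windows: list[PeptideWindow] = []
    for protein in proteome:
        windows.extend(enumerate_windows(protein, k))
    if not windows:
        return []
    scores = score_windows(query, windows, matrix)
    keep = [w for w, s in zip(windows, scores) if s >= min_score]
    score_by_pep = {
        w.peptide: int(s) for w, s in zip(windows, scores) if s >= min_score
    }
    hits = _merge_windows_to_hits(keep, "search3", query)
    return [
        PeptideHit(
            peptide=h.peptide,
            windows=h.windows,
            found_by=h.found_by,
            scores={"align_score": float(score_by_pep[h.peptide])},
            is_self=h.is_self,
        )
        for h in hits
    ]
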