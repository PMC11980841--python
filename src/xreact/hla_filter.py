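"""HLA-A*02:01 binding plausibility scoring and candidate filtering.

Cross-reactivity candidates are only dangerous if they can actually be
presented, so hits from the sequence searches are filtered by predicted MHC
binding. The predictor is a pluggable contract (higher score = stronger
predicted binding, deterministic, defined for all standard 9-mers); any
adapter honouring the contract — including a wrapper around an external
neural predictor — is interchangeable. The shipped default is a transparent
position-specific scoring matrix encoding the canonical HLA-A*02:01 anchor
preferences (aliphatic residues at positions 2 and 9). It is a declared
simplification, not a reimplementation of NetMHC-class predictors, and all
outputs record the predictor name.

Scores are reported as percentile ranks against a background of 9-mers
sampled from the analysed proteome (mirroring the rank convention of public
pMHC prediction servers): the rank of a peptide is the percentage of
background peptides scoring strictly better, so lower = stronger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .peptide_core import (
    STANDARD_AA,
    EpitopePeptide,
    PeptideError,
    ProteinRecord,
    enumerate_windows,
)
from .motif_search import PeptideHit

#: Conventional percentile-rank cutoff below which a peptide is called a
#: plausible binder.
DEFAULT_RANK_THRESHOLD: float = 2.0
#: Default background sample size for percentile-rank calibration.
DEFAULT_BACKGROUND_SIZE: int = 100_000

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


class BindingError(ValueError):
    """Invalid binding-prediction input."""


@runtime_checkable
class BindingPredictor(Protocol):
    """Contract for pMHC binding predictors.

    ``score`` is deterministic, defined for every peptide of
    ``supported_length`` over the standard alphabet, and oriented so that
    higher = stronger predicted binding (adapters invert affinity-like
    scales before exposing them here).
    """

    name: str
    supported_length: int

    def score(self, peptide: str) -> float: ...


def _default_a0201_weights() -> np.ndarray:
    """9x20 weight matrix for the default HLA-A*02:01 anchor PSSM.

    Strong positive weights for the canonical primary anchors (L/M at
    position 2, V/L/I at position 9), mildly favourable auxiliary residues,
    a proline penalty at the anchors (incompatible with the B and F
    pockets), and minor weights elsewhere.
    """
    w = np.zeros((9, 20))

    def put(pos: int, residue_weights: dict[str, float]) -> None:
        for res, val in residue_weights.items():
            w[pos - 1, _AA_INDEX[res]] = val

    put(1, {"F": 0.5, "Y": 0.5, "K": 0.3, "I": 0.2})
    put(2, {"L": 4.0, "M": 3.0, "I": 1.5, "V": 1.0, "A": 0.3, "T": 0.3, "P": -4.0})
    put(3, {"W": 0.2, "F": 0.2, "Y": 0.2})
    put(6, {"V": 0.2, "L": 0.2, "I": 0.2})
    put(9, {"V": 4.0, "L": 3.5, "I": 2.0, "A": 0.3, "M": 0.3, "P": -4.0})
    return w


@dataclass(frozen=True)
class AnchorPSSM:
    """Additive position-specific scoring matrix predictor.

    The score of a peptide is the sum over positions of the weight of its
    residue at that position. The built-in default encodes HLA-A*02:01
    anchor preferences.
    """

    weights: np.ndarray = field(default_factory=_default_a0201_weights)
    name: str = "anchor-pssm-A0201"

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.weights.shape[1] != 20:
            raise BindingError("PSSM weights must be (k, 20)")
        if not np.all(np.isfinite(self.weights)):
            raise BindingError("PSSM weights must be finite")

    @property
    def supported_length(self) -> int:
        return self.weights.shape[0]

    def score(self, peptide: str) -> float:
        if len(peptide) != self.supported_length:
            raise BindingError(
                f"peptide length {len(peptide)} unsupported by {self.name} "
                f"(expects {self.supported_length})"
            )
        try:
            idx = [_AA_INDEX[res] for res in peptide]
        except KeyError as exc:
            raise BindingError(f"non-standard residue in {peptide!r}") from exc
        return float(self.weights[np.arange(self.supported_length), idx].sum())


@dataclass(frozen=True)
class PercentileRank:
    """A score expressed against a background sample; lower = stronger."""

    rank: float
    background_size: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rank <= 100:
            raise BindingError(f"rank {self.rank} outside [0,100]")


def score_binding(peptide: EpitopePeptide | str, predictor: BindingPredictor) -> float:
    """Predicted binding strength of a peptide (higher = stronger)."""
    seq = peptide.sequence if isinstance(peptide, EpitopePeptide) else peptide
    return predictor.score(seq)


def sample_background(
    proteome: Sequence[ProteinRecord],
    k: int = 9,
    n: int = DEFAULT_BACKGROUND_SIZE,
    seed: int = 0,
) -> list[str]:
    """Sample ``n`` k-mers uniformly (with replacement) from a proteome's windows.

    The background underlying percentile ranks; the seed is recorded so the
    calibration is reproducible.
    """
    windows = [w.peptide for p in proteome for w in enumerate_windows(p, k)]
    if not windows:
        raise BindingError(f"proteome has no unambiguous {k}-mer windows")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(windows), size=n)
    return [windows[i] for i in idx]


def percentile_rank(
    peptide: EpitopePeptide | str,
    predictor: BindingPredictor,
    background: Sequence[str],
    seed: int | None = None,
) -> PercentileRank:
    """Percentile rank: 100 x (fraction of background scoring strictly higher).

    Ties count in the peptide's favour (a peptide matching the whole
    background ranks 0).
    """
    if not background:
        raise BindingError("background must be nonempty")
    s = score_binding(peptide, predictor)
    higher = sum(1 for b in background if predictor.score(b) > s)
    return PercentileRank(
        rank=100.0 * higher / len(background),
        background_size=len(background),
        seed=seed,
    )


def filter_candidates(
    hits: Sequence[PeptideHit],
    predictor: BindingPredictor,
    background: Sequence[str],
    rank_threshold: float = DEFAULT_RANK_THRESHOLD,
) -> list[PeptideHit]:
    """Retain hits whose percentile rank is <= ``rank_threshold``.

    Each retained hit's ``scores`` map is annotated with ``binding_score``
    and ``binding_rank``. Background scores are computed once and reused
    across hits.
    """
    if not 0 < rank_threshold <= 100:
        raise BindingError(f"rank_threshold {rank_threshold} outside (0,100]")
    if not background:
        raise BindingError("background must be nonempty")
    bg_scores = np.sort(np.array([predictor.score(b) for b in background]))
    n = len(bg_scores)
    retained = []
    for hit in hits:
        s = predictor.score(hit.peptide)
        higher = n - int(np.searchsorted(bg_scores, s, side="right"))
        rank = 100.0 * higher / n
        if rank <= rank_threshold:
            retained.append(
                replace(
                    hit,
                    scores={**hit.scores, "binding_score": s, "binding_rank": rank},
                )
            )
    return retained
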