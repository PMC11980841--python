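"""Positional-scan interpretation and recognition-motif construction.

A positional (alanine/glycine) scan substitutes each residue of an epitope
in turn and measures (a) the T cell effector response to the altered peptide
ligand and (b) its predicted MHC binding. Positions are classified as:

* **anchor** — the substitution worsens predicted MHC binding by at least a
  fold threshold; the residue docks the peptide into the MHC groove
  (canonically positions 2 and 9 of an HLA-A*02:01 9-mer), so loss of
  response is attributed to loss of presentation, not TCR contact;
* **contact** — binding is preserved but the response collapses below a
  fraction of the wild-type response; the residue contacts the TCR;
* **tolerant** — neither criterion fires.

Anchor takes precedence over contact. Contact positions, fixed to their
wild-type residues, define the TCR recognition motif used to search a
proteome for potentially cross-reactive peptides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

from .peptide_core import STANDARD_AA_SET, EpitopePeptide, PeptideError

#: Default response-abrogation threshold: a variant responding at <= 10% of
#: wild type counts as abrogated.
DEFAULT_RESPONSE_THRESHOLD: float = 0.1
#: Default binding-worsening fold for calling an anchor position.
DEFAULT_BINDING_FOLD_THRESHOLD: float = 5.0

PositionLabel = Literal["anchor", "contact", "tolerant"]
BindingOrientation = Literal["affinity", "score"]


class ScanError(ValueError):
    """Malformed or uninformative positional-scan input."""


@dataclass(frozen=True)
class ScanVariant:
    """One altered peptide ligand: a single-position substitution.

    ``predicted_binding`` is on the scale declared by the parent table's
    orientation: "affinity" (lower = stronger binding, e.g. IC50-like) or
    "score" (higher = stronger).
    """

    position: int
    substituted_residue: str
    response: float
    predicted_binding: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ScanError(f"variant position {self.position} must be >= 1")
        if self.substituted_residue not in STANDARD_AA_SET:
            raise ScanError(
                f"substituted residue {self.substituted_residue!r} not standard"
            )
        if self.response < 0:
            raise ScanError("variant response must be nonnegative")
        if self.predicted_binding <= 0:
            raise ScanError("predicted binding must be positive")


@dataclass(frozen=True)
class PositionalScanTable:
    """A complete single-substitution scan of one epitope.

    Exactly one variant per position 1..k. The substituted residue is alanine,
    or glycine where the wild-type residue already is alanine.
    """

    wild_type: EpitopePeptide
    wt_response: float
    wt_predicted_binding: float
    variants: tuple[ScanVariant, ...]
    orientation: BindingOrientation = "affinity"

    def __post_init__(self) -> None:
        if self.wt_response <= 0:
            raise ScanError("wild-type response must be positive")
        if self.wt_predicted_binding <= 0:
            raise ScanError("wild-type predicted binding must be positive")
        if self.orientation not in ("affinity", "score"):
            raise ScanError(f"unknown binding orientation {self.orientation!r}")
        k = self.wild_type.k
        positions = sorted(v.position for v in self.variants)
        if positions != list(range(1, k + 1)):
            raise ScanError(
                f"scan must have exactly one variant per position 1..{k}, "
                f"got positions {positions}"
            )
        for v in self.variants:
            wt_res = self.wild_type.residue(v.position)
            if v.substituted_residue == wt_res:
                raise ScanError(
                    f"variant at position {v.position} substitutes the wild-type "
                    f"residue {wt_res!r} with itself"
                )

    def variant_at(self, position: int) -> ScanVariant:
        for v in self.variants:
            if v.position == position:
                return v
        raise ScanError(f"no variant at position {position}")

    def binding_fold_worsening(self, position: int) -> float:
        """Fold by which the variant at ``position`` worsens predicted binding.

        Orientation-aware: for affinity-like values (lower = stronger) this is
        variant/wt; for score-like values it is wt/variant. 1.0 = unchanged,
        > 1 = worse.
        """
        v = self.variant_at(position)
        if self.orientation == "affinity":
            return v.predicted_binding / self.wt_predicted_binding
        return self.wt_predicted_binding / v.predicted_binding


@dataclass(frozen=True)
class PositionClassification:
    """Per-position anchor/contact/tolerant labels plus the thresholds used."""

    labels: tuple[PositionLabel, ...]
    response_threshold: float
    binding_fold_threshold: float

    @property
    def k(self) -> int:
        return len(self.labels)

    def positions(self, label: PositionLabel) -> frozenset[int]:
        """1-based positions carrying ``label``."""
        return frozenset(
            i + 1 for i, lab in enumerate(self.labels) if lab == label
        )

    @property
    def anchors(self) -> frozenset[int]:
        return self.positions("anchor")

    @property
    def contacts(self) -> frozenset[int]:
        return self.positions("contact")

    @property
    def tolerant(self) -> frozenset[int]:
        return self.positions("tolerant")


def classify_positions(
    scan: PositionalScanTable,
    response_threshold: float = DEFAULT_RESPONSE_THRESHOLD,
    binding_fold_threshold: float = DEFAULT_BINDING_FOLD_THRESHOLD,
) -> PositionClassification:
    """Classify each epitope position as anchor, contact or tolerant.

    Position p is **anchor** iff its variant worsens predicted binding by a
    fold >= ``binding_fold_threshold`` relative to wild type; otherwise
    **contact** iff response(p) <= ``response_threshold`` x wt_response
    (threshold inclusive); otherwise **tolerant**. Anchor precedence reflects
    that a presentation-destroying substitution abrogates the response for
    reasons other than TCR contact.
    """
    if not 0 < response_threshold < 1:
        raise ScanError(f"response_threshold {response_threshold} must be in (0,1)")
    if binding_fold_threshold <= 1:
        raise ScanError(
            f"binding_fold_threshold {binding_fold_threshold} must be > 1"
        )
    labels: list[PositionLabel] = []
    for p in range(1, scan.wild_type.k + 1):
        v = scan.variant_at(p)
        if scan.binding_fold_worsening(p) >= binding_fold_threshold:
            labels.append("anchor")
        elif v.response <= response_threshold * scan.wt_response:
            labels.append("contact")
        else:
            labels.append("tolerant")
    return PositionClassification(
        labels=tuple(labels),
        response_threshold=response_threshold,
        binding_fold_threshold=binding_fold_threshold,
    )


@dataclass(frozen=True)
class RecognitionMotif:
    """Per-position allowed-residue sets; a peptide matches iff every residue
    is in the allowed set at its position.

    Contact positions carry a singleton {wild-type residue}; anchor and
    tolerant positions carry the full alphabet (binding plausibility at
    anchors is enforced downstream by the HLA filter).
    """

    allowed: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        for i, s in enumerate(self.allowed):
            if not s:
                raise ScanError(f"motif position {i + 1} allows no residue")
            bad = s - STANDARD_AA_SET
            if bad:
                raise ScanError(
                    f"motif position {i + 1} allows non-standard {sorted(bad)}"
                )

    @property
    def k(self) -> int:
        return len(self.allowed)

    def matches(self, peptide: str) -> bool:
        if len(peptide) != self.k:
            return False
        return all(res in allow for res, allow in zip(peptide, self.allowed))

    def constrained_positions(self) -> frozenset[int]:
        """1-based positions whose allowed set is smaller than the alphabet."""
        return frozenset(
            i + 1
            for i, s in enumerate(self.allowed)
            if len(s) < len(STANDARD_AA_SET)
        )

    def to_regex(self) -> str:
        """Equivalent character-class regex (mainly for interchange)."""
        parts = []
        for s in self.allowed:
            if len(s) == len(STANDARD_AA_SET):
                parts.append(".")
            elif len(s) == 1:
                parts.append(next(iter(s)))
            else:
                parts.append("[" + "".join(sorted(s)) + "]")
        return "".join(parts)

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k, "allowed": ["".join(sorted(s)) for s in self.allowed]}
        )

    @classmethod
    def from_json(cls, text: str) -> "RecognitionMotif":
        data = json.loads(text)
        return cls(allowed=tuple(frozenset(s) for s in data["allowed"]))


def build_motif(
    classification: PositionClassification, wild_type: EpitopePeptide
) -> RecognitionMotif:
    """Build the contact-residue recognition motif from a classification.

    Raises :class:`ScanError` if no position is a contact — the motif would
    match every k-mer, signalling an uninformative scan.
    """
    if classification.k != wild_type.k:
        raise ScanError(
            f"classification length {classification.k} != peptide length {wild_type.k}"
        )
    if not classification.contacts:
        raise ScanError("no contact positions: motif would match everything")
    allowed = []
    for p in range(1, wild_type.k + 1):
        if p in classification.contacts:
            allowed.append(frozenset(wild_type.residue(p)))
        else:
            allowed.append(STANDARD_AA_SET)
    return RecognitionMotif(allowed=tuple(allowed))


# ---------------------------------------------------------------------------
# TSV interchange: columns position, substituted_residue, response,
# predicted_binding; '#key=value' header lines carry the wild type, wild-type
# readouts and the binding orientation.
# ---------------------------------------------------------------------------

def write_scan_tsv(scan: PositionalScanTable, path: str | Path) -> None:
    lines = [
        f"#wild_type={scan.wild_type.sequence}",
        f"#wt_response={scan.wt_response!r}",
        f"#wt_predicted_binding={scan.wt_predicted_binding!r}",
        f"#orientation={scan.orientation}",
        "position\tsubstituted_residue\tresponse\tpredicted_binding",
    ]
    for v in sorted(scan.variants, key=lambda v: v.position):
        lines.append(
            f"{v.position}\t{v.substituted_residue}\t{v.response!r}\t"
            f"{v.predicted_binding!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_scan_tsv(path: str | Path) -> PositionalScanTable:
    meta: dict[str, str] = {}
    variants: list[ScanVariant] = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif not header_seen:
            header_seen = True  # column header row
        else:
            pos, res, resp, bind = line.split("\t")
            variants.append(
                ScanVariant(
                    position=int(pos),
                    substituted_residue=res,
                    response=float(resp),
                    predicted_binding=float(bind),
                )
            )
    missing = {"wild_type", "wt_response", "wt_predicted_binding"} - set(meta)
    if missing:
        raise ScanError(f"scan TSV missing header field(s) {sorted(missing)}")
    return PositionalScanTable(
        wild_type=EpitopePeptide(meta["wild_type"]),
        wt_response=float(meta["wt_response"]),
        wt_predicted_binding=float(meta["wt_predicted_binding"]),
        variants=tuple(variants),
        orientation=meta.get("orientation", "affinity"),  # type: ignore[arg-type]
    )
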