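# Methods

## Problem and model

A TCR engages a peptide-MHC complex through a subset of the peptide's side
chains. For an MHC class I 9-mer, two kinds of positions matter differently:
**anchor** positions dock the peptide into the MHC groove (for HLA-A\*02:01,
canonically positions 2 and 9, preferring aliphatic residues), and
**contact** positions face the TCR. A single-substitution (alanine, or
glycine where the wild type is alanine) scan separates them: substituting an
anchor abolishes *presentation* (visible as a collapse in predicted MHC
binding), while substituting a contact abolishes *recognition* (the effector
response collapses although binding is preserved).

The screening model is deliberately conservative and transparent: a
candidate cross-reactive peptide is any proteome 9-mer that either (i)
conserves all contact residues exactly, (ii) conserves them up to
physicochemical similarity, or (iii) resembles the epitope under local
alignment regardless of the motif — intersected with the requirement that
the peptide be a plausible HLA-A\*02:01 binder. The three routes are
complementary: (i) ⊆ (ii) by construction, and (iii) catches register-true
lookalikes that break the motif at a contact while compensating elsewhere.

## Position classification

Given a scan table with wild-type response `R_wt` and per-position variants,
position `p` is labelled:

- **anchor** iff the variant's predicted binding worsens by a fold
  ≥ `theta_b` relative to wild type (orientation-aware: variant/wt on
  affinity-like scales where lower is stronger, wt/variant on score-like
  scales);
- else **contact** iff `R_p ≤ theta_r × R_wt` (inclusive);
- else **tolerant**.

Anchor takes precedence over contact: a substitution that destroys
presentation also destroys the response, so the response readout carries no
information about TCR contact at that position.

Defaults are `theta_r = 0.1` and `theta_b = 5`. "Almost completely
abrogated" responses in scan data are typically ≤ a few percent of wild
type while tolerated substitutions stay near wild type, so any threshold in
roughly 0.05–0.3 separates them; 0.1 is the conventional order-of-magnitude
cut. A 5-fold worsening of predicted affinity is far outside predictor
noise yet far below the ~100-fold collapse an anchor substitution actually
causes. Both thresholds are mandatory, recorded parameters of every result,
not estimated from data (single-concentration scans carry too little
information to fit them).

The motif fixes contact positions to the wild-type residue and leaves all
other positions — anchors included — unconstrained; binding plausibility at
anchors is enforced by the downstream filter instead, which evaluates the
whole peptide rather than one position. A scan yielding zero contacts is
rejected as uninformative (the motif would match the entire proteome).

## Similarity classes (Search 2)

The default partition is {A,G}, {I,L,M,V}, {F,W,Y}, {K,R,H}, {D,E}, {N,Q},
{S,T}, {C}, {P} — the standard small / aliphatic / aromatic / basic /
acidic / amide / hydroxyl grouping, with cysteine and proline kept apart
for their distinctive chemistry. The partition is a configurable parameter
(`SimilarityClasses`); the pipeline's guarantees (Search-1 ⊆ Search-2,
planted recall) hold for any partition because expansion is reflexive.
Expansion is applied to constrained (contact) positions only: anchors are
already unconstrained in the motif, and widening tolerant positions is
meaningless.

## Alignment search (Search 3)

Realized as exhaustive Smith-Waterman local alignment of the 9-mer query
against every unambiguous proteome window, under BLOSUM62 with affine gaps
(NCBI convention, a gap of length L costs `open + extend × L`; defaults
open 11, extend 1). For a 9-residue query, exhaustive alignment is exact,
fast and version-independent, which is why it replaces a heuristic seeded
search here; no E-value statistics are computed, and acceptance is a plain
score threshold recorded in the output. The default threshold is
`floor(0.6 × self_score)` — 26 for FLSNDTVQL, whose self-score (the BLOSUM62
diagonal sum) is 44. 60% of self-score admits roughly two to three
non-conservative substitutions' worth of divergence, about where TCR
cross-recognition of 9-mers becomes chemically implausible, while staying
high enough that random windows essentially never qualify.

Numerics: the production scorer is a vectorized Gotoh recurrence across all
windows (score only); tracebacks are computed per reported hit by a scalar
three-state DP. Cell scores clamp at zero (local semantics), optimal
alignments never end in a gap because gap penalties are positive, and
traceback ties are broken deterministically: diagonal, then up
(query-consuming), then left, preferring to close a gap over extending it.
The matrix loader asserts symmetry and that each diagonal entry is its row
maximum — the property that makes the query self-hit provably maximal among
same-length windows.

## Binding filter

The predictor contract is: deterministic, defined for all standard-alphabet
9-mers, higher score = stronger predicted binding (adapters invert
affinity-like scales at the boundary). Scores are converted to **percentile
ranks** against a background of `n = 100,000` 9-mers sampled uniformly with
replacement, with a recorded seed, from the proteome under analysis —
self-contained, reproducible, and matched in composition to the search
space. Rank = 100 × (fraction of background scoring *strictly* higher), so
ties favour the candidate; hits with rank ≤ 2.0 (the conventional binder
cutoff) are retained, and every output records predictor name, score and
rank. The filter is applied uniformly to the merged hits of all three
searches.

The shipped default predictor is an additive 9×20 position-specific scoring
matrix encoding canonical HLA-A\*02:01 preferences: strong positive weights
for L/M/I/V at position 2 and V/L/I at position 9, small auxiliary weights
at positions 1, 3 and 6, a proline penalty at both anchors, and zero
elsewhere. It is a declared simplification — adequate to rank anchor-intact
peptides above anchor-destroyed ones, which is all the pipeline's own logic
requires — not a substitute predictor for real screening decisions, where a
user should plug a full pMHC predictor into the contract.

## Dose translation

Human adoptive-cell doses are prescribed in cells/kg; xenograft doses in
cells/mouse. Under weight-based scaling,
`cells_per_mouse = cells_per_kg × mouse_mass`, with the adult NSG mouse
default `mouse_mass = 0.02 kg` (20 g), always overridable. Fold-excess is
the plain ratio of an experimental dose to the proportional dose. For the
worked numbers: 0.5–1 × 10⁶ cells/kg maps to 1–2 × 10⁴ cells/mouse, so a
5 × 10⁶ cells/mouse experimental dose is 250- to 500-fold above the
proportional range. Only linear per-kg scaling is implemented; body-surface
area and allometric exponents are out of scope.

## Synthetic data: what it emulates, and what it does not

`generate_proteome` draws background residues i.i.d. (uniform by default;
any 20-vector of frequencies may be supplied) and overwrites planted
peptides at non-overlapping random positions, recording every coordinate in
a truth table. Plant labels map one-to-one onto pipeline stages:
`exact_motif` → Search 1, `class_variant` (one contact substituted within
its class) → Search 2 only, `align_decoy` (one contact substituted by the
best-scoring out-of-class residue) → Search 3 only, `nonbinder_decoy`
(anchors replaced by proline) → found then removed by the filter.

`generate_scan_table` plants contact positions at 2% of the wild-type
response, tolerant positions at 90%, and anchors at a 100-fold affinity
worsening with a suppressed response (a non-presented peptide cannot
stimulate), under multiplicative log-normal noise (default σ = 0.2) on
every readout. Wild-type response defaults to 1000 (the scale of an
overnight-coculture IFN-γ ELISA in pg/ml) and wild-type predicted binding
to 20 (an affinity-like scale, lower = stronger). With these magnitudes the
planted classes sit many noise standard deviations from the thresholds,
which is why classification recovers them in ≥ 99% of replicates at
σ = 0.2 — the margin, not the noise model, is doing the work.

What passing these benchmarks does **not** show: real proteomes are not
i.i.d. (repeats, paralogs, biased composition inflate motif hit counts);
real scan data can show partial, position-coupled effects that a
single-threshold classifier cannot express; and the default PSSM is not a
validated binding predictor. Synthetic recall demonstrates the machinery is
correct, not that a real screen with these defaults would be exhaustive.

## Degenerate inputs and conventions

All coordinates are 1-based with closed intervals. Input peptides are
case-normalized to uppercase; queries must be pure standard alphabet, while
proteome sequences may contain ambiguity codes (X, B, Z, J, O, and U —
selenocysteine is treated as ambiguity, not mapped to C), and any window
containing one is skipped rather than erroring. `k` longer than a protein
yields no windows, not an error. Duplicate FASTA ids are rejected. Hits are
always reported sorted by peptide, then protein id, then offset, making
every output byte-deterministic for fixed inputs and seeds; the provenance
snapshot (query, thresholds, classes, matrix and gap costs, min-score,
predictor, background size and seed, proteome SHA-256) is sufficient to
reproduce a run bit-identically.

## Benchmark problem sizes

The packaged test suite and acceptance script run on synthetic proteomes of
~10⁴ residues (40–60 proteins of 200–300 residues), 50-proteome batches for
the brute-force oracle comparisons, 1,000 replicates for scan-recovery
rates, and rank backgrounds of 10,000–100,000 peptides — sizes at which the
independent oracles (regex scans, quadratic DP) remain exact and the whole
suite runs in about a minute, while every scaling-relevant code path
(vectorized alignment, merged provenance, background calibration) is
exercised. The library itself has no such limits; a full human proteome
(~10⁷ residues) is a linear scan for Searches 1–2 and a few minutes of
vectorized alignment for Search 3.
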