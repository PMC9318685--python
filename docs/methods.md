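# Methods

## Signature-indel model

A conserved signature indel (CSI) is modelled as a gap block in a protein
multiple-sequence alignment satisfying three criteria relative to a named
clade partition (ingroup vs outgroup):

1. **Exclusivity.** All ingroup taxa present in the alignment carry one
   character state (residues or gap) across the block and all outgroup
   taxa the other, up to `max_ingroup_exceptions` and
   `max_outgroup_sharing` tolerated violations (both default 0).
   Polarity — insertion vs deletion in the ingroup — is called against
   the outgroup *majority* state, the outgroup serving as ancestral
   proxy. An outgroup exactly split between states yields no call
   (`pattern_mixed`): a majority that does not exist cannot anchor
   polarity.
2. **Fixed length.** The indel length, measured as residues carried by
   the state-bearing side, must lie in `[min_indel_len, max_indel_len]`
   (defaults 1–25). Bearing taxa may carry slightly different residue
   counts inside one block; the record then reports a length range
   (e.g. "2–4 aa ins"), as real catalogues do.
3. **Flank conservation.** Each side of the block must contain at least
   `min_flank_conserved` conserved columns (default 5) within a window
   of `flank_window` columns (default 40, counted per side). A column is
   conserved when ≥ 2 rows are non-gap and the modal residue covers at
   least `flank_conservation_fraction` (default 0.8) of the non-gap
   rows; `X` matches nothing, including itself. Conservation is
   computed over ingroup *and* outgroup rows, since genuine signature
   flanks are conserved across all compared taxa. The criterion in the
   field is phrased as "4–5 conserved residues in the neighbouring
   40–50"; the defaults sit at the strict ends and are configurable,
   conserved columns need not be consecutive, and whether the window is
   per side or total is interpreted as per side.

A **gap block** is a maximal run of columns each containing at least one
gap among the partition's taxa, bounded by gap-free columns. Taxa fully
gapped across the run form `gapped_taxa`; taxa with ≥ 1 residue form
`bearing_taxa` with per-taxon residue counts. This definition (rather
than runs of strictly constant per-column gap membership) is what allows
a single block to represent a variable-length indel; adjacent or
overlapping signals are reported independently, never merged.

Ingroup taxa absent from an alignment ("missing homologs") are excluded
from the sharing test and counted separately by default; a strict mode
counts them as violations. Reported positions are 1-based residue
coordinates in a designated reference sequence (default: first ingroup
taxon in alignment order) and delimit the fragment spanning the indel
± 20 reference residues, matching how catalogue position ranges describe
fragments rather than exact indel columns.

The scanner asserts exclusivity only against the supplied outgroup —
database-wide re-validation of each marker is outside its scope, and the
JSON output records that limitation.

## Query matching and classification

`match_query` extracts `flank_length` (default 15) reference residues on
each side of the indel and locates both flanks in each query protein by
Smith–Waterman local alignment (BLOSUM62, gap open 11 / extend 1).
Unaligned flank overhangs are projected onto the query and counted as
mismatches, so a flank must genuinely match end to end; each flank
tolerates `max_flank_mismatches` (default 3). When both flanks match,
the intervening query segment length is compared with the ingroup state
(within the record's length range for insertions, zero for deletions)
and the outgroup state; the best-scoring protein decides
`csi_present` / `csi_absent`, and a query with no matching flank pair is
`protein_not_found`. A segment length matching neither state reports
`csi_absent`: the signature as defined is not carried. Classification
over a catalogue reports per-clade counts ("k of n CSIs present") and a
verdict only when at least one marker is present; all-not-found yields
"undetermined".

## POCP

POCP(1,2) = 100·(C1+C2)/(T1+T2), with Ci the number of genome *i*'s
proteins having ≥ 1 match in the other genome at E-value ≤ 1e-5,
identity ≥ 40% and alignable fraction ≥ 50% of the query (the standard
POCP thresholds; all three exposed in `MatchParams`). Matching is
one-directional per side; reciprocity is not required. The similarity
search is a pluggable contract `aligner(query, target) -> (identity_pct,
alignable_fraction, evalue)`; the default backend is Biopython's
Smith–Waterman with BLOSUM62/11/1 and a Karlin–Altschul E-value
E = K·m·n·exp(−λS) using the standard gapped constants for that scheme
(λ = 0.267, K = 0.041). Because E is a function of the score alone, the
implementation screens every pair with a score-only pass and computes
the traceback (needed for identity and coverage) only for pairs already
passing the E-value bar — an exact optimisation, not a heuristic.
Identical sequences short-circuit the target search but still pass
through the threshold test.

## AAI and core families

AAI is computed from a concatenated core-protein alignment: identical
residue pairs over jointly non-gap columns (the jointly-non-gap
convention is an explicit choice; `X` never scores as identical). This
makes AAI(concatenation) exactly the weighted mean of per-family AAIs
with jointly-non-gap column counts as weights — an identity the tests
assert. The AAI path shares no code with POCP.

Core-family filtering anchors to the reference genome's member: a family
is accepted iff every member has ≥ 50% identity to the reference member
and ≥ 50% of its length, and the family occupies ≥ 80% of the input
genomes. The anchor-to-reference reading (rather than all-pairs) is a
deliberate choice surfaced in `CoreFilterThresholds`.

Single-linkage grouping of a similarity matrix at a threshold (scipy
hierarchical clustering on the complement distance) is provided for the
two-family block-structure analysis; matrix output order always follows
input order — visual ordering in published heatmaps is presentation, not
computation.

## Synthetic data

`generate_family` emulates exactly the structure the scan assumes: a
uniform random ancestor, descendants mutated per site at
`background_sub_rate` (default 0.05) under a uniform replacement model,
a planted indel present in all ingroup and no outgroup taxa, and flank
windows (width 40 per side) in which an exact `flank_conservation`
fraction of columns is frozen across all taxa. Freezing an exact
fraction (not per-site coin flips) makes planted-marker recovery a
deterministic guarantee whenever the frozen count reaches the scan's
flank threshold, so the 100%-recovery property is provable rather than
probabilistic. Because substitutions never create gaps, the planted
block is the only gap signal — recovery tests are therefore clean of
alignment-ambiguity effects. Default sizes (10 ingroup, 8 outgroup,
~120-residue proteins) mirror the 8–10-sequences-per-side working sets
typical of signature scanning.

What the generator does *not* emulate: tree-structured evolution,
empirical substitution matrices, alignment-program gap-placement
ambiguity, or indel evolution beyond the single planted event. Passing
tests therefore demonstrate correctness of the detection logic under the
model's assumptions, not robustness to mis-alignment — the alignment is
always treated as given, consistent with treating MSA construction as an
upstream step.

`generate_proteome_set` builds genomes from three pools — proteins
shared by all genomes, proteins shared within a group, and unique random
proteins — so every pair's expected POCP is a closed form:
100·(B+W)/P within groups, 100·B/P between. With identical shared
copies the measured POCP equals the expectation exactly; random unique
proteins (length ≥ 50) cannot reach the match thresholds, which the
zero-sharing tests verify empirically. Every generator takes an explicit
seed; there is no hidden global random state.

## Numerical and formatting choices

* Positions are 1-based inclusive throughout; alignment columns and
  reference-sequence residues are distinct coordinate systems and named
  as such.
* Rejections are values with typed reasons (`not_exclusive`,
  `flank_left_weak`, `flank_right_weak`, `too_short`, `too_long`,
  `pattern_mixed`), never exceptions; an empty scan result is a valid
  outcome with exit code 0.
* Record ordering is deterministic: `(col_start, col_end, polarity)`.
* Excerpt rendering is lossless: `-` means identity with the top line,
  `.` means gap, so replacing dashes by the top-line residue inverts the
  rendering exactly; the indel columns are flagged by a caret line.
  Variable-length sizes print with an en dash ("2–4 aa ins") as in the
  conventional table format.
* Ambiguity codes B/Z/J/U/O/`*` normalise to `X` on load; genuinely
  illegal characters raise with the offending position. All-gap columns
  are stripped on load.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use 200 synthetic families
(planted lengths 1–12, both polarities), 40–50 indel-free negative
controls, 500 random-relabelling nulls, 500 random alignments (≤ 8 taxa
× 80 columns) for the brute-force gap-block oracle, proteome pairs of
100 proteins and 6-genome sets of 24–30 proteins (lengths 50–120) for
POCP, and 20–50 two-family separation trials. These sizes were chosen so
the full validation runs in a few minutes on a single core while keeping
every check exact (closed-form equalities, not tolerances).

## Known limitations

* Exclusivity is relative to the supplied outgroup; a marker can be
  clade-exclusive in the alignment yet present elsewhere in sequence
  space. Database-wide validation is out of scope by design.
* The permutation-null utility bounds the chance of a planted marker
  surviving random relabelling; no analytical significance model for
  indels is provided.
* `match_query` assumes the query proteome is complete; fragmented
  assemblies can turn `csi_present` into `protein_not_found`.
* The default E-value constants are calibrated for BLOSUM62 with 11/1
  gaps; plugging a different scoring scheme into the contract requires
  supplying a consistent E-value (or score threshold) of its own.
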