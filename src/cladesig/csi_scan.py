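"""Detection of conserved signature indels (CSIs) in protein alignments.

A CSI is a fixed-length insertion or deletion that (a) is shared by all (or
all but a tolerated few) members of a named clade, (b) is absent from every
outgroup homolog, and (c) sits inside a conserved region — the alignment
columns on both sides of the indel must contain a minimum number of
conserved positions within a fixed window.  Such indels arise from rare
genetic events and serve as synapomorphies: molecular evidence, independent
of tree topology, that the clade's members share an exclusive common
ancestor.

The scan proceeds in three steps:

1. :func:`find_gap_blocks` extracts every maximal run of alignment columns
   containing at least one gap among the partition's taxa;
2. :func:`evaluate_candidate` tests one block for clade exclusivity and
   flank conservation, producing a :class:`CsiRecord` or a typed
   :class:`Rejection`;
3. :func:`scan_alignment` composes the two and orders accepted records.

:func:`match_query` performs the converse operation: given a known CSI and
a query proteome, it locates the signature region in the query by local
alignment of the indel's flanks and reads off whether the query carries the
ingroup or the outgroup state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import Alignment, CladePartition, PartitionError, Proteome

__all__ = [
    "ScanParams",
    "GapBlock",
    "FlankEvidence",
    "SharingStats",
    "CsiRecord",
    "Rejection",
    "RejectionReason",
    "MatchOutcome",
    "MatchParams",
    "INSERTION",
    "DELETION",
    "column_conservation",
    "find_gap_blocks",
    "evaluate_candidate",
    "scan_alignment",
    "variable_length_summary",
    "match_query",
]

INSERTION = "insertion_in_ingroup"
DELETION = "deletion_in_ingroup"

#: Number of reference residues included on each side of the indel when a
#: record's reported fragment coordinates are computed.  The published
#: catalogue positions describe such a fragment, not the indel itself.
REPORT_FLANK = 20


@dataclass(frozen=True)
class ScanParams:
    """Tunable thresholds of the signature-indel scan.

    min_flank_conserved
        Conserved columns required on *each* side of a candidate indel
        (the "minimally 4–5 conserved residues" criterion; strict end 5).
    flank_window
        Columns examined per side when counting conserved columns (the
        "neighbouring 40–50 residues"; strict end 40, counted per side).
    flank_conservation_fraction
        Fraction of non-gap rows that must carry the consensus residue for
        a column to count as conserved.  1.0 demands strict identity;
        the default 0.8 reflects that published signature flanks are
        conserved but not invariant.
    max_ingroup_exceptions
        Ingroup taxa allowed to violate the clade's indel state.
    max_outgroup_sharing
        Outgroup taxa allowed to share the ingroup state before the
        candidate fails the exclusivity test.
    min_indel_len / max_indel_len
        Accepted indel length range in residues.
    treat_missing_homolog_as
        ``"excluded"`` (default): ingroup taxa absent from the alignment
        are counted separately and excluded from the sharing test;
        ``"violation"``: they count against ``max_ingroup_exceptions``.
    """

    min_flank_conserved: int = 5
    flank_window: int = 40
    flank_conservation_fraction: float = 0.8
    max_ingroup_exceptions: int = 0
    max_outgroup_sharing: int = 0
    min_indel_len: int = 1
    max_indel_len: int = 25
    treat_missing_homolog_as: str = "excluded"

    def __post_init__(self) -> None:
        if self.min_flank_conserved > self.flank_window:
            raise ValueError("min_flank_conserved exceeds flank_window")
        for name in ("min_flank_conserved", "flank_window",
                     "max_ingroup_exceptions", "max_outgroup_sharing",
                     "min_indel_len", "max_indel_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.flank_conservation_fraction <= 1.0:
            raise ValueError("flank_conservation_fraction must be in (0, 1]")
        if self.min_indel_len > self.max_indel_len:
            raise ValueError("min_indel_len exceeds max_indel_len")
        if self.treat_missing_homolog_as not in ("excluded", "violation"):
            raise ValueError("treat_missing_homolog_as must be "
                             "'excluded' or 'violation'")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class GapBlock:
    """A maximal run of alignment columns each containing at least one gap
    among the taxa under consideration.

    ``gapped_taxa`` are fully gapped across the block; ``bearing_taxa``
    carry at least one residue in it.  ``per_taxon_residue_count`` records
    how many residues each bearing taxon contributes — unequal counts are
    what produce variable-length catalogue entries such as "2–4 aa ins".
    Columns immediately outside the block are gap-free.
    """

    col_start: int  # 1-based, inclusive
    col_end: int
    gapped_taxa: frozenset[str]
    bearing_taxa: frozenset[str]
    per_taxon_residue_count: dict[str, int]

    @property
    def width(self) -> int:
        return self.col_end - self.col_start + 1

    def to_dict(self) -> dict:
        return {
            "col_start": self.col_start,
            "col_end": self.col_end,
            "gapped_taxa": sorted(self.gapped_taxa),
            "bearing_taxa": sorted(self.bearing_taxa),
            "per_taxon_residue_count": dict(self.per_taxon_residue_count),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GapBlock":
        return cls(d["col_start"], d["col_end"],
                   frozenset(d["gapped_taxa"]), frozenset(d["bearing_taxa"]),
                   dict(d["per_taxon_residue_count"]))


@dataclass(frozen=True)
class FlankEvidence:
    """Conserved-column count observed in one flank window."""

    conserved_columns: int
    window_used: int


@dataclass(frozen=True)
class SharingStats:
    n_ingroup_conforming: int
    n_ingroup_violating: int
    n_ingroup_missing_homolog: int
    n_outgroup_sharing: int


@dataclass(frozen=True)
class CsiRecord:
    """One accepted conserved signature indel with its full evidence."""

    protein: str
    polarity: str  # INSERTION or DELETION
    length_min: int
    length_max: int
    ref_position_start: int
    ref_position_end: int
    block: GapBlock
    flank_left: FlankEvidence
    flank_right: FlankEvidence
    sharing: SharingStats
    params_used: ScanParams
    reference_taxon: str
    clade: str = ""
    accession: str = ""
    ingroup_present: tuple[str, ...] = ()
    outgroup_present: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.length_min <= self.length_max:
            raise ValueError("invalid indel length range")

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein, self.ref_position_start)

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "accession": self.accession,
            "clade": self.clade,
            "polarity": self.polarity,
            "length_min": self.length_min,
            "length_max": self.length_max,
            "ref_position_start": self.ref_position_start,
            "ref_position_end": self.ref_position_end,
            "reference_taxon": self.reference_taxon,
            "block": self.block.to_dict(),
            "flank_left": vars(self.flank_left).copy(),
            "flank_right": vars(self.flank_right).copy(),
            "sharing": vars(self.sharing).copy(),
            "params_used": self.params_used.to_dict(),
            "ingroup_present": list(self.ingroup_present),
            "outgroup_present": list(self.outgroup_present),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CsiRecord":
        return cls(
            protein=d["protein"],
            accession=d.get("accession", ""),
            clade=d.get("clade", ""),
            polarity=d["polarity"],
            length_min=d["length_min"],
            length_max=d["length_max"],
            ref_position_start=d["ref_position_start"],
            ref_position_end=d["ref_position_end"],
            reference_taxon=d["reference_taxon"],
            block=GapBlock.from_dict(d["block"]),
            flank_left=FlankEvidence(**d["flank_left"]),
            flank_right=FlankEvidence(**d["flank_right"]),
            sharing=SharingStats(**d["sharing"]),
            params_used=ScanParams(**d["params_used"]),
            ingroup_present=tuple(d.get("ingroup_present", ())),
            outgroup_present=tuple(d.get("outgroup_present", ())),
        )


class RejectionReason(str, enum.Enum):
    NOT_EXCLUSIVE = "not_exclusive"
    FLANK_LEFT_WEAK = "flank_left_weak"
    FLANK_RIGHT_WEAK = "flank_right_weak"
    TOO_LONG = "too_long"
    TOO_SHORT = "too_short"
    PATTERN_MIXED = "pattern_mixed"


@dataclass(frozen=True)
class Rejection:
    """A candidate gap block that failed one of the acceptance tests."""

    block: GapBlock
    reason: RejectionReason
    detail: str = ""


# ---------------------------------------------------------------------------
# Step 1 — column conservation and gap blocks


def _considered_taxa(alignment: Alignment,
                     partition: CladePartition) -> list[str]:
    """Partition taxa present in the alignment, in alignment order.  Taxa in
    the alignment but in neither partition side are excluded from scanning
    (homolog sets routinely contain extra sequences)."""
    return [t for t in alignment.ids if t in partition.taxa]


def column_conservation(alignment: Alignment, params: ScanParams,
                        taxa: Sequence[str] | None = None) -> np.ndarray:
    """Per-column conservation flags.

    A column is conserved when at least two of the examined rows are
    non-gap and the most frequent residue among them (``X`` never counts:
    it matches nothing, not even itself) occurs in at least
    ``flank_conservation_fraction`` of the non-gap rows.
    """
    rows = [alignment.residues(t) for t in taxa] if taxa is not None \
        else list(alignment.seqs)
    mat = np.frombuffer("".join(rows).encode("ascii"),
                        dtype="S1").reshape(len(rows), -1)
    gap = mat == b"-"
    unknown = mat == b"X"
    n_nongap = (~gap).sum(axis=0)
    flags = np.zeros(mat.shape[1], dtype=bool)
    fraction = params.flank_conservation_fraction
    for c in np.nonzero(n_nongap >= 2)[0]:
        col = mat[:, c]
        counting = col[~gap[:, c] & ~unknown[:, c]]
        if counting.size == 0:
            continue
        _, counts = np.unique(counting, return_counts=True)
        flags[c] = counts.max() >= fraction * n_nongap[c]
    return flags


def find_gap_blocks(alignment: Alignment,
                    partition: CladePartition) -> list[GapBlock]:
    """Maximal runs of gap-containing columns among the partition's taxa.

    Each returned block is flanked by gap-free columns (or the alignment
    ends); within a block, a taxon gapped in every column is recorded in
    ``gapped_taxa`` and every other taxon in ``bearing_taxa`` together with
    its residue count.  Blocks are ordered by ``col_start``.
    """
    taxa = _considered_taxa(alignment, partition)
    present = set(taxa)
    for side_name, side in (("ingroup", partition.ingroup),
                            ("outgroup", partition.outgroup)):
        if not (side & present):
            raise PartitionError(
                f"partition side absent from alignment: no {side_name} taxa found")

    rows = [alignment.residues(t) for t in taxa]
    mat = np.frombuffer("".join(rows).encode("ascii"),
                        dtype="S1").reshape(len(rows), -1)
    gap = mat == b"-"
    gappy = gap.any(axis=0)

    blocks: list[GapBlock] = []
    n_cols = mat.shape[1]
    c = 0
    while c < n_cols:
        if not gappy[c]:
            c += 1
            continue
        start = c
        while c < n_cols and gappy[c]:
            c += 1
        end = c - 1  # inclusive, 0-based
        sub = gap[:, start:end + 1]
        res_counts = (~sub).sum(axis=1)
        gapped = frozenset(t for t, n in zip(taxa, res_counts) if n == 0)
        bearing = frozenset(t for t, n in zip(taxa, res_counts) if n > 0)
        counts = {t: int(n) for t, n in zip(taxa, res_counts) if n > 0}
        blocks.append(GapBlock(start + 1, end + 1, gapped, bearing, counts))
    return blocks


# ---------------------------------------------------------------------------
# Step 2 — candidate evaluation


def _reference_taxon(alignment: Alignment, partition: CladePartition,
                     reference: str | None) -> str:
    if reference is not None:
        if reference not in alignment:
            raise ValueError(f"reference taxon {reference!r} not in alignment")
        return reference
    for t in alignment.ids:
        if t in partition.ingroup:
            return t
    raise PartitionError("no ingroup taxon present to serve as reference")


def _ref_fragment_bounds(alignment: Alignment, ref: str,
                         block: GapBlock) -> tuple[int, int]:
    """1-based residue coordinates, in the reference sequence, of the
    reported fragment: the indel region plus REPORT_FLANK residues per side,
    clipped to the sequence."""
    row = alignment.residues(ref)
    before = sum(1 for ch in row[: block.col_start - 1] if ch != "-")
    through = before + sum(
        1 for ch in row[block.col_start - 1: block.col_end] if ch != "-")
    ref_len = sum(1 for ch in row if ch != "-")
    if ref_len == 0:
        raise ValueError(f"reference taxon {ref!r} is fully gapped")
    # indel occupies reference positions before+1..through (or sits between
    # before and before+1 when the reference is gapped in the block)
    start = max(1, before - REPORT_FLANK + 1)
    end = min(ref_len, through + REPORT_FLANK)
    return start, end


def evaluate_candidate(alignment: Alignment, partition: CladePartition,
                       block: GapBlock, params: ScanParams | None = None,
                       conserved: np.ndarray | None = None,
                       reference: str | None = None,
                       ) -> CsiRecord | Rejection:
    """Test one gap block against the exclusivity and flank criteria.

    Polarity is called relative to the outgroup majority state, the
    outgroup serving as ancestral proxy: if most outgroup taxa are gapped
    the candidate is an ingroup insertion, if most bear residues it is an
    ingroup deletion.  Rejection is a value, never an exception.
    """
    params = params or ScanParams()
    taxa = _considered_taxa(alignment, partition)
    present = set(taxa)
    ing_present = [t for t in taxa if t in partition.ingroup]
    out_present = [t for t in taxa if t in partition.outgroup]
    n_missing = len(partition.ingroup - present)

    out_gapped = [t for t in out_present if t in block.gapped_taxa]
    out_bearing = [t for t in out_present if t in block.bearing_taxa]

    if len(out_gapped) > len(out_bearing):
        polarity = INSERTION
    elif len(out_bearing) > len(out_gapped):
        polarity = DELETION
    else:
        return Rejection(block, RejectionReason.PATTERN_MIXED,
                         "outgroup evenly split between gap and residue states")

    if polarity == INSERTION:
        conforming = [t for t in ing_present if t in block.bearing_taxa]
        violating = [t for t in ing_present if t in block.gapped_taxa]
        sharing_out = out_bearing
        length_carriers = conforming
    else:
        conforming = [t for t in ing_present if t in block.gapped_taxa]
        violating = [t for t in ing_present if t in block.bearing_taxa]
        sharing_out = out_gapped
        length_carriers = out_bearing  # deletion length is what the outgroup retains

    n_violating = len(violating)
    if params.treat_missing_homolog_as == "violation":
        n_violating += n_missing
        n_missing_reported = 0
    else:
        n_missing_reported = n_missing

    if not conforming:
        return Rejection(block, RejectionReason.PATTERN_MIXED,
                         "no ingroup taxon carries the candidate state")
    if n_violating > params.max_ingroup_exceptions:
        return Rejection(
            block, RejectionReason.PATTERN_MIXED,
            f"{n_violating} ingroup taxa violate the {polarity} pattern "
            f"(max {params.max_ingroup_exceptions})")
    if len(sharing_out) > params.max_outgroup_sharing:
        return Rejection(
            block, RejectionReason.NOT_EXCLUSIVE,
            f"{len(sharing_out)} outgroup taxa share the ingroup state "
            f"(max {params.max_outgroup_sharing})")

    counts = [block.per_taxon_residue_count[t] for t in length_carriers
              if t in block.per_taxon_residue_count]
    if not counts:
        return Rejection(block, RejectionReason.PATTERN_MIXED,
                         "no residue-bearing taxon to measure the indel")
    length_min, length_max = min(counts), max(counts)
    if length_min < params.min_indel_len:
        return Rejection(block, RejectionReason.TOO_SHORT,
                         f"shortest state {length_min} < {params.min_indel_len}")
    if length_max > params.max_indel_len:
        return Rejection(block, RejectionReason.TOO_LONG,
                         f"longest state {length_max} > {params.max_indel_len}")

    if conserved is None:
        conserved = column_conservation(alignment, params, taxa)
    w = params.flank_window
    left_lo = max(0, block.col_start - 1 - w)
    left_window = conserved[left_lo: block.col_start - 1]
    right_window = conserved[block.col_end: block.col_end + w]
    flank_left = FlankEvidence(int(left_window.sum()), int(left_window.size))
    flank_right = FlankEvidence(int(right_window.sum()), int(right_window.size))
    if flank_left.conserved_columns < params.min_flank_conserved:
        return Rejection(block, RejectionReason.FLANK_LEFT_WEAK,
                         f"{flank_left.conserved_columns} conserved columns "
                         f"in left window of {flank_left.window_used}")
    if flank_right.conserved_columns < params.min_flank_conserved:
        return Rejection(block, RejectionReason.FLANK_RIGHT_WEAK,
                         f"{flank_right.conserved_columns} conserved columns "
                         f"in right window of {flank_right.window_used}")

    ref = _reference_taxon(alignment, partition, reference)
    pos_start, pos_end = _ref_fragment_bounds(alignment, ref, block)

    return CsiRecord(
        protein=alignment.source_protein or "",
        accession=alignment.accessions.get(ref, ""),
        clade=partition.clade_name,
        polarity=polarity,
        length_min=length_min,
        length_max=length_max,
        ref_position_start=pos_start,
        ref_position_end=pos_end,
        reference_taxon=ref,
        block=block,
        flank_left=flank_left,
        flank_right=flank_right,
        sharing=SharingStats(
            n_ingroup_conforming=len(conforming),
            n_ingroup_violating=n_violating,
            n_ingroup_missing_homolog=n_missing_reported,
            n_outgroup_sharing=len(sharing_out),
        ),
        params_used=params,
        ingroup_present=tuple(ing_present),
        outgroup_present=tuple(out_present),
    )


# ---------------------------------------------------------------------------
# Step 3 — whole-alignment scan


def scan_alignment(alignment: Alignment, partition: CladePartition,
                   params: ScanParams | None = None,
                   reference: str | None = None,
                   return_rejections: bool = False):
    """Scan one alignment for clade-exclusive conserved signature indels.

    Returns the accepted :class:`CsiRecord` list ordered by
    ``(col_start, col_end, polarity)``; with ``return_rejections=True``
    returns ``(records, rejections)``.  Deterministic for fixed inputs.
    """
    params = params or ScanParams()
    blocks = find_gap_blocks(alignment, partition)
    taxa = _considered_taxa(alignment, partition)
    conserved = column_conservation(alignment, params, taxa)
    records: list[CsiRecord] = []
    rejections: list[Rejection] = []
    for block in blocks:
        result = evaluate_candidate(alignment, partition, block, params,
                                    conserved=conserved, reference=reference)
        if isinstance(result, CsiRecord):
            records.append(result)
        else:
            rejections.append(result)
    records.sort(key=lambda r: (r.block.col_start, r.block.col_end, r.polarity))
    if return_rejections:
        return records, rejections
    return records


def variable_length_summary(record: CsiRecord) -> str:
    """Catalogue-style size string: ``"5 aa ins"``, ``"2–4 aa ins"``,
    ``"1 aa del"`` (en dash for variable-length indels)."""
    kind = "ins" if record.polarity == INSERTION else "del"
    if record.length_min == record.length_max:
        return f"{record.length_min} aa {kind}"
    return f"{record.length_min}–{record.length_max} aa {kind}"


# ---------------------------------------------------------------------------
# Querying proteomes for known CSIs


class MatchOutcome(str, enum.Enum):
    CSI_PRESENT = "csi_present"
    CSI_ABSENT = "csi_absent"
    PROTEIN_NOT_FOUND = "protein_not_found"


@dataclass(frozen=True)
class MatchParams:
    """Flank-matching thresholds for :func:`match_query`."""

    flank_length: int = 15
    max_flank_mismatches: int = 3


def _flank_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _best_flank_hit(aligner, protein: str, flank: str):
    """Best local hit of a flank in a protein.

    Returns ``(mismatches, eff_start, eff_end, score)`` where eff_start /
    eff_end are 0-based query-protein coordinates of the flank's implied
    full extent (unaligned flank overhangs are projected onto the protein
    and counted as mismatches), or None when no alignment exists.
    """
    if not protein:
        return None
    alns = aligner.align(protein, flank)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    t_blocks, q_blocks = aln.aligned
    identities = 0
    aligned_flank = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        seg_t = protein[ts:te]
        seg_q = flank[qs:qe]
        identities += sum(1 for a, b in zip(seg_t, seg_q)
                          if a == b and a != "X")
        aligned_flank += qe - qs
    # project unaligned flank overhangs onto the protein
    f_start = int(q_blocks[0][0])
    f_end = int(q_blocks[-1][1])
    t_start = int(t_blocks[0][0]) - f_start
    t_end = int(t_blocks[-1][1]) + (len(flank) - f_end)
    mismatches = len(flank) - identities
    return mismatches, t_start, t_end, float(aln.score)


def match_query(record: CsiRecord, reference_alignment: Alignment,
                query: Proteome,
                match_params: MatchParams | None = None) -> MatchOutcome:
    """Test a query proteome for the presence or absence of a known CSI.

    The reference fragment consists of ``flank_length`` residues on each
    side of the indel in the record's reference (ingroup) sequence.  Each
    query protein is searched by local alignment of the two flanks; when
    both match with at most ``max_flank_mismatches`` mismatches, the length
    of the intervening query segment is compared with the ingroup and
    outgroup states.  The best-scoring protein with matching flanks decides
    the outcome; if none matches, the host protein is declared not found.
    """
    mp = match_params or MatchParams()
    ref = record.reference_taxon
    if ref not in reference_alignment:
        raise ValueError(f"reference taxon {ref!r} not in reference alignment")
    row = reference_alignment.residues(ref)
    block = record.block
    before = sum(1 for ch in row[: block.col_start - 1] if ch != "-")
    in_block = sum(1 for ch in row[block.col_start - 1: block.col_end]
                   if ch != "-")
    ungapped = row.replace("-", "")
    if before < mp.flank_length or len(ungapped) - before - in_block < mp.flank_length:
        raise ValueError(
            f"flank_length {mp.flank_length} exceeds available reference "
            f"sequence around the indel")
    left = ungapped[before - mp.flank_length: before]
    right = ungapped[before + in_block: before + in_block + mp.flank_length]

    if record.polarity == INSERTION:
        ingroup_range = (record.length_min, record.length_max)
        outgroup_len = 0
    else:
        ingroup_range = (0, 0)
        outgroup_len = None  # any length in [length_min, length_max]

    aligner = _flank_aligner()
    best_score = -np.inf
    best_outcome: MatchOutcome | None = None
    for seq in query.sequences():
        hit_l = _best_flank_hit(aligner, seq, left)
        if hit_l is None or hit_l[0] > mp.max_flank_mismatches:
            continue
        tail = seq[max(hit_l[2], 0):]
        hit_r = _best_flank_hit(aligner, tail, right)
        if hit_r is None or hit_r[0] > mp.max_flank_mismatches:
            continue
        gap_len = max(hit_l[2], 0) + hit_r[1] - hit_l[2]
        score = hit_l[3] + hit_r[3]
        if score <= best_score:
            continue
        best_score = score
        if ingroup_range[0] <= gap_len <= ingroup_range[1]:
            best_outcome = MatchOutcome.CSI_PRESENT
        elif record.polarity == INSERTION and gap_len == outgroup_len:
            best_outcome = MatchOutcome.CSI_ABSENT
        elif record.polarity == DELETION and \
                record.length_min <= gap_len <= record.length_max:
            best_outcome = MatchOutcome.CSI_ABSENT
        else:
            # flanks found but segment length matches neither state;
            # the signature, as defined, is not carried
            best_outcome = MatchOutcome.CSI_ABSENT
    return best_outcome if best_outcome is not None \
        else MatchOutcome.PROTEIN_NOT_FOUND
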