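"""Rendering of signature-alignment excerpts, catalogue tables and
proteome classification reports.

Excerpts follow the figure convention of the CSI literature: the
reference (top) sequence is spelled out in full under a coordinate
header, every other row shows ``-`` where it is identical to the top
line and the residue itself where it differs, and ``.`` marks an
alignment gap.  The indel columns are flagged by a caret line.  The
rendering is lossless: replacing each ``-`` with the top-line residue
and each ``.`` with a gap reproduces the underlying excerpt exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alignment_io import Alignment, CsiCatalogue, Proteome
from .csi_scan import (CsiRecord, INSERTION, MatchOutcome, MatchParams,
                       match_query, variable_length_summary)

__all__ = [
    "ExcerptStyle",
    "ClassificationReport",
    "format_excerpt",
    "classify_proteome",
    "emit_catalogue_table",
]

GAP_MARK = "."
IDENTITY_MARK = "-"


@dataclass(frozen=True)
class ExcerptStyle:
    """Presentation options for :func:`format_excerpt`."""

    excerpt_flank: int = 20
    dash_identity: bool = True
    group_labels: Mapping[str, str] = field(default_factory=dict)
    reference_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.excerpt_flank < 1:
            raise ValueError("excerpt_flank must be >= 1")


def _excerpt_columns(alignment: Alignment, record: CsiRecord,
                     flank: int) -> tuple[int, int]:
    """0-based half-open column range spanning the indel block plus
    ``flank`` reference residues per side."""
    ref_row = alignment.residues(record.reference_taxon)
    block = record.block
    # walk left collecting reference residues
    c = block.col_start - 1
    seen = 0
    while c > 0 and seen < flank:
        c -= 1
        if ref_row[c] != "-":
            seen += 1
    start = c
    c = block.col_end
    seen = 0
    while c < len(ref_row) and seen < flank:
        if ref_row[c] != "-":
            seen += 1
        c += 1
    return start, c


def format_excerpt(alignment: Alignment, record: CsiRecord,
                   style: ExcerptStyle | None = None) -> str:
    """Render a signature alignment excerpt as a text block."""
    style = style or ExcerptStyle()
    ref = style.reference_taxon or record.reference_taxon
    if ref not in alignment:
        raise ValueError(f"reference taxon {ref!r} not in alignment")
    cs, ce = _excerpt_columns(alignment, record, style.excerpt_flank)
    ref_row = alignment.residues(ref)
    if all(ch == "-" for ch in ref_row[cs:ce]):
        raise ValueError(
            f"reference taxon {ref!r} is gapped across the entire excerpt")

    # reference coordinates of the excerpt
    before = sum(1 for ch in ref_row[:cs] if ch != "-")
    n_res = sum(1 for ch in ref_row[cs:ce] if ch != "-")
    pos_lo, pos_hi = before + 1, before + n_res

    # order: reference first, then remaining ingroup, then outgroup,
    # then any unpartitioned taxa present in the alignment
    ing = [t for t in record.ingroup_present if t != ref]
    out = list(record.outgroup_present)
    rest = [t for t in alignment.ids
            if t not in set(ing) | set(out) | {ref}]
    order = [ref] + ing + out + rest

    labels = {t: style.group_labels.get(t, "") for t in order}
    name_w = max(len(t) for t in order) + 2
    acc_w = max([len(alignment.accessions.get(t, "")) for t in order],
                default=0)
    acc_w = acc_w + 2 if acc_w else 0
    lab_w = max([len(v) for v in labels.values()], default=0)
    lab_w = lab_w + 2 if lab_w else 0
    prefix = name_w + acc_w + lab_w

    lines = []
    header = f"{record.protein}"
    if record.accession:
        header += f" ({record.accession})"
    header += f"  positions {pos_lo}-{pos_hi}  [{variable_length_summary(record)}]"
    lines.append(header)

    marker = [" "] * (ce - cs)
    for c in range(record.block.col_start - 1, record.block.col_end):
        if cs <= c < ce:
            marker[c - cs] = "^"
    lines.append(" " * prefix + "".join(marker))

    top = ref_row[cs:ce]
    top_render = "".join(GAP_MARK if ch == "-" else ch for ch in top)

    def line_for(taxon: str) -> str:
        seq = alignment.residues(taxon)[cs:ce]
        if taxon == ref:
            body = top_render
        else:
            chars = []
            for ch, top_ch in zip(seq, top):
                if ch == "-":
                    chars.append(GAP_MARK)
                elif style.dash_identity and ch == top_ch and ch != "X":
                    chars.append(IDENTITY_MARK)
                else:
                    chars.append(ch)
            body = "".join(chars)
        cells = [taxon.ljust(name_w)]
        if acc_w:
            cells.append(alignment.accessions.get(taxon, "").ljust(acc_w))
        if lab_w:
            cells.append(labels[taxon].ljust(lab_w))
        return "".join(cells) + body

    lines.extend(line_for(t) for t in order)
    return "\n".join(lines) + "\n"


def read_excerpt_residues(excerpt: str) -> dict[str, str]:
    """Invert :func:`format_excerpt`: recover each taxon's gapped residues
    from a rendered excerpt block (used for round-trip verification).

    Sequence bodies are the last whitespace-separated field of each line;
    labels and accessions must therefore not contain whitespace, which
    :func:`format_excerpt` guarantees for its own output.
    """
    lines = excerpt.rstrip("\n").split("\n")
    marker_idx = next(i for i, ln in enumerate(lines)
                      if ln.strip() and set(ln.strip()) == {"^"})
    out: dict[str, str] = {}
    top_seq: str | None = None
    for ln in lines[marker_idx + 1:]:
        taxon = ln.split()[0]
        body = ln.split()[-1]
        if top_seq is None:
            top_seq = body.replace(GAP_MARK, "-")
            out[taxon] = top_seq
        else:
            out[taxon] = "".join(
                "-" if ch == GAP_MARK else
                (top_seq[i] if ch == IDENTITY_MARK else ch)
                for i, ch in enumerate(body))
    return out


@dataclass
class ClassificationReport:
    """Per-CSI outcomes for one query genome, with clade-level verdicts.

    The verdict is never a bare label: it always carries the count of
    supporting signatures over the clade's catalogue size, because real
    catalogues admit isolated exceptions.
    """

    genome_id: str
    outcomes: dict[tuple[str, int], MatchOutcome]
    record_clades: dict[tuple[str, int], str]
    verdict: str = ""
    clade_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        per_clade: dict[str, Counter] = {}
        for key, outcome in self.outcomes.items():
            clade = self.record_clades[key]
            per_clade.setdefault(clade, Counter())[outcome] += 1
        self.clade_counts = {
            clade: (c[MatchOutcome.CSI_PRESENT], sum(c.values()))
            for clade, c in per_clade.items()
        }
        if all(o is MatchOutcome.PROTEIN_NOT_FOUND
               for o in self.outcomes.values()):
            self.verdict = "undetermined"
        else:
            best = max(self.clade_counts.items(),
                       key=lambda kv: kv[1][0] / kv[1][1])
            self.verdict = best[0] if best[1][0] > 0 else "undetermined"

    def summary(self) -> str:
        parts = [f"{self.genome_id}: verdict={self.verdict}"]
        for clade, (present, total) in sorted(self.clade_counts.items()):
            parts.append(f"  {clade}: {present} of {total} CSIs present")
        return "\n".join(parts)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "verdict": self.verdict,
            "clade_counts": {c: {"present": p, "total": t}
                             for c, (p, t) in self.clade_counts.items()},
            "outcomes": [
                {"protein": k[0], "position": k[1],
                 "clade": self.record_clades[k], "outcome": v.value}
                for k, v in self.outcomes.items()
            ],
        }


def classify_proteome(catalogue: CsiCatalogue,
                      reference_alignments: Mapping[str, Alignment],
                      query: Proteome,
                      match_params: MatchParams | None = None,
                      ) -> ClassificationReport:
    """Test a query proteome against every catalogued CSI.

    ``reference_alignments`` maps each record's protein name to the
    alignment the record was derived from.
    """
    if len(catalogue) == 0:
        raise ValueError("empty CSI catalogue")
    outcomes: dict[tuple[str, int], MatchOutcome] = {}
    clades: dict[tuple[str, int], str] = {}
    for record in catalogue:
        try:
            aln = reference_alignments[record.protein]
        except KeyError as exc:
            raise KeyError(
                f"no reference alignment for protein {record.protein!r}"
            ) from exc
        outcomes[record.key] = match_query(record, aln, query, match_params)
        clades[record.key] = record.clade or "(unassigned)"
    return ClassificationReport(query.genome_id, outcomes, clades)


def emit_catalogue_table(records: Sequence[CsiRecord],
                         clade_labels: Mapping[tuple[str, int], str] | None = None,
                         ) -> str:
    """TSV catalogue in the published table schema.

    Columns: protein, accession, indel type, size min, size max, position
    start, position end, clade.  Rows are ordered by (clade, protein,
    position).
    """
    clade_labels = clade_labels or {}
    header = ["protein", "accession", "indel_type", "size_min", "size_max",
              "position_start", "position_end", "clade"]
    rows = []
    for r in records:
        clade = clade_labels.get(r.key, r.clade)
        rows.append([
            r.protein, r.accession,
            "ins" if r.polarity == INSERTION else "del",
            str(r.length_min), str(r.length_max),
            str(r.ref_position_start), str(r.ref_position_end),
            clade,
        ])
    rows.sort(key=lambda row: (row[7], row[0], int(row[5])))
    lines = ["\t".join(header)] + ["\t".join(row) for row in rows]
    return "\n".join(lines) + "\n"
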