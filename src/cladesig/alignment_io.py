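"""Readers, writers and validated containers for the pipeline's inputs.

Four kinds of objects move through the pipeline:

* :class:`Alignment` — a protein multiple-sequence alignment, the substrate
  of signature-indel scanning;
* :class:`CladePartition` — the named ingroup/outgroup split that defines
  clade exclusivity;
* :class:`Proteome` — one genome's unaligned protein set, the unit of
  POCP computation;
* :class:`CsiCatalogue` — a collection of accepted signature-indel records,
  serialisable to JSON (full evidence) or TSV (table schema).

File parsing is delegated to Biopython (``Bio.SeqIO`` / ``Bio.AlignIO``);
this module adds the validation and normalisation the downstream scanners
rely on: upper-casing, ``.`` → ``-``, rare ambiguity codes mapped to ``X``,
removal of all-gap columns, uniqueness of taxon identifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "ALIGNMENT_ALPHABET",
    "Alignment",
    "CladePartition",
    "Proteome",
    "CsiCatalogue",
    "MalformedAlignmentError",
    "PartitionError",
    "ProteomeError",
    "read_alignment",
    "write_alignment",
    "read_proteome",
    "write_proteome",
    "read_partition",
    "write_partition",
]

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues legal inside an alignment: standard amino acids, the unknown
#: residue ``X`` and the gap character.
ALIGNMENT_ALPHABET = frozenset(AMINO_ACIDS) | {"X", "-"}

# Ambiguity / rare residue codes normalised to X on load.  B and Z are
# ambiguous (N/D, Q/E), J is I/L, U is selenocysteine, O is pyrrolysine.
_AMBIGUOUS = {"B": "X", "Z": "X", "J": "X", "U": "X", "O": "X", "*": "X"}


class MalformedAlignmentError(ValueError):
    """Raised when an alignment file violates the alignment invariants."""


class PartitionError(ValueError):
    """Raised when a clade-partition configuration is inconsistent."""


class ProteomeError(ValueError):
    """Raised when a proteome FASTA is empty, gapped or otherwise invalid."""


def _normalise_residues(raw: str, taxon: str) -> str:
    """Upper-case, map ``.``→``-`` and ambiguity codes to ``X``; reject
    anything outside the alignment alphabet, naming the offending position."""
    out = []
    for i, ch in enumerate(raw.upper()):
        if ch == ".":
            ch = "-"
        ch = _AMBIGUOUS.get(ch, ch)
        if ch not in ALIGNMENT_ALPHABET:
            raise MalformedAlignmentError(
                f"illegal character {ch!r} at position {i + 1} of sequence {taxon!r}"
            )
        out.append(ch)
    return "".join(out)


def _split_header(record: SeqRecord) -> tuple[str, str | None]:
    """Taxon id and optional accession from a FASTA/Clustal header.

    Convention: the identifier's first ``|``-separated field is the taxon id
    and the second, when present, is an accession (e.g.
    ``Chlorobium_limicola|WP_012466203``).  Headers without ``|`` carry no
    accession.
    """
    ident = record.id
    if "|" in ident:
        taxon, accession = ident.split("|", 1)
        return taxon, (accession or None)
    return ident, None


@dataclass
class Alignment:
    """An ordered, validated protein multiple-sequence alignment.

    ``ids`` and ``seqs`` run in parallel; every sequence has exactly
    ``n_columns`` characters over :data:`ALIGNMENT_ALPHABET`, taxon ids are
    unique and no column is all-gap.
    """

    ids: list[str]
    seqs: list[str]
    source_protein: str | None = None
    accessions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ids:
            raise MalformedAlignmentError("alignment has no sequences")
        if len(self.ids) != len(self.seqs):
            raise MalformedAlignmentError("ids and seqs differ in length")
        n = len(self.seqs[0])
        for taxon, seq in zip(self.ids, self.seqs):
            if len(seq) != n:
                raise MalformedAlignmentError(
                    f"sequence {taxon!r} has length {len(seq)}, expected {n}"
                )
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({t for t in self.ids if self.ids.count(t) > 1})
            raise MalformedAlignmentError(f"duplicate taxon ids: {dupes}")
        if n == 0:
            raise MalformedAlignmentError("alignment has zero columns")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.seqs))

    @property
    def _index(self) -> dict[str, int]:
        idx = getattr(self, "_index_cache", None)
        if idx is None or len(idx) != len(self.ids):
            idx = {t: i for i, t in enumerate(self.ids)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def residues(self, taxon: str) -> str:
        """The gapped row for one taxon."""
        return self.seqs[self._index[taxon]]

    def ungapped(self, taxon: str) -> str:
        return self.residues(taxon).replace("-", "")

    def column(self, col: int) -> str:
        """Column ``col`` (1-based) as a string, one character per taxon."""
        return "".join(seq[col - 1] for seq in self.seqs)

    # -- normalisation -----------------------------------------------------

    def strip_all_gap_columns(self) -> "Alignment":
        """Return a copy with columns consisting entirely of ``-`` removed."""
        keep = [
            c for c in range(self.n_columns)
            if any(seq[c] != "-" for seq in self.seqs)
        ]
        if len(keep) == self.n_columns:
            return self
        seqs = ["".join(seq[c] for c in keep) for seq in self.seqs]
        return Alignment(list(self.ids), seqs, self.source_protein,
                         dict(self.accessions))


@dataclass(frozen=True)
class CladePartition:
    """A named split of taxa into the clade of interest and everything else.

    The ingroup is the clade whose exclusive markers are sought; the
    outgroup is the reference set against which exclusivity is tested
    (and the proxy for the ancestral character state).
    """

    clade_name: str
    ingroup: frozenset[str]
    outgroup: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ingroup", frozenset(self.ingroup))
        object.__setattr__(self, "outgroup", frozenset(self.outgroup))
        if not self.ingroup:
            raise PartitionError("ingroup is empty")
        if not self.outgroup:
            raise PartitionError(
                "outgroup is empty — exclusivity is undefined without an outgroup"
            )
        shared = self.ingroup & self.outgroup
        if shared:
            raise PartitionError(
                f"taxa listed in both ingroup and outgroup: {sorted(shared)}"
            )

    @property
    def taxa(self) -> frozenset[str]:
        return self.ingroup | self.outgroup

    def side(self, taxon: str) -> str | None:
        if taxon in self.ingroup:
            return "ingroup"
        if taxon in self.outgroup:
            return "outgroup"
        return None


@dataclass(frozen=True)
class Proteome:
    """One genome's set of unaligned protein sequences."""

    genome_id: str
    proteins: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ProteomeError(f"empty proteome {self.genome_id!r}")
        for pid, seq in self.proteins.items():
            if not seq:
                raise ProteomeError(f"empty sequence {pid!r} in {self.genome_id!r}")
            if "-" in seq or "." in seq:
                raise ProteomeError(
                    f"gap character in protein {pid!r} of {self.genome_id!r}: "
                    "proteomes must be unaligned"
                )

    @property
    def T(self) -> int:
        """Total protein count (the POCP denominator contribution)."""
        return len(self.proteins)

    def sequences(self) -> Iterator[str]:
        return iter(self.proteins.values())


# ---------------------------------------------------------------------------
# Alignment IO


def read_alignment(path: str | Path, format: str = "fasta",
                   source_protein: str | None = None) -> Alignment:
    """Read and validate a protein alignment.

    Parameters
    ----------
    path : str or Path
        The alignment file.
    format : {"fasta", "clustal"}
        Input dialect.  Both CLUSTAL W and CLUSTAL O headers are accepted;
        Clustal conservation lines are ignored.
    source_protein : str, optional
        Name/accession of the protein family, carried into reports.

    All-gap columns are stripped, residues are upper-cased, ``.`` is read as
    ``-`` and rare ambiguity codes are mapped to ``X``.
    """
    path = Path(path)
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "clustal"))
        except ValueError as exc:
            raise MalformedAlignmentError(f"{path}: {exc}") from exc
    if not records:
        raise MalformedAlignmentError(f"{path}: no sequences found")

    ids, seqs, accessions = [], [], {}
    for rec in records:
        taxon, accession = _split_header(rec)
        ids.append(taxon)
        seqs.append(_normalise_residues(str(rec.seq), taxon))
        if accession:
            accessions[taxon] = accession

    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        expected = len(seqs[0])
        for taxon, seq in zip(ids, seqs):
            if len(seq) != expected:
                raise MalformedAlignmentError(
                    f"{path}: sequence {taxon!r} has length {len(seq)}, "
                    f"expected {expected} — not a valid alignment"
                )
    aln = Alignment(ids, seqs, source_protein, accessions)
    return aln.strip_all_gap_columns()


def write_alignment(alignment: Alignment, path: str | Path,
                    format: str = "fasta") -> None:
    """Write an alignment in aligned-FASTA or Clustal format."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    records = []
    for taxon, seq in alignment:
        ident = taxon
        if taxon in alignment.accessions:
            ident = f"{taxon}|{alignment.accessions[taxon]}"
        records.append(SeqRecord(Seq(seq), id=ident, description=""))
    msa = MultipleSeqAlignment(records)
    AlignIO.write(msa, str(path), format)


# ---------------------------------------------------------------------------
# Proteome IO


def read_proteome(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read one genome's proteome from a plain (unaligned) FASTA file."""
    path = Path(path)
    genome_id = genome_id or path.stem
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in proteins:
            raise ProteomeError(f"{path}: duplicate protein id {rec.id!r}")
        proteins[rec.id] = seq
    if not proteins:
        raise ProteomeError(f"{path}: empty proteome")
    return Proteome(genome_id, proteins)


def write_proteome(proteome: Proteome, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="")
               for pid, seq in proteome.proteins.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Partition IO


def read_partition(path: str | Path) -> CladePartition:
    """Read a clade partition from YAML (or JSON, a YAML subset).

    Expected keys: ``clade`` (or ``clade_name``), ``ingroup``, ``outgroup``,
    the latter two being lists of taxon ids.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise PartitionError(f"{path}: expected a mapping at top level")
    name = data.get("clade", data.get("clade_name"))
    if not name:
        raise PartitionError(f"{path}: missing 'clade' name")
    try:
        ingroup = data["ingroup"]
        outgroup = data["outgroup"]
    except KeyError as exc:
        raise PartitionError(f"{path}: missing {exc.args[0]!r} list") from exc
    if ingroup is None or outgroup is None:
        raise PartitionError(f"{path}: ingroup/outgroup must be non-empty lists")
    return CladePartition(str(name), frozenset(map(str, ingroup)),
                          frozenset(map(str, outgroup)))


def write_partition(partition: CladePartition, path: str | Path) -> None:
    data = {
        "clade": partition.clade_name,
        "ingroup": sorted(partition.ingroup),
        "outgroup": sorted(partition.outgroup),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CSI catalogue IO (record class lives in csi_scan; IO here)

#: TSV schema mirroring the published catalogue tables.
CATALOGUE_TSV_COLUMNS = [
    "protein", "accession", "indel_type", "size_min", "size_max",
    "position_start", "position_end", "clade",
]


@dataclass
class CsiCatalogue:
    """A collection of signature-indel records with unique (protein,
    position) keys, serialisable to JSON (full evidence) and TSV (table
    schema)."""

    entries: list  # list[CsiRecord]; untyped here to avoid a module cycle

    def __post_init__(self) -> None:
        keys = [(r.protein, r.ref_position_start) for r in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (protein, position) entries: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_json(self, path: str | Path, metadata: dict | None = None) -> None:
        payload = {
            "metadata": metadata or {},
            "entries": [r.to_dict() for r in self.entries],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CsiCatalogue":
        from .csi_scan import CsiRecord  # deferred: avoids circular import
        with open(path) as fh:
            payload = json.load(fh)
        entries = [CsiRecord.from_dict(d) for d in payload["entries"]]
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        from .reporting import emit_catalogue_table
        Path(path).write_text(emit_catalogue_table(self.entries))
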