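"""Synthetic protein families and proteome sets with known planted truth.

Every pipeline stage is testable offline against data whose ground truth
is known by construction:

* :func:`generate_family` builds a protein alignment in which a single
  fixed-length indel, exclusive to the ingroup, is planted between two
  flank windows held at a controlled cross-taxon conservation level, over
  uniform background substitution noise.  The generator never introduces
  gaps other than the planted indel, so the planted block is the only gap
  signal in the alignment.

* :func:`generate_proteome_set` builds genome proteomes with an exact,
  closed-form shared-protein structure (a fraction shared within a group,
  a smaller fraction shared between groups) so that the expected POCP of
  every genome pair is known exactly.

Both generators take an explicit seed and are fully deterministic; there
is no hidden global random state.  Substitutions use a uniform
residue-replacement model — adequate for exercising conservation
thresholds, and simple to reason about analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import AMINO_ACIDS, Alignment, CladePartition, Proteome
from .csi_scan import DELETION, INSERTION

__all__ = [
    "FamilySpec",
    "ProteomeSetSpec",
    "SyntheticTruth",
    "generate_family",
    "generate_proteome_set",
]

_AA = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic protein family.

    ``seq_length`` is the ancestral (outgroup-state) sequence length;
    ``indel_pos`` counts the ancestral residues preceding the indel;
    ``indel_len = 0`` plants nothing (negative-control families).
    ``flank_conservation`` is the exact fraction of columns frozen across
    all taxa inside the ``flank_width`` windows flanking the indel; all
    other columns mutate per taxon at ``background_sub_rate``.
    """

    n_ingroup: int = 10
    n_outgroup: int = 8
    seq_length: int = 120
    indel_len: int = 5
    indel_pos: int = 60
    polarity: str = INSERTION
    flank_conservation: float = 1.0
    background_sub_rate: float = 0.05
    flank_width: int = 40
    missing_homolog_taxa: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ingroup < 1 or self.n_outgroup < 1:
            raise ValueError("need at least one taxon per side")
        if self.indel_len < 0:
            raise ValueError("indel_len must be >= 0")
        if not 0 < self.indel_pos and self.indel_len == 0:
            pass
        if self.indel_pos + self.indel_len > self.seq_length:
            raise ValueError("indel_pos + indel_len exceeds seq_length")
        if self.indel_pos < 1:
            raise ValueError("indel_pos must be >= 1")
        for name in ("flank_conservation", "background_sub_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.polarity not in (INSERTION, DELETION):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        object.__setattr__(self, "missing_homolog_taxa",
                           frozenset(self.missing_homolog_taxa))

    @property
    def ingroup_taxa(self) -> list[str]:
        return [f"ing_{i:02d}" for i in range(1, self.n_ingroup + 1)]

    @property
    def outgroup_taxa(self) -> list[str]:
        return [f"out_{i:02d}" for i in range(1, self.n_outgroup + 1)]

    def partition(self, clade_name: str = "synthetic_clade") -> CladePartition:
        return CladePartition(clade_name, frozenset(self.ingroup_taxa),
                              frozenset(self.outgroup_taxa))


@dataclass(frozen=True)
class ProteomeSetSpec:
    """Parameters of a synthetic proteome set with known shared structure.

    Every genome carries ``proteins_per_genome`` proteins: a pool shared
    by *all* genomes sized so that between-group pairs share
    ``shared_fraction_between`` of their proteins, a per-group pool
    raising within-group sharing to ``shared_fraction_within``, and
    independently drawn unique proteins for the remainder.  Shared copies
    are exact when ``identity_of_shared`` is 1.0, otherwise mutated to
    that expected identity.
    """

    n_genomes: int = 6
    proteins_per_genome: int = 40
    group_assignment: Mapping[str, str] | None = None
    shared_fraction_within: float = 0.7
    shared_fraction_between: float = 0.2
    identity_of_shared: float = 1.0
    protein_length_range: tuple[int, int] = (60, 120)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shared_fraction_within", "shared_fraction_between",
                     "identity_of_shared"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.shared_fraction_within < self.shared_fraction_between:
            raise ValueError("within-group sharing must be >= between-group")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid protein_length_range")
        if self.n_genomes < 1 or self.proteins_per_genome < 1:
            raise ValueError("counts must be positive")

    @property
    def genomes(self) -> list[str]:
        return [f"g{i:02d}" for i in range(1, self.n_genomes + 1)]

    def groups(self) -> dict[str, str]:
        if self.group_assignment is not None:
            return dict(self.group_assignment)
        # default: split genomes evenly into two groups A and B
        gs = self.genomes
        half = (len(gs) + 1) // 2
        return {g: ("A" if i < half else "B") for i, g in enumerate(gs)}


@dataclass
class SyntheticTruth:
    """The planted parameters a recovery test scores against."""

    seed: int
    planted_csi: dict | None = None
    expected_pocp: dict[tuple[str, str], float] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_AA, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            mask: np.ndarray | None = None) -> np.ndarray:
    """Substitute each unmasked site with probability ``rate``, drawing the
    replacement uniformly from the 19 other residues."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    if mask is not None:
        hit &= ~mask
    for i in np.nonzero(hit)[0]:
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_family(spec: FamilySpec) -> tuple[Alignment, SyntheticTruth]:
    """Build one alignment with (optionally) a planted clade-exclusive indel.

    For an ingroup insertion the alignment has ``seq_length + indel_len``
    columns and every outgroup taxon is gapped across the insert columns;
    for an ingroup deletion it has ``seq_length`` columns and every
    ingroup taxon is gapped across the deleted columns.  Taxa listed in
    ``missing_homolog_taxa`` are omitted from the alignment entirely,
    emulating genomes in which no homolog was found.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = _random_seq(rng, spec.seq_length)
    insert = _random_seq(rng, spec.indel_len) if spec.indel_len else \
        np.array([], dtype=_AA.dtype)

    # columns frozen across all taxa: an exact flank_conservation fraction
    # of each flank window (windows measured in ancestral coordinates,
    # adjacent to the indel site)
    frozen = np.zeros(spec.seq_length, dtype=bool)
    if spec.indel_len:
        left = np.arange(max(0, spec.indel_pos - spec.flank_width),
                         spec.indel_pos)
        right = np.arange(min(spec.seq_length,
                              spec.indel_pos + (spec.indel_len
                                                if spec.polarity == DELETION
                                                else 0)),
                          min(spec.seq_length,
                              spec.indel_pos + spec.flank_width
                              + (spec.indel_len
                                 if spec.polarity == DELETION else 0)))
        for window in (left, right):
            k = int(round(spec.flank_conservation * len(window)))
            if k:
                frozen[rng.choice(window, size=k, replace=False)] = True

    is_insertion = spec.polarity == INSERTION and spec.indel_len > 0
    is_deletion = spec.polarity == DELETION and spec.indel_len > 0

    ids, seqs = [], []
    for taxon in spec.ingroup_taxa + spec.outgroup_taxa:
        if taxon in spec.missing_homolog_taxa:
            continue
        ing = taxon.startswith("ing_")
        body = _mutate(rng, ancestor, spec.background_sub_rate, mask=frozen)
        if is_insertion:
            if ing:
                ins = _mutate(rng, insert, spec.background_sub_rate)
                row = np.concatenate([body[:spec.indel_pos], ins,
                                      body[spec.indel_pos:]])
            else:
                gapcols = np.full(spec.indel_len, "-", dtype=_AA.dtype)
                row = np.concatenate([body[:spec.indel_pos], gapcols,
                                      body[spec.indel_pos:]])
        elif is_deletion and ing:
            row = body.copy()
            row[spec.indel_pos: spec.indel_pos + spec.indel_len] = "-"
        else:
            row = body
        ids.append(taxon)
        seqs.append("".join(row))

    alignment = Alignment(ids, seqs, source_protein="synthetic_family")
    if spec.indel_len:
        planted = {
            "polarity": spec.polarity,
            "length": spec.indel_len,
            "col_start": spec.indel_pos + 1,
            "col_end": spec.indel_pos + spec.indel_len,
        }
    else:
        planted = None
    return alignment, SyntheticTruth(seed=spec.seed, planted_csi=planted)


def generate_proteome_set(spec: ProteomeSetSpec
                          ) -> tuple[list[Proteome], SyntheticTruth]:
    """Build proteomes whose pairwise POCP is known in closed form.

    With P proteins per genome, B globally shared and W additionally
    shared within each group, a same-group pair expects
    POCP = 100*(B+W)/P and a cross-group pair POCP = 100*B/P (exact when
    ``identity_of_shared`` is 1.0).
    """
    rng = np.random.default_rng(spec.seed)
    P = spec.proteins_per_genome
    B = int(round(spec.shared_fraction_between * P))
    W = int(round(spec.shared_fraction_within * P)) - B
    lo, hi = spec.protein_length_range
    groups = spec.groups()

    def draw(n: int) -> list[str]:
        return ["".join(_random_seq(rng, int(rng.integers(lo, hi + 1))))
                for _ in range(n)]

    global_pool = draw(B)
    group_pools = {lab: draw(W) for lab in sorted(set(groups.values()))}

    proteomes = []
    for genome in spec.genomes:
        shared = global_pool + group_pools[groups[genome]]
        if spec.identity_of_shared < 1.0:
            shared = ["".join(_mutate(rng, np.array(list(s)),
                                      1.0 - spec.identity_of_shared))
                      for s in shared]
        unique = draw(P - len(shared))
        proteins = {f"{genome}_p{i:04d}": s
                    for i, s in enumerate(shared + unique)}
        proteomes.append(Proteome(genome, proteins))

    truth = SyntheticTruth(seed=spec.seed)
    gs = spec.genomes
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            same = groups[gs[i]] == groups[gs[j]]
            shared_n = B + W if same else B
            truth.expected_pocp[(gs[i], gs[j])] = 100.0 * shared_n / P
    return proteomes, truth
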