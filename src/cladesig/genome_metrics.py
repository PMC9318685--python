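"""Whole-proteome relatedness metrics: POCP, AAI and core-family filtering.

POCP (percentage of conserved proteins) between genomes 1 and 2 is

    POCP = 100 * (C1 + C2) / (T1 + T2)

where Ti is genome i's total protein count and Ci the number of its
proteins with at least one qualifying match in the other genome — a match
with E-value <= 1e-5, identity > 40% and an alignable region covering
> 50% of the query, the thresholds of the standard POCP protocol.  POCP
discriminates prokaryotic taxa at the genus rank and above; here its
block structure over a set of genomes is what demarcates family-level
clades.

AAI (average amino-acid identity) is computed from a concatenated
alignment of shared core proteins: for a pair of taxa it is the fraction
of identical residue pairs over the columns where both carry a residue.
The POCP and AAI code paths are fully independent.

The similarity search behind POCP is a contract, not a tool: any callable
``aligner(query, target) -> (identity_pct, alignable_fraction, evalue)``
may be plugged in.  The default :class:`LocalProteinAligner` is a
Smith–Waterman search (BLOSUM62, affine gaps 11/1) with a Karlin–Altschul
E-value computed from the local score; it screens pairs on score alone
before doing any traceback, which keeps all-vs-all scans fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment_io import Alignment, Proteome, ProteomeError

__all__ = [
    "MatchParams",
    "LocalProteinAligner",
    "SimilarityMatrix",
    "HomologFamily",
    "CoreFilterThresholds",
    "CoreSet",
    "conserved_protein_count",
    "pocp",
    "pocp_matrix",
    "aai_from_core_alignment",
    "aai_matrix",
    "build_matrix",
    "filter_core_families",
    "single_linkage_groups",
]


@dataclass(frozen=True)
class MatchParams:
    """Thresholds a protein pair must pass to count as conserved.

    Defaults are the standard POCP criteria: E-value below 1e-5, identity
    above 40% and an alignable region covering more than half of the
    query.
    """

    max_evalue: float = 1e-5
    min_identity_pct: float = 40.0
    min_alignable_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in (0, 100]")
        if not 0 < self.min_alignable_fraction <= 1:
            raise ValueError("min_alignable_fraction must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


class LocalProteinAligner:
    """Smith–Waterman local protein alignment with a score-based E-value.

    Scoring is BLOSUM62 with affine gap penalties (open 11, extend 1).
    The E-value is the Karlin–Altschul estimate E = K*m*n*exp(-lambda*S)
    with the standard gapped BLASTP parameters for this scoring scheme
    (lambda = 0.267, K = 0.041).  Because E depends on the score only,
    candidate pairs are screened with a score-only pass and the traceback
    (needed for identity and coverage) is computed just for pairs whose
    E-value already qualifies.
    """

    LAMBDA = 0.267
    K = 0.041

    def __init__(self) -> None:
        from Bio import Align
        from Bio.Align import substitution_matrices
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        self._aligner = aligner

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.LAMBDA * score)

    def score(self, query: str, target: str) -> float:
        return float(self._aligner.score(query, target))

    def __call__(self, query: str, target: str
                 ) -> tuple[float, float, float]:
        """(identity_pct, alignable_fraction_of_query, evalue)."""
        score = self.score(query, target)
        ev = self.evalue(score, len(query), len(target))
        if score <= 0:
            return 0.0, 0.0, ev
        aln = self._aligner.align(query, target)[0]
        q_blocks, t_blocks = aln.aligned
        identities = 0
        aligned_cols = 0
        q_covered = 0
        for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
            seg_q = query[qs:qe]
            seg_t = target[ts:te]
            identities += sum(1 for a, b in zip(seg_q, seg_t)
                              if a == b and a != "X")
            aligned_cols += qe - qs
            q_covered += qe - qs
        if aligned_cols == 0:
            return 0.0, 0.0, ev
        identity_pct = 100.0 * identities / aligned_cols
        return identity_pct, q_covered / len(query), ev

    def qualifies(self, query: str, target: str,
                  params: MatchParams) -> bool:
        """Full three-threshold test with the cheap score screen first."""
        score = self.score(query, target)
        if self.evalue(score, len(query), len(target)) > params.max_evalue:
            return False
        identity, fraction, ev = self(query, target)
        return (ev <= params.max_evalue
                and identity >= params.min_identity_pct
                and fraction >= params.min_alignable_fraction)


AlignerContract = Callable[[str, str], tuple[float, float, float]]


def _pair_qualifies(aligner, query: str, target: str,
                    params: MatchParams) -> bool:
    if isinstance(aligner, LocalProteinAligner):
        return aligner.qualifies(query, target, params)
    identity, fraction, ev = aligner(query, target)
    return (ev <= params.max_evalue
            and identity >= params.min_identity_pct
            and fraction >= params.min_alignable_fraction)


def conserved_protein_count(a: Proteome, b: Proteome,
                            params: MatchParams | None = None,
                            aligner: AlignerContract | None = None,
                            ) -> tuple[int, int]:
    """(C1, C2): proteins of ``a`` with a qualifying match in ``b`` and
    vice versa.  Matching is one-directional per side; reciprocity is not
    required.  Identical sequences short-circuit the search for a target
    but still pass through the E-value screen (a very short exact repeat
    can legitimately fail it)."""
    params = params or MatchParams()
    aligner = aligner or LocalProteinAligner()

    def count_into(src: Proteome, dst: Proteome) -> int:
        dst_seqs = list(dst.sequences())
        dst_set = set(dst_seqs)
        n = 0
        for q in src.sequences():
            if q in dst_set and _pair_qualifies(aligner, q, q, params):
                n += 1
                continue
            if any(_pair_qualifies(aligner, q, t, params) for t in dst_seqs):
                n += 1
        return n

    return count_into(a, b), count_into(b, a)


def pocp(a: Proteome, b: Proteome, params: MatchParams | None = None,
         aligner: AlignerContract | None = None) -> float:
    """Percentage of conserved proteins, 100*(C1+C2)/(T1+T2); symmetric."""
    c1, c2 = conserved_protein_count(a, b, params, aligner)
    return 100.0 * (c1 + c2) / (a.T + b.T)


# ---------------------------------------------------------------------------
# Similarity matrices


@dataclass
class SimilarityMatrix:
    """A symmetric taxon-by-taxon similarity matrix (POCP % or AAI
    fraction) with input-order rows; no implicit clustering is applied."""

    taxa: list[str]
    values: np.ndarray
    metric: str  # "POCP_percent" or "AAI_fraction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix is not symmetric")
        diag = 100.0 if self.metric == "POCP_percent" else 1.0
        if not np.allclose(np.diag(self.values), diag):
            raise ValueError(f"diagonal must equal {diag} for {self.metric}")

    def value(self, ti: str, tj: str) -> float:
        i, j = self.taxa.index(ti), self.taxa.index(tj)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, metric: str) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), metric)


def pocp_matrix(proteomes: Sequence[Proteome],
                params: MatchParams | None = None,
                aligner: AlignerContract | None = None,
                ) -> SimilarityMatrix:
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    aligner = aligner or LocalProteinAligner()
    n = len(proteomes)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = pocp(proteomes[i], proteomes[j], params, aligner)
            vals[i, j] = vals[j, i] = v
    return SimilarityMatrix([p.genome_id for p in proteomes], vals,
                            "POCP_percent")


def aai_from_core_alignment(concatenated: Alignment, taxon_i: str,
                            taxon_j: str) -> float:
    """Pairwise identity over columns where both taxa carry a residue.

    ``X`` participates as a residue for column counting but never scores
    as identical.  Raises when the two rows share no residue columns.
    """
    a = np.frombuffer(concatenated.residues(taxon_i).encode("ascii"),
                      dtype="S1")
    b = np.frombuffer(concatenated.residues(taxon_j).encode("ascii"),
                      dtype="S1")
    joint = (a != b"-") & (b != b"-")
    n_joint = int(joint.sum())
    if n_joint == 0:
        raise ValueError(
            f"AAI undefined: {taxon_i!r} and {taxon_j!r} share no "
            "jointly aligned columns")
    identical = int(((a == b) & joint & (a != b"X")).sum())
    return identical / n_joint


def aai_matrix(concatenated: Alignment,
               taxa: Sequence[str] | None = None) -> SimilarityMatrix:
    taxa = list(taxa) if taxa is not None else list(concatenated.ids)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    n = len(taxa)
    vals = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = aai_from_core_alignment(concatenated, taxa[i], taxa[j])
            vals[i, j] = vals[j, i] = v
    return SimilarityMatrix(taxa, vals, "AAI_fraction")


def build_matrix(items, metric: str, params: MatchParams | None = None,
                 aligner: AlignerContract | None = None,
                 taxa: Sequence[str] | None = None) -> SimilarityMatrix:
    """Dispatch to :func:`pocp_matrix` (items = proteomes) or
    :func:`aai_matrix` (items = a concatenated core alignment)."""
    if metric == "POCP_percent":
        return pocp_matrix(items, params, aligner)
    if metric == "AAI_fraction":
        return aai_matrix(items, taxa)
    raise ValueError(f"unknown metric {metric!r}")


def single_linkage_groups(matrix: SimilarityMatrix,
                          threshold: float) -> list[set[str]]:
    """Single-linkage grouping: cut the dendrogram so that taxa joined by
    any chain of pairwise similarities >= threshold share a group."""
    scale = 100.0 if matrix.metric == "POCP_percent" else 1.0
    dist = scale - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    labels = fcluster(linkage(condensed, method="single"),
                      t=scale - threshold, criterion="distance")
    groups: dict[int, set[str]] = {}
    for taxon, lab in zip(matrix.taxa, labels):
        groups.setdefault(int(lab), set()).add(taxon)
    return list(groups.values())


# ---------------------------------------------------------------------------
# Core protein-family filtering


@dataclass(frozen=True)
class HomologFamily:
    """One protein family: at most one member sequence per genome."""

    family_id: str
    members: Mapping[str, str]  # genome_id -> ungapped sequence
    n_genomes: int  # size of the input genome set

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id!r} has no members")
        if self.n_genomes < len(self.members):
            raise ValueError("n_genomes smaller than member count")

    @property
    def occupancy(self) -> float:
        return len(self.members) / self.n_genomes


@dataclass(frozen=True)
class CoreFilterThresholds:
    """Acceptance thresholds for core families: members at >= 50% identity
    and >= 50% length of the reference member, family present in >= 80%
    of the input genomes."""

    min_identity: float = 0.5
    min_length_fraction: float = 0.5
    min_occupancy: float = 0.8


@dataclass
class CoreSet:
    families: list[HomologFamily]
    thresholds: CoreFilterThresholds
    rejected: list[tuple[HomologFamily, str]]


def filter_core_families(families: Iterable[HomologFamily],
                         reference: str,
                         thresholds: CoreFilterThresholds | None = None,
                         aligner: LocalProteinAligner | None = None,
                         ) -> CoreSet:
    """Apply the core-set rule, anchored to the reference genome's member.

    A family is accepted iff every member reaches ``min_identity`` to the
    reference member, is at least ``min_length_fraction`` of its length,
    and the family occupies at least ``min_occupancy`` of the input
    genomes.  Rejected families carry the first failing reason.
    """
    thresholds = thresholds or CoreFilterThresholds()
    aligner = aligner or LocalProteinAligner()
    accepted, rejected = [], []
    for fam in families:
        if reference not in fam.members:
            raise ValueError(
                f"family {fam.family_id!r} lacks a member in reference "
                f"genome {reference!r}")
        ref_seq = fam.members[reference]
        reason = None
        if fam.occupancy < thresholds.min_occupancy:
            reason = (f"occupancy {fam.occupancy:.2f} < "
                      f"{thresholds.min_occupancy}")
        else:
            for genome, seq in fam.members.items():
                if genome == reference:
                    continue
                if len(seq) < thresholds.min_length_fraction * len(ref_seq):
                    reason = (f"member {genome!r} length {len(seq)} < "
                              f"{thresholds.min_length_fraction:.0%} of "
                              f"reference")
                    break
                identity, _, _ = aligner(seq, ref_seq)
                if identity / 100.0 < thresholds.min_identity:
                    reason = (f"member {genome!r} identity "
                              f"{identity:.1f}% < "
                              f"{thresholds.min_identity:.0%}")
                    break
        if reason is None:
            accepted.append(fam)
        else:
            rejected.append((fam, reason))
    return CoreSet(accepted, thresholds, rejected)
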