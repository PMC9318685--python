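"""Shared fixtures: tiny hand-built alignments and planted synthetic data."""

import numpy as np
import pytest

from cladesig import (Alignment, CladePartition, FamilySpec, ScanParams,
                      generate_family)
from cladesig.alignment_io import AMINO_ACIDS

_AA = np.array(list(AMINO_ACIDS))


def random_gapped_alignment(rng, n_taxa, n_cols, gap_prob=0.15):
    """A random alignment with gaps, no all-gap columns; for oracle tests."""
    while True:
        mat = rng.choice(_AA, size=(n_taxa, n_cols))
        gaps = rng.random((n_taxa, n_cols)) < gap_prob
        # never gap out a full column
        full = gaps.all(axis=0)
        gaps[:, full] = False
        mat[gaps] = "-"
        seqs = ["".join(row) for row in mat]
        ids = [f"t{i}" for i in range(n_taxa)]
        return Alignment(ids, seqs)


def brute_force_gap_blocks(alignment, partition):
    """Independent enumeration oracle for gap-block extraction.

    Tests every (start, end) column pair directly against the block
    definition: all columns in the range contain a gap among the
    partition's taxa, and the columns immediately outside do not.
    """
    taxa = [t for t in alignment.ids if t in partition.taxa]
    rows = {t: alignment.residues(t) for t in taxa}
    n = alignment.n_columns

    def col_has_gap(c):  # 1-based
        return any(rows[t][c - 1] == "-" for t in taxa)

    blocks = []
    for start in range(1, n + 1):
        for end in range(start, n + 1):
            if not all(col_has_gap(c) for c in range(start, end + 1)):
                continue
            if start > 1 and col_has_gap(start - 1):
                continue
            if end < n and col_has_gap(end + 1):
                continue
            gapped = frozenset(
                t for t in taxa
                if all(rows[t][c - 1] == "-" for c in range(start, end + 1)))
            bearing = frozenset(taxa) - gapped
            counts = {
                t: sum(1 for c in range(start, end + 1)
                       if rows[t][c - 1] != "-")
                for t in bearing
            }
            blocks.append((start, end, gapped, bearing, counts))
    return sorted(blocks)


@pytest.fixture
def planted_family():
    """A default synthetic family with a 5-residue ingroup insertion."""
    spec = FamilySpec(seed=42)
    alignment, truth = generate_family(spec)
    return spec, alignment, truth, spec.partition("TestClade")


@pytest.fixture
def toy_partition():
    return CladePartition("toy", frozenset({"a", "b", "c"}),
                          frozenset({"d", "e", "f"}))
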