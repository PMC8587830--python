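"""Position maps: built-in aligner vs an independent DP oracle, FASTA import."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from contactdiff.contact_map import ContactMap
from contactdiff.seqalign import (
    AlignmentError,
    AlignParams,
    PositionMap,
    align_pair,
    identity_map,
    load_alignment,
    map_contact,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def affine_nw_score(a, b, matrix, gap_open, gap_extend):
    """Independent affine-gap global alignment optimum (Gotoh three-matrix DP).

    Gap of length L costs gap_open + (L-1)*gap_extend, matching the
    aligner's open/extend convention.
    """
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (moving along a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def test_identical_sequences_give_identity_map():
    pm = align_pair("GASDV", "GASDV")
    assert pm.pairs == tuple((i, i) for i in range(1, 6))


def test_substitution_does_not_break_mapping():
    pm = align_pair("GASDV", "GACDV")
    assert pm.pairs == tuple((i, i) for i in range(1, 6))


def test_empty_sequence_rejected():
    with pytest.raises(AlignmentError):
        align_pair("", "GAS")


def test_alignment_score_matches_dp_oracle():
    from Bio import Align

    params = AlignParams()
    matrix = substitution_matrices.load(params.matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = "".join(rng.choice(list(AA), size=8))
        b = "".join(rng.choice(list(AA), size=8))
        expected = affine_nw_score(a, b, matrix, params.gap_open, params.gap_extend)
        assert aligner.score(a, b) == pytest.approx(expected)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.text(alphabet=AA, min_size=1, max_size=25),
    b=st.text(alphabet=AA, min_size=1, max_size=25),
)
def test_position_maps_are_strictly_increasing_and_one_to_one(a, b):
    pm = align_pair(a, b)
    rs = [r for r, _ in pm.pairs]
    ts = [t for _, t in pm.pairs]
    assert rs == sorted(set(rs)) and ts == sorted(set(ts))
    assert all(1 <= r <= len(a) for r in rs)
    assert all(1 <= t <= len(b) for t in ts)


def test_position_map_invariant_rejects_crossings():
    with pytest.raises(ValueError):
        PositionMap("a", "b", ((1, 2), (2, 1)))


MSA = ">ref\nGASDV\n>tgt\nGA-DV\n>extra\nGASDV\n"


def test_msa_gap_column_unmapped(tmp_path):
    p = tmp_path / "aln.fasta"
    p.write_text(MSA)
    pm = load_alignment(p, "ref", "tgt")
    assert pm.as_dict() == {1: 1, 2: 2, 4: 3, 5: 4}  # ref position 3 unmapped


def test_msa_projection_independent_of_other_rows(tmp_path):
    p = tmp_path / "aln3.fasta"
    p.write_text(MSA)
    p2 = tmp_path / "aln2.fasta"
    p2.write_text(">ref\nGASDV\n>tgt\nGA-DV\n")
    assert load_alignment(p, "ref", "tgt") == load_alignment(p2, "ref", "tgt")


def test_msa_no_gaps_identity(tmp_path):
    p = tmp_path / "flat.fasta"
    p.write_text(">a\nGASDV\n>b\nMASDV\n")
    assert load_alignment(p, "a", "b").pairs == tuple((i, i) for i in range(1, 6))


def test_msa_errors(tmp_path):
    p = tmp_path / "ragged.fasta"
    p.write_text(">a\nGASDV\n>b\nGAS\n")
    with pytest.raises(AlignmentError):
        load_alignment(p, "a", "b")
    with pytest.raises(AlignmentError):
        load_alignment(p, "a", "missing")


def test_map_contact_statuses():
    tgt = ContactMap("t", 5.0, "all_atom", 2, frozenset({(2, 7)}))
    pm = identity_map("r", "t", 10)
    assert map_contact((2, 7), pm, tgt) == "shared"
    assert map_contact((2, 6), pm, tgt) == "absent"
    partial = PositionMap("r", "t", ((2, 2),))  # endpoint 7 unmapped
    assert map_contact((2, 7), partial, tgt) == "unalignable"


def test_map_contact_under_identity_is_set_membership(default_dataset):
    from contactdiff.contact_map import build_contact_map

    m = default_dataset.models[1]
    cm = build_contact_map(m)
    pm = identity_map("m", "m", len(m))
    for c in cm.contacts:
        assert map_contact(c, pm, cm) == "shared"
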