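"""Pairwise alignment scores, percent identity, core trimming, distances."""

import numpy as np
import pytest

from pletype.align import (
    AlignmentParams,
    CoreRegion,
    NoCoreFoundError,
    PairwiseAlignment,
    distance_matrix,
    global_align,
    percent_identity,
    trim_to_core,
)
from pletype.synthetic import reference_core, make_gene, SimSpec

from conftest import random_nt

# ------------------------------------------------------------- DP oracle


def gotoh_score(a, b, match=5.0, mismatch=-4.0, gap_open=10.0, gap_extend=0.5):
    """Textbook affine-gap global alignment score (first gap residue costs
    gap_open, each further residue gap_extend)."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


# ------------------------------------------------------------ global_align


def test_self_alignment_is_gapless_full_score():
    s = "ACGTACGTACGT"
    aln = global_align(s, s)
    assert aln.a == aln.b == s
    assert aln.score == 5.0 * len(s)
    assert percent_identity(aln) == 100.0


def test_single_deletion_produces_one_gap_column():
    aln = global_align("ACGT", "ACT")
    assert sorted([aln.a.count("-"), aln.b.count("-")]) == [0, 1]


def test_alignment_score_matches_dp_oracle():
    rng = np.random.default_rng(77)
    for _ in range(15):
        a = random_nt(rng, int(rng.integers(20, 60)))
        b = random_nt(rng, int(rng.integers(20, 60)))
        aln = global_align(a, b)
        assert aln.score == pytest.approx(gotoh_score(a, b), abs=1e-9)


def test_score_invariant_under_pair_swap(rng):
    a, b = random_nt(rng, 80), random_nt(rng, 75)
    assert global_align(a, b).score == pytest.approx(global_align(b, a).score)


def test_mixed_alphabet_rejected():
    with pytest.raises(ValueError):
        global_align("ACGT", "MKLF", AlignmentParams(alphabet="nt"))


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_align("", "ACGT")


# -------------------------------------------------------- percent_identity


def test_identity_equals_hamming_for_gapfree_pairs(rng):
    for _ in range(10):
        a = random_nt(rng, 300)
        b = list(a)
        k = int(rng.integers(1, 30))
        pos = rng.choice(300, size=k, replace=False)
        for i in pos:
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b)
        hamming = sum(x != y for x, y in zip(a, b))
        aln = global_align(a, b)
        if "-" not in aln.a + aln.b:  # gapless optimum: exact Hamming identity
            assert percent_identity(aln) == pytest.approx(100 * (1 - hamming / 300))


def test_ten_percent_mutation_gives_about_ninety_identity():
    rng = np.random.default_rng(99)
    a = random_nt(rng, 1000)
    b = list(a)
    pos = rng.choice(1000, size=100, replace=False)
    for i in pos:
        b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
    ident = percent_identity(global_align(a, "".join(b)))
    assert ident == pytest.approx(90.0, abs=1.5)


def test_identity_symmetry_and_range(rng):
    a, b = random_nt(rng, 120), random_nt(rng, 110)
    i1 = percent_identity(global_align(a, b))
    i2 = percent_identity(global_align(b, a))
    assert i1 == pytest.approx(i2)
    assert 0.0 <= i1 <= 100.0


def test_terminal_gap_exclusion():
    aln = PairwiseAlignment("AAACGT", "---CGT", 0.0)
    assert percent_identity(aln, "exclude") == 100.0
    assert percent_identity(aln, "include") == pytest.approx(50.0)
    with pytest.raises(ValueError):
        percent_identity(PairwiseAlignment("AA--", "--AA", 0.0), "exclude")


# ----------------------------------------------------------- trim_to_core


@pytest.fixture(scope="module")
def core():
    return CoreRegion.packaged()


def test_core_region_geometry(core):
    assert len(core) == 878
    assert core.end - core.start + 1 == 878
    with pytest.raises(ValueError):
        CoreRegion(core_seq="ACGT" * 10)  # wrong length for 590..1467


def test_full_gene_trims_to_exact_core(core):
    gene = make_gene(SimSpec(seed=5), np.random.default_rng(5))
    frag = trim_to_core(gene, core)
    assert len(frag.sequence) == 878
    assert frag.sequence == core.core_seq
    assert frag.coverage == pytest.approx(1.0)
    assert not frag.partial


def test_trimming_core_itself_is_identity(core):
    frag = trim_to_core(core.core_seq, core)
    assert frag.sequence == core.core_seq
    assert frag.coverage == pytest.approx(1.0)


def test_trim_is_idempotent(core):
    gene = make_gene(SimSpec(seed=6), np.random.default_rng(6))
    once = trim_to_core(gene, core)
    twice = trim_to_core(once.sequence, core)
    assert twice.sequence == once.sequence
    assert twice.coverage == pytest.approx(1.0)


def test_three_prime_truncation_flags_partial(core):
    truncated = core.core_seq[:-100]
    frag = trim_to_core(truncated, core)
    assert frag.coverage == pytest.approx(778 / 878, abs=1e-3)
    assert frag.partial


def test_non_pleb_queries_are_rejected_or_heavily_partial(core, rng):
    # low-complexity input: almost none of the core aligns -> hard error
    with pytest.raises(NoCoreFoundError):
        trim_to_core("A" * 900, core)
    # unrelated random DNA: gapped alignment hovers near background identity
    # with low coverage; a stricter identity floor rejects it outright
    q = random_nt(rng, 900)
    frag = trim_to_core(q, core)
    assert frag.partial and frag.identity < 55.0
    with pytest.raises(NoCoreFoundError):
        trim_to_core(q, core, min_identity=60.0)


def test_short_query_rejected(core):
    with pytest.raises(ValueError):
        trim_to_core("ACGT" * 40, core)


# -------------------------------------------------------- distance_matrix


def test_identical_sequences_give_zero_matrix():
    dm = distance_matrix([("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGTACGT")])
    assert np.allclose(dm.values, 0.0)


def test_distance_matrix_matches_pairwise_loop(rng):
    seqs = [(f"s{i}", random_nt(rng, 150)) for i in range(6)]
    dm = distance_matrix(seqs)
    for i in range(6):
        for j in range(i + 1, 6):
            expected = 1 - percent_identity(global_align(seqs[i][1], seqs[j][1])) / 100
            assert dm.values[i, j] == pytest.approx(expected)
            assert dm.values[j, i] == dm.values[i, j]
    assert np.allclose(np.diag(dm.values), 0.0)


def test_duplicate_labels_rejected(rng):
    seqs = [("a", "ACGTAC"), ("a", "ACGTAA"), ("b", "ACGTAT")]
    with pytest.raises(ValueError, match="duplicate"):
        distance_matrix(seqs)


def test_phylip_and_tsv_export(rng):
    dm = distance_matrix([("a 1", "ACGTAC"), ("b", "ACGTAA"), ("c", "ACGTAT")])
    phy = dm.to_phylip()
    assert phy.startswith(" 3\n")
    assert "a_1" in phy
    assert dm.to_tsv().count("\n") == 4
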