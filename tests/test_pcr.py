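"""IUPAC matching, primer degeneracy, site search, virtual amplification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pletype.pcr import (
    BANAMPGAC,
    PUTXANTOL,
    DegeneratePrimer,
    amplify,
    degeneracy,
    expansions,
    find_sites,
    iupac_sets,
    reverse_complement,
)

from conftest import random_nt

# ---------------------------------------------------------------- oracles

SETS = iupac_sets()


def brute_degeneracy(seq: str) -> int:
    """Count expansions by exhaustive enumeration (inosine = one molecule)."""
    n = 1
    for c in seq.replace(" ", "").upper():
        n *= 1 if c == "I" else len(SETS[c])
    return n


def brute_sites(template: str, primer: DegeneratePrimer, max_mismatch: int,
                clamp_len: int):
    """Position-by-position scan over all offsets and both strands."""
    template = template.upper()
    P = len(primer.sequence)
    out = []
    for strand in "+-":
        pat = primer.sequence if strand == "+" else reverse_complement(primer.sequence)
        # 3' end: last position on +, first position on -
        clamp = (
            set(range(P - clamp_len, P)) if strand == "+" else set(range(clamp_len))
        )
        for off in range(len(template) - P + 1):
            bad = [
                k
                for k in range(P)
                if not (SETS[pat[k]] & SETS[template[off + k]])
            ]
            if len(bad) <= max_mismatch and not any(k in clamp for k in bad):
                out.append((strand, off + 1, off + P, len(bad)))
    return sorted(out, key=lambda t: (t[1], t[0]))


# ------------------------------------------------------------- iupac table


def test_iupac_sets_cover_all_codes():
    assert SETS["R"] == {"A", "G"}
    assert SETS["N"] == {"A", "C", "G", "T"}
    assert SETS["B"] == {"C", "G", "T"}
    assert SETS["I"] == {"A", "C", "G", "T"}
    assert len(SETS) == 16
    for code, bases in SETS.items():
        assert bases <= {"A", "C", "G", "T"}, code


def test_reverse_complement_involution():
    assert reverse_complement("ACGT") == "ACGT"
    s = "TGCACAACGTCGARATBCC"
    assert reverse_complement(reverse_complement(s)) == s
    with pytest.raises(ValueError):
        reverse_complement("ACGJ")


# ------------------------------------------------------------- degeneracy


@pytest.mark.parametrize(
    "primer, expected",
    [
        (BANAMPGAC[0], 6),    # R x B
        (BANAMPGAC[1], 16),   # I(x1) x R x R x R x Y
        (PUTXANTOL[0], 48),   # Y x R x R x S x B
        (PUTXANTOL[1], 8),    # R x R x R
    ],
)
def test_published_primer_degeneracy_matches_enumeration(primer, expected):
    assert degeneracy(primer) == expected
    assert len(set(expansions(primer))) == expected
    assert brute_degeneracy(primer.sequence) == expected


def test_plain_sequence_has_degeneracy_one():
    assert degeneracy("ACGTACGTACGTACGT") == 1
    with pytest.raises(ValueError):
        degeneracy("ACGJACGTACGTACG")


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTRYSWKMBDHVNI", min_size=15, max_size=24))
def test_degeneracy_equals_bruteforce_enumeration(seq):
    assert degeneracy(seq) == brute_degeneracy(seq)


def test_primer_validation():
    with pytest.raises(ValueError):
        DegeneratePrimer("short", "ACGTACGT", "forward")
    with pytest.raises(ValueError):
        DegeneratePrimer("badchar", "ACGTACGTACGTACGJ", "forward")
    with pytest.raises(ValueError):
        DegeneratePrimer("badrole", "ACGTACGTACGTACGT", "fwd")


# ------------------------------------------------------------- find_sites


def test_embedded_expansion_found_with_zero_mismatches(rng):
    fwd = BANAMPGAC[0]
    site = next(expansions(fwd))
    template = random_nt(rng, 200) + site + random_nt(rng, 200)
    hits = [s for s in find_sites(template, fwd) if s.mismatches == 0]
    assert any(s.start == 201 and s.strand == "+" for s in hits)


def test_reverse_complement_template_gives_minus_strand_site(rng):
    fwd = PUTXANTOL[0]
    site = next(expansions(fwd))
    template = random_nt(rng, 150) + site + random_nt(rng, 150)
    rc = reverse_complement(template)
    plus = [s for s in find_sites(template, fwd) if s.mismatches == 0]
    minus = [s for s in find_sites(rc, fwd) if s.mismatches == 0]
    assert any(s.strand == "+" for s in plus)
    assert any(s.strand == "-" for s in minus)
    # mirrored coordinates
    p = next(s for s in plus if s.strand == "+")
    m = next(s for s in minus if s.strand == "-")
    assert m.start == len(template) - p.end + 1


def test_template_shorter_than_primer_is_empty():
    assert find_sites("ACGT", BANAMPGAC[0]) == []


@pytest.mark.parametrize("max_mismatch", [0, 1, 2])
def test_site_search_matches_bruteforce_scan(max_mismatch):
    rng = np.random.default_rng(500 + max_mismatch)
    primers = [BANAMPGAC[0], BANAMPGAC[1], PUTXANTOL[0], PUTXANTOL[1]]
    for rep in range(25):
        template = random_nt(rng, int(rng.integers(300, 900)))
        primer = primers[rep % 4]
        got = find_sites(template, primer, max_mismatch, clamp_len=3)
        expected = brute_sites(template, primer, max_mismatch, clamp_len=3)
        assert [(s.strand, s.start, s.end, s.mismatches) for s in got] == expected


def test_mismatch_monotonicity(rng):
    template = random_nt(rng, 2000)
    primer = PUTXANTOL[0]
    prev: set = set()
    for mm in (0, 1, 2, 3):
        sites = {(s.strand, s.start) for s in find_sites(template, primer, mm)}
        assert prev <= sites
        prev = sites


# --------------------------------------------------------------- amplify


def _construct(rng, fwd, rev, insert_len):
    return (
        random_nt(rng, 120)
        + next(expansions(fwd))
        + random_nt(rng, insert_len)
        + reverse_complement(next(expansions(rev)))
        + random_nt(rng, 120)
    )


def test_constructed_template_yields_exact_product_length(rng):
    fwd, rev = BANAMPGAC
    template = _construct(rng, fwd, rev, 900)
    hits = amplify(template, fwd, rev)
    assert len(hits) == 1
    h = hits[0]
    assert h.product_length == 900 + len(fwd) + len(rev)
    assert h.product_length == len(h.product_seq)
    assert h.fwd_site.strand == "+" and h.rev_site.strand == "-"


def test_forward_site_alone_gives_no_product(rng):
    fwd, rev = PUTXANTOL
    template = random_nt(rng, 300) + next(expansions(fwd)) + random_nt(rng, 800)
    assert amplify(template, fwd, rev) == []


def test_strand_symmetry_of_amplification(rng):
    fwd, rev = BANAMPGAC
    template = _construct(rng, fwd, rev, 700)
    a = amplify(template, fwd, rev)
    b = amplify(reverse_complement(template), fwd, rev)
    assert [h.product_seq for h in a] == [h.product_seq for h in b]
    assert [h.product_length for h in a] == [h.product_length for h in b]
    # coordinates mirror
    L = len(template)
    assert a[0].fwd_site.start == L - b[0].fwd_site.end + 1


def test_size_window_monotonicity(rng):
    fwd, rev = BANAMPGAC
    template = _construct(rng, fwd, rev, 900)
    small = amplify(template, fwd, rev, size_max=500)
    assert small == []
    grown = amplify(template, fwd, rev, size_max=2500)
    assert len(grown) == 1


def test_bad_size_window_raises(rng):
    fwd, rev = BANAMPGAC
    with pytest.raises(ValueError):
        amplify("ACGT" * 300, fwd, rev, size_min=1000, size_max=500)


def test_role_check():
    fwd, rev = BANAMPGAC
    with pytest.raises(ValueError):
        amplify("ACGT" * 300, rev, fwd)
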