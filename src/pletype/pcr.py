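"""In-silico PCR with IUPAC-degenerate primers.

Models virtual amplification of the ~2-kb *pleB* marker gene of
lipopeptide-producing *Pseudomonas* with the two published degenerate
primer pairs: ``BanAmpGac`` (Bananamide/Amphisin/Gacamide families,
~1,300-bp product) and ``PutXanTol`` (Putisolvin/Xantholysin/Entolysin/
Tolaasin families, ~1,000-bp product).

Matching is purely sequence-based: a primer position is compatible with a
template position when their IUPAC base sets intersect.  Thermodynamics
(melting temperature, annealing, dimers) are deliberately not modeled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegeneratePrimer",
    "PrimerSite",
    "AmpliconHit",
    "BANAMPGAC",
    "PUTXANTOL",
    "PRIMER_SETS",
    "iupac_sets",
    "degeneracy",
    "expansions",
    "reverse_complement",
    "find_sites",
    "amplify",
]

# Base-set encoding: A=1, C=2, G=4, T=8; an IUPAC code is the OR of its bases.
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    # Inosine: a universal-pairing nucleoside analog used in wet primers.
    # It matches any template base but is a single physical nucleotide, so it
    # contributes x1 to degeneracy (see `degeneracy`).
    "I": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    "I": "N",  # complement of an any-base position is any-base
}

_MASK = {code: np.uint8(sum(_BITS[b] for b in bases)) for code, bases in _IUPAC.items()}
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in _MASK.items():
    _MASK_LUT[ord(_c)] = _m
    _MASK_LUT[ord(_c.lower())] = _m


def iupac_sets() -> dict[str, frozenset[str]]:
    """Return the IUPAC ambiguity table (15 codes plus inosine ``I``)."""
    return dict(_IUPAC)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string, IUPAC codes included."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"not a IUPAC nucleotide code: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named IUPAC-degenerate oligonucleotide, written 5'->3'."""

    name: str
    sequence: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        seq = self.sequence.replace(" ", "").upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set(_IUPAC)
        if bad:
            raise ValueError(f"primer {self.name}: invalid IUPAC code(s) {sorted(bad)}")
        if len(seq) < 15:
            raise ValueError(f"primer {self.name}: length {len(seq)} < 15")
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name}: role must be forward/reverse")

    def __len__(self) -> int:
        return len(self.sequence)


# The two published assay primer pairs.
BANAMPGAC = (
    DegeneratePrimer("BanAmpGac F", "TGC ACA ACG TCG ARA TBC C", "forward"),
    DegeneratePrimer("BanAmpGac R", "GCC ATI CGR ATR CCR ATY TC", "reverse"),
)
PUTXANTOL = (
    DegeneratePrimer("PutXanTol F", "YGG CAA RGA RGT SAT GAA BA", "forward"),
    DegeneratePrimer("PutXanTol R", "TGC ATR ATG CTR TCR AGG TT", "reverse"),
)
PRIMER_SETS: dict[str, tuple[DegeneratePrimer, DegeneratePrimer]] = {
    "BanAmpGac": BANAMPGAC,
    "PutXanTol": PUTXANTOL,
}


def degeneracy(primer: DegeneratePrimer | str) -> int:
    """Number of distinct concrete oligonucleotides the primer encodes.

    Product over positions of base-set sizes; inosine counts as one
    nucleotide (it is a single analog, not a synthesis mixture).
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.replace(" ", "").upper()
    n = 1
    for c in seq:
        if c not in _IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r}")
        n *= 1 if c == "I" else len(_IUPAC[c])
    return n


def expansions(primer: DegeneratePrimer | str):
    """Yield every concrete A/C/G/T expansion of a degenerate primer.

    Inosine positions are expanded to a single arbitrary representative
    (``A``) since any template base pairs with them.
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.replace(" ", "").upper()
    pools = [sorted(_IUPAC[c]) if c != "I" else ["A"] for c in seq]
    for combo in itertools.product(*pools):
        yield "".join(combo)


@dataclass(frozen=True)
class PrimerSite:
    """A putative primer-binding site on a template (+ strand coordinates)."""

    template_id: str
    primer_name: str
    strand: str  # "+" | "-"
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    mismatches: int
    three_prime_mismatch: bool


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product."""

    template_id: str
    primer_set: str
    fwd_site: PrimerSite
    rev_site: PrimerSite
    product_length: int
    product_seq: str


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _MASK_LUT[arr]
    if np.any(masks == 0):
        bad = sorted({seq[i] for i in np.nonzero(masks == 0)[0][:5]})
        raise ValueError(f"template contains non-IUPAC character(s): {bad}")
    return masks


def _scan_one_strand(tmask: np.ndarray, pmask: np.ndarray, max_mismatch: int,
                     clamp_idx: np.ndarray) -> list[tuple[int, int, bool]]:
    """All offsets (0-based) where primer-vs-template incompatibilities fit.

    Returns (offset, n_mismatch, clamp_hit) tuples; offsets with a clamp-region
    incompatibility are excluded from amplifiable sites but flagged here.
    """
    L, P = len(tmask), len(pmask)
    if L < P:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(tmask, P)
    incompat = (windows & pmask) == 0  # (L-P+1, P) boolean
    total = incompat.sum(axis=1)
    ok = np.nonzero(total <= max_mismatch)[0]
    out = []
    for off in ok:
        clamp_hit = bool(incompat[off, clamp_idx].any()) if clamp_idx.size else False
        out.append((int(off), int(total[off]), clamp_hit))
    return out


def find_sites(
    template: str,
    primer: DegeneratePrimer,
    max_mismatch: int = 2,
    clamp_len: int = 3,
    template_id: str = "template",
    keep_clamp_violations: bool = False,
) -> list[PrimerSite]:
    """Locate primer-binding sites on both strands of a template.

    A template position is compatible with a primer position when their IUPAC
    base sets intersect.  A site qualifies when it has at most ``max_mismatch``
    incompatible positions and none of them falls within the 3'-terminal
    ``clamp_len`` bases of the primer (the polymerase-extension clamp).
    Coordinates are 1-based inclusive on the + strand; sorted by start.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    template = template.upper()
    if len(template) < len(primer):
        return []
    tmask = _encode(template)
    P = len(primer)
    sites: list[PrimerSite] = []

    # + strand: primer read 5'->3' left-to-right; 3' clamp = last clamp_len.
    pmask_fwd = _encode(primer.sequence)
    clamp_fwd = np.arange(max(0, P - clamp_len), P)
    for off, nm, clamp_hit in _scan_one_strand(tmask, pmask_fwd, max_mismatch, clamp_fwd):
        if clamp_hit and not keep_clamp_violations:
            continue
        sites.append(PrimerSite(template_id, primer.name, "+", off + 1, off + P, nm, clamp_hit))

    # - strand: match the reverse complement pattern on the + strand; the
    # primer's 3' end then sits at the lowest template coordinate.
    pmask_rev = _encode(reverse_complement(primer.sequence))
    clamp_rev = np.arange(0, min(clamp_len, P))
    for off, nm, clamp_hit in _scan_one_strand(tmask, pmask_rev, max_mismatch, clamp_rev):
        if clamp_hit and not keep_clamp_violations:
            continue
        sites.append(PrimerSite(template_id, primer.name, "-", off + 1, off + P, nm, clamp_hit))

    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    template: str,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    max_mismatch: int = 2,
    clamp_len: int = 3,
    size_min: int = 400,
    size_max: int = 2500,
    template_id: str = "template",
    primer_set: str | None = None,
) -> list[AmpliconHit]:
    """Pair forward/reverse primer sites into virtual PCR products.

    A product forms between a forward site and a downstream reverse site on
    opposite strands; the symmetric orientation (forward primer binding the
    - strand) is also reported, with the product sequence given on the
    forward-primer strand.  Products outside [size_min, size_max] are
    suppressed, mimicking the size window of a wet assay.
    """
    if fwd.role != "forward" or rev.role != "reverse":
        raise ValueError("amplify() expects fwd.role='forward' and rev.role='reverse'")
    if size_min > size_max:
        raise ValueError(f"size_min ({size_min}) > size_max ({size_max})")
    template = template.upper()
    setname = primer_set or f"{fwd.name}/{rev.name}"
    fsites = find_sites(template, fwd, max_mismatch, clamp_len, template_id)
    rsites = find_sites(template, rev, max_mismatch, clamp_len, template_id)

    hits: list[AmpliconHit] = []
    for fs in fsites:
        for rs in rsites:
            if fs.strand == "+" and rs.strand == "-" and rs.start > fs.start:
                length = rs.end - fs.start + 1
                if size_min <= length <= size_max:
                    seq = template[fs.start - 1 : rs.end]
                    hits.append(AmpliconHit(template_id, setname, fs, rs, length, seq))
            elif fs.strand == "-" and rs.strand == "+" and fs.end > rs.start:
                length = fs.end - rs.start + 1
                if size_min <= length <= size_max:
                    seq = reverse_complement(template[rs.start - 1 : fs.end])
                    hits.append(AmpliconHit(template_id, setname, fs, rs, length, seq))
    hits.sort(key=lambda h: (h.product_length, h.fwd_site.start))
    return hits
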