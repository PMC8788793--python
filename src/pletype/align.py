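"""Pairwise alignment, percent identity, diagnostic-core trimming.

All identity figures in the typing workflow are pairwise: queries against
reference *pleB* genes, and the ~880-bp diagnostic core against full-length
genes or Sanger amplicons.  The diagnostic core corresponds to nucleotide
positions 590-1467 (878 nt) of the *arfE* reference gene and covers the MacB
periplasmic core domain that initiates selective lipopeptide export.

Dynamic programming is delegated to :class:`Bio.Align.PairwiseAligner`
(affine gaps); this module owns the scoring conventions, the identity
bookkeeping and the trimming logic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentParams",
    "PairwiseAlignment",
    "CoreRegion",
    "TrimmedFragment",
    "DistanceMatrix",
    "global_align",
    "percent_identity",
    "trim_to_core",
    "distance_matrix",
    "NoCoreFoundError",
]

_NT = set("ACGTRYSWKMBDHVN-")
_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")


class NoCoreFoundError(ValueError):
    """The diagnostic core could not be located in the query (likely not pleB)."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for pairwise alignment.

    Nucleotide default +5/-4 with affine gaps (open 10, extend 0.5); protein
    scoring uses BLOSUM62.  ``mode`` is ``global`` (Needleman-Wunsch) or
    ``semiglobal`` (free terminal gaps, for locating a fragment inside a
    longer sequence).
    """

    match_score: float = 5.0
    mismatch_score: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    mode: str = "global"
    alphabet: str = "nt"  # "nt" | "aa"

    def __post_init__(self) -> None:
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.mode not in ("global", "semiglobal"):
            raise ValueError("mode must be 'global' or 'semiglobal'")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError("alphabet must be 'nt' or 'aa'")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        if self.alphabet == "aa":
            a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        else:
            a.match_score = self.match_score
            a.mismatch_score = self.mismatch_score
        a.open_gap_score = -self.gap_open
        a.extend_gap_score = -self.gap_extend
        if self.mode == "semiglobal":
            a.end_insertion_score = 0.0
            a.end_deletion_score = 0.0
        return a


DEFAULT_NT = AlignmentParams()
DEFAULT_AA = AlignmentParams(alphabet="aa")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment (rows of equal length) with its score."""

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b) or not self.a:
            raise ValueError("alignment rows must be non-empty and equal length")

    def __len__(self) -> int:
        return len(self.a)


def _check_alphabets(a: str, b: str, alphabet: str) -> None:
    allowed = _NT if alphabet == "nt" else _AA
    for name, s in (("a", a), ("b", b)):
        bad = set(s) - allowed
        if bad:
            raise ValueError(
                f"sequence {name} contains characters {sorted(bad)} outside the "
                f"{alphabet} alphabet; check that both sequences share one alphabet"
            )


def global_align(a: str, b: str, params: AlignmentParams = DEFAULT_NT) -> PairwiseAlignment:
    """Optimal affine-gap pairwise alignment of two sequences.

    Traceback is deterministic (the aligner's first-ranked path, preferring
    substitution columns over gaps on ties).
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_alphabets(a, b, params.alphabet)
    aln = params.aligner().align(a, b)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def percent_identity(alignment: PairwiseAlignment, terminal_gaps: str = "exclude") -> float:
    """100 x matches / counted columns.

    With ``terminal_gaps='exclude'`` (default), columns inside leading or
    trailing gap runs of either row are not counted, so a partial amplicon
    compares fairly against a full-length gene.
    """
    if terminal_gaps not in ("exclude", "include"):
        raise ValueError("terminal_gaps must be 'exclude' or 'include'")
    a, b = alignment.a, alignment.b
    lo, hi = 0, len(a)
    if terminal_gaps == "exclude":
        while lo < hi and (a[lo] == "-" or b[lo] == "-"):
            lo += 1
        while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
            hi -= 1
    n = hi - lo
    if n == 0:
        raise ValueError("all alignment columns excluded; identity undefined")
    matches = sum(1 for i in range(lo, hi) if a[i] == b[i] and a[i] != "-")
    return 100.0 * matches / n


@dataclass(frozen=True)
class CoreRegion:
    """The ~880-bp diagnostic region shared by both amplicon types.

    Coordinates follow the *arfE* reference gene (positions 590-1467, i.e.
    878 nt).  The packaged default carries a synthetic stand-in sequence of
    the same geometry (see :func:`pletype.synthetic.reference_core`); supply
    the real user-fetched reference sequence to type against public data.
    """

    core_seq: str
    reference_id: str = "arfE-core-synthetic-standin"
    start: int = 590
    end: int = 1467

    def __post_init__(self) -> None:
        object.__setattr__(self, "core_seq", self.core_seq.upper())
        if self.end - self.start + 1 != len(self.core_seq):
            raise ValueError(
                f"core coordinates {self.start}-{self.end} imply "
                f"{self.end - self.start + 1} nt, got {len(self.core_seq)}"
            )

    @classmethod
    def packaged(cls) -> "CoreRegion":
        from .synthetic import reference_core

        return cls(core_seq=reference_core())

    def __len__(self) -> int:
        return len(self.core_seq)


@dataclass(frozen=True)
class TrimmedFragment:
    """Result of trimming a query to the diagnostic core."""

    query_id: str
    sequence: str
    coverage: float     # fraction of core positions aligned to query bases
    identity: float     # % identity over the aligned core region
    partial: bool       # coverage < 0.9


def trim_to_core(
    query: str,
    core: CoreRegion | None = None,
    params: AlignmentParams | None = None,
    query_id: str = "query",
    min_identity: float = 40.0,
    min_coverage: float = 0.3,
    partial_below: float = 0.9,
) -> TrimmedFragment:
    """Extract the diagnostic-core-matching subsequence of a query.

    The core is aligned semiglobally against the query; the returned fragment
    is the query subsequence spanning the aligned core columns.  Queries whose
    aligned region falls below ``min_identity`` percent identity — or where
    less than ``min_coverage`` of the core aligns at all, as with
    low-complexity input — raise :class:`NoCoreFoundError` (the input is
    probably not a *pleB* gene).  Note that gapped alignment of unrelated
    random DNA yields ~43% identity at low coverage: such input passes
    trimming as heavily partial and is rejected later at typing, below the
    family identity floor.
    """
    query = query.upper()
    if len(query) < 200:
        raise ValueError(f"query {query_id!r} is {len(query)} nt; need >= 200")
    if core is None:
        core = CoreRegion.packaged()
    params = replace(params or DEFAULT_NT, mode="semiglobal")
    aln = params.aligner().align(query, core.core_seq)[0]
    blocks_q, blocks_c = aln.aligned  # matched blocks: query coords, core coords
    if len(blocks_q) == 0:
        raise NoCoreFoundError(f"no alignment between core and query {query_id!r}")
    q_lo, q_hi = int(blocks_q[0][0]), int(blocks_q[-1][1])
    aligned_core = int(sum(e - s for s, e in blocks_c))
    coverage = aligned_core / len(core)
    ident = percent_identity(PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score)))
    if coverage < min_coverage:
        raise NoCoreFoundError(
            f"only {coverage:.1%} of the diagnostic core aligns to {query_id!r} "
            f"(< {min_coverage:.0%}); query likely not pleB"
        )
    if ident < min_identity:
        raise NoCoreFoundError(
            f"aligned core region of {query_id!r} is only {ident:.1f}% identical "
            f"(< {min_identity}%); query likely not pleB"
        )
    return TrimmedFragment(
        query_id=query_id,
        sequence=query[q_lo:q_hi],
        coverage=coverage,
        identity=ident,
        partial=coverage < partial_below,
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise-distance matrix, distance = 1 - identity/100."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM

        return SkbioDM(self.values, ids=list(self.labels))

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab.replace(" ", "_") + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        header = "\t".join(("",) + self.labels)
        lines = [header]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def distance_matrix(
    seqs: list[tuple[str, str]] | dict[str, str],
    params: AlignmentParams = DEFAULT_NT,
) -> DistanceMatrix:
    """All-pairs identity distances (input order preserved)."""
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len(items) < 3:
        raise ValueError("need at least 3 sequences")
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    n = len(items)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(global_align(items[i][1], items[j][1], params))
            vals[i, j] = vals[j, i] = 1.0 - ident / 100.0
    return DistanceMatrix(tuple(labels), vals)
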