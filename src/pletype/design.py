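"""Degenerate-primer candidate design from aligned pleB sequences.

Re-derives consensus primer candidates the way the published assay primers
were obtained: scan windows of a multiple alignment, collapse each column
to the smallest IUPAC code covering its observed bases, and keep windows
whose total degeneracy stays low and whose 3'-clamp columns are
non-degenerate.  When no window qualifies, the empty result mirrors the
finding that a single primer set covering all families was not possible.

Alignments are user-supplied (any aligner); only equal lengths are checked.
Inosine is accepted in input primers elsewhere but never emitted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .pcr import iupac_sets

logger = logging.getLogger(__name__)

__all__ = ["PrimerCandidate", "GAP_SENTINEL", "column_consensus", "scan_windows",
           "pair_candidates"]

GAP_SENTINEL = "-"

_SETS = {k: v for k, v in iupac_sets().items() if k != "I"}
_CODE_FOR = {frozenset(v): k for k, v in _SETS.items()}


@dataclass(frozen=True)
class PrimerCandidate:
    """A consensus window over the design alignment."""

    window_start: int  # 1-based alignment column of the window's first base
    length: int
    consensus: str  # IUPAC, 5'->3' in primer orientation
    degeneracy: int
    worst_column_coverage: float  # min over columns of covered-base fraction
    orientation: str  # forward | reverse


def column_consensus(column: list[str], min_freq: float = 0.05) -> str:
    """Smallest IUPAC code covering every base at frequency >= min_freq.

    Gap-majority columns (or columns whose bases are all below min_freq)
    return the gap sentinel, which disqualifies any window containing them.
    """
    if not column:
        raise ValueError("empty column")
    bases = [c.upper() for c in column]
    n = len(bases)
    gaps = bases.count("-")
    if gaps * 2 >= n:
        return GAP_SENTINEL
    counts: dict[str, int] = {}
    for b in bases:
        if b == "-":
            continue
        if b not in "ACGT":
            # ambiguous input base: spread over its set (conservative coverage)
            for sub in _SETS[b]:
                counts[sub] = counts.get(sub, 0) + 1
            continue
        counts[b] = counts.get(b, 0) + 1
    non_gap = n - gaps
    keep = frozenset(b for b, c in counts.items() if c / non_gap >= min_freq or min_freq == 0)
    if not keep:
        return GAP_SENTINEL
    return _CODE_FOR[keep]


def _column_coverage(column: list[str], code: str) -> float:
    covered = _SETS[code]
    obs = [c.upper() for c in column if c != "-"]
    if not obs:
        return 0.0
    ok = sum(1 for b in obs if frozenset(_SETS.get(b, b)) <= covered or b in covered)
    return ok / len(obs)


def _revcomp_code(code: str) -> str:
    comp = {frozenset({"A"}): "T", frozenset({"C"}): "G", frozenset({"G"}): "C",
            frozenset({"T"}): "A"}
    flipped = frozenset({"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in _SETS[code])
    return _CODE_FOR[flipped]


def scan_windows(
    alignment: list[tuple[str, str]] | dict[str, str],
    len_min: int = 18,
    len_max: int = 22,
    max_degeneracy: int = 64,
    clamp_len: int = 1,
    min_freq: float = 0.05,
    orientation: str = "both",
) -> list[PrimerCandidate]:
    """Ranked degenerate-primer candidates from a design alignment.

    Ranking: degeneracy ascending, worst-column coverage descending, length
    descending.  ``clamp_len`` 3'-terminal columns must be non-degenerate;
    the default of 1 matches the published assay primers, which carry
    ambiguity codes as close as two bases from the 3' end.
    """
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    if len(items) < 2:
        raise ValueError("need at least 2 aligned sequences")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    ncol = lengths.pop()
    cols = [[s[i] for _, s in items] for i in range(ncol)]
    codes = [column_consensus(c, min_freq) for c in cols]
    covers = [
        _column_coverage(c, code) if code != GAP_SENTINEL else 0.0
        for c, code in zip(cols, codes)
    ]

    wanted = ("forward", "reverse") if orientation == "both" else (orientation,)
    out: list[PrimerCandidate] = []
    for L in range(len_min, len_max + 1):
        for start in range(0, ncol - L + 1):
            win = codes[start : start + L]
            if GAP_SENTINEL in win:
                continue
            deg = 1
            for code in win:
                deg *= len(_SETS[code])
            if deg > max_degeneracy:
                continue
            cov = min(covers[start : start + L])
            for orient in wanted:
                if orient == "forward":
                    clamp = win[-clamp_len:]
                    consensus = "".join(win)
                else:
                    clamp = win[:clamp_len][::-1]
                    consensus = "".join(_revcomp_code(c) for c in reversed(win))
                if any(len(_SETS[c]) > 1 for c in clamp):
                    continue
                out.append(
                    PrimerCandidate(
                        window_start=start + 1,
                        length=L,
                        consensus=consensus,
                        degeneracy=deg,
                        worst_column_coverage=cov,
                        orientation=orient,
                    )
                )
    if not out:
        logger.info(
            "no qualifying primer window at max_degeneracy=%d; a single set "
            "covering this alignment is not attainable", max_degeneracy,
        )
    out.sort(key=lambda c: (c.degeneracy, -c.worst_column_coverage, -c.length,
                            c.window_start, c.orientation))
    return out


def pair_candidates(
    candidates_fwd: list[PrimerCandidate],
    candidates_rev: list[PrimerCandidate],
    product_min: int,
    product_max: int,
) -> list[tuple[PrimerCandidate, PrimerCandidate, int]]:
    """All fwd/rev combinations whose alignment span implies an in-range
    product size (in alignment columns; gap content shifts real sizes)."""
    if product_min > product_max:
        raise ValueError(f"product_min ({product_min}) > product_max ({product_max})")
    pairs = []
    for f in candidates_fwd:
        if f.orientation != "forward":
            continue
        for r in candidates_rev:
            if r.orientation != "reverse":
                continue
            size = (r.window_start + r.length - 1) - f.window_start + 1
            if product_min <= size <= product_max:
                pairs.append((f, r, size))
    pairs.sort(key=lambda t: (t[0].degeneracy * t[1].degeneracy, t[2]))
    return pairs
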