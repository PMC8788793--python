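"""Correlation between pleB nucleotide identity and NRPS protein identity.

Within a lipopeptide family, the diagnostic-core region of the transporter
gene tracks the diversity of the nonribosomal peptide synthetases that
assemble its substrate.  This module computes, over all strain pairs, the
Pearson correlation between pleB nucleotide percent identity and
concatenated-NRPS amino-acid percent identity, with a Mantel-style
permutation test for significance: pairwise identities are not independent
observations, so strain labels of the NRPS identity matrix are permuted and
the coefficient recomputed.  The naive parametric p-value is also reported
for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .align import AlignmentParams, DEFAULT_AA, DEFAULT_NT, global_align, percent_identity

__all__ = ["PairedIdentitySet", "build_pairs", "pearson_r", "naive_p", "mantel_p",
           "concatenate_nrps"]


@dataclass(frozen=True)
class PairedIdentitySet:
    """Per-pair pleB (x) and NRPS (y) percent identities for one family."""

    family: str
    strains: tuple[str, ...]
    x_matrix: np.ndarray  # (n, n) pleB nt identity, %
    y_matrix: np.ndarray  # (n, n) NRPS aa identity, %

    def __post_init__(self) -> None:
        n = len(self.strains)
        for name, m in (("x_matrix", self.x_matrix), ("y_matrix", self.y_matrix)):
            if m.shape != (n, n):
                raise ValueError(f"{name} shape {m.shape} does not match {n} strains")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        n = len(self.strains)
        return [(self.strains[i], self.strains[j]) for i in range(n) for j in range(i + 1, n)]

    @property
    def x(self) -> np.ndarray:
        iu = np.triu_indices(len(self.strains), k=1)
        return self.x_matrix[iu]

    @property
    def y(self) -> np.ndarray:
        iu = np.triu_indices(len(self.strains), k=1)
        return self.y_matrix[iu]


def concatenate_nrps(parts: list[str]) -> str:
    """Concatenate NRPS protein sequences in biosynthetic gene order
    (first gene of the cluster first)."""
    return "".join(p.upper() for p in parts)


def build_pairs(
    pleb_seqs: dict[str, str],
    nrps_seqs: dict[str, str],
    family: str,
    params_nt: AlignmentParams = DEFAULT_NT,
    params_aa: AlignmentParams = DEFAULT_AA,
    method: str = "auto",
) -> PairedIdentitySet:
    """All-pairs identities for a family's strains.

    ``pleb_seqs`` are nucleotide core fragments, ``nrps_seqs`` concatenated
    NRPS protein sequences; both keyed by strain id over the same strain set.
    ``method='global'`` aligns every pair; ``method='pdistance'`` computes
    ungapped Hamming identity and requires equal-length fragments per set.
    The default ``'auto'`` uses p-distance when both sets are length-uniform
    (trimmed cores of indel-free sequences), falling back to alignment
    otherwise: for gap-free homologs of equal length the p-distance is the
    exact identity, whereas an optimal-score alignment can occasionally
    over-match by shifting a region between two compensating gaps.
    """
    ids_p, ids_n = set(pleb_seqs), set(nrps_seqs)
    if ids_p != ids_n:
        raise ValueError(
            f"strain-id mismatch: only in pleB set {sorted(ids_p - ids_n)}; "
            f"only in NRPS set {sorted(ids_n - ids_p)}"
        )
    strains = tuple(pleb_seqs)  # insertion order
    n = len(strains)
    if n < 3:
        raise ValueError("need at least 3 strains")
    if method not in ("auto", "global", "pdistance"):
        raise ValueError("method must be 'auto', 'global' or 'pdistance'")
    if method == "auto":
        uniform = all(
            len({len(s) for s in seqs.values()}) == 1
            for seqs in (pleb_seqs, nrps_seqs)
        )
        method = "pdistance" if uniform else "global"
    if method == "pdistance":
        for name, seqs in (("pleB", pleb_seqs), ("NRPS", nrps_seqs)):
            if len({len(s) for s in seqs.values()}) != 1:
                raise ValueError(f"method='pdistance' needs equal-length {name} fragments")

    def _ident(a: str, b: str, params: AlignmentParams) -> float:
        if method == "pdistance":
            arr_a = np.frombuffer(a.upper().encode(), dtype=np.uint8)
            arr_b = np.frombuffer(b.upper().encode(), dtype=np.uint8)
            return 100.0 * float((arr_a == arr_b).mean())
        return percent_identity(global_align(a, b, params))

    x = np.zeros((n, n))
    y = np.zeros((n, n))
    for i in range(n):
        x[i, i] = y[i, i] = 100.0
        for j in range(i + 1, n):
            xi = _ident(pleb_seqs[strains[i]], pleb_seqs[strains[j]], params_nt)
            yi = _ident(nrps_seqs[strains[i]], nrps_seqs[strains[j]], params_aa)
            x[i, j] = x[j, i] = xi
            y[i, j] = y[j, i] = yi
    return PairedIdentitySet(family=family, strains=strains, x_matrix=x, y_matrix=y)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in identities; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def pearson_r(pair_set: PairedIdentitySet) -> float:
    """Product-moment correlation over strain pairs."""
    if len(pair_set.x) < 3:
        raise ValueError("need at least 3 pairs")
    return _pearson(pair_set.x, pair_set.y)


def naive_p(pair_set: PairedIdentitySet) -> float:
    """Parametric two-sided p-value treating pairs as independent (reported
    for comparability only; pairs sharing a strain are not independent)."""
    return float(stats.pearsonr(pair_set.x, pair_set.y).pvalue)


def mantel_p(pair_set: PairedIdentitySet, n_perm: int = 999, seed: int = 0) -> float:
    """One-sided Mantel permutation p-value for the observed correlation.

    Strain labels of the NRPS identity matrix are permuted; the permutation
    p-value is (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    n = len(pair_set.strains)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 strains")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    iu = np.triu_indices(n, k=1)
    x = pair_set.x_matrix[iu]
    r_obs = _pearson(x, pair_set.y_matrix[iu])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = pair_set.y_matrix[np.ix_(perm, perm)][iu]
        if np.ptp(y_perm) == 0:
            continue
        if _pearson(x, y_perm) >= r_obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
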