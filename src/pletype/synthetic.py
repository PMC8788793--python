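"""Synthetic pleB-like genes, reference panels, and coupled pleB/NRPS sets.

The generator emulates the geometry of the real marker gene: a ~2-kb
transporter gene whose diagnostic core occupies positions 590-1467 (878 nt),
flanked by binding sites for both published primer sets such that the
first assay amplifies a ~1,300-bp product and the second a ~1,000-bp
product, both spanning the core.  Families are simulated as star-topology
clusters: each family centroid core diverges from a common reference, and
members diverge from their centroid; mutations are substitutions by default
so identity arithmetic stays exact (an indel mode exists for trimming
stress tests).  Backbone GC content is fixed at 0.60 to resemble
*Pseudomonas* genomes (cosmetic).

All generators are pure functions of (spec, seed): identical inputs give
byte-identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pcr import BANAMPGAC, PUTXANTOL, DegeneratePrimer, expansions, reverse_complement

__all__ = [
    "SimSpec",
    "PanelMember",
    "Panel",
    "CoupledSet",
    "reference_core",
    "make_gene",
    "make_panel",
    "make_coupled_set",
    "calibrate_noise_sd",
    "write_fasta",
]

_CORE_SEED = 20220125  # fixed: the packaged synthetic core stand-in
_GC = 0.60

# gene geometry (1-based inclusive coordinates)
GENE_LENGTH = 1950
CORE_START, CORE_END = 590, 1467
CORE_LENGTH = CORE_END - CORE_START + 1  # 878
# primer-site placement: BanAmpGac spans 300..1599 (1,300 bp product),
# PutXanTol spans 520..1519 (1,000 bp product); both products contain the core
_SITE_LAYOUT = {
    "BanAmpGac": (300, 1600),  # fwd start, rev-end-exclusive on + strand
    "PutXanTol": (520, 1520),
}


def _random_seq(rng: np.random.Generator, n: int, gc: float = _GC) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _substitute_at(seq: str, positions, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in sorted(positions):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _mutate(seq: str, n_sub: int, rng: np.random.Generator,
            protected: frozenset[int] = frozenset()) -> str:
    """Substitute n_sub distinct non-protected positions (0-based)."""
    allowed = np.array([i for i in range(len(seq)) if i not in protected])
    if n_sub > len(allowed):
        raise ValueError("more substitutions requested than mutable positions")
    pos = rng.choice(allowed, size=n_sub, replace=False)
    return _substitute_at(seq, (int(i) for i in pos), rng)


def _apply_indels(seq: str, indel_rate: float, rng: np.random.Generator) -> str:
    if indel_rate <= 0:
        return seq
    out = []
    i = 0
    while i < len(seq):
        if rng.random() < indel_rate:
            if rng.random() < 0.5:  # deletion of 1-3 nt
                i += int(rng.integers(1, 4))
                continue
            out.append(_random_seq(rng, int(rng.integers(1, 4))))
        out.append(seq[i])
        i += 1
    return "".join(out)


def reference_core(seed: int = _CORE_SEED) -> str:
    """The packaged 878-nt synthetic stand-in for the diagnostic core.

    Synthetic: generated from a fixed seed with Pseudomonas-like GC content;
    it shares only geometry (not sequence) with the real reference gene, for
    which a user-supplied fetch can be swapped in via
    :meth:`pletype.align.CoreRegion`.
    """
    return _random_seq(np.random.default_rng(seed), CORE_LENGTH)


@dataclass(frozen=True)
class SimSpec:
    """Conditions for panel simulation.

    Divergences are pairwise fractions: members of one family differ at
    ~``intra_divergence`` of core positions, members of different families
    at ~``inter_divergence``.
    """

    seed: int = 0
    n_families: int = 5
    refs_per_family: int = 4
    n_queries: int = 20
    intra_divergence: float = 0.05
    inter_divergence: float = 0.35
    gene_length: int = GENE_LENGTH
    core_offset: int = CORE_START
    core_length: int = CORE_LENGTH
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.intra_divergence <= self.inter_divergence <= 0.75:
            raise ValueError("need 0 <= intra_divergence <= inter_divergence <= 0.75")
        if self.core_offset + self.core_length - 1 > self.gene_length:
            raise ValueError("core does not fit within the gene")
        if self.gene_length < _SITE_LAYOUT["BanAmpGac"][1]:
            raise ValueError("gene too short for the primer-site layout")


def _pick_expansion(primer: DegeneratePrimer, rng: np.random.Generator) -> str:
    exps = list(expansions(primer))
    return exps[int(rng.integers(0, len(exps)))]


def _flanks(spec: SimSpec, rng: np.random.Generator) -> tuple[str, str, frozenset[int]]:
    """Shared left/right flanks carrying exact-match sites for both primer
    sets; returns (left, right, protected core positions — none)."""
    left = list(_random_seq(rng, spec.core_offset - 1))
    right = list(_random_seq(rng, spec.gene_length - (spec.core_offset + spec.core_length - 1)))
    right_base = spec.core_offset + spec.core_length  # 1-based coord of right[0]
    for name, pair in (("BanAmpGac", BANAMPGAC), ("PutXanTol", PUTXANTOL)):
        fwd, rev = pair
        f_start, r_end_excl = _SITE_LAYOUT[name]
        f_site = _pick_expansion(fwd, rng)
        left[f_start - 1 : f_start - 1 + len(f_site)] = list(f_site)
        r_site = reverse_complement(_pick_expansion(rev, rng))
        r_start = r_end_excl - len(r_site)  # 1-based
        off = r_start - right_base
        right[off : off + len(r_site)] = list(r_site)
    return "".join(left), "".join(right), frozenset()


def make_gene(
    spec: SimSpec,
    rng: np.random.Generator,
    core_seq: str | None = None,
) -> str:
    """Assemble one pleB-like gene: flanks with exact primer sites around the
    diagnostic core (the packaged synthetic core unless one is supplied)."""
    core = core_seq if core_seq is not None else reference_core()
    if len(core) != spec.core_length:
        raise ValueError(f"core must be {spec.core_length} nt, got {len(core)}")
    left, right, _ = _flanks(spec, rng)
    gene = left + core + right
    if spec.indel_rate > 0:
        gene = _apply_indels(gene, spec.indel_rate, rng)
    return gene


@dataclass(frozen=True)
class PanelMember:
    label: str
    family: str
    core: str
    gene: str


@dataclass(frozen=True)
class Panel:
    spec: SimSpec
    references: tuple[PanelMember, ...]
    queries: tuple[PanelMember, ...]  # true family recorded in .family


def _planted_fraction(pair_divergence: float) -> float:
    """Per-lineage fraction of positions to substitute so that two lineages
    mutating independently show the requested *pairwise* p-distance.

    Two lineages each changing a fraction p of sites differ at
    2p(1-p) + (2/3)p^2 of sites (coincident hits agree 1/3 of the time);
    inverting that quadratic corrects for multiple hits.
    """
    t = pair_divergence
    if not 0 <= t <= 0.75:
        raise ValueError("pairwise divergence must be within [0, 0.75]")
    return (2 - np.sqrt(4 - 16 * t / 3)) / (8 / 3)


def make_panel(spec: SimSpec) -> Panel:
    """Reference panel plus held-out queries with known true families.

    Star topology: every family centroid core substitutes a multiple-hit-
    corrected fraction of positions of the common reference, and every
    member/query substitutes a further fraction at positions disjoint from
    its centroid's, so *pairwise* p-distances land on the requested
    ``intra_divergence`` / ``inter_divergence`` (substitutions only unless
    ``indel_rate`` > 0).
    """
    rng = np.random.default_rng(spec.seed)
    ref_core = reference_core()
    left, right, _ = _flanks(spec, rng)
    L = spec.core_length
    n_member = round(_planted_fraction(spec.intra_divergence) * L)
    n_centroid = max(round(_planted_fraction(spec.inter_divergence) * L) - n_member, 0)

    centroids: dict[str, str] = {}
    centroid_sites: dict[str, frozenset[int]] = {}
    for f in range(spec.n_families):
        fam = f"fam{f + 1}"
        sites = frozenset(int(i) for i in rng.choice(L, size=n_centroid, replace=False))
        centroids[fam] = _substitute_at(ref_core, sites, rng)
        centroid_sites[fam] = sites

    def member(label: str, family: str) -> PanelMember:
        core = _mutate(centroids[family], n_member, rng,
                       protected=centroid_sites[family])
        gene = left + core + right
        if spec.indel_rate > 0:
            gene = _apply_indels(gene, spec.indel_rate, rng)
        return PanelMember(label, family, core, gene)

    refs = tuple(
        member(f"{fam}_ref{r + 1}", fam)
        for fam in centroids
        for r in range(spec.refs_per_family)
    )
    fams = list(centroids)
    queries = tuple(
        member(f"query{q + 1}", fams[int(rng.integers(0, len(fams)))])
        for q in range(spec.n_queries)
    )
    return Panel(spec=spec, references=refs, queries=queries)


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_AA20))[rng.integers(0, 20, size=n)])


def _mutate_protein(seq: str, pos: np.ndarray, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in pos:
        out[i] = rng.choice([a for a in _AA20 if a != out[i]])
    return "".join(out)


@dataclass(frozen=True)
class CoupledSet:
    pleb: dict[str, str]
    nrps: dict[str, str]
    realized_slope: float
    noise_sd: float


def make_coupled_set(
    n_strains: int = 10,
    slope: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pleb_len: int = CORE_LENGTH,
    nrps_len: int = 1200,
) -> CoupledSet:
    """Coupled pleB (nucleotide) / NRPS (protein) strain sets.

    Each strain mutates a disjoint block of positions in both molecules
    (star topology), so pairwise divergences are exactly additive:
    pleB pair divergence is proportional to u_i + u_j and NRPS pair
    divergence to slope x (u_i + u_j) plus per-strain Gaussian noise
    (``noise_sd``, in divergence-fraction units, truncated at the block
    budget).  With ``noise_sd=0`` the pair identities are exactly affine,
    hence Pearson r = 1 to machine precision.
    """
    if n_strains < 3:
        raise ValueError("need at least 3 strains")
    if slope < 0 or noise_sd < 0:
        raise ValueError("slope and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ancestor_nt = _random_seq(rng, pleb_len)
    ancestor_aa = _random_protein(rng, nrps_len)

    units = rng.permutation(n_strains) + 1  # 1..n in random order
    sum_u = int(units.sum())
    # Mutable positions sit on a stride-3 grid so every mismatch is isolated;
    # an isolated mismatch (-4) can never be beaten by gaps (>= -21 for an
    # insertion/deletion pair), so the optimal alignment of any strain pair is
    # gapless and pair identities are exactly additive in the mutation counts.
    grid_nt = np.arange(0, pleb_len, 3)
    grid_aa = np.arange(0, nrps_len, 3)
    step_nt = max(1, int(0.9 * len(grid_nt)) // sum_u)

    def _step_aa(snt: int) -> int:
        return max(1, round(slope * snt * len(grid_aa) / len(grid_nt))) if slope > 0 else 0

    step_aa = _step_aa(step_nt)
    while slope > 0 and step_aa * sum_u > int(0.9 * len(grid_aa)) and step_nt > 1:
        step_nt -= 1
        step_aa = _step_aa(step_nt)

    pleb: dict[str, str] = {}
    nrps: dict[str, str] = {}
    # disjoint position blocks per strain, consumed cumulatively
    nt_pos = rng.permutation(grid_nt)
    aa_pos = rng.permutation(grid_aa)
    nt_cursor = aa_cursor = 0
    for i in range(n_strains):
        sid = f"strain{i + 1:02d}"
        d_i = step_nt * int(units[i])
        m_i = step_aa * int(units[i])
        if noise_sd > 0:
            m_i += round(rng.normal(0.0, noise_sd * nrps_len))
        m_i = int(np.clip(m_i, 0, len(aa_pos) - aa_cursor))
        pleb[sid] = _mutate_protein_like(ancestor_nt, nt_pos[nt_cursor : nt_cursor + d_i], rng, "ACGT")
        nt_cursor += d_i
        nrps[sid] = _mutate_protein(ancestor_aa, aa_pos[aa_cursor : aa_cursor + m_i], rng)
        aa_cursor += m_i
    realized = (step_aa / nrps_len) / (step_nt / pleb_len) if step_nt else 0.0
    return CoupledSet(pleb=pleb, nrps=nrps, realized_slope=realized, noise_sd=noise_sd)


def _mutate_protein_like(seq: str, pos: np.ndarray, rng: np.random.Generator,
                         alphabet: str) -> str:
    out = list(seq)
    for i in pos:
        out[i] = rng.choice([a for a in alphabet if a != out[i]])
    return "".join(out)


def _fast_pair_r(cs: CoupledSet) -> float:
    """Hamming-based Pearson r (exact for these equal-length, gap-free sets);
    used only inside noise calibration for speed."""
    sids = list(cs.pleb)
    n = len(sids)
    nt = np.array([np.frombuffer(cs.pleb[s].encode(), dtype=np.uint8) for s in sids])
    aa = np.array([np.frombuffer(cs.nrps[s].encode(), dtype=np.uint8) for s in sids])
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            xs.append((nt[i] != nt[j]).mean())
            ys.append((aa[i] != aa[j]).mean())
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def calibrate_noise_sd(
    target_r: float,
    slope: float = 1.0,
    n_strains: int = 10,
    seed: int = 0,
    n_probe: int = 20,
    tol: float = 0.01,
) -> float:
    """Bisection for the per-strain noise level giving mean pair-level
    Pearson r near ``target_r`` under these generator settings."""
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")

    def mean_r(sd: float) -> float:
        rs = [
            _fast_pair_r(make_coupled_set(n_strains, slope, sd, seed=seed + 1000 + rep))
            for rep in range(n_probe)
        ]
        return float(np.nanmean(rs))

    lo, hi = 0.0, 0.005
    while mean_r(hi) > target_r and hi < 0.5:
        hi *= 2
    for _ in range(20):
        mid = (lo + hi) / 2
        r = mean_r(mid)
        if abs(r - target_r) < tol:
            return mid
        if r > target_r:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    items = list(records.items()) if isinstance(records, dict) else list(records)
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
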