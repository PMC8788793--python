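"""Neighbor-joining trees over pleB identity distances.

The typing workflow's claims rest on cluster membership, not on
branch-length estimation, so trees are built by neighbor joining on
pairwise-identity distances; the distance matrix can be exported for
external maximum-likelihood tools when model-based branch lengths are
needed.  Bootstrap support is computed by resampling alignment columns of
equal-length trimmed core fragments.

Trees are :class:`skbio.TreeNode` objects; Newick serialization is done
here so that support values and label quoting are under package control.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .align import DistanceMatrix

__all__ = [
    "nj_tree",
    "bootstrap_support",
    "write_newick",
    "read_newick",
    "midpoint_root",
]


def _join_lengths(dij: float, ri: float, rj: float, m: int) -> tuple[float, float]:
    """Branch lengths for a neighbor-joining merge, with negative-length
    clamping: a negative branch is set to 0 and its deficit moved to the
    sibling branch (path lengths through the new node are preserved)."""
    bi = 0.5 * dij + (ri - rj) / (2 * (m - 2)) if m > 2 else 0.5 * dij
    bj = dij - bi
    if bi < 0:
        bj += bi
        bi = 0.0
    if bj < 0:
        bi += bj
        bj = 0.0
    return max(bi, 0.0), max(bj, 0.0)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Standard neighbor-joining agglomeration.

    Deterministic: on Q-criterion ties the lowest (row, column) pair in the
    current node order is joined.  An all-zero matrix (identical sequences)
    yields a star tree with zero-length branches.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = matrix.values.astype(float).copy()

    nodes = [TreeNode(name=lab, length=0.0) for lab in labels]
    if np.allclose(d, 0.0):
        root = TreeNode(children=nodes)
        for c in root.children:
            c.length = 0.0
        return root

    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def D(i: int, j: int) -> float:
        return dist[(i, j)] if i < j else dist[(j, i)]

    next_idx = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        bi, bj = _join_lengths(D(i, j), r[i], r[j], m)
        nodes[i].length, nodes[j].length = bi, bj
        new = TreeNode(children=[nodes[i], nodes[j]], length=0.0)
        nodes.append(new)
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D(i, k) + D(j, k) - D(i, j))
            dist[(k, next_idx) if k < next_idx else (next_idx, k)] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1

    # three-point closed form for the final join
    a, b, c = active
    dab, dac, dbc = D(a, b), D(a, c), D(b, c)
    nodes[a].length = max(0.5 * (dab + dac - dbc), 0.0)
    nodes[b].length = max(0.5 * (dab + dbc - dac), 0.0)
    nodes[c].length = max(0.5 * (dac + dbc - dab), 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def _p_distance_matrix(labels: list[str], cols: np.ndarray) -> DistanceMatrix:
    """p-distances from an (n_seqs, n_cols) character matrix; columns where
    either sequence has a gap are ignored for that pair."""
    n = cols.shape[0]
    gap = cols == ord("-")
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            use = ~(gap[i] | gap[j])
            tot = int(use.sum())
            p = float((cols[i, use] != cols[j, use]).sum()) / tot if tot else 0.0
            vals[i, j] = vals[j, i] = p
    return DistanceMatrix(tuple(labels), vals)


def _bipartitions(tree: TreeNode, tip_set: frozenset[str]) -> set[frozenset[str]]:
    """Unrooted bipartitions as canonical (smaller-or-lexicographic) tip sets,
    excluding trivial splits."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tip_set - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        parts.add(canon)
    return parts


def bootstrap_support(
    seqs: list[tuple[str, str]] | dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with bootstrap support from column resampling.

    ``seqs`` must be equal-length (aligned or trimmed-core) fragments; unequal
    lengths raise with a pointer to :func:`pletype.align.trim_to_core`.
    Support (percent of replicates containing each internal bipartition) is
    attached to internal nodes as ``node.name``.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError(
            "fragments have unequal lengths; trim them to the diagnostic core "
            "first (pletype.align.trim_to_core)"
        )
    labels = [lab for lab, _ in items]
    cols = np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8) for _, s in items])
    base = nj_tree(_p_distance_matrix(labels, cols))
    tip_set = frozenset(labels)

    rng = np.random.default_rng(seed)
    ncol = cols.shape[1]
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = nj_tree(_p_distance_matrix(labels, cols[:, idx]))
        for part in _bipartitions(rep, tip_set):
            counts[part] = counts.get(part, 0) + 1

    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tip_set - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.name = str(round(100.0 * counts.get(canon, 0) / n_replicates))
    return base


_NEEDS_QUOTE = set(" ()[]{}:;,'\"")


def _fmt_label(name: str | None) -> str:
    if not name:
        return ""
    if set(name) & _NEEDS_QUOTE:
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        s = _fmt_label(node.name)
    else:
        s = "(" + ",".join(_newick_node(c) for c in node.children) + ")" + _fmt_label(node.name)
    if node.length is not None:
        s += f":{node.length:.10g}"
    return s


def write_newick(tree: TreeNode) -> str:
    """Serialize to Newick (branch lengths; internal names carry support)."""
    return "(" + ",".join(_newick_node(c) for c in tree.children) + ")" + _fmt_label(tree.name) + ";"


def read_newick(text: str) -> TreeNode:
    return TreeNode.read([text])


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Midpoint-rooted copy for display; typing itself is rooting-agnostic."""
    return tree.copy().root_at_midpoint()
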