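"""Poisson-corrected protein distances, neighbor joining and bootstrap.

Distances are d = -ln(1 - p) for the proportion p of differing comparable
sites.  The tree is built by the Saitou-Nei agglomeration with a
deterministic lowest-index tie rule; negative branch-length estimates are
clamped to zero with the deficit moved to the sibling edge (raw values kept).
Bootstrap resamples alignment columns with replacement and scores each
internal split of the point-estimate tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GAP_CHARS = "-."


class SaturatedDistanceError(ValueError):
    """All (or too many) comparable sites differ: -ln(1-p) is undefined."""


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    raw_length: float = 0.0
    support: Optional[float] = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    names: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any() or not np.isfinite(m).all():
            raise ValueError("distances must be finite and non-negative")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def poisson_distance(seq_i: str, seq_j: str, deletion: str = "pairwise") -> float:
    """d = -ln(1 - p), p the proportion of differing comparable sites.

    With pairwise deletion a site is comparable when neither sequence has a
    gap there; 'complete' additionally requires callers to have removed all
    gapped columns already (enforced).
    """
    if len(seq_i) != len(seq_j):
        raise ValueError("aligned sequences must have equal length")
    comparable = differing = 0
    for a, b in zip(seq_i.upper(), seq_j.upper()):
        gap_a, gap_b = a in GAP_CHARS, b in GAP_CHARS
        if gap_a or gap_b:
            if deletion == "complete":
                raise ValueError("complete deletion requires gap-free input columns")
            continue
        comparable += 1
        if a != b:
            differing += 1
    if comparable == 0:
        raise ValueError("zero comparable sites")
    p = differing / comparable
    if p >= 1:
        raise SaturatedDistanceError(f"saturated pair (p = {p:.3f})")
    return -np.log(1.0 - p)


def drop_gapped_columns(seqs: Sequence[str]) -> list:
    """Complete deletion: remove every column holding a gap in any sequence."""
    keep = [
        i
        for i in range(len(seqs[0]))
        if all(s[i] not in GAP_CHARS for s in seqs)
    ]
    return ["".join(s[i] for i in keep) for s in seqs]


def distance_matrix(names: Sequence[str], seqs: Sequence[str], gap_mode: str = "complete") -> DistanceMatrix:
    """Pairwise Poisson-corrected distances under the chosen gap policy."""
    if len(names) != len(seqs):
        raise ValueError("names and sequences differ in number")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("alignment rows must have equal length")
    if gap_mode not in ("complete", "pairwise"):
        raise ValueError("gap_mode must be 'complete' or 'pairwise'")
    work = drop_gapped_columns(seqs) if gap_mode == "complete" else list(seqs)
    if gap_mode == "complete" and len(work[0]) == 0:
        raise ValueError("no columns left after complete deletion")
    n = len(names)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = poisson_distance(
                work[i], work[j],
                deletion="complete" if gap_mode == "complete" else "pairwise",
            )
    return DistanceMatrix(tuple(names), m)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree whose root is
    the final trifurcation (or the 3-taxon star)."""
    n = len(dm.names)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=nm) for nm in dm.names]
    d = dm.matrix.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin realizes the lowest (row, column) tie rule
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        ci, cj = nodes[i], nodes[j]
        ci.raw_length, cj.raw_length = li, lj
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        ci.length, cj.length = li, lj
        parent = TreeNode(children=[ci, cj])

        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    (a, b, c), d3 = nodes, d
    la = 0.5 * (d3[0, 1] + d3[0, 2] - d3[1, 2])
    lb = 0.5 * (d3[0, 1] + d3[1, 2] - d3[0, 2])
    lc = 0.5 * (d3[0, 2] + d3[1, 2] - d3[0, 1])
    for node, raw in zip((a, b, c), (la, lb, lc)):
        node.raw_length = raw
        node.length = max(raw, 0.0)
    return TreeNode(children=[a, b, c])


def total_branch_length(tree: TreeNode) -> float:
    total = 0.0
    stack = list(tree.children)
    while stack:
        node = stack.pop()
        total += node.length
        stack.extend(node.children)
    return total


def internal_splits(tree: TreeNode) -> dict:
    """Map each internal bipartition to its subtending node.

    A split is keyed by the frozenset of leaves on the side *not* containing
    the alphabetically first taxon; trivial splits are excluded.
    """
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    out = {}
    stack = list(tree.children)
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        if node.is_leaf:
            continue
        side = frozenset(node.leaves())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    names: Sequence[str],
    seqs: Sequence[str],
    n_replicates: int = 500,
    seed: int = 0,
    gap_mode: str = "complete",
):
    """Point-estimate NJ tree with per-split bootstrap supports.

    Columns are resampled with replacement; replicates whose distance matrix
    saturates are skipped and tallied.  Taxa are sorted canonically first so
    supports do not depend on input order.  Returns (tree, n_skipped).
    """
    order = sorted(range(len(names)), key=lambda i: names[i])
    names = [names[i] for i in order]
    seqs = [seqs[i] for i in order]

    tree = nj_tree(distance_matrix(names, seqs, gap_mode))
    splits = internal_splits(tree)
    if n_replicates == 0:
        return tree, 0

    rng = np.random.default_rng(seed)
    n_sites = len(seqs[0])
    arr = np.array([list(s) for s in seqs])
    tally = {s: 0 for s in splits}
    skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        sample = ["".join(row) for row in arr[:, cols]]
        try:
            rep_tree = nj_tree(distance_matrix(names, sample, gap_mode))
        except ValueError:
            skipped += 1
            continue
        rep_splits = internal_splits(rep_tree)
        for s in tally:
            if s in rep_splits:
                tally[s] += 1
    successful = n_replicates - skipped
    for s, node in splits.items():
        node.support = 100.0 * tally[s] / successful if successful else None
    return tree, skipped


# ---------------------------------------------------------------------------
# Newick output
# ---------------------------------------------------------------------------


def to_newick(tree: TreeNode, digits: int = 6) -> str:
    """Newick string with bootstrap supports as internal node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.{digits}f}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:.0f}"
        return f"({inner}){label}:{node.length:.{digits}f}"

    inner = ",".join(fmt(c) for c in tree.children)
    label = "" if tree.support is None else f"{tree.support:.0f}"
    return f"({inner}){label};"
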