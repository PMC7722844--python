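"""Shared test helpers: random additive trees and their path-length oracle."""

import numpy as np

from silentscan.phylo import DistanceMatrix, TreeNode, internal_splits


def random_additive_tree(n_taxa, rng, low=0.1, high=2.0):
    """Random unrooted binary tree built by repeated edge subdivision.

    Returns (names, edges) with edges as a dict {(u, v): length} over node
    labels; leaves are 'L1'..'Ln', internal nodes 'X*'.
    """
    names = [f"L{i + 1}" for i in range(n_taxa)]
    counter = [0]

    def new_internal():
        counter[0] += 1
        return f"X{counter[0]}"

    hub = new_internal()
    edges = {}
    for leaf in names[:3]:
        edges[(hub, leaf)] = float(rng.uniform(low, high))
    for leaf in names[3:]:
        keys = sorted(edges)
        u, v = keys[rng.integers(len(keys))]
        w = edges.pop((u, v))
        mid = new_internal()
        frac = float(rng.uniform(0.2, 0.8))
        edges[(u, mid)] = w * frac
        edges[(mid, v)] = w * (1 - frac)
        edges[(mid, leaf)] = float(rng.uniform(low, high))
    return names, edges


def _adjacency(edges):
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    return adj


def path_length_matrix(names, edges):
    """BFS accumulation of additive path lengths between all leaf pairs."""
    adj = _adjacency(edges)
    n = len(names)
    m = np.zeros((n, n))
    for i, src in enumerate(names):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for j, dst in enumerate(names):
            m[i, j] = dist[dst]
    return DistanceMatrix(tuple(names), m)


def true_split_lengths(names, edges):
    """Map canonical bipartition -> edge length for the generated tree.

    Singleton leaf splits are keyed by frozenset({leaf}); internal splits by
    the side not containing the alphabetically first taxon.
    """
    adj = _adjacency(edges)
    leaves = set(names)
    anchor = min(names)
    out = {}
    for (u, v), w in edges.items():
        # leaves reachable from v without crossing (u, v)
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            if node in leaves:
                side.add(node)
            for nbr, _ in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        if len(side) == 1:
            out[frozenset(side)] = w
        else:
            canonical = frozenset(side) if anchor not in side else frozenset(leaves - side)
            if 2 <= len(canonical) <= len(leaves) - 2:
                out[canonical] = w
    return out


def recovered_split_lengths(tree: TreeNode):
    """Same keying for a reconstructed tree (leaf edges + internal edges)."""
    out = {}
    stack = list(tree.children)
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        if node.is_leaf:
            out[frozenset([node.name])] = node.length
    for side, node in internal_splits(tree).items():
        out[side] = node.length
    return out
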