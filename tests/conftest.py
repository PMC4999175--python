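"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from chemomine.motif_engine import AA_ALPHABET, MotifSpec, builtin_motifs


# ---------------------------------------------------------------------------
# Independent brute-force motif oracle
# ---------------------------------------------------------------------------

def oracle_scan(protein: str, spec: MotifSpec) -> list[tuple[int, ...]]:
    """Exhaustively enumerate every increasing anchor-position tuple and keep
    those satisfying the gap ranges and tail requirement.  Independent of the
    backtracking scanner: no gap-based pruning during enumeration."""
    by_letter = {
        a: [i for i, r in enumerate(protein) if r == a] for a in set(spec.anchors)
    }
    k = len(spec.anchors)
    found: list[tuple[int, ...]] = []

    def rec(idx: int, prev: int, acc: list[int]) -> None:
        if idx == k:
            found.append(tuple(acc))
            return
        for p in by_letter[spec.anchors[idx]]:
            if p > prev:
                rec(idx + 1, p, acc + [p])

    rec(0, -1, [])
    good = []
    for combo in found:
        ok = all(
            lo <= b - a - 1 <= hi
            for (a, b), (lo, hi) in zip(zip(combo, combo[1:]), spec.gaps)
        )
        if ok and (len(protein) - 1 - combo[-1]) >= spec.min_tail:
            good.append(combo)
    return sorted(good)


# ---------------------------------------------------------------------------
# Random additive trees (for NJ correctness)
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random unrooted binary tree as (splits, distance matrix, labels).

    Built by sequential leaf attachment; returns the set of non-trivial leaf
    bipartitions (frozensets of the smaller side, canonicalised) and the exact
    leaf-to-leaf path-length matrix.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # adjacency with branch lengths; nodes are ints, leaves 0..n-1
    next_node = n_taxa
    edges: dict[tuple[int, int], float] = {}

    def add_edge(a, b, w):
        edges[(min(a, b), max(a, b))] = w

    def blen():
        return float(rng.uniform(0.05, 1.0))

    # start with a 3-star
    center = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(leaf, center, blen())
    for leaf in range(3, n_taxa):
        # split a uniformly chosen edge with a new internal node
        (a, b), w = list(edges.items())[rng.integers(len(edges))]
        del edges[(a, b)]
        mid = next_node
        next_node += 1
        u = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, w * u)
        add_edge(mid, b, w * (1 - u))
        add_edge(leaf, mid, blen())

    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    # all-pairs leaf distances by DFS from each leaf
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]

    # splits: removing each internal edge partitions the leaves
    all_leaves = frozenset(labels)
    splits = set()
    for (a, b) in edges:
        if a < n_taxa or b < n_taxa:
            continue  # pendant edge -> trivial split
        # leaves on a's side when edge (a,b) removed
        side = set()
        stack = [a]
        seen = {a, b}
        while stack:
            u = stack.pop()
            if u < n_taxa:
                side.add(labels[u])
            for v, _ in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        side_f = frozenset(side)
        other = all_leaves - side_f
        if 1 < len(side_f) < n_taxa - 1:
            splits.add(side_f if sorted(side_f) <= sorted(other) else other)
    return labels, D, splits


def tree_distance_matrix(tree, labels):
    """Leaf-to-leaf path lengths of a chemomine TreeNode tree."""
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))

    def walk(node):
        """Return {leaf: distance-to-node}; accumulate cross-child pairs."""
        if node.is_leaf:
            return {node.label: 0.0}
        maps = []
        for c in node.children:
            m = walk(c)
            maps.append({l: d + c.length for l, d in m.items()})
        merged: dict[str, float] = {}
        for i, mi in enumerate(maps):
            for j in range(i + 1, len(maps)):
                for la, da in mi.items():
                    for lb, db in maps[j].items():
                        D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = da + db
            merged.update(mi)
        return merged

    walk(tree)
    return D


@pytest.fixture(scope="session")
def motif_library():
    return builtin_motifs()


@pytest.fixture
def rng():
    return np.random.default_rng(20160825)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))
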