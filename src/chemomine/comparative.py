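"""Pairwise identity, p-distances, neighbour-joining trees and bootstrap.

The aligner is a global (end-to-end) Needleman–Wunsch–Gotoh dynamic program
with affine gap penalties; percent identity is identical aligned residue
pairs over the full alignment length, gap columns included.  Distances for
tree building are p-distances (proportion of differing sites over columns
where neither sequence is gapped); the distance model is deliberately simple
and configurable.  Trees come from the Saitou–Nei neighbour-joining
agglomeration, which reconstructs additive distance matrices exactly, and
edge supports from nonparametric bootstrap over alignment columns.

Default alignment penalties mirror the common progressive-alignment defaults
for proteins at this scale: match +1, mismatch 0, gap opening 10, gap
extension 0.2 per residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "AlignParams",
    "DistanceMatrix",
    "TreeNode",
    "align_pair",
    "pairwise_identity",
    "identity_matrix",
    "center_star_align",
    "p_distance_matrix",
    "nj_build",
    "bootstrap_supports",
    "tree_to_newick",
    "write_newick",
    "bipartitions",
]


@dataclass(frozen=True)
class AlignParams:
    match_score: float = 1.0
    mismatch_score: float = 0.0
    gap_open: float = 10.0
    gap_extend: float = 0.2


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValidationError("negative distances are not allowed")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TreeNode:
    """A rooted view of an (un)rooted tree; the root trifurcates for unrooted
    topologies.  ``support`` is a bootstrap percentage on the edge above an
    internal node."""

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]


# ---------------------------------------------------------------------------
# Pairwise alignment and identity
# ---------------------------------------------------------------------------

def align_pair(
    seq_a: str, seq_b: str, params: AlignParams = AlignParams()
) -> tuple[str, str, float]:
    """Global affine-gap alignment (Gotoh); returns (aligned_a, aligned_b, score).

    A gap of length k costs ``gap_open + k * gap_extend``.  Traceback prefers
    substitution over a gap in ``seq_b`` over a gap in ``seq_a``, making the
    reported alignment deterministic.
    """
    if not seq_a or not seq_b:
        raise ValidationError("cannot align an empty sequence")
    n, m = len(seq_a), len(seq_b)
    NEG = -np.inf
    go, ge = params.gap_open, params.gap_extend
    M = np.full((n + 1, m + 1), NEG)  # ends in a substitution column
    X = np.full((n + 1, m + 1), NEG)  # ends in a gap in seq_b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # ends in a gap in seq_a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + ge * i)
    for j in range(1, m + 1):
        Y[0, j] = -(go + ge * j)
    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            s = params.match_score if ai == seq_b[j - 1] else params.mismatch_score
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge, Y[i - 1, j] - go - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge, X[i, j - 1] - go - ge)
    # traceback from the best final state, preference M > X > Y
    states = {"M": M, "X": X, "Y": Y}
    state = max("MXY", key=lambda s: states[s][n, m])
    score = states[state][n, m]
    a_out, b_out = [], []
    i, j = n, m
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = params.match_score if seq_a[i - 1] == seq_b[j - 1] else params.mismatch_score
            prev = M[i, j] - s
            for cand in "MXY":
                if abs(states[cand][i - 1, j - 1] - prev) < tol:
                    state_next = cand
                    break
            a_out.append(seq_a[i - 1])
            b_out.append(seq_b[j - 1])
            i, j = i - 1, j - 1
            state = state_next
        elif state == "X":
            v = X[i, j]
            if abs(M[i - 1, j] - go - ge - v) < tol:
                state_next = "M"
            elif abs(X[i - 1, j] - ge - v) < tol:
                state_next = "X"
            else:
                state_next = "Y"
            a_out.append(seq_a[i - 1])
            b_out.append("-")
            i -= 1
            state = state_next
        else:
            v = Y[i, j]
            if abs(M[i, j - 1] - go - ge - v) < tol:
                state_next = "M"
            elif abs(Y[i, j - 1] - ge - v) < tol:
                state_next = "Y"
            else:
                state_next = "X"
            a_out.append("-")
            b_out.append(seq_b[j - 1])
            j -= 1
            state = state_next
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return "".join(reversed(a_out)), "".join(reversed(b_out)), float(score)


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    params: AlignParams = AlignParams(),
) -> float:
    """Percent identity of the optimal global alignment.

    identity = 100 * identical aligned residue pairs / alignment length,
    where the alignment length includes gap columns.
    """
    a, b, _ = align_pair(seq_a, seq_b, params)
    same = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * same / len(a)


def identity_matrix(
    proteins: dict[str, str] | list[tuple[str, str]],
    params: AlignParams = AlignParams(),
) -> tuple[list[str], np.ndarray, tuple[float, float]]:
    """All-pairs percent identity with an off-diagonal (min, max) summary."""
    items = list(proteins.items()) if isinstance(proteins, dict) else list(proteins)
    labels = [k for k, _ in items]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate protein labels")
    if len(items) < 2:
        raise ValidationError("need >= 2 proteins")
    n = len(items)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(items[i][1], items[j][1], params)
            mat[i, j] = mat[j, i] = pid
    off = mat[~np.eye(n, dtype=bool)]
    return labels, mat, (float(off.min()), float(off.max()))


def center_star_align(
    proteins: dict[str, str], params: AlignParams = AlignParams()
) -> dict[str, str]:
    """Center-star multiple alignment from pairwise global alignments.

    The center is the sequence with the highest total pairwise score (ties by
    label); every other sequence is aligned to it and the pairwise alignments
    are merged by gap propagation ("once a gap, always a gap").  Adequate at
    candidate-set scale; a dedicated progressive aligner is not reimplemented.
    """
    labels = sorted(proteins)
    if len(labels) < 2:
        raise ValidationError("need >= 2 sequences to align")
    totals = {}
    pair_cache: dict[tuple[str, str], tuple[str, str, float]] = {}
    for i, la in enumerate(labels):
        tot = 0.0
        for lb in labels:
            if la == lb:
                continue
            key = (min(la, lb), max(la, lb))
            if key not in pair_cache:
                pair_cache[key] = align_pair(proteins[key[0]], proteins[key[1]], params)
            tot += pair_cache[key][2]
        totals[la] = tot
    center = max(labels, key=lambda l: (totals[l], l))
    center_seq = proteins[center]
    # master center string with accumulated gaps; map others into it
    master = list(center_seq)
    rows: dict[str, list[str]] = {center: master}

    def insert_gap(col: int) -> None:
        for row in rows.values():
            row.insert(col, "-")

    for lab in labels:
        if lab == center:
            continue
        a, b, _ = align_pair(center_seq, proteins[lab], params)
        # walk the pair alignment against the current master
        new_row: list[str] = []
        mi = 0  # column in master
        for ca, cb in zip(a, b):
            if ca == "-":
                # gap in center: insert a new master column here
                insert_gap(mi)
                new_row.append(cb)
                mi += 1
            else:
                # advance past master gap columns introduced by other rows
                while master[mi] == "-":
                    new_row.append("-")
                    mi += 1
                new_row.append(cb)
                mi += 1
        while mi < len(master):
            new_row.append("-")
            mi += 1
        rows[lab] = new_row
    width = len(master)
    return {lab: "".join(row).ljust(width, "-") for lab, row in rows.items()}


# ---------------------------------------------------------------------------
# Distances and neighbour joining
# ---------------------------------------------------------------------------

def p_distance_matrix(aligned: dict[str, str]) -> DistanceMatrix:
    """p-distance: differing over comparable (both-ungapped) columns.

    Raises if any pair shares zero comparable columns.
    """
    labels = list(aligned)
    seqs = [aligned[l] for l in labels]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValidationError("aligned sequences must have equal length")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diff = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x != "-" and y != "-":
                    comparable += 1
                    if x != y:
                        diff += 1
            if comparable == 0:
                raise ValidationError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = diff / comparable
    return DistanceMatrix(labels=labels, d=d)


def nj_build(dist: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbour joining.

    Q(i,j) = (r-2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k); at each step the minimal-Q
    pair joins, with ties broken by the lexicographically smallest (sorted)
    label pair.  Branch lengths use the standard formulas, clamped at zero.
    On additive matrices the true tree is recovered exactly.  The final three
    lineages attach to a trifurcating root (unrooted representation).
    """
    n = len(dist)
    if n < 3:
        raise ValidationError("neighbour joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dist.labels]
    # smallest current label under each working node, for deterministic ties
    tie_key: list[str] = list(dist.labels)
    D = dist.d.copy()
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                pair_key = tuple(sorted((tie_key[i], tie_key[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # distances to the new node
        u = i  # reuse slot i
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[u] = new
        tie_key[u] = min(tie_key[i], tie_key[j])
        active.remove(j)
    i, j, k = active
    # three-point formulas for the final trifurcation
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    order = sorted([(tie_key[x], x) for x in (i, j, k)])
    lengths = {i: max(li, 0.0), j: max(lj, 0.0), k: max(lk, 0.0)}
    root = TreeNode()
    for _, x in order:
        nodes[x].length = lengths[x]
        root.children.append(nodes[x])
    return root


def bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Non-trivial leaf bipartitions of internal edges, keyed by the smaller
    side (canonicalised against the full leaf set)."""
    all_leaves = frozenset(tree.leaf_labels())
    out: dict[frozenset[str], TreeNode] = {}

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            key = below if sorted(below) <= sorted(other) else other
            out[key] = node
        return below

    walk(tree)
    return out


def bootstrap_supports(
    aligned: dict[str, str], n_reps: int, seed: int
) -> tuple[TreeNode, int]:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each replicate's
    p-distance NJ tree votes for the original tree's bipartitions.  Support is
    the percentage of successful replicates containing the bipartition.
    Replicates where some pair has no comparable columns are skipped (with a
    warning); the count of skipped replicates is returned.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    tree = nj_build(p_distance_matrix(aligned))
    splits = bipartitions(tree)
    counts = {key: 0 for key in splits}
    labels = list(aligned)
    L = len(next(iter(aligned.values())))
    rng = np.random.default_rng(seed)
    used = 0
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = {l: "".join(aligned[l][c] for c in cols) for l in labels}
        try:
            rep_tree = nj_build(p_distance_matrix(resampled))
        except ValidationError:
            skipped += 1
            continue
        used += 1
        rep_splits = bipartitions(rep_tree)
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    if skipped:
        warnings.warn(
            f"{skipped} bootstrap replicate(s) skipped (no comparable columns)",
            RuntimeWarning,
            stacklevel=2,
        )
    for key, node in splits.items():
        node.support = round(100 * counts[key] / used) if used else 0
    return tree, skipped


# ---------------------------------------------------------------------------
# Newick output
# ---------------------------------------------------------------------------

_NEWICK_META = set("()[]':;, \t\n")


def _quote(label: str) -> str:
    if any(c in _NEWICK_META for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


def tree_to_newick(tree: TreeNode) -> str:
    def render(node: TreeNode, at_root: bool) -> str:
        if node.is_leaf:
            s = _quote(node.label or "")
        else:
            inner = ",".join(render(c, False) for c in node.children)
            label = "" if node.support is None else str(int(node.support))
            s = f"({inner}){label}"
        if not at_root:
            s += f":{_fmt_len(node.length)}"
        return s

    return render(tree, True) + ";"


def write_newick(tree: TreeNode, path) -> None:
    """Write the tree as newick: branch lengths to 6 significant digits,
    integer bootstrap supports as internal node labels, metacharacter-bearing
    labels quoted."""
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")
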