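"""Distance-based phylogeny: minimum evolution trees and bootstrap consensus.

The tree search follows the classic heuristic: a neighbor-joining starting
topology, ordinary-least-squares (OLS) branch lengths, and
nearest-neighbor-interchange hill climbing minimising the total tree length
(the minimum-evolution criterion).  Negative OLS branch-length estimates
are clamped to zero and flagged.  Bootstrap support is the percentage of
column-resampled replicates whose ME tree contains each bipartition;
consensus topologies are majority-rule (>50%).  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from . import distances as _dist


class TreeError(ValueError):
    pass


class PhyloTree:
    """Unrooted tree: integer nodes, leaf labels, optional branch lengths
    and per-bipartition supports (percent, keyed by the leaf set of the
    split side not containing the reference taxon)."""

    def __init__(self, adj, leaf_labels, supports=None):
        self.adj = {u: dict(nbrs) for u, nbrs in adj.items()}
        self.leaf_labels = dict(leaf_labels)
        self.supports = dict(supports or {})
        self.negative_clamped = 0

    # -- basics -----------------------------------------------------------
    @property
    def taxa(self):
        return sorted(self.leaf_labels.values())

    def copy(self) -> "PhyloTree":
        t = PhyloTree(self.adj, self.leaf_labels, self.supports)
        t.negative_clamped = self.negative_clamped
        return t

    def edges(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if (v, u) not in seen:
                    seen.add((u, v))
                    yield u, v
        return

    def total_length(self) -> float:
        return sum(self.adj[u][v] or 0.0 for u, v in self.edges())

    def _leafset_beyond(self, u, v):
        """Leaf labels reachable from v when the edge u-v is removed."""
        out, stack, seen = [], [v], {u, v}
        while stack:
            w = stack.pop()
            if w in self.leaf_labels:
                out.append(self.leaf_labels[w])
            for x in self.adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(out)

    def splits(self, include_trivial: bool = False):
        """Bipartitions as frozensets of leaf labels, canonicalised to the
        side not containing the lexicographically smallest taxon."""
        ref = min(self.taxa)
        out = set()
        for u, v in self.edges():
            side = self._leafset_beyond(u, v)
            if ref in side:
                side = frozenset(self.taxa) - side
            if include_trivial or 1 < len(side) < len(self.taxa) - 1:
                out.add(side)
        return out

    # -- newick -----------------------------------------------------------
    def newick(self, support_min: float | None = None) -> str:
        root = next(u for u in self.adj if u not in self.leaf_labels)
        taxa = frozenset(self.taxa)
        ref = min(taxa)

        def fmt_len(x):
            return "" if x is None else f":{x:.6f}"

        def rec(u, parent):
            if u in self.leaf_labels:
                return self.leaf_labels[u] + fmt_len(self.adj[parent][u] if parent is not None else None)
            parts = [rec(v, u) for v in sorted(self.adj[u]) if v != parent]
            label = ""
            if parent is not None and self.supports:
                side = self._leafset_beyond(parent, u)
                if ref in side:
                    side = taxa - side
                sup = self.supports.get(side)
                if sup is not None and (support_min is None or sup > support_min):
                    label = f"{sup:.0f}"
            blen = fmt_len(self.adj[parent][u]) if parent is not None else ""
            return "(" + ",".join(parts) + ")" + label + blen

        return rec(root, None) + ";"


# ---------------------------------------------------------------------------


def _adjacency_from_skbio(tree_node):
    """skbio TreeNode -> (adj, leaf_labels), suppressing degree-2 nodes."""
    ids = {}
    adj = {}
    leaf_labels = {}

    def nid(node):
        if id(node) not in ids:
            ids[id(node)] = len(ids)
            adj[ids[id(node)]] = {}
        return ids[id(node)]

    for node in tree_node.traverse():
        u = nid(node)
        if node.is_tip():
            leaf_labels[u] = node.name
        for child in node.children:
            v = nid(child)
            length = child.length if child.length is not None else 0.0
            adj[u][v] = length
            adj[v][u] = length
    # suppress degree-2 internal nodes (rooted representation artefacts)
    for u in list(adj):
        if u not in leaf_labels and len(adj[u]) == 2:
            (a, la), (b, lb) = adj[u].items()
            del adj[a][u], adj[b][u], adj[u]
            adj[a][b] = adj[b][a] = la + lb
    return adj, leaf_labels


def _ols_lengths(tree: PhyloTree, dm: DistanceMatrix) -> float:
    """Fit OLS branch lengths in place; returns the total tree length."""
    taxa = tree.taxa
    leaf_of = {lab: u for u, lab in tree.leaf_labels.items()}
    edge_list = list(tree.edges())
    edge_idx = {}
    for e_i, (u, v) in enumerate(edge_list):
        edge_idx[(u, v)] = edge_idx[(v, u)] = e_i
    pairs = [(i, j) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]
    a = np.zeros((len(pairs), len(edge_list)))
    d = np.zeros(len(pairs))
    # paths from each leaf by BFS
    paths = {}
    for lab in taxa:
        start = leaf_of[lab]
        prev = {start: None}
        stack = [start]
        while stack:
            w = stack.pop()
            for x in tree.adj[w]:
                if x not in prev:
                    prev[x] = w
                    stack.append(x)
        paths[lab] = prev
    for p_i, (i, j) in enumerate(pairs):
        d[p_i] = dm[taxa[i], taxa[j]]
        prev = paths[taxa[i]]
        w = leaf_of[taxa[j]]
        while prev[w] is not None:
            a[p_i, edge_idx[(prev[w], w)]] += 1
            w = prev[w]
    x, *_ = np.linalg.lstsq(a, d, rcond=None)
    clamped = int(np.sum(x < 0))
    x = np.clip(x, 0.0, None)
    for (u, v), val in zip(edge_list, x):
        tree.adj[u][v] = tree.adj[v][u] = float(val)
    tree.negative_clamped = clamped
    return float(x.sum())


def _nni_neighbors(tree: PhyloTree, u, v):
    """The two NNI rearrangements around the internal edge u-v."""
    a, b = sorted(n for n in tree.adj[u] if n != v)[:2]
    c, d = sorted(n for n in tree.adj[v] if n != u)[:2]
    for swap_u, swap_v in ((b, c), (b, d)):
        t = tree.copy()
        lu = t.adj[u].pop(swap_u)
        t.adj[swap_u].pop(u)
        lv = t.adj[v].pop(swap_v)
        t.adj[swap_v].pop(v)
        t.adj[u][swap_v] = t.adj[swap_v][u] = lv
        t.adj[v][swap_u] = t.adj[swap_u][v] = lu
        yield t


def me_tree(dm: DistanceMatrix) -> PhyloTree:
    """Minimum-evolution tree: NJ start, OLS lengths, NNI hill climbing.

    Deterministic: edges are examined in a fixed order and the first
    length-reducing rearrangement is taken each sweep.
    """
    n = len(dm.ids)
    if n < 3:
        raise TreeError("need at least 3 taxa")
    if n == 3:
        # unique unrooted topology, closed-form three-point lengths
        i, j, k = dm.ids
        adj = {0: {}, 1: {}, 2: {}, 3: {}}
        lens = {
            0: max(0.0, 0.5 * (dm[i, j] + dm[i, k] - dm[j, k])),
            1: max(0.0, 0.5 * (dm[i, j] + dm[j, k] - dm[i, k])),
            2: max(0.0, 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])),
        }
        for leaf, lab in zip((0, 1, 2), (i, j, k)):
            adj[leaf][3] = adj[3][leaf] = lens[leaf]
        return PhyloTree(adj, {0: i, 1: j, 2: k})

    start = _skbio_nj(dm)
    adj, leaf_labels = _adjacency_from_skbio(start)
    tree = PhyloTree(adj, leaf_labels)
    best_len = _ols_lengths(tree, dm)
    improved = True
    sweeps = 0
    while improved and sweeps < 100:
        improved = False
        sweeps += 1
        internal_edges = [
            (u, v)
            for u, v in sorted(tree.edges())
            if u not in tree.leaf_labels and v not in tree.leaf_labels
        ]
        for u, v in internal_edges:
            for cand in _nni_neighbors(tree, u, v):
                cand_len = _ols_lengths(cand, dm)
                if cand_len < best_len - 1e-12:
                    tree, best_len, improved = cand, cand_len, True
                    break
            if improved:
                break
    return tree


def _consensus_from_splits(taxa, split_support):
    """Majority-rule consensus tree from compatible splits (support > 50)."""
    taxa = sorted(taxa)
    n_node = [0]
    adj = {}
    leaf_labels = {}

    def new_node():
        adj[n_node[0]] = {}
        n_node[0] += 1
        return n_node[0] - 1

    root = new_node()
    holder = {}  # frozenset cluster (or single taxon) -> node
    members = {}  # node -> leafset
    for t in taxa:
        u = new_node()
        leaf_labels[u] = t
        adj[root][u] = adj[u][root] = None
        holder[u] = root
        members[u] = frozenset([t])
    members[root] = frozenset(taxa)
    clusters = sorted(split_support, key=lambda c: (-len(c), sorted(c)))
    for c in clusters:
        # the parent is the smallest current node whose members contain c
        candidates = [u for u in adj if u not in leaf_labels and members[u] >= c]
        parent = min(candidates, key=lambda u: len(members[u]))
        node = new_node()
        members[node] = c
        moved = [w for w in list(adj[parent]) if members.get(w, frozenset()) <= c]
        for w in moved:
            del adj[parent][w], adj[w][parent]
            adj[node][w] = adj[w][node] = None
        adj[parent][node] = adj[node][parent] = None
    supports = {c: split_support[c] for c in split_support}
    return PhyloTree(adj, leaf_labels, supports)


def bootstrap_consensus(msa, n_replicates: int, seed: int, support_display_min: float = 50.0):
    """Majority-rule bootstrap consensus of JTT/ME trees.

    Columns (after complete gap deletion) are resampled with replacement;
    each replicate is run through the JTT distance + minimum evolution
    pipeline; bipartition supports are percentages of replicates.  Returns
    a :class:`PhyloTree` whose ``supports`` hold all observed majority
    bipartitions; ``newick(support_min=support_display_min)`` renders
    supports above the display threshold.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    msa = list(msa)
    ids = [i for i, _ in msa]
    coded = _dist.complete_deletion([s for _, s in msa])
    rng = np.random.default_rng(seed)
    counts: dict = {}
    n_cols = coded.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        sub = coded[:, cols]
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                cm = np.zeros((20, 20))
                np.add.at(cm, (sub[i], sub[j]), 1.0)
                cm = 0.5 * (cm + cm.T)
                dist, _f = _dist.jtt.ml_distance(cm)
                d[i, j] = d[j, i] = dist
        rep_tree = me_tree(DistanceMatrix(d, ids=ids))
        for split in rep_tree.splits():
            counts[split] = counts.get(split, 0) + 1
    support = {
        c: 100.0 * k / n_replicates for c, k in counts.items() if k / n_replicates > 0.5
    }
    tree = _consensus_from_splits(ids, support)
    tree.support_display_min = support_display_min
    return tree
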