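"""Independent oracles used by the test suite.

These deliberately avoid the dynamic-programming / counting code paths they
check: exhaustive path enumeration for profile alignment scores, exhaustive
topology enumeration for small trees, and dendropy-based bipartition
extraction for consensus supports.
"""

import numpy as np

from plpmine.alphabet import AMINO_ACIDS
from plpmine.hmm import ProfileHMM


def random_toy_profile(rng, n_match):
    """A random valid profile with ``n_match`` states."""
    me = rng.dirichlet(np.ones(20) * 0.5, size=n_match)
    ie = rng.dirichlet(np.ones(20), size=max(n_match - 1, 0))
    if n_match > 1:
        m = rng.dirichlet(np.ones(3), size=n_match - 1)
        i = rng.dirichlet(np.ones(2), size=n_match - 1)
        d = rng.dirichlet(np.ones(2), size=n_match - 1)
        tr = {"mm": m[:, 0], "mi": m[:, 1], "md": m[:, 2],
              "im": i[:, 0], "ii": i[:, 1], "dm": d[:, 0], "dd": d[:, 1]}
    else:
        tr = {n: np.zeros(0) for n in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    bg = rng.dirichlet(np.ones(20) * 5)
    return ProfileHMM(name="toy", match_emissions=me, insert_emissions=ie,
                      transitions=tr, background=bg)


def enumerate_path_odds(p: ProfileHMM, seq: str):
    """Odds of every legal local path (enter at a match state, exit from a
    match state); brute force, exponential — keep inputs tiny."""
    x = [AMINO_ACIDS.index(c) for c in seq]
    big_k, length = p.n_match, len(seq)
    tr = p.transitions
    out = []

    def ext(state, k, i, odds):
        if state == "M":
            out.append(odds)  # free exit from any match state
            if k < big_k:
                if i < length:
                    ext("M", k + 1, i + 1,
                        odds * tr["mm"][k - 1] * p.match_emissions[k, x[i]] / p.background[x[i]])
                    ext("I", k, i + 1,
                        odds * tr["mi"][k - 1] * p.insert_emissions[k - 1, x[i]] / p.background[x[i]])
                ext("D", k + 1, i, odds * tr["md"][k - 1])
        elif state == "I":
            if i < length:
                ext("M", k + 1, i + 1,
                    odds * tr["im"][k - 1] * p.match_emissions[k, x[i]] / p.background[x[i]])
                ext("I", k, i + 1,
                    odds * tr["ii"][k - 1] * p.insert_emissions[k - 1, x[i]] / p.background[x[i]])
        elif state == "D" and k < big_k:
            if i < length:
                ext("M", k + 1, i + 1,
                    odds * tr["dm"][k - 1] * p.match_emissions[k, x[i]] / p.background[x[i]])
            ext("D", k + 1, i, odds * tr["dd"][k - 1])

    for j in range(1, big_k + 1):
        for s in range(length):
            ext("M", j, s + 1, (1.0 / big_k) * p.match_emissions[j - 1, x[s]] / p.background[x[s]])
    return out


def all_unrooted_topologies(taxa):
    """Every unrooted binary topology over the taxa, as frozensets-of-splits.

    Recursive leaf insertion: each new leaf attaches to any existing edge.
    Returns a list of (adjacency, leaf_labels) pairs in plpmine's tree
    representation.
    """
    from plpmine.tree import PhyloTree

    taxa = list(taxa)
    assert len(taxa) >= 3
    base_adj = {0: {3: None}, 1: {3: None}, 2: {3: None}, 3: {0: None, 1: None, 2: None}}
    base_labels = {0: taxa[0], 1: taxa[1], 2: taxa[2]}
    trees = [(base_adj, base_labels, 4)]
    for leaf_i, taxon in enumerate(taxa[3:], start=3):
        new_trees = []
        for adj, labels, next_id in trees:
            edges = set()
            for u in adj:
                for v in adj[u]:
                    if (v, u) not in edges:
                        edges.add((u, v))
            for u, v in sorted(edges):
                a2 = {w: dict(n) for w, n in adj.items()}
                mid, leaf = next_id, next_id + 1
                del a2[u][v], a2[v][u]
                a2[mid] = {u: None, v: None, leaf: None}
                a2[u][mid] = a2[v][mid] = None
                a2[leaf] = {mid: None}
                l2 = dict(labels)
                l2[leaf] = taxon
                new_trees.append((a2, l2, next_id + 2))
        trees = new_trees
    return [PhyloTree(adj, labels) for adj, labels, _ in trees]


def random_additive_matrix(rng, n_taxa):
    """A random binary tree with positive branch lengths and its exact
    additive distance matrix; returns (DistanceMatrix, true_splits)."""
    from skbio import DistanceMatrix

    taxa = [f"T{i}" for i in range(n_taxa)]
    topo = all_unrooted_topologies(taxa)
    tree = topo[int(rng.integers(len(topo)))] if n_taxa <= 5 else None
    if tree is None:
        # build by random sequential insertion for larger n
        tree = _random_topology(rng, taxa)
    for u in tree.adj:
        for v in tree.adj[u]:
            if tree.adj[u][v] is None:
                length = float(rng.uniform(0.5, 3.0))
                tree.adj[u][v] = tree.adj[v][u] = length
    leaf_of = {lab: u for u, lab in tree.leaf_labels.items()}
    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        # BFS distances
        dist = {leaf_of[taxa[i]]: 0.0}
        stack = [leaf_of[taxa[i]]]
        while stack:
            w = stack.pop()
            for x, lw in tree.adj[w].items():
                if x not in dist:
                    dist[x] = dist[w] + lw
                    stack.append(x)
        for j in range(n_taxa):
            d[i, j] = dist[leaf_of[taxa[j]]]
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(d, ids=taxa), tree.splits()


def _random_topology(rng, taxa):
    from plpmine.tree import PhyloTree

    adj = {0: {3: None}, 1: {3: None}, 2: {3: None}, 3: {0: None, 1: None, 2: None}}
    labels = {0: taxa[0], 1: taxa[1], 2: taxa[2]}
    next_id = 4
    for taxon in taxa[3:]:
        edges = []
        for u in adj:
            for v in adj[u]:
                if (v, u) not in edges and (u, v) not in edges:
                    edges.append((u, v))
        u, v = edges[int(rng.integers(len(edges)))]
        mid, leaf = next_id, next_id + 1
        del adj[u][v], adj[v][u]
        adj[mid] = {u: None, v: None, leaf: None}
        adj[u][mid] = adj[v][mid] = None
        adj[leaf] = {mid: None}
        labels[leaf] = taxon
        next_id += 2
    return PhyloTree(adj, labels)


def dendropy_split_counts(newicks, taxa):
    """Count bipartitions across newick strings with dendropy (independent
    of plpmine's split extraction)."""
    import dendropy

    tns = dendropy.TaxonNamespace(taxa)
    counts = {}
    for nwk in newicks:
        tree = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
        tree.encode_bipartitions()
        for bp in tree.bipartition_encoding:
            leafset = frozenset(
                t.label for t in bp.leafset_taxa(tns)
            )
            if 1 < len(leafset) < len(taxa) - 1:
                ref = min(taxa)
                if ref in leafset:
                    leafset = frozenset(taxa) - leafset
                counts[leafset] = counts.get(leafset, 0) + 1
    return counts
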