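"""Independent brute-force oracles used to verify the fast implementations.

These deliberately avoid the package's canonical-form machinery: subgraph
classification goes through networkx isomorphism tests, order classes
through explicit permutation enumeration, and the Wilcoxon null through
full sign-flip enumeration.
"""

from itertools import combinations, permutations

import networkx as nx
import numpy as np


def naive_graphlet_counts(graph, catalog):
    """Count induced occurrences of every catalog type by enumerating all
    node subsets and testing isomorphism with networkx."""
    counts = np.zeros(len(catalog), dtype=int)
    type_graphs = [t.to_networkx() for t in catalog.types]
    nodes = sorted(graph)
    memo = {}
    for k in range(catalog.k_min, catalog.k_max + 1):
        k_indices = [i for i, t in enumerate(catalog.types) if t.k == k]
        for subset in combinations(nodes, k):
            key = (k, frozenset(
                (a, b) for a, b in combinations(range(k), 2)
                if graph.has_edge(subset[a], subset[b])
            ))
            if key not in memo:
                sg = graph.subgraph(subset)
                if not nx.is_connected(sg):
                    memo[key] = None
                else:
                    memo[key] = next(
                        i for i in k_indices if nx.is_isomorphic(sg, type_graphs[i])
                    )
            if memo[key] is not None:
                counts[memo[key]] += 1
    return counts


def naive_ordered_counts(graph, k_min, k_max):
    """Ordered-graphlet counts keyed by the rank-labelled edge pattern.

    Nodes are ranked by their (integer) identifiers; each connected induced
    subset contributes one occurrence of the pattern formed by its edges on
    rank labels.
    """
    patterns = {}
    nodes = sorted(graph)
    for k in range(k_min, k_max + 1):
        for subset in combinations(nodes, k):
            edges = frozenset(
                (a, b) for a, b in combinations(range(k), 2)
                if graph.has_edge(subset[a], subset[b])
            )
            if not nx.is_connected(graph.subgraph(subset)):
                continue
            patterns[(k, edges)] = patterns.get((k, edges), 0) + 1
    return patterns


def order_class_count(edges, k):
    """Number of distinct total orders of a graphlet modulo automorphism,
    by explicit enumeration of rank assignments (equals k!/|Aut|)."""
    seen = set()
    for perm in permutations(range(k)):
        relabeled = frozenset(frozenset((perm[u], perm[v])) for u, v in edges)
        seen.add(relabeled)
    return len(seen)


def exact_wilcoxon_greater(diffs):
    """One-sided (greater) signed-rank p-value by full 2^n sign-flip
    enumeration; requires nonzero, tie-free |differences|."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    observed = ranks[diffs > 0].sum()
    count = 0
    for mask in range(1 << n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if w >= observed:
            count += 1
    return count / (1 << n)


def all_pairs_bfs_diameter(graph):
    """Diameter via explicit per-node BFS."""
    best = 0
    for source in graph:
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for v in frontier:
                for u in graph[v]:
                    if u not in dist:
                        dist[u] = dist[v] + 1
                        nxt.append(u)
            frontier = nxt
        if len(dist) != graph.number_of_nodes():
            raise ValueError("graph is disconnected")
        best = max(best, max(dist.values()))
    return best
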