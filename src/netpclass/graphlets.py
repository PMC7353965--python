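"""Exact graphlet and ordered-graphlet enumeration and counting.

A graphlet is a small connected induced non-isomorphic undirected subgraph
(2-5 nodes here).  An ordered graphlet additionally carries a total order on
its nodes inherited from amino-acid sequence positions; two ordered
graphlets are the same type iff an isomorphism exists between them that
preserves that order.  Because the order is total, each ordered type
corresponds to exactly one edge pattern on rank-labelled nodes, and each
unordered graphlet g on k nodes expands into k!/|Aut(g)| ordered types.

Catalogs are enumerated exhaustively over edge bitmasks and canonicalised
by the lexicographically minimal adjacency encoding over all node
permutations, giving a deterministic type order.  Counting enumerates every
connected induced subgraph once (ESU-style extension) and classifies it by
a precomputed bitmask lookup, so counts are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import factorial

import networkx as nx
import numpy as np

from .features import FeatureVector


def _pairs(k):
    return list(combinations(range(k), 2))


def mask_to_edges(mask, k):
    """Decode an edge bitmask (bit b set <=> b-th pair in lexicographic order)."""
    return [p for b, p in enumerate(_pairs(k)) if mask >> b & 1]


def edges_to_mask(edges, k):
    index = {p: b for b, p in enumerate(_pairs(k))}
    mask = 0
    for u, v in edges:
        mask |= 1 << index[(u, v) if u < v else (v, u)]
    return mask


def _is_connected_mask(mask, k):
    adj = [0] * k
    for u, v in mask_to_edges(mask, k):
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    seen = 1
    frontier = 1
    while frontier:
        reach = seen
        for i in range(k):
            if frontier >> i & 1:
                reach |= adj[i]
        frontier = reach & ~seen
        seen = reach
    return seen == (1 << k) - 1


def _permute_mask(mask, k, perm):
    return edges_to_mask([(perm[u], perm[v]) for u, v in mask_to_edges(mask, k)], k)


def canonical_mask(mask, k):
    """Lexicographically minimal edge bitmask over all node relabelings."""
    return min(_permute_mask(mask, k, perm) for perm in permutations(range(k)))


def automorphism_count(mask, k):
    """|Aut(g)| for the graph encoded by mask."""
    return sum(1 for perm in permutations(range(k)) if _permute_mask(mask, k, perm) == mask)


@dataclass(frozen=True)
class GraphletType:
    """One canonical graphlet: node count and canonical edge bitmask."""

    k: int
    mask: int
    name: str

    @property
    def edges(self):
        return mask_to_edges(self.mask, self.k)

    def to_networkx(self):
        g = nx.Graph()
        g.add_nodes_from(range(self.k))
        g.add_edges_from(self.edges)
        return g


class GraphletCatalog:
    """Deterministic enumeration of unordered graphlet types for k in [k_min, k_max].

    Types are ordered by (k, canonical mask); the per-size counts match the
    exhaustive totals 1, 2, 6 and 21 for k = 2, 3, 4 and 5.
    """

    ordered = False

    def __init__(self, k_min, k_max):
        if not (2 <= k_min <= k_max <= 5):
            raise ValueError(f"unsupported graphlet size range [{k_min}, {k_max}]; supported is [2, 5]")
        self.k_min, self.k_max = k_min, k_max
        self.types = []
        self._labeled_lookup = {}  # (k, labeled mask) -> type index
        for k in range(k_min, k_max + 1):
            canon = sorted({
                canonical_mask(m, k)
                for m in range(1 << len(_pairs(k)))
                if _is_connected_mask(m, k)
            })
            for i, cm in enumerate(canon):
                self.types.append(GraphletType(k, cm, f"g{k}_{i + 1}"))
            base = len(self.types) - len(canon)
            canon_index = {cm: base + i for i, cm in enumerate(canon)}
            for m in range(1 << len(_pairs(k))):
                if _is_connected_mask(m, k):
                    self._labeled_lookup[(k, m)] = canon_index[canonical_mask(m, k)]

    def __len__(self):
        return len(self.types)

    @property
    def names(self):
        return [t.name for t in self.types]

    def index_of(self, k, labeled_mask):
        return self._labeled_lookup[(k, labeled_mask)]


class OrderedGraphletCatalog:
    """Ordered graphlet types for k in [k_min, k_max] (3-4 nodes supported).

    With a total node order, each order-class of an unordered graphlet g is
    one distinct edge pattern on rank-labelled nodes, so the ordered types of
    size k are exactly the connected labelled graphs on k ordered nodes and
    each g contributes k!/|Aut(g)| of them.
    """

    ordered = True

    def __init__(self, k_min, k_max):
        if not (3 <= k_min <= k_max <= 4):
            raise ValueError(f"unsupported ordered-graphlet size range [{k_min}, {k_max}]; supported is [3, 4]")
        self.k_min, self.k_max = k_min, k_max
        self.types = []
        self._labeled_lookup = {}
        self.base_type_mask = []  # canonical mask of the underlying unordered graphlet
        for k in range(k_min, k_max + 1):
            masks = sorted(
                m for m in range(1 << len(_pairs(k))) if _is_connected_mask(m, k)
            )
            for i, m in enumerate(masks):
                self._labeled_lookup[(k, m)] = len(self.types)
                self.types.append(GraphletType(k, m, f"og{k}_{i + 1}"))
                self.base_type_mask.append(canonical_mask(m, k))

    def __len__(self):
        return len(self.types)

    @property
    def names(self):
        return [t.name for t in self.types]

    def index_of(self, k, labeled_mask):
        return self._labeled_lookup[(k, labeled_mask)]


def enumerate_graphlets(k_min, k_max) -> GraphletCatalog:
    return GraphletCatalog(k_min, k_max)


def enumerate_ordered_graphlets(k_min, k_max) -> OrderedGraphletCatalog:
    return OrderedGraphletCatalog(k_min, k_max)


def expected_order_class_count(graphlet: GraphletType) -> int:
    """k!/|Aut(g)|: number of ordered types an unordered graphlet expands into."""
    return factorial(graphlet.k) // automorphism_count(graphlet.mask, graphlet.k)


@dataclass
class GraphletCountVector:
    catalog: object
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.catalog):
            raise ValueError("count vector length must match catalog size")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


def _enumerate_connected_subgraphs(adj, k):
    """Yield every connected induced k-node subgraph (as a sorted tuple) once.

    ESU-style extension: grow from each root using only higher-numbered
    nodes, extending with exclusive neighbourhood members.
    """
    nodes = sorted(adj)

    def extend(sub, extension, root):
        if len(sub) == k:
            yield tuple(sorted(sub))
            return
        ext = set(extension)
        while ext:
            w = ext.pop()
            new_ext = ext | {
                u for u in adj[w] if u > root and u not in sub and all(u not in adj[s] for s in sub)
            }
            yield from extend(sub + [w], new_ext, root)

    for v in nodes:
        yield from extend([v], {u for u in adj[v] if u > v}, v)


def _adjacency(graph_like):
    g = graph_like if isinstance(graph_like, nx.Graph) else graph_like.graph
    return {v: set(g[v]) for v in g}


def _count(graph_like, catalog):
    adj = _adjacency(graph_like)
    counts = np.zeros(len(catalog), dtype=np.int64)
    for k in range(catalog.k_min, catalog.k_max + 1):
        pair_bits = {p: b for b, p in enumerate(_pairs(k))}
        for sub in _enumerate_connected_subgraphs(adj, k):
            mask = 0
            for (a, b), bit in pair_bits.items():
                if sub[b] in adj[sub[a]]:
                    mask |= 1 << bit
            counts[catalog.index_of(k, mask)] += 1
    return GraphletCountVector(catalog, counts)


def count_graphlets(psn, catalog: GraphletCatalog) -> GraphletCountVector:
    """Exact induced counts of every catalog type; each node subset counted once."""
    return _count(psn, catalog)


def count_ordered_graphlets(psn, ordered_catalog: OrderedGraphletCatalog) -> GraphletCountVector:
    """Exact ordered counts: subsets classified with node order = sequence order.

    Node identifiers are residue sequence indices, so sorting a subset
    ascending yields the rank labelling that defines the ordered type.
    """
    return _count(psn, ordered_catalog)


def to_log_feature(count_vector: GraphletCountVector, feature_name="graphlet-log") -> FeatureVector:
    """ln(c_i + 1) per type; the +1 keeps zero counts finite."""
    return FeatureVector(
        feature_name, list(count_vector.catalog.names), np.log(count_vector.counts + 1.0)
    )


def to_raw_feature(count_vector: GraphletCountVector, feature_name="graphlet-raw") -> FeatureVector:
    return FeatureVector(
        feature_name, list(count_vector.catalog.names), count_vector.counts.astype(float)
    )


def to_normalized_feature(count_vector: GraphletCountVector, feature_name="graphlet-norm") -> FeatureVector:
    """c_i / sum(c); all zeros when the total count is zero."""
    total = count_vector.counts.sum()
    values = count_vector.counts / total if total > 0 else np.zeros(len(count_vector.counts))
    return FeatureVector(feature_name, list(count_vector.catalog.names), values)
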