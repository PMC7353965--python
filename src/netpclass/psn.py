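"""Protein structure network (PSN) construction and admissibility filtering.

Nodes are residues (identified by their 1-based sequence index); an edge
joins two residues whose minimum heavy-atom distance is within a cutoff
(4 A by default, 6 A as a named variant).  The weighted counterpart is the
residue-residue minimum-distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ProteinDomainStructure, ResidueRecord

DEFAULT_CUTOFF = 4.0
WIDE_CUTOFF = 6.0  # used by the 6 A ordered-graphlet feature variant


@dataclass
class PSN:
    """Unweighted simple graph over residues, nodes in sequence order."""

    graph: nx.Graph
    cutoff: float = DEFAULT_CUTOFF
    atom_policy: str = "any-heavy-atom"
    name: str = ""

    def __post_init__(self):
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("PSN must not contain self-loops")

    @property
    def node_ids(self):
        """Residue sequence indices, strictly increasing."""
        return sorted(self.graph.nodes)

    @property
    def edges(self):
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self):
        return self.graph.number_of_nodes()

    @property
    def n_edges(self):
        return self.graph.number_of_edges()

    def to_edgelist(self, path):
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{u}\t{v}\n")

    @classmethod
    def from_edgelist(cls, path, cutoff=DEFAULT_CUTOFF):
        g = nx.read_edgelist(path, nodetype=int)
        return cls(g, cutoff=cutoff)


@dataclass
class DistanceMatrix:
    """Symmetric residue-residue minimum heavy-atom distance matrix (A)."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distance")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self):
        return self.values.shape[0]

    def to_csv(self, path):
        np.savetxt(path, self.values, delimiter=",", fmt="%.6f")


def residue_min_distance(res_a: ResidueRecord, res_b: ResidueRecord) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs of two residues."""
    if len(res_a.coords) == 0 or len(res_b.coords) == 0:
        raise ValueError("residue has no heavy atoms")
    return float(cdist(res_a.coords, res_b.coords).min())


def build_distance_matrix(structure: ProteinDomainStructure) -> DistanceMatrix:
    """All-pairs residue minimum heavy-atom distance matrix.

    Computed from the full atom-atom distance matrix, block-reduced per
    residue pair, which matches a brute-force scan over atom pairs.
    """
    coords = np.vstack([r.coords for r in structure.residues])
    counts = [len(r.coords) for r in structure.residues]
    starts = np.concatenate([[0], np.cumsum(counts)])[:-1]
    atom_d = cdist(coords, coords)
    # reduce atoms -> residues along each axis
    rows = np.minimum.reduceat(atom_d, starts, axis=0)
    d = np.minimum.reduceat(rows, starts, axis=1)
    np.fill_diagonal(d, 0.0)
    d = np.minimum(d, d.T)  # guard symmetry against float noise
    return DistanceMatrix(d, name=structure.domain_id)


def psn_from_distance_matrix(dm: DistanceMatrix, cutoff: float = DEFAULT_CUTOFF, name: str = "") -> PSN:
    """Threshold a distance matrix into a PSN: edge (i, j) iff D_ij <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = dm.n
    g = nx.Graph()
    g.add_nodes_from(range(1, n + 1))
    ii, jj = np.nonzero(np.triu(dm.values <= cutoff, k=1))
    g.add_edges_from(zip(ii + 1, jj + 1))
    return PSN(g, cutoff=cutoff, name=name or dm.name)


def build_psn(structure: ProteinDomainStructure, cutoff: float = DEFAULT_CUTOFF) -> PSN:
    """Build the unweighted PSN of a domain at the given heavy-atom cutoff."""
    return psn_from_distance_matrix(build_distance_matrix(structure), cutoff, name=structure.domain_id)


@dataclass
class FilterVerdict:
    keep: bool
    reason: str = ""

    def __bool__(self):
        return self.keep


#: Admissibility thresholds for a "meaningful" PSN.
MIN_DIAMETER = 6
MIN_NODES = 100


def filter_psn(psn: PSN, min_diameter: int = MIN_DIAMETER, min_nodes: int = MIN_NODES) -> FilterVerdict:
    """Admissibility check: connected, diameter >= 6, and >= 100 nodes.

    The reason names the first criterion that fails, in that order.
    """
    g = psn.graph
    if g.number_of_nodes() == 0 or not nx.is_connected(g):
        return FilterVerdict(False, "disconnected")
    if nx.diameter(g) < min_diameter:
        return FilterVerdict(False, "diameter")
    if g.number_of_nodes() < min_nodes:
        return FilterVerdict(False, "size")
    return FilterVerdict(True)
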