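"""Baseline sequence, contact-map and global-network protein features.

These are the non-graphlet descriptors the graphlet features are compared
against: amino-acid and di-amino-acid composition, the cutoff scanning
matrix (CSM), and a seven-component summary of global PSN topology.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .features import FeatureVector
from .psn import PSN, DistanceMatrix, build_distance_matrix

#: Canonical one-letter alphabet of the 20 standard amino acids.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: CSM distance cutoffs: 0.0 to 30.0 A in 0.2 A steps (151 values).
CSM_CUTOFFS = np.round(np.arange(151) * 0.2, 10)


def aa_composition(sequence: str) -> FeatureVector:
    """Relative frequency of each of the 20 amino-acid types (sums to 1)."""
    if not sequence:
        raise ValueError("empty sequence")
    unknown = set(sequence) - set(AA_ALPHABET)
    if unknown:
        raise ValueError(f"unknown amino-acid letters: {sorted(unknown)}")
    counts = np.array([sequence.count(a) for a in AA_ALPHABET], dtype=float)
    return FeatureVector("aacomposition", list(AA_ALPHABET), counts / len(sequence))


def daa_composition(sequence: str) -> FeatureVector:
    """Relative frequency of the 400 ordered di-amino-acid combinations.

    The denominator is the number of adjacent pairs actually present
    (len - 1), so the vector is a probability distribution.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2 for dipeptides")
    unknown = set(sequence) - set(AA_ALPHABET)
    if unknown:
        raise ValueError(f"unknown amino-acid letters: {sorted(unknown)}")
    index = {a: i for i, a in enumerate(AA_ALPHABET)}
    counts = np.zeros((20, 20))
    for a, b in zip(sequence, sequence[1:]):
        counts[index[a], index[b]] += 1
    labels = [a + b for a in AA_ALPHABET for b in AA_ALPHABET]
    return FeatureVector("daacomposition", labels, counts.ravel() / (len(sequence) - 1))


def csm(structure_or_dm) -> FeatureVector:
    """Cutoff scanning matrix: residue-pair contact counts at 151 cutoffs.

    Component k counts unordered residue pairs whose minimum heavy-atom
    distance is <= 0.2k A (k = 0..150); the vector is monotone
    non-decreasing by construction.
    """
    dm = structure_or_dm if isinstance(structure_or_dm, DistanceMatrix) else build_distance_matrix(structure_or_dm)
    iu = np.triu_indices(dm.n, k=1)
    pair_d = np.sort(dm.values[iu])
    counts = np.searchsorted(pair_d, CSM_CUTOFFS, side="right").astype(float)
    labels = [f"csm_{c:.1f}" for c in CSM_CUTOFFS]
    return FeatureVector("csm", labels, counts)


def _intra_hub_connectivity(g: nx.Graph) -> float:
    """Share of hub-incident edges whose both endpoints are hubs.

    Hubs are nodes with degree above mean + 1 s.d.; 0 when no edge touches
    a hub.
    """
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    threshold = degrees.mean() + degrees.std()
    hubs = {v for v, d in g.degree() if d > threshold}
    touching = [(u, v) for u, v in g.edges if u in hubs or v in hubs]
    if not touching:
        return 0.0
    both = sum(1 for u, v in touching if u in hubs and v in hubs)
    return both / len(touching)


def _assortativity(g: nx.Graph) -> float:
    """Pearson degree-degree correlation over edges; 0 for regular graphs."""
    degrees = {d for _, d in g.degree()}
    if len(degrees) == 1:
        return 0.0  # zero degree variance; correlation undefined
    value = nx.degree_assortativity_coefficient(g)
    return 0.0 if not np.isfinite(value) else float(value)


EXISTING_ALL_COMPONENTS = [
    "average_degree",
    "average_distance",
    "maximum_distance",
    "average_closeness",
    "average_clustering",
    "intra_hub_connectivity",
    "assortativity",
]


def existing_all(psn: PSN) -> FeatureVector:
    """Seven global network statistics of a connected PSN.

    In order: average degree, average shortest-path distance (over node
    pairs), maximum distance (diameter), average closeness centrality,
    average clustering coefficient, intra-hub connectivity, assortativity.
    """
    g = psn.graph if isinstance(psn, PSN) else psn
    if g.number_of_nodes() < 2 or not nx.is_connected(g):
        raise ValueError("existing_all requires a connected PSN; apply filter_psn first")
    n = g.number_of_nodes()
    values = np.array([
        2.0 * g.number_of_edges() / n,
        nx.average_shortest_path_length(g),
        float(nx.diameter(g)),
        float(np.mean(list(nx.closeness_centrality(g).values()))),
        nx.average_clustering(g),
        _intra_hub_connectivity(g),
        _assortativity(g),
    ])
    return FeatureVector("existing-all", list(EXISTING_ALL_COMPONENTS), values)
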