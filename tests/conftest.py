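"""Shared fixtures: small structures, graphs and the synthetic benchmark.

The benchmark (helix vs extended, 60 domains per class, noise 0.3 A) and
its cross-validation results are computed once per session and shared by
the unit and acceptance tests.
"""

import numpy as np
import pytest

import netpclass as npc
from netpclass.structure_io import ProteinDomainStructure, ResidueRecord


def make_structure(coords_per_residue, aa_codes=None, domain_id="test"):
    """Build a structure from a list of per-residue (n_atoms, 3) coordinate arrays."""
    residues = []
    for i, coords in enumerate(coords_per_residue):
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        aa = (aa_codes[i] if aa_codes else "A")
        residues.append(ResidueRecord(i + 1, aa, tuple("C" * len(coords)), coords))
    return ProteinDomainStructure(domain_id, residues)


@pytest.fixture
def two_residue_structure():
    """Two single-atom residues 5.0 A apart (a 3-4-5 triangle)."""
    return make_structure([[(0.0, 0.0, 0.0)], [(3.0, 4.0, 0.0)]])


@pytest.fixture
def line_structure():
    """Ten single-atom residues on a line, spaced 3.8 A apart."""
    return make_structure([[(3.8 * i, 0.0, 0.0)] for i in range(10)])


@pytest.fixture(scope="session")
def benchmark_specs():
    return [
        npc.SyntheticClassSpec("helix", backbone_kind="helix", noise_sigma=0.3),
        npc.SyntheticClassSpec("extended", backbone_kind="extended", noise_sigma=0.3),
    ]


@pytest.fixture(scope="session")
def benchmark_dataset(benchmark_specs):
    structures, table = npc.generate_dataset(benchmark_specs, per_class_n=60, seed=7)
    labels = [table[s.domain_id] for s in structures]
    return structures, table, labels


@pytest.fixture(scope="session")
def benchmark_og34(benchmark_dataset):
    structures, _, _ = benchmark_dataset
    return npc.compute_feature_matrix(structures, "orderedgraphlet-3-4")


@pytest.fixture(scope="session")
def benchmark_aa(benchmark_dataset):
    structures, _, _ = benchmark_dataset
    return npc.compute_feature_matrix(structures, "aacomposition")


@pytest.fixture(scope="session")
def benchmark_lr_results(benchmark_og34, benchmark_dataset):
    _, _, labels = benchmark_dataset
    return npc.PSNClassificationModel(benchmark_og34, labels).fit(seed=1)


@pytest.fixture(scope="session")
def benchmark_aa_results(benchmark_aa, benchmark_dataset):
    _, _, labels = benchmark_dataset
    return npc.PSNClassificationModel(benchmark_aa, labels).fit(seed=1)


@pytest.fixture(scope="session")
def benchmark_dl_results(benchmark_dataset):
    structures, _, labels = benchmark_dataset
    matrices = [npc.build_distance_matrix(s) for s in structures]
    return npc.DistanceMatrixDLModel(matrices, labels).fit(seed=1)
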