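"""Synthetic protein structures and graph fixtures for end-to-end testing.

Two structurally distinct backbone families are emulated:

* ``helix`` — residue anchors on a parametric helix (radius 2.3 A, rise
  1.5 A per residue, 100 degrees per residue).  Axial pseudo-atom offsets
  give the chain i -> i+3 heavy-atom contacts at 4 A, the way real
  alpha-helices gain short-range contacts, so its PSN carries chords and
  short cycles.
* ``extended`` — a strand-like zigzag with 3.3 A rise whose PSN at 4 A is
  essentially a path (sequential contacts only).

Every residue carries four backbone-like pseudo heavy atoms (N, CA, C, O)
and a one-letter type drawn uniformly from the 20-letter alphabet,
identically across classes — so composition features are uninformative by
construction while network features separate the classes.  Geometry mimics
secondary-structure contact density, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .classic_features import AA_ALPHABET
from .structure_io import LabelTable, ProteinDomainStructure, ResidueRecord, write_labels, write_pdb

HELIX_RADIUS = 2.3     # A
HELIX_RISE = 1.5       # A per residue
HELIX_TWIST = 100.0    # degrees per residue
EXTENDED_RISE = 3.3    # A per residue
EXTENDED_SWAY = 1.0    # lateral zigzag amplitude, A

#: Backbone-like pseudo-atom offsets per residue: (element, radial, axial) in A.
#: The +2.0 axial carbonyl-oxygen offset is what creates helix i -> i+3 contacts.
ATOM_OFFSETS = (
    ("N", -0.10, -0.50),
    ("C", 0.00, 0.00),   # CA
    ("C", 0.10, 0.75),
    ("O", 0.50, 2.00),
)


@dataclass
class SyntheticClassSpec:
    """Recipe for one synthetic structural class."""

    class_name: str
    backbone_kind: str = "helix"            # helix | extended | mixed
    n_residues: tuple = (100, 120)          # inclusive range
    noise_sigma: float = 0.3                # A, per coordinate
    atoms_per_residue: int = 4
    segment_length: int = 15                # for the mixed kind

    def __post_init__(self):
        if self.backbone_kind not in ("helix", "extended", "mixed"):
            raise ValueError(f"unknown backbone kind: {self.backbone_kind}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (1 <= self.atoms_per_residue <= len(ATOM_OFFSETS)):
            raise ValueError(f"atoms_per_residue must be in [1, {len(ATOM_OFFSETS)}]")
        lo, hi = self.n_residues
        if lo > hi or lo < 1:
            raise ValueError("invalid n_residues range")


def _helix_frames(n, start_index=0):
    """(anchor, radial unit, axial unit) per residue on the parametric helix."""
    i = np.arange(start_index, start_index + n)
    theta = np.deg2rad(HELIX_TWIST) * i
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    anchors = HELIX_RADIUS * radial + np.outer(i - start_index, [0.0, 0.0, HELIX_RISE])
    axial = np.tile([0.0, 0.0, 1.0], (n, 1))
    return anchors, radial, axial


def _extended_frames(n):
    i = np.arange(n)
    sway = EXTENDED_SWAY * np.where(i % 2 == 0, 1.0, -1.0)
    anchors = np.stack([sway, np.zeros(n), EXTENDED_RISE * i], axis=1)
    radial = np.stack([np.where(i % 2 == 0, 1.0, -1.0), np.zeros(n), np.zeros(n)], axis=1)
    axial = np.tile([0.0, 0.0, 1.0], (n, 1))
    return anchors, radial, axial


def _backbone_frames(kind, n, segment_length):
    if kind == "helix":
        return _helix_frames(n)
    if kind == "extended":
        return _extended_frames(n)
    # mixed: alternate helix/extended segments stacked along z
    anchors, radial, axial = [], [], []
    z_offset = 0.0
    kind_cycle = ["helix", "extended"]
    done = 0
    seg = 0
    while done < n:
        m = min(segment_length, n - done)
        a, r, x = _backbone_frames(kind_cycle[seg % 2], m, segment_length)
        a = a + np.array([0.0, 0.0, z_offset])
        z_offset = a[-1, 2] + 3.5
        anchors.append(a)
        radial.append(r)
        axial.append(x)
        done += m
        seg += 1
    return np.vstack(anchors), np.vstack(radial), np.vstack(axial)


def generate_structure(spec: SyntheticClassSpec, seed: int = 0, domain_id: str = None) -> ProteinDomainStructure:
    """Generate one noisy synthetic domain; deterministic under (spec, seed)."""
    rng = np.random.default_rng(seed)
    lo, hi = spec.n_residues
    n = int(rng.integers(lo, hi + 1))
    anchors, radial, axial = _backbone_frames(spec.backbone_kind, n, spec.segment_length)
    residues = []
    sequence = rng.choice(list(AA_ALPHABET), size=n)
    for i in range(n):
        elements, coords = [], []
        for element, dr, dz in ATOM_OFFSETS[: spec.atoms_per_residue]:
            pos = anchors[i] + dr * radial[i] + dz * axial[i]
            elements.append(element)
            coords.append(pos)
        coords = np.asarray(coords)
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        residues.append(ResidueRecord(i + 1, str(sequence[i]), tuple(elements), coords))
    name = domain_id or f"{spec.class_name}_{seed}"
    return ProteinDomainStructure(name, residues)


def generate_dataset(specs, per_class_n: int, seed: int = 0, out_dir=None):
    """Generate ``per_class_n`` structures per class spec plus a label table.

    Returns (structures, LabelTable); if ``out_dir`` is given, PDB files and
    a ``labels.tsv`` are written there.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("need at least two class specs")
    structures, entries = [], {}
    for c, spec in enumerate(specs):
        for i in range(per_class_n):
            domain_id = f"{spec.class_name}{i:04d}"
            s = generate_structure(spec, seed=seed + c * per_class_n + i, domain_id=domain_id)
            structures.append(s)
            entries[domain_id] = spec.class_name
    table = LabelTable(entries)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in structures:
            write_pdb(s, out_dir / f"{s.domain_id}.pdb")
        write_labels(table, out_dir / "labels.tsv")
    return structures, table


def graph_fixtures() -> dict:
    """Named small graphs used by the graphlet oracle tests."""
    paw = nx.cycle_graph(3)
    paw.add_edge(2, 3)
    diamond = nx.complete_graph(4)
    diamond.remove_edge(0, 1)
    return {
        "P3": nx.path_graph(3),
        "P4": nx.path_graph(4),
        "P5": nx.path_graph(5),
        "C4": nx.cycle_graph(4),
        "C5": nx.cycle_graph(5),
        "C6": nx.cycle_graph(6),
        "S4": nx.star_graph(3),
        "K3": nx.complete_graph(3),
        "K4": nx.complete_graph(4),
        "K5": nx.complete_graph(5),
        "paw": paw,
        "diamond": diamond,
    }


def erdos_renyi(n: int, p: float, seed: int) -> nx.Graph:
    """Seeded Erdos-Renyi graph with nodes 1..n (sequence-order labels)."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {v: v + 1 for v in g.nodes})
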