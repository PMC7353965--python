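"""Read protein domain structures from PDB files and class labels from TSV tables.

A domain structure is an ordered list of residues, each carrying the 3D
coordinates of its heavy atoms (C, N, O, S).  Hydrogens are never retained;
selenium (from selenomethionine) is dropped when MSE is remapped to MET.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

logger = logging.getLogger(__name__)

#: Elements counted as heavy atoms in standard amino acids.
HEAVY_ELEMENTS = frozenset({"C", "N", "O", "S"})

#: Three-letter to one-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class ResidueRecord:
    """One residue: sequence position, amino-acid type and heavy-atom coordinates.

    Parameters
    ----------
    seq_index : int
        1-based position within the domain chain (contiguous after parsing,
        regardless of author numbering gaps).
    aa_code : str
        One-letter code, one of the 20 standard types.
    elements : tuple of str
        Element symbol per heavy atom; each is in :data:`HEAVY_ELEMENTS`.
    coords : ndarray of shape (n_atoms, 3)
        Cartesian coordinates in Angstroms.
    """

    seq_index: int
    aa_code: str
    elements: tuple
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n_atoms, 3) array")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        if len(self.coords) == 0:
            raise ValueError("residue must have at least one heavy atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinate")
        bad = set(self.elements) - HEAVY_ELEMENTS
        if bad:
            raise ValueError(f"non heavy-atom elements: {sorted(bad)}")

    @property
    def heavy_atoms(self):
        """List of (element, x, y, z) tuples."""
        return [(e, *xyz) for e, xyz in zip(self.elements, self.coords)]


@dataclass
class ProteinDomainStructure:
    """An ordered protein domain: the raw input to PSN construction."""

    domain_id: str
    residues: list = field(default_factory=list)

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty structure: {self.domain_id}")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("seq_index must be strictly increasing")

    def __len__(self):
        return len(self.residues)

    @property
    def sequence(self):
        return "".join(r.aa_code for r in self.residues)


@dataclass
class LabelTable:
    """Mapping of domain identifier to (possibly hierarchical) class label."""

    entries: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, domain_id):
        return self.entries[domain_id]


def extract_sequence(structure: ProteinDomainStructure) -> str:
    """One-letter sequence of the domain, in seq_index order."""
    return structure.sequence


def parse_pdb(path, chain_selector=None, residue_range=None, domain_id=None):
    """Parse a PDB file into a :class:`ProteinDomainStructure`.

    Only the first model of multi-model (e.g. NMR) files is used.  Hydrogens
    and any element outside {C, N, O, S} are discarded.  For disordered atoms
    the highest-occupancy conformer is kept (ties resolved toward altloc 'A').
    MSE is remapped to MET; other non-standard residues are skipped with a
    warning.

    Parameters
    ----------
    path : str or Path
        PDB file with ATOM records.
    chain_selector : str, optional
        Chain identifier; default is the first chain encountered.
    residue_range : (int, int), optional
        Inclusive author-numbering range to keep.
    domain_id : str, optional
        Identifier for the result; defaults to the file stem.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            pdb_structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise ValueError(f"PDB parse error in {path}: {exc}") from exc

    models = list(pdb_structure)
    if not models:
        raise ValueError(f"empty structure: no models in {path}")
    model = models[0]  # first-model convention

    chains = list(model)
    if chain_selector is not None:
        chains = [c for c in chains if c.id == chain_selector]
        if not chains:
            raise ValueError(f"empty structure: chain {chain_selector!r} not in {path}")
    chain = chains[0]

    raw = []
    for res in chain:
        hetflag, resseq, icode = res.id
        resname = res.get_resname().strip()
        if resname == "MSE":
            resname = "MET"  # selenomethionine -> methionine; Se dropped below
        elif hetflag.strip():
            logger.warning("skipping HETATM residue %s %s in %s", resname, resseq, path.name)
            continue
        if resname not in THREE_TO_ONE:
            logger.warning("skipping non-standard residue %s %s in %s", resname, resseq, path.name)
            continue
        if residue_range is not None:
            lo, hi = residue_range
            if not (lo <= resseq <= hi):
                continue
        elements, coords = [], []
        for atom in res.get_unpacked_list():
            if atom.is_disordered():
                parent = res[atom.get_name()] if atom.get_name() in res else None
                if parent is not None and parent.is_disordered():
                    if atom.get_altloc() != _best_altloc(parent):
                        continue
            element = (atom.element or "").strip().upper()
            if not element:
                element = atom.get_name().strip()[:1].upper()
            if element not in HEAVY_ELEMENTS:
                continue
            elements.append(element)
            coords.append(atom.get_coord())
        if not coords:
            logger.warning("residue %s %s has no heavy atoms; skipped", resname, resseq)
            continue
        raw.append(((resseq, icode), THREE_TO_ONE[resname], elements, coords))

    if not raw:
        raise ValueError(f"empty structure: no parsable residues in {path}")

    raw.sort(key=lambda item: item[0])  # author number, then insertion code
    residues = [
        ResidueRecord(i + 1, aa, tuple(elements), np.array(coords))
        for i, (_, aa, elements, coords) in enumerate(raw)
    ]
    return ProteinDomainStructure(domain_id or path.stem, residues)


def _best_altloc(disordered_atom):
    """Altloc id with the highest occupancy; ties broken alphabetically."""
    best = min(
        disordered_atom.disordered_get_id_list(),
        key=lambda a: (-(disordered_atom.disordered_get(a).get_occupancy() or 0.0), a),
    )
    return best


def write_pdb(structure: ProteinDomainStructure, path):
    """Write a structure as minimal ATOM records (one chain 'A', occupancy 1)."""
    with open(path, "w") as fh:
        serial = 1
        for res in structure.residues:
            resname = ONE_TO_THREE[res.aa_code]
            per_elem = {}
            for element, (x, y, z) in zip(res.elements, res.coords):
                per_elem[element] = per_elem.get(element, 0) + 1
                name = f"{element}{per_elem[element]}"
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s}{resname:>4s} A{res.seq_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{element:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


def read_labels(path) -> LabelTable:
    """Read a ``domain_id<TAB>class`` table into a :class:`LabelTable`.

    Duplicate domain identifiers are rejected; an empty file yields an empty
    table with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"domain_id", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}, got {list(df.columns)}")
    if df.empty:
        logger.warning("label table %s is empty", path)
        return LabelTable({})
    if df["domain_id"].duplicated().any():
        dupes = df.loc[df["domain_id"].duplicated(), "domain_id"].tolist()
        raise ValueError(f"duplicate domain_id entries: {dupes}")
    return LabelTable(dict(zip(df["domain_id"], df["class"])))


def write_labels(table: LabelTable, path):
    pd.DataFrame(
        {"domain_id": list(table.entries), "class": list(table.entries.values())}
    ).to_csv(path, sep="\t", index=False)
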