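"""Feature registry and end-to-end pipeline orchestration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .classic_features import aa_composition, csm, daa_composition, existing_all
from .classify import PSNClassificationModel
from .dl_classifier import DLConfig, DistanceMatrixDLModel
from .features import FeatureMatrix
from .graphlets import (
    count_graphlets,
    count_ordered_graphlets,
    enumerate_graphlets,
    enumerate_ordered_graphlets,
    to_log_feature,
    to_normalized_feature,
    to_raw_feature,
)
from .psn import DEFAULT_CUTOFF, WIDE_CUTOFF, build_distance_matrix, filter_psn, psn_from_distance_matrix
from .structure_io import parse_pdb, read_labels
from .transform import concatenate_matrices, pca_transform

logger = logging.getLogger(__name__)

_G34 = enumerate_graphlets(3, 4)
_G35 = enumerate_graphlets(3, 5)
_OG3 = enumerate_ordered_graphlets(3, 3)
_OG34 = enumerate_ordered_graphlets(3, 4)


def _graphlet_extractor(catalog, transform, cutoff, name):
    counter = count_ordered_graphlets if catalog.ordered else count_graphlets

    def extract(ctx):
        vec = transform(counter(ctx.psn(cutoff), catalog))
        vec.feature_name = name
        return vec

    return extract


class _StructureContext:
    """Per-structure cache of the distance matrix and PSNs at used cutoffs."""

    def __init__(self, structure):
        self.structure = structure
        self._dm = None
        self._psns = {}

    @property
    def dm(self):
        if self._dm is None:
            self._dm = build_distance_matrix(self.structure)
        return self._dm

    def psn(self, cutoff):
        if cutoff not in self._psns:
            self._psns[cutoff] = psn_from_distance_matrix(self.dm, cutoff, name=self.structure.domain_id)
        return self._psns[cutoff]


#: Registered per-protein feature extractors, keyed by their public names.
FEATURE_REGISTRY = {
    "aacomposition": lambda ctx: aa_composition(ctx.structure.sequence),
    "daacomposition": lambda ctx: daa_composition(ctx.structure.sequence),
    "csm": lambda ctx: csm(ctx.dm),
    "existing-all": lambda ctx: existing_all(ctx.psn(DEFAULT_CUTOFF)),
    "graphlet-3-4": _graphlet_extractor(_G34, to_log_feature, DEFAULT_CUTOFF, "graphlet-3-4"),
    "graphlet-3-5": _graphlet_extractor(_G35, to_log_feature, DEFAULT_CUTOFF, "graphlet-3-5"),
    "normgraphlet-3-4": _graphlet_extractor(_G34, to_normalized_feature, DEFAULT_CUTOFF, "normgraphlet-3-4"),
    "normgraphlet-3-5": _graphlet_extractor(_G35, to_normalized_feature, DEFAULT_CUTOFF, "normgraphlet-3-5"),
    "orderedgraphlet-3": _graphlet_extractor(_OG3, to_raw_feature, DEFAULT_CUTOFF, "orderedgraphlet-3"),
    "orderedgraphlet-3-4": _graphlet_extractor(_OG34, to_raw_feature, DEFAULT_CUTOFF, "orderedgraphlet-3-4"),
    "normorderedgraphlet-3": _graphlet_extractor(_OG3, to_normalized_feature, DEFAULT_CUTOFF, "normorderedgraphlet-3"),
    "normorderedgraphlet-3-4": _graphlet_extractor(_OG34, to_normalized_feature, DEFAULT_CUTOFF, "normorderedgraphlet-3-4"),
    "orderedgraphlet-3-4-6a": _graphlet_extractor(_OG34, to_raw_feature, WIDE_CUTOFF, "orderedgraphlet-3-4-6a"),
}


def compute_feature(structure, feature_name: str):
    """Compute one registered feature for one structure."""
    if feature_name not in FEATURE_REGISTRY:
        raise ValueError(f"unknown feature {feature_name!r}; known: {sorted(FEATURE_REGISTRY)}")
    return FEATURE_REGISTRY[feature_name](_StructureContext(structure))


def compute_feature_matrix(structures, feature_name: str) -> FeatureMatrix:
    """Compute one registered feature over a structure collection."""
    if feature_name not in FEATURE_REGISTRY:
        raise ValueError(f"unknown feature {feature_name!r}; known: {sorted(FEATURE_REGISTRY)}")
    extractor = FEATURE_REGISTRY[feature_name]
    vectors = [extractor(_StructureContext(s)) for s in structures]
    return FeatureMatrix.from_vectors([s.domain_id for s in structures], vectors)


@dataclass
class RunConfig:
    """Declarative description of one end-to-end run."""

    pdb_dir: str = None
    labels_path: str = None
    features: list = field(default_factory=lambda: ["orderedgraphlet-3-4"])
    cutoff: float = DEFAULT_CUTOFF
    apply_filter: bool = True
    pca: bool = False
    pca_variance: float = 0.9
    mode: str = "proportional"
    dl: bool = False
    seed: int = 0
    out_dir: str = "netpclass_out"

    def validate(self):
        unknown = [f for f in self.features if f not in FEATURE_REGISTRY]
        if unknown:
            raise ValueError(f"unknown feature(s) {unknown}; known: {sorted(FEATURE_REGISTRY)}")
        if self.mode not in ("proportional", "proportional+smote"):
            raise ValueError(f"unknown mode: {self.mode}")

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def load_structures(pdb_dir, labels_path):
    labels = read_labels(labels_path)
    structures = []
    for domain_id in labels.entries:
        structures.append(parse_pdb(Path(pdb_dir) / f"{domain_id}.pdb", domain_id=domain_id))
    return structures, labels


def run_pipeline(config: RunConfig, structures=None, labels=None) -> dict:
    """Parse -> PSN -> features -> (PCA) -> classify/DL, with a manifest.

    Structures and labels may be passed in-memory (e.g. from the synthetic
    generator) instead of via config paths.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if structures is None:
        if config.pdb_dir is None or config.labels_path is None:
            raise ValueError("either pass structures/labels or set pdb_dir and labels_path")
        structures, labels = load_structures(config.pdb_dir, config.labels_path)

    if config.apply_filter:
        kept = []
        for s in structures:
            ctx = _StructureContext(s)
            verdict = filter_psn(ctx.psn(config.cutoff))
            if verdict.keep:
                kept.append(s)
            else:
                logger.warning("dropping %s: %s", s.domain_id, verdict.reason)
        structures = kept
    if not structures:
        raise ValueError("no structures left after PSN filtering")

    y = [labels[s.domain_id] for s in structures]
    results = {}
    for feature_name in config.features:
        fm = compute_feature_matrix(structures, feature_name)
        fm.to_csv(out_dir / f"features_{feature_name}.csv")
        if config.pca:
            fm = pca_transform(fm, variance_threshold=config.pca_variance)
        model = PSNClassificationModel(fm, y, mode=config.mode)
        results[feature_name] = model.fit(seed=config.seed).cv.to_dict()

    if config.dl:
        matrices = [_StructureContext(s).dm for s in structures]
        dl_model = DistanceMatrixDLModel(matrices, y, DLConfig())
        results["distance-matrix-dl"] = dl_model.fit(seed=config.seed).cv.to_dict()

    manifest = {
        "netpclass_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "n_structures": len(structures),
        "classes": sorted(set(y)),
    }
    bundle = {"manifest": manifest, "results": results}
    with open(out_dir / "result.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_jsonable)
    return bundle


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
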