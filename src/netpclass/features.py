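"""Fixed-length per-protein descriptors and their matrix form.

FeatureVector is the interchange object between feature extraction and
classification; FeatureMatrix stacks vectors of one feature over a protein
set (rows = proteins, columns = feature components).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureVector:
    feature_name: str
    component_labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature values must be one-dimensional")
        if len(self.values) != len(self.component_labels):
            raise ValueError("labels and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")

    def __len__(self):
        return len(self.values)


@dataclass
class FeatureMatrix:
    """M proteins x N components, with row identity preserved."""

    protein_ids: list
    feature_name: str
    values: np.ndarray
    component_labels: list = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be two-dimensional")
        if len(self.protein_ids) != self.values.shape[0]:
            raise ValueError("row count must equal protein id count")
        if self.component_labels is None:
            self.component_labels = [f"{self.feature_name}.{i}" for i in range(self.values.shape[1])]
        if len(self.component_labels) != self.values.shape[1]:
            raise ValueError("column count must equal component label count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")

    @property
    def shape(self):
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.component_labels)

    def to_csv(self, path):
        df = self.to_dataframe()
        df.index.name = "protein_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, feature_name=None):
        df = pd.read_csv(path, index_col=0)
        return cls(
            protein_ids=list(df.index),
            feature_name=feature_name or "feature",
            values=df.to_numpy(dtype=float),
            component_labels=list(df.columns),
        )

    @classmethod
    def from_vectors(cls, protein_ids, vectors):
        """Stack per-protein FeatureVectors (all of the same feature) into a matrix."""
        names = {v.feature_name for v in vectors}
        if len(names) != 1:
            raise ValueError(f"cannot stack mixed features: {sorted(names)}")
        labels = vectors[0].component_labels
        for v in vectors:
            if v.component_labels != labels:
                raise ValueError("inconsistent component labels across proteins")
        return cls(
            protein_ids=list(protein_ids),
            feature_name=names.pop(),
            values=np.vstack([v.values for v in vectors]),
            component_labels=list(labels),
        )
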