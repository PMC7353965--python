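"""PCA transformation of feature matrices and concatenation-based integration."""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .features import FeatureMatrix, FeatureVector


def choose_n_components(explained_variance_ratio, variance_threshold=0.9, r_min=2):
    """Smallest r whose cumulative explained variance reaches the threshold,
    floored at r_min and capped at the number of available components."""
    cumulative = np.cumsum(explained_variance_ratio)
    reached = np.nonzero(cumulative >= variance_threshold - 1e-12)[0]
    r = int(reached[0]) + 1 if len(reached) else len(cumulative)
    return min(max(r, r_min), len(cumulative))


def _fix_signs(components, scores):
    """Deterministic sign convention: largest-|loading| entry positive."""
    for j in range(components.shape[0]):
        pivot = np.argmax(np.abs(components[j]))
        if components[j, pivot] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    return components, scores


def pca_transform(matrix: FeatureMatrix, variance_threshold: float = 0.9, r_min: int = 2) -> FeatureMatrix:
    """Centered (unscaled) PCA scores keeping at least r_min components and
    as few as possible while explaining >= variance_threshold of variance.

    The component cap is min(M - 1, N) for an M x N input.
    """
    X = matrix.values
    m, n = X.shape
    if m < 2 or n < 2:
        raise ValueError("PCA requires at least 2 rows and 2 columns")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant feature matrix: zero total variance")
    cap = min(m - 1, n)
    pca = PCA(n_components=cap)
    scores = pca.fit_transform(X)
    r = min(choose_n_components(pca.explained_variance_ratio_, variance_threshold, r_min), cap)
    components, scores = _fix_signs(pca.components_.copy(), scores.copy())
    return FeatureMatrix(
        protein_ids=list(matrix.protein_ids),
        feature_name=f"{matrix.feature_name}-pca",
        values=scores[:, :r],
        component_labels=[f"pc{i + 1}" for i in range(r)],
    )


def concatenate_features(vectors) -> FeatureVector:
    """Concatenate per-protein feature vectors; labels keep their source prefix."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("nothing to concatenate")
    if len(vectors) == 1:
        return vectors[0]
    labels = [f"{v.feature_name}.{lab}" for v in vectors for lab in v.component_labels]
    values = np.concatenate([v.values for v in vectors])
    name = "+".join(v.feature_name for v in vectors)
    return FeatureVector(name, labels, values)


def concatenate_matrices(matrices) -> FeatureMatrix:
    """Column-wise concatenation of feature matrices over the same proteins."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("nothing to concatenate")
    ids = matrices[0].protein_ids
    for m in matrices:
        if list(m.protein_ids) != list(ids):
            raise ValueError("feature matrices must cover the same proteins in the same order")
    return FeatureMatrix(
        protein_ids=list(ids),
        feature_name="+".join(m.feature_name for m in matrices),
        values=np.hstack([m.values for m in matrices]),
        component_labels=[f"{m.feature_name}.{lab}" for m in matrices for lab in m.component_labels],
    )
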