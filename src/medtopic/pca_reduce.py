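"""Principal-component reduction of feature matrices before clustering.

Count features are high-dimensional, redundant and correlated; replacing
them with the leading principal components both reduces dimensionality and
decorrelates the inputs handed to the mixture model. Columns are centered
but not scaled (all blocks share count units); the retained component count
is the smallest m whose cumulative explained-variance ratio reaches the
coverage target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .features import FeatureMatrix

__all__ = ["PCAModel", "fit_pca", "transform", "save_pca", "load_pca"]

ArrayLike = Union[np.ndarray, FeatureMatrix]


@dataclass
class PCAModel:
    mean: np.ndarray                      # (d,)
    components: np.ndarray                # (m, d) orthonormal rows
    explained_variance_ratio: np.ndarray  # (m,) non-increasing
    coverage_target: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _as_array(matrix: ArrayLike) -> np.ndarray:
    if isinstance(matrix, FeatureMatrix):
        return np.asarray(matrix.values, dtype=np.float64)
    return np.asarray(matrix, dtype=np.float64)


def fit_pca(matrix: ArrayLike, coverage_target: float = 0.95,
            selection: str = "coverage", max_elbow: int = 50) -> PCAModel:
    """Fit by singular-value decomposition of the centered matrix.

    Two retention rules: ``coverage`` keeps the smallest m whose cumulative
    explained-variance ratio reaches ``coverage_target``; ``elbow`` keeps
    the m (searched up to ``max_elbow``) maximizing the successive
    eigenvalue drop ratio — the scree elbow. For bag-of-words count data,
    whose variance is diffuse across hundreds of near-noise directions,
    the elbow isolates the low-dimensional between-topic subspace that
    coverage-based retention cannot.

    Sign convention: each component's largest-magnitude loading is made
    positive, so fits are deterministic. A matrix with zero total variance
    is an error.
    """
    if not 0.0 < coverage_target <= 1.0:
        raise ValueError("coverage_target must be in (0, 1]")
    if selection not in ("coverage", "elbow"):
        raise ValueError("selection must be 'coverage' or 'elbow'")
    X = _as_array(matrix)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (X.shape[0] - 1)
    total = var.sum()
    if total <= 0.0:
        raise ValueError("matrix has zero total variance (all rows identical)")
    # numerical rank: drop components explaining (relatively) nothing
    nonzero = var > var[0] * 1e-12
    var, Vt = var[nonzero], Vt[nonzero]
    ratio = var / total
    if selection == "elbow" and len(ratio) > 1:
        upto = min(max_elbow, len(ratio) - 1)
        drops = ratio[:upto] / ratio[1:upto + 1]
        m = int(np.argmax(drops)) + 1
    else:
        cum = np.cumsum(ratio)
        m = int(np.searchsorted(cum, coverage_target - 1e-12) + 1)
        m = min(m, len(ratio))
    components = Vt[:m].copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return PCAModel(mean=mean, components=components,
                    explained_variance_ratio=ratio[:m],
                    coverage_target=coverage_target)


def transform(model: PCAModel, matrix: ArrayLike) -> np.ndarray:
    """Project rows onto the retained components after mean subtraction."""
    X = _as_array(matrix)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"column count {X.shape[1]} does not match model ({model.mean.shape[0]})"
        )
    return (X - model.mean) @ model.components.T


def save_pca(model: PCAModel, path) -> None:
    Path(path).write_text(json.dumps({
        "mean": model.mean.tolist(),
        "components": model.components.tolist(),
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
        "coverage_target": model.coverage_target,
    }), encoding="utf-8")


def load_pca(path) -> PCAModel:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return PCAModel(mean=np.asarray(d["mean"]),
                    components=np.asarray(d["components"]),
                    explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
                    coverage_target=d["coverage_target"])
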