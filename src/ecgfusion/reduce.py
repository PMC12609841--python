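"""Fusion strategies for the handcrafted feature block.

Three alternatives feed the classifier heads:

* ``concat`` — use the feature vectors as-is;
* ``pca`` — principal component analysis with a cumulative explained-variance
  target (default 95%) choosing the minimal number of retained components;
* ``weighting`` — variance-based selective scaling: each column is scaled by
  its sample standard deviation normalized to sum to one, emphasizing
  high-variance features without changing dimensionality.

PCA is always fit on training folds only and the frozen transform is applied
to validation/test data (leakage guard enforced by the training pipeline).
Per-record vectors are obtained from frame x channel matrices by averaging
over frames (``flatten_mode="mean"``) or by full flattening.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .ecg_io import ValidationError
from .features import CombinedFeatures

FUSION_STRATEGIES = ("concat", "pca", "weighting")


def record_vector(features: CombinedFeatures | np.ndarray, flatten_mode: str = "mean") -> np.ndarray:
    """Collapse a frames x channels matrix to one per-record vector."""
    values = features.values if isinstance(features, CombinedFeatures) else np.asarray(features)
    if flatten_mode == "mean":
        return values.mean(axis=0)
    if flatten_mode == "flatten":
        return values.ravel()
    raise ValidationError(f"unknown flatten_mode {flatten_mode!r}")


@dataclass
class PCAModel:
    """Frozen PCA transform with variance-target component selection."""

    mean_vector: np.ndarray
    components: np.ndarray       # (k, d), row-orthonormal
    explained_ratio: np.ndarray  # (k,), non-increasing
    k: int
    variance_target: float

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[1] != self.mean_vector.size:
            raise ValidationError(
                f"feature dimension {features.shape[1]} does not match "
                f"model dimension {self.mean_vector.size}"
            )
        return (features - self.mean_vector) @ self.components.T

    def inverse_transform(self, projected: np.ndarray) -> np.ndarray:
        projected = np.atleast_2d(np.asarray(projected, dtype=np.float64))
        return projected @ self.components + self.mean_vector

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            mean_vector=self.mean_vector,
            components=self.components,
            explained_ratio=self.explained_ratio,
            k=self.k,
            variance_target=self.variance_target,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        z = np.load(path)
        return cls(
            mean_vector=z["mean_vector"],
            components=z["components"],
            explained_ratio=z["explained_ratio"],
            k=int(z["k"]),
            variance_target=float(z["variance_target"]),
        )


def fit_pca(features: np.ndarray, variance_target: float = 0.95) -> PCAModel:
    """Fit PCA retaining the minimal k with cumulative explained ratio >= target.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making the fit deterministic.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValidationError("PCA needs a 2-D matrix with at least 2 rows")
    if not 0 < variance_target <= 1:
        raise ValidationError(f"variance_target must be in (0, 1], got {variance_target}")
    if np.allclose(features.var(axis=0), 0):
        raise ValidationError("zero-variance input: nothing for PCA to explain")

    # full decomposition, then cut at the variance target; svd_flip inside
    # sklearn enforces the largest-|loading|-positive sign convention
    full = _SkPCA(svd_solver="full")
    full.fit(features)
    ratios = full.explained_variance_ratio_
    cum = np.cumsum(ratios)
    if variance_target >= cum[-1]:
        k = ratios.size
    else:
        k = int(np.searchsorted(cum, variance_target) + 1)
    return PCAModel(
        mean_vector=full.mean_.copy(),
        components=full.components_[:k].copy(),
        explained_ratio=ratios[:k].copy(),
        k=k,
        variance_target=variance_target,
    )


def transform(model: PCAModel, features: np.ndarray) -> np.ndarray:
    """Project features onto the frozen PCA basis (centered)."""
    return model.transform(features)


def variance_weighting(features: np.ndarray) -> np.ndarray:
    """Scale each column by its normalized sample standard deviation.

    Weights are w_j = s_j / sum(s); zero-variance columns get weight 0 (and
    a constant all-zero column in the output).
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValidationError("variance weighting needs a 2-D matrix with >= 2 rows")
    s = features.std(axis=0, ddof=1)
    total = s.sum()
    weights = s / total if total > 0 else np.zeros_like(s)
    return features * weights


@dataclass
class FusionReducer:
    """Train-fold-fitted reducer applying one of the three fusion strategies."""

    strategy: str = "concat"
    variance_target: float = 0.95
    pca_model: PCAModel | None = None
    weights: np.ndarray | None = None

    def fit(self, train_features: np.ndarray) -> "FusionReducer":
        if self.strategy not in FUSION_STRATEGIES:
            raise ValidationError(f"unknown fusion strategy {self.strategy!r}")
        train_features = np.asarray(train_features, dtype=np.float64)
        if self.strategy == "pca":
            self.pca_model = fit_pca(train_features, self.variance_target)
        elif self.strategy == "weighting":
            s = train_features.std(axis=0, ddof=1)
            total = s.sum()
            self.weights = s / total if total > 0 else np.zeros_like(s)
        return self

    def apply(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if self.strategy == "concat":
            return features
        if self.strategy == "pca":
            if self.pca_model is None:
                raise ValidationError("reducer not fitted")
            return self.pca_model.transform(features)
        if self.weights is None:
            raise ValidationError("reducer not fitted")
        return features * self.weights

    @property
    def output_dim(self) -> int | None:
        if self.strategy == "pca" and self.pca_model is not None:
            return self.pca_model.k
        if self.strategy == "weighting" and self.weights is not None:
            return self.weights.size
        return None
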