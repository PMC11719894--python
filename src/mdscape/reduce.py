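"""PCA with smallest-component-count selection at a variance threshold.

The feature matrix is centred by column means and decomposed by SVD (via
scikit-learn's full-solver PCA); component signs are fixed by making each
component's largest-magnitude loading positive, so serialized models are
reproducible across runs and platforms.  The retained dimensionality is the
smallest m whose cumulative explained-variance ratio reaches the threshold
(default 0.80, which reduces well-sampled multidomain distance features to a
handful of collective-motion coordinates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .featurize import FeatureMatrix

__all__ = ["PCAModel", "ReducedSpace", "fit_pca", "n_components_for_threshold", "project"]


@dataclass
class PCAModel:
    """Fitted PCA: feature means, orthonormal loadings, eigenvalues.

    ``eigenvalues`` are the variances along each component (descending);
    ``total_variance`` is the total per-column variance of the centred data,
    so explained-variance ratios are ``eigenvalues / total_variance``.
    """

    mean: np.ndarray
    components: np.ndarray  # (R, D), rows orthonormal
    eigenvalues: np.ndarray
    total_variance: float

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-negative")

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        if self.total_variance == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savez_compressed(
            prefix.with_suffix(".npz"),
            mean=self.mean,
            components=self.components,
            eigenvalues=self.eigenvalues,
        )
        manifest = {
            "total_variance": float(self.total_variance),
            "n_components": int(len(self.eigenvalues)),
            "n_features": int(len(self.mean)),
        }
        (prefix.parent / f"{prefix.name}.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "PCAModel":
        prefix = Path(prefix)
        with np.load(prefix.with_suffix(".npz")) as data:
            mean, components, eigenvalues = (
                data["mean"],
                data["components"],
                data["eigenvalues"],
            )
        manifest = json.loads((prefix.parent / f"{prefix.name}.json").read_text())
        return cls(mean, components, eigenvalues, manifest["total_variance"])


@dataclass
class ReducedSpace:
    """Projection of a feature matrix onto the leading m components."""

    scores: np.ndarray  # (frames, m)
    frame_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] < 1:
            raise ValueError("scores must be (frames, m) with m >= 1")
        if len(self.frame_meta) == 0:
            self.frame_meta = pd.DataFrame(
                {"run_id": "", "condition": "", "frame": np.arange(len(self.scores))}
            )
        if len(self.frame_meta) != len(self.scores):
            raise ValueError("frame_meta length must match scores")

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]

    @property
    def m(self) -> int:
        return self.scores.shape[1]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude entry positive."""
    flips = np.sign(components[np.arange(len(components)), np.argmax(np.abs(components), axis=1)])
    flips[flips == 0] = 1.0
    return components * flips[:, None]


def fit_pca(feature_matrix: FeatureMatrix | np.ndarray) -> PCAModel:
    """Fit PCA on the (pooled) feature matrix.

    Centres by column means and keeps all min(frames-1, D) components; the
    covariance normalization is 1/(n-1), which does not affect variance
    ratios.
    """
    values = (
        feature_matrix.values
        if isinstance(feature_matrix, FeatureMatrix)
        else np.asarray(feature_matrix, dtype=float)
    )
    n, d = values.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 frames")
    pca = PCA(n_components=min(n - 1, d), svd_solver="full")
    pca.fit(values)
    components = _fix_signs(pca.components_)
    total_variance = float(values.var(axis=0, ddof=1).sum())
    return PCAModel(
        mean=pca.mean_,
        components=components,
        eigenvalues=pca.explained_variance_,
        total_variance=total_variance,
    )


def n_components_for_threshold(pca_model: PCAModel, threshold: float) -> int:
    """Smallest m whose cumulative explained-variance ratio >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cumulative = np.cumsum(pca_model.explained_variance_ratio)
    # guard against float shortfall at threshold 1.0 on full-rank data
    hits = np.flatnonzero(cumulative >= threshold - 1e-12)
    if len(hits) == 0:
        return len(cumulative)
    return int(hits[0]) + 1


def project(
    pca_model: PCAModel,
    feature_matrix: FeatureMatrix | np.ndarray,
    m: int,
) -> ReducedSpace:
    """Scores = (values - means) @ components[:m].T."""
    if m < 1 or m > len(pca_model.components):
        raise ValueError(f"m={m} out of range (1..{len(pca_model.components)})")
    if isinstance(feature_matrix, FeatureMatrix):
        values = feature_matrix.values
        meta = feature_matrix.frame_meta.copy()
    else:
        values = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
        meta = pd.DataFrame()
    if values.shape[1] != len(pca_model.mean):
        raise ValueError("feature dimension does not match the fitted model")
    scores = (values - pca_model.mean) @ pca_model.components[:m].T
    return ReducedSpace(scores=scores, frame_meta=meta)


def reconstruct(pca_model: PCAModel, reduced: ReducedSpace) -> np.ndarray:
    """Back-project scores into feature space (lossless at full rank)."""
    return reduced.scores @ pca_model.components[: reduced.m] + pca_model.mean
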