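"""Gaussian-mixture clustering of the reduced space.

The mixture is fit by expectation-maximization with full covariance matrices,
a diagonal covariance floor, and the best of ``n_init`` deterministic-seeded
random initializations kept by final log-likelihood.  The per-iteration
log-likelihood path is recorded on the model: EM guarantees it is
non-decreasing, and that guarantee is enforced as a test invariant.

Cluster-count selection follows the standard two-heuristic protocol: an elbow
(maximum discrete second difference, i.e. maximum curvature) on the BIC-vs-K
curve, and the mean silhouette ranking.  Nothing is auto-selected; the report
exposes both so the caller weighs them, as one does when the two heuristics
disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.metrics import silhouette_samples as _sk_silhouette_samples

from .reduce import ReducedSpace

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterModel",
    "ModelSelectionReport",
    "ClusterReport",
    "fit_gmm",
    "scan_k",
    "silhouette",
    "assign",
    "responsibilities",
    "cluster_weights",
    "populations_by_condition",
    "representative_frames",
    "match_labels",
]


@dataclass
class ClusterModel:
    """Fitted Gaussian mixture: weights, means, full covariances."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, m)
    covariances: np.ndarray  # (K, m, m)
    log_likelihood: float
    seed: int
    ll_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def m(self) -> int:
        return self.means.shape[1]


@dataclass
class ModelSelectionReport:
    """Per-K fit scores and silhouettes, plus elbow and silhouette rankings."""

    table: pd.DataFrame  # columns: K, log_likelihood, nll, bic, silhouette
    elbow_k: int | None
    best_silhouette_k: int | None
    second_best_silhouette_k: int | None
    models: dict[int, ClusterModel] = field(default_factory=dict)


@dataclass
class ClusterReport:
    """Frame assignments, weights, per-condition populations, representatives."""

    labels: np.ndarray
    weights: np.ndarray
    populations: pd.DataFrame
    representatives: dict[int, int]
    model: ClusterModel


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def _log_gaussians(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log density of each point under each component, (n, K)."""
    n, m = x.shape
    out = np.empty((n, len(means)))
    for k in range(len(means)):
        factor = cho_factor(covs[k], lower=True)
        dev = x - means[k]
        maha = np.einsum("ij,ij->i", dev, cho_solve(factor, dev.T).T)
        logdet = 2.0 * np.log(np.diag(factor[0])).sum()
        out[:, k] = -0.5 * (m * np.log(2.0 * np.pi) + logdet + maha)
    return out


def _kmeanspp_means(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """D^2-weighted seeding: spreads initial means over separated basins."""
    n = len(x)
    means = [x[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min(((x[:, None, :] - np.asarray(means)[None]) ** 2).sum(-1), axis=1)
        total = d2.sum()
        if total <= 0:
            means.append(x[rng.integers(n)])
            continue
        means.append(x[rng.choice(n, p=d2 / total)])
    return np.asarray(means)


def _em_single(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    reg: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    n, m = x.shape
    means = _kmeanspp_means(x, k, rng)
    # Lloyd refinement + hard-assignment M-step: component covariances start
    # local, which keeps EM out of merged/degenerate optima when basins are
    # widely separated.
    for _ in range(10):
        nearest = ((x[:, None, :] - means[None]) ** 2).sum(-1).argmin(1)
        new_means = np.array(
            [x[nearest == j].mean(0) if np.any(nearest == j) else means[j] for j in range(k)]
        )
        if np.allclose(new_means, means):
            break
        means = new_means
    nearest = ((x[:, None, :] - means[None]) ** 2).sum(-1).argmin(1)
    covs = np.empty((k, m, m))
    weights = np.empty(k)
    base_cov = np.cov(x, rowvar=False, ddof=1).reshape(m, m)
    for j in range(k):
        members = x[nearest == j]
        weights[j] = max(len(members), 1) / n
        covs[j] = np.cov(members, rowvar=False, ddof=0).reshape(m, m) if len(members) > 1 else base_cov
        covs[j][np.diag_indices(m)] += reg
    weights /= weights.sum()

    ll_path: list[float] = []
    for _ in range(max_iter):
        log_joint = np.log(weights)[None, :] + _log_gaussians(x, means, covs)
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])

        nk = resp.sum(axis=0)
        if np.any(nk < 1e-12):  # component lost all mass: reseed its mean
            dead = np.flatnonzero(nk < 1e-12)
            means[dead] = x[rng.choice(n, size=len(dead), replace=False)]
            continue
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        for j in range(k):
            dev = x - means[j]
            covs[j] = (resp[:, j, None] * dev).T @ dev / nk[j]
            covs[j][np.diag_indices(m)] += reg

        if ll_path and ll - ll_path[-1] < tol:
            ll_path.append(ll)
            break
        ll_path.append(ll)
    return weights, means, covs, ll_path


def fit_gmm(
    reduced_space: ReducedSpace | np.ndarray,
    K: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    reg: float = 1e-6,
) -> ClusterModel:
    """Fit a K-component full-covariance Gaussian mixture by EM.

    The best of ``n_init`` random initializations (seeded ``seed + i``) by
    final log-likelihood is returned; convergence is declared when the total
    log-likelihood gain falls below ``tol`` or after ``max_iter`` iterations.
    ``reg`` is the diagonal covariance floor.
    """
    x = reduced_space.scores if isinstance(reduced_space, ReducedSpace) else np.asarray(reduced_space, dtype=float)
    x = np.atleast_2d(x)
    n = len(x)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of frames ({n})")
    if K > 1 and len(np.unique(x, axis=0)) < K:
        raise ValueError("fewer distinct frames than components")

    if K == 1:
        mean = x.mean(axis=0, keepdims=True)
        cov = np.atleast_2d(np.cov(x, rowvar=False, ddof=0))
        cov[np.diag_indices_from(cov)] += reg
        ll = float(_log_gaussians(x, mean, cov[None]).sum())
        return ClusterModel(
            weights=np.array([1.0]),
            means=mean,
            covariances=cov[None],
            log_likelihood=ll,
            seed=seed,
            ll_path=np.array([ll]),
        )

    best = None
    for i in range(n_init):
        rng = np.random.default_rng(seed + i)
        weights, means, covs, ll_path = _em_single(x, K, rng, max_iter, tol, reg)
        if best is None or ll_path[-1] > best[3][-1]:
            best = (weights, means, covs, ll_path)
    weights, means, covs, ll_path = best
    return ClusterModel(
        weights=weights,
        means=means,
        covariances=covs,
        log_likelihood=ll_path[-1],
        seed=seed,
        ll_path=np.asarray(ll_path),
    )


def _elbow_from_curve(ks: np.ndarray, score: np.ndarray) -> int | None:
    """Interior K maximizing drop(K-1 -> K) / drop(K -> K+1) on a decreasing curve.

    Drops beyond the corner are ~zero (or negative, once the BIC penalty
    dominates), so the ratio explodes exactly where improvement stops; a tiny
    positive floor on the denominator keeps it finite.  Ks whose incoming drop
    is not positive cannot be corners and are skipped.
    """
    if len(score) < 3:
        return None
    drops = -np.diff(score)  # drop[i] = score(k_i) - score(k_i+1)
    floor = 1e-9 * max(abs(score[0]), 1.0)
    best_k, best_ratio = None, -np.inf
    for i in range(1, len(score) - 1):
        incoming, outgoing = drops[i - 1], drops[i]
        if incoming <= 0:
            continue
        ratio = incoming / max(outgoing, floor)
        if ratio > best_ratio:
            best_k, best_ratio = int(ks[i]), ratio
    return best_k


def _bic(model: ClusterModel, n: int) -> float:
    m = model.m
    p = (model.K - 1) + model.K * m + model.K * m * (m + 1) // 2
    return -2.0 * model.log_likelihood + p * np.log(n)


def scan_k(
    reduced_space: ReducedSpace | np.ndarray,
    k_min: int = 2,
    k_max: int = 8,
    seed: int = 0,
    n_init: int = 10,
    elbow_metric: str = "bic",
) -> ModelSelectionReport:
    """Fit every K in [k_min, k_max] and report elbow and silhouette rankings.

    The elbow K is the interior K maximizing the ratio of the score drop into
    K over the drop beyond K (BIC curve by default; negative log-likelihood
    with ``elbow_metric='nll'``): the corner where adding a component stops
    paying.  This scale-invariant form localizes the corner even when the
    pre-elbow drops are uneven, where the raw second difference peaks at
    whichever early drop happens to be largest.  With fewer than three Ks no
    elbow is claimed.
    """
    x = reduced_space.scores if isinstance(reduced_space, ReducedSpace) else np.asarray(reduced_space, dtype=float)
    if k_min > k_max:
        raise ValueError("empty K range")
    if k_min < 2:
        raise ValueError("silhouette analysis requires k_min >= 2")
    if k_max > len(x):
        raise ValueError("k_max exceeds the number of frames")

    rows = []
    models: dict[int, ClusterModel] = {}
    for k in range(k_min, k_max + 1):
        model = fit_gmm(x, k, seed=seed, n_init=n_init)
        labels = assign(model, x)
        if len(np.unique(labels)) > 1:
            sil, _ = silhouette(x, labels, seed=seed)
        else:
            sil = np.nan
        models[k] = model
        rows.append(
            {
                "K": k,
                "log_likelihood": model.log_likelihood,
                "nll": -model.log_likelihood,
                "bic": _bic(model, len(x)),
                "silhouette": sil,
            }
        )
    table = pd.DataFrame(rows)

    if elbow_metric not in ("bic", "nll"):
        raise ValueError("elbow_metric must be 'bic' or 'nll'")
    score = table[elbow_metric].to_numpy()
    elbow_k = _elbow_from_curve(table["K"].to_numpy(), score)

    by_sil = table.dropna(subset=["silhouette"]).sort_values(
        "silhouette", ascending=False
    )
    best_k = int(by_sil["K"].iloc[0]) if len(by_sil) else None
    second_k = int(by_sil["K"].iloc[1]) if len(by_sil) > 1 else None
    return ModelSelectionReport(table, elbow_k, best_k, second_k, models)


# ---------------------------------------------------------------------------
# Silhouette
# ---------------------------------------------------------------------------

def silhouette(
    reduced_space: ReducedSpace | np.ndarray,
    labels: np.ndarray,
    max_n: int = 20000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean and per-sample silhouette scores (Euclidean distance).

    Singleton clusters score 0 by convention.  Above ``max_n`` frames the
    scores are computed on a seeded subsample (the pairwise-distance matrix
    would otherwise be quadratic in frames); the per-sample array then covers
    the subsample only.
    """
    x = reduced_space.scores if isinstance(reduced_space, ReducedSpace) else np.asarray(reduced_space, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(x):
        raise ValueError("labels length must match frames")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")

    if len(x) > max_n:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(x), size=max_n, replace=False))
        x, labels = x[keep], labels[keep]
        if len(np.unique(labels)) < 2:
            raise ValueError("subsample collapsed to one cluster; increase max_n")

    if len(np.unique(labels)) == len(labels):
        # every cluster a singleton: all scores 0 by the singleton convention
        return 0.0, np.zeros(len(labels))
    scores = _sk_silhouette_samples(x, labels, metric="euclidean")
    return float(scores.mean()), scores


# ---------------------------------------------------------------------------
# Assignment and summaries
# ---------------------------------------------------------------------------

def responsibilities(model: ClusterModel, reduced_space: ReducedSpace | np.ndarray) -> np.ndarray:
    """Posterior responsibilities, one row per frame (rows sum to 1)."""
    x = reduced_space.scores if isinstance(reduced_space, ReducedSpace) else np.asarray(reduced_space, dtype=float)
    x = np.atleast_2d(x)
    if x.shape[1] != model.m:
        raise ValueError("dimension mismatch between model and data")
    log_joint = np.log(model.weights)[None, :] + _log_gaussians(
        x, model.means, model.covariances
    )
    return np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])


def assign(model: ClusterModel, reduced_space: ReducedSpace | np.ndarray) -> np.ndarray:
    """Hard assignment to the maximal-responsibility component (ties: lowest)."""
    return np.argmax(responsibilities(model, reduced_space), axis=1)


def cluster_weights(labels: np.ndarray, K: int | None = None) -> np.ndarray:
    """Fraction of frames per cluster."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    K = int(labels.max()) + 1 if K is None else K
    return np.bincount(labels, minlength=K) / len(labels)


def populations_by_condition(labels: np.ndarray, frame_meta: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized condition x cluster population table."""
    labels = np.asarray(labels, dtype=int)
    if len(frame_meta) != len(labels):
        raise ValueError("frame_meta length must match labels")
    if len(labels) == 0:
        raise ValueError("no frames")
    conditions = frame_meta["condition"].to_numpy()
    if pd.isna(conditions).any() or (conditions == "").any():
        raise ValueError("every frame must carry a condition label")
    table = pd.crosstab(pd.Series(conditions, name="condition"), pd.Series(labels, name="cluster"))
    table = table.reindex(columns=range(labels.max() + 1), fill_value=0)
    return table.div(table.sum(axis=1), axis=0)


def representative_frames(
    model: ClusterModel,
    reduced_space: ReducedSpace | np.ndarray,
    labels: np.ndarray,
) -> dict[int, int]:
    """Per cluster, the assigned frame closest to the component mean.

    Ties break to the lowest frame index; an empty cluster raises.
    """
    x = reduced_space.scores if isinstance(reduced_space, ReducedSpace) else np.asarray(reduced_space, dtype=float)
    labels = np.asarray(labels, dtype=int)
    reps: dict[int, int] = {}
    for k in range(model.K):
        members = np.flatnonzero(labels == k)
        if len(members) == 0:
            raise ValueError(f"cluster {k} has no assigned frames")
        dists = np.linalg.norm(x[members] - model.means[k], axis=1)
        reps[k] = int(members[np.argmin(dists)])
    return reps


def match_labels(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Relabel predicted clusters to best match ground-truth states.

    Solves the assignment problem maximizing contingency overlap; returns the
    relabelled prediction (predicted clusters beyond the matched set keep
    fresh labels).
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    n_pred, n_true = pred.max() + 1, truth.max() + 1
    contingency = np.zeros((n_pred, n_true))
    np.add.at(contingency, (pred, truth), 1)
    rows, cols = linear_sum_assignment(-contingency)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    next_label = n_true
    out = np.empty_like(pred)
    for cluster in range(n_pred):
        if cluster not in mapping:
            mapping[cluster] = next_label
            next_label += 1
        out[pred == cluster] = mapping[cluster]
    return out
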