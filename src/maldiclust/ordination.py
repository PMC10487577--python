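"""Principal coordinates analysis (classical MDS) on distance matrices.

PCoA double-centres the matrix of squared dissimilarities
(B = -1/2 J D^2 J with J the centring matrix) and eigendecomposes B.
Coordinates are eigenvectors scaled by the square roots of their
(positive) eigenvalues, so Euclidean distances between rows reproduce the
centred inner products.  Bray-Curtis dissimilarities are generally
non-Euclidean, which surfaces as negative eigenvalues; those axes are
dropped and reported rather than corrected, keeping the retained
coordinates interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import adjusted_rand_score

from .matrices import DistanceMatrix

__all__ = ["PCoA", "PCoAResult", "pcoa", "kmedoids", "cluster_recovery_score"]


class PCoA(BaseEstimator):
    """Classical-scaling estimator.

    Parameters
    ----------
    n_axes : int or None
        Number of leading axes to keep; ``None`` keeps every axis with a
        strictly positive eigenvalue.

    Attributes (after :meth:`fit`)
    ------------------------------
    eigenvalues_ : all eigenvalues, descending (negatives included).
    coordinates_ : (n_samples, n_retained) embedding.
    proportion_explained_ : share of each retained axis among the positive
        eigenvalues (sums to 1 over retained axes when all are kept).
    n_negative_eigenvalues_, most_negative_eigenvalue_ : the non-Euclidean
        remainder that was dropped.
    """

    def __init__(self, n_axes: int | None = None):
        self.n_axes = n_axes

    def fit(self, D: np.ndarray, y=None) -> "PCoA":
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(np.isnan(D)):
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        n = D.shape[0]
        if n < 2:
            raise ValueError("need at least two samples")

        A = -0.5 * D**2
        J = np.eye(n) - np.ones((n, n)) / n
        B = J @ A @ J
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]

        tol = max(abs(eigval[0]), 1.0) * 1e-10 if eigval.size else 0.0
        positive = eigval > tol
        coords = eigvec[:, positive] * np.sqrt(eigval[positive])
        # Deterministic axis orientation: largest-|loading| entry positive.
        for k in range(coords.shape[1]):
            pivot = np.argmax(np.abs(coords[:, k]))
            if coords[pivot, k] < 0:
                coords[:, k] = -coords[:, k]
        if self.n_axes is not None:
            coords = coords[:, : self.n_axes]

        negative = eigval < -tol
        self.eigenvalues_ = eigval
        self.coordinates_ = coords
        pos_sum = eigval[positive].sum()
        self.proportion_explained_ = (
            eigval[positive][: coords.shape[1]] / pos_sum if pos_sum > 0 else np.zeros(0)
        )
        self.n_negative_eigenvalues_ = int(negative.sum())
        self.most_negative_eigenvalue_ = float(eigval[negative].min()) if negative.any() else 0.0
        return self

    def fit_transform(self, D: np.ndarray, y=None) -> np.ndarray:
        return self.fit(D).coordinates_


@dataclass
class PCoAResult:
    labels: list[str]
    eigenvalues: np.ndarray
    coordinates: pd.DataFrame  # labels x axes
    proportion_explained: np.ndarray
    negative_eigenvalue_report: tuple[int, float]

    def to_csv(self, path) -> None:
        self.coordinates.to_csv(path)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    est = PCoA(n_axes=n_axes).fit(d.values)
    axes = [f"PCo{k + 1}" for k in range(est.coordinates_.shape[1])]
    return PCoAResult(
        labels=list(d.labels),
        eigenvalues=est.eigenvalues_,
        coordinates=pd.DataFrame(est.coordinates_, index=d.labels, columns=axes),
        proportion_explained=est.proportion_explained_,
        negative_eigenvalue_report=(
            est.n_negative_eigenvalues_,
            est.most_negative_eigenvalue_,
        ),
    )


def kmedoids(
    X: np.ndarray, k: int, seed: int, n_init: int = 10, max_iter: int = 200
) -> np.ndarray:
    """Seeded PAM-style k-medoids on Euclidean distances.

    Alternates assignment and medoid update from ``n_init`` random starts
    and returns the labelling with the lowest total within-cluster
    distance.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    rng = np.random.default_rng(seed)
    best_cost, best_labels = np.inf, None
    for _ in range(n_init):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(max_iter):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        cost = D[np.arange(n), medoids[labels]].sum()
        if cost < best_cost - 1e-12:
            best_cost, best_labels = cost, labels
    return best_labels


def cluster_recovery_score(
    result: PCoAResult,
    true_labels: list,
    k: int,
    n_axes: int = 2,
    seed: int = 0,
) -> float:
    """Adjusted Rand index between seeded k-medoids clusters on the leading
    ordination axes and the true labels (quantifies visual separation)."""
    coords = result.coordinates.to_numpy()
    if n_axes > coords.shape[1]:
        raise ValueError(f"only {coords.shape[1]} axes available, asked for {n_axes}")
    if len(true_labels) != coords.shape[0]:
        raise ValueError("one true label per sample required")
    pred = kmedoids(coords[:, :n_axes], k=k, seed=seed)
    return float(adjusted_rand_score(true_labels, pred))
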