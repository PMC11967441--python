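"""Fuzzy c-means clustering of stage-expression trajectories and the
data-driven contiguous two-phase partition of developmental stages.

Gene trajectories (per-line stage means, z-scored per gene) are grouped into
soft clusters by classic fuzzy c-means with fuzzifier m: memberships
u_ik in [0,1] with rows summing to 1, centroids v_k = sum u^m x / sum u^m,
and u_ik = 1 / sum_j (d_ik/d_ij)^(2/(m-1)).  The phase split scores every
contiguous cut of the ordered stages by the ratio of between-phase to
within-phase mean pairwise distance of stage vectors, and picks the maximum
(ties toward the earlier cut) — making explicit the visual judgement that
early and late ear development form two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .expression import zscore_rows

__all__ = ["standardize_profiles", "FuzzyCMeans", "fuzzy_cmeans", "score_phase_splits", "PhasePartition"]


def standardize_profiles(stage_means: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scored stage profiles; constant rows are masked, not NaN.

    Returns (profiles restricted to non-constant genes, boolean mask of the
    rows that were dropped).
    """
    if stage_means.shape[1] < 2:
        raise ValueError("need at least two stages to form a profile")
    z, mask = zscore_rows(stage_means)
    return z.loc[~mask], mask


def _memberships(dist2: np.ndarray, m: float) -> np.ndarray:
    """FCM membership update from squared distances (genes x clusters)."""
    exponent = 1.0 / (m - 1.0)
    zero = dist2 <= 1e-300
    u = np.zeros_like(dist2)
    any_zero = zero.any(axis=1)
    # coincident point and centroid: full membership there (split over ties)
    if any_zero.any():
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    rest = ~any_zero
    if rest.any():
        inv = (1.0 / dist2[rest]) ** exponent
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means with multiple random restarts.

    Parameters
    ----------
    n_clusters : number of soft clusters (the temporal archetypes; default 4).
    m : fuzzifier > 1; memberships harden as m -> 1.
    tol : convergence threshold on max |delta u|.
    max_iter : iteration cap per restart.
    n_init : random restarts; the solution with the lowest objective is kept.
    random_state : integer seed; the model is bit-reproducible given it.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (n_clusters, n_stages) centroids.
    membership_ : (n_genes, n_clusters) soft memberships, rows sum to 1.
    labels_ : hard assignment (argmax membership).
    objective_trace_ : objective J = sum u^m d^2 per iteration (best restart);
        non-increasing.
    n_iter_ : iterations used by the best restart.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        m: float = 2.0,
        tol: float = 1e-6,
        max_iter: int = 1000,
        n_init: int = 10,
        random_state: int | None = 0,
    ) -> None:
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def _single_run(self, X: np.ndarray, rng: np.random.Generator):
        n, _ = X.shape
        c, m = self.n_clusters, self.m
        u = rng.dirichlet(np.ones(c), size=n)
        trace: list[float] = []
        for iteration in range(1, self.max_iter + 1):
            um = u**m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            diff = X[:, None, :] - centers[None, :, :]
            dist2 = np.einsum("ikj,ikj->ik", diff, diff)
            new_u = _memberships(dist2, m)
            trace.append(float((new_u**m * dist2).sum()))
            delta = np.abs(new_u - u).max()
            u = new_u
            if delta < self.tol:
                break
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        return u, centers, trace, iteration

    def fit(self, X, y=None) -> "FuzzyCMeans":
        X = pd.DataFrame(X)
        arr = X.to_numpy(dtype=float)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must exceed 1")
        if np.unique(arr, axis=0).shape[0] < self.n_clusters:
            raise ValueError("need at least n_clusters distinct profiles")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_init)
        best = None
        for ss in seeds:
            result = self._single_run(arr, np.random.default_rng(ss))
            if best is None or result[2][-1] < best[2][-1]:
                best = result
        u, centers, trace, n_iter = best
        self.membership_ = pd.DataFrame(
            u, index=X.index, columns=[f"cluster{k + 1}" for k in range(self.n_clusters)]
        )
        self.cluster_centers_ = centers
        self.labels_ = u.argmax(axis=1)
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = n_iter
        self.n_features_in_ = arr.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Hard cluster of new profiles against the fitted centroids."""
        check_is_fitted(self, "cluster_centers_")
        arr = pd.DataFrame(X).to_numpy(dtype=float)
        diff = arr[:, None, :] - self.cluster_centers_[None, :, :]
        dist2 = np.einsum("ikj,ikj->ik", diff, diff)
        return _memberships(dist2, self.m).argmax(axis=1)


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 4,
    m: float = 2.0,
    seed: int | None = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_init: int = 10,
) -> FuzzyCMeans:
    """Functional wrapper over :class:`FuzzyCMeans` (genes x stages in)."""
    model = FuzzyCMeans(
        n_clusters=c, m=m, tol=tol, max_iter=max_iter, n_init=n_init, random_state=seed
    )
    return model.fit(profiles)


@dataclass
class PhasePartition:
    """A contiguous split of the ordered stages into Phase I and Phase II."""

    split_index: int                    # stages[:split_index] form Phase I
    phase1: list[str]
    phase2: list[str]
    scores: pd.DataFrame                # per-candidate-split score table


def score_phase_splits(stage_vectors: pd.DataFrame) -> PhasePartition:
    """Choose the contiguous two-phase split of ordered stages.

    ``stage_vectors`` is stages x features (rows ordered by development; the
    features are typically the per-gene z-scored or log expression values at
    that stage).  Each split k is scored as mean between-phase pairwise
    Euclidean distance over pooled mean within-phase distance; the maximising
    k wins, ties going to the earlier split.  Splits with no within-phase
    pair (T = 2) score by between-distance alone.
    """
    stages = list(stage_vectors.index)
    T = len(stages)
    if T < 2:
        raise ValueError("need at least two stages to split")
    arr = stage_vectors.to_numpy(dtype=float)
    d = np.sqrt(((arr[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2))
    rows = []
    for k in range(1, T):
        left = np.arange(k)
        right = np.arange(k, T)
        between = d[np.ix_(left, right)].mean()
        within_pairs = [
            d[i, j]
            for part in (left, right)
            for a, i in enumerate(part)
            for j in part[a + 1:]
        ]
        within = float(np.mean(within_pairs)) if within_pairs else 0.0
        score = between / within if within > 0 else np.inf
        rows.append((k, "+".join(stages[:k]), "+".join(stages[k:]), between, within, score))
    table = pd.DataFrame(
        rows, columns=["split_index", "phase1", "phase2", "between", "within", "score"]
    )
    best_k = int(table.loc[table["score"].idxmax(), "split_index"])
    return PhasePartition(
        split_index=best_k,
        phase1=stages[:best_k],
        phase2=stages[best_k:],
        scores=table,
    )
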