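"""PQk-Means: k-means-style clustering operating directly on PQ codes.

The algorithm never decodes. Assignment uses the symmetric distance (SD)
computed from the per-subspace codeword-distance lookup tables; the centroid
update works subspace by subspace: for each cluster and subspace the new
centroid index is the codeword minimizing the summed squared table distance
to the members' indices in that subspace, computed as a histogram of member
indices multiplied against the L×L table. Because the squared-SD objective is
separable over subspaces, this per-subspace argmin is the exact minimizer and
the Lloyd objective is non-increasing.

Empty clusters are left in place during fitting (not re-seeded) and dropped
afterwards by :func:`compact`, mirroring the populated/requested distinction
one sees at scale (e.g. 92,464 populated of 100,000 requested clusters).
All tie-breaks — nearest centroid, codeword vote, representative pick —
resolve to the lowest index so every stage is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .pq import _canonical_order

__all__ = ["PQKMeans", "Assignment", "compact", "select_representatives", "update_centroids"]


@dataclass(frozen=True)
class Assignment:
    """Cluster label and SD-to-centroid for each molecule."""

    labels: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        if self.labels.shape[0] != self.distances.shape[0]:
            raise ValueError("labels and distances must have equal length")


def _sq_sd_to_centroids(codes: np.ndarray, centroids: np.ndarray, tables: np.ndarray) -> np.ndarray:
    """Squared SD from each code (rows) to each centroid code (columns)."""
    out = np.zeros((codes.shape[0], centroids.shape[0]), dtype=np.float64)
    for j in range(tables.shape[0]):
        out += tables[j][codes[:, j][:, None], centroids[:, j][None, :]]
    return out


def update_centroids(
    codes: np.ndarray,
    labels: np.ndarray,
    tables: np.ndarray,
    n_clusters: int,
    current: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-subspace codeword-vote centroid update.

    For cluster c and subspace j the new index is
    ``argmin_w Σ_i∈c tables[j][codes[i, j], w]``, evaluated for all L
    codewords at once as ``hist_cj @ tables[j]`` where ``hist_cj`` is the
    histogram of member indices. Empty clusters keep their current code and
    are flagged False in the returned mask.
    """
    m, L, _ = tables.shape
    new = current.copy()
    populated = np.zeros(n_clusters, dtype=bool)
    sizes = np.bincount(labels, minlength=n_clusters)
    for j in range(m):
        # hist[c, w] = number of members of cluster c using codeword w in subspace j
        hist = np.zeros((n_clusters, L), dtype=np.float64)
        np.add.at(hist, (labels, codes[:, j]), 1.0)
        cost = hist @ tables[j]  # (k, L) summed squared distance per candidate
        winners = np.argmin(cost, axis=1).astype(np.uint8)
        mask = sizes > 0
        new[mask, j] = winners[mask]
    populated[:] = sizes > 0
    return new, populated


class PQKMeans(BaseEstimator, ClusterMixin):
    """Cluster PQ codes with Lloyd iterations over SD lookup tables.

    Parameters
    ----------
    n_clusters : int
        Requested number of clusters ``k``; the populated count after
        assignment may be smaller.
    tables : ndarray of shape (m, L, L)
        Squared codeword-distance tables from the quantizer that produced
        the codes (``ProductQuantizer.sd_tables_``).
    max_iter : int, default=20
        Lloyd iteration cap; iteration stops early when labels stabilize.
    batch_size : int, default=100_000
        Batch size for streaming assignment in :meth:`predict`.
    random_state : int or None
        Seed for the k-means++ initialization in code space.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k, m), uint8
        Centroid PQ codes.
    labels_ : ndarray
        Training-set labels.
    inertia_ : float
        Final objective (sum of squared SD to assigned centroid).
    objective_history_ : list of float
        Objective after each assignment step; non-increasing.
    populated_ : ndarray of bool, shape (k,)
        Whether each centroid has at least one training member.
    """

    def __init__(
        self,
        n_clusters: int,
        tables: np.ndarray | None = None,
        max_iter: int = 20,
        batch_size: int = 100_000,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.tables = tables
        self.max_iter = max_iter
        self.batch_size = batch_size
        self.random_state = random_state

    def _check_tables(self) -> np.ndarray:
        if self.tables is None:
            raise ValueError("PQKMeans requires the quantizer's SD tables (tables=...)")
        return np.asarray(self.tables, dtype=np.float64)

    def _init_centroids(self, codes: np.ndarray, tables: np.ndarray) -> np.ndarray:
        """Greedy k-means++ in code space using squared SD.

        At each step several candidates are drawn from the d² distribution
        and the one yielding the lowest resulting potential is kept — the
        same greedy variant standard k-means++ implementations use, which
        markedly lowers the chance of seeding two centroids in one natural
        cluster. Fully deterministic for a fixed seed.
        """
        rng = np.random.default_rng(self.random_state)
        n = codes.shape[0]
        k = self.n_clusters
        n_candidates = 2 + int(np.log(max(k, 2)))
        centroids = np.empty((k, codes.shape[1]), dtype=np.uint8)
        first = int(rng.integers(n))
        centroids[0] = codes[first]
        d2 = _sq_sd_to_centroids(codes, centroids[:1], tables)[:, 0]
        for c in range(1, k):
            total = d2.sum()
            if total <= 0:
                # all mass collapsed on existing centroids: spread uniformly
                centroids[c] = codes[int(rng.integers(n))]
                continue
            cand_idx = rng.choice(n, size=n_candidates, p=d2 / total)
            cand_d2 = _sq_sd_to_centroids(codes, codes[cand_idx], tables)
            potentials = np.minimum(d2[:, None], cand_d2).sum(axis=0)
            best = cand_idx[int(np.argmin(potentials))]
            centroids[c] = codes[best]
            np.minimum(d2, _sq_sd_to_centroids(codes, codes[best : best + 1], tables)[:, 0], out=d2)
        return centroids

    def fit(self, X, y=None):
        codes = np.asarray(X, dtype=np.uint8)
        tables = self._check_tables()
        n = codes.shape[0]
        if n < self.n_clusters:
            raise ValueError(f"n={n} codes but n_clusters={self.n_clusters}; need n >= k")
        if codes.shape[1] != tables.shape[0]:
            raise ValueError("codes do not match the tables' subspace count (codebook mismatch)")
        # canonical training order: the fitted model is a pure function of
        # the code multiset, invariant to input permutation
        train = _canonical_order(codes)
        centroids = self._init_centroids(train, tables)
        labels = np.full(n, -1, dtype=np.int64)
        history: list[float] = []
        populated = np.ones(self.n_clusters, dtype=bool)
        for _ in range(self.max_iter):
            d2 = _sq_sd_to_centroids(train, centroids, tables)
            new_labels = np.argmin(d2, axis=1)
            history.append(float(d2[np.arange(n), new_labels].sum()))
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centroids, populated = update_centroids(
                train, labels, tables, self.n_clusters, centroids
            )
        self.cluster_centers_ = centroids
        self.objective_history_ = history
        self.inertia_ = history[-1]
        self.n_iter_ = len(history)
        self.populated_ = populated
        # labels for the caller's original ordering
        assignment = self.predict(codes)
        self.labels_ = assignment.labels
        return self

    def predict(self, X, batch_size: int | None = None) -> Assignment:
        """Assign codes to their nearest centroid by SD, in streaming batches.

        Ties break to the lowest centroid index; any batch partition yields
        bit-identical results.
        """
        check_is_fitted(self, "cluster_centers_")
        codes = np.asarray(X, dtype=np.uint8)
        tables = self._check_tables()
        if codes.shape[1] != tables.shape[0]:
            raise ValueError("codes do not match the tables' subspace count (codebook mismatch)")
        bs = batch_size or self.batch_size
        labels = np.empty(codes.shape[0], dtype=np.int64)
        dists = np.empty(codes.shape[0], dtype=np.float64)
        for start in range(0, codes.shape[0], bs):
            batch = codes[start : start + bs]
            d2 = _sq_sd_to_centroids(batch, self.cluster_centers_, tables)
            lab = np.argmin(d2, axis=1)
            labels[start : start + bs] = lab
            dists[start : start + bs] = np.sqrt(
                np.maximum(d2[np.arange(batch.shape[0]), lab], 0.0)
            )
        return Assignment(labels=labels, distances=dists)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def compact(model: PQKMeans, assignment: Assignment) -> tuple[PQKMeans, Assignment, np.ndarray]:
    """Drop unpopulated centroids and re-index clusters densely.

    Returns the compacted model, the remapped assignment, and the mapping
    table ``old_id -> new_id`` (−1 for dropped clusters). Molecule count is
    conserved: the remap is a bijection on populated labels.
    """
    check_is_fitted(model, "cluster_centers_")
    k = model.n_clusters
    counts = np.bincount(assignment.labels, minlength=k)
    keep = counts > 0
    mapping = np.full(k, -1, dtype=np.int64)
    mapping[keep] = np.arange(int(keep.sum()))
    new_model = PQKMeans(
        n_clusters=int(keep.sum()),
        tables=model.tables,
        max_iter=model.max_iter,
        batch_size=model.batch_size,
        random_state=model.random_state,
    )
    new_model.cluster_centers_ = model.cluster_centers_[keep]
    new_model.populated_ = np.ones(int(keep.sum()), dtype=bool)
    new_assignment = Assignment(
        labels=mapping[assignment.labels], distances=assignment.distances.copy()
    )
    return new_model, new_assignment, mapping


def select_representatives(
    codes: np.ndarray,
    assignment: Assignment,
    model: PQKMeans,
    tables: np.ndarray,
    ids: np.ndarray | None = None,
) -> "pd.DataFrame":
    """Pick, per populated cluster, the member with minimal SD to the centroid.

    Ties resolve to the lowest molecule id. Returns a DataFrame indexed by
    cluster id with columns ``molecule_id`` and ``sd``.
    """
    import pandas as pd

    check_is_fitted(model, "cluster_centers_")
    codes = np.asarray(codes, dtype=np.uint8)
    labels = assignment.labels
    if ids is None:
        ids = np.arange(codes.shape[0], dtype=np.int64)
    ids = np.asarray(ids, dtype=np.int64)
    d2 = np.zeros(codes.shape[0], dtype=np.float64)
    cent = model.cluster_centers_[labels]
    for j in range(tables.shape[0]):
        d2 += tables[j][codes[:, j], cent[:, j]]
    sd = np.sqrt(np.maximum(d2, 0.0))
    # sort by (label, sd, id): first row per label is the representative
    order = np.lexsort((ids, sd, labels))
    lab_sorted = labels[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = lab_sorted[1:] != lab_sorted[:-1]
    sel = order[first]
    return pd.DataFrame(
        {"molecule_id": ids[sel], "sd": sd[sel]},
        index=pd.Index(labels[sel], name="cluster_id"),
    ).sort_index()
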