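"""Cluster-quality diagnostics.

Four complementary views of a clustering's quality:

* agreement between the symmetric distance (SD) on PQ codes and the true
  Euclidean distance on MQN vectors, summarized by a Pearson correlation
  against a fixed reference molecule;
* within- vs between-cluster distance summaries from a small fixed sample
  design (``n_clusters`` random clusters × ``n_per_cluster`` random members,
  exhaustive pairs within the sample);
* a block-ordered pairwise-distance heatmap matrix over the same kind of
  sample, where diagonal blocks are within-cluster distances;
* per-cluster dispersion of the physicochemical panel (CV = σ/μ, IQR,
  range), reported as 5th/median/95th percentiles across clusters. Clusters
  whose mean is zero for a descriptor are excluded from that descriptor's
  CV, since dividing by a vanishing mean inflates CV without reflecting
  real spread.

Every summary is a pure function of (data, assignment, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .pq import ProductQuantizer, sd_matrix
from .pqkmeans import Assignment

__all__ = [
    "DistanceSampleSummary",
    "sd_vs_euclidean",
    "sample_cluster_distances",
    "distance_heatmap",
    "dispersion_stats",
    "cluster_size_distribution",
]

METRICS = ("euclidean_mqn", "manhattan_mqn", "sd_pq")


@dataclass(frozen=True)
class DistanceSampleSummary:
    metric: str
    within_mean: float
    within_sd: float
    between_mean: float
    between_sd: float
    n_clusters: int
    n_per_cluster: int
    seed: int
    sampled_clusters: tuple[int, ...] = field(default=(), repr=False)


def sd_vs_euclidean(
    X: np.ndarray, quantizer: ProductQuantizer, reference: np.ndarray
) -> pd.DataFrame:
    """Paired (Euclidean, SD) distances from every sample vector to a reference.

    Returns a DataFrame with columns ``euclidean`` and ``sd`` and attrs
    ``pearson_r`` and ``slope`` (least-squares through the origin). For
    codeword-exact inputs the two columns agree exactly.
    """
    X = np.asarray(X, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64).reshape(1, -1)
    euclid = np.linalg.norm(X - reference, axis=1)
    codes = quantizer.transform(X)
    ref_code = quantizer.transform(reference)
    sd = sd_matrix(codes, ref_code, quantizer.sd_tables_)[:, 0]
    out = pd.DataFrame({"euclidean": euclid, "sd": sd})
    if len(out) > 1 and euclid.std() > 0 and sd.std() > 0:
        out.attrs["pearson_r"] = float(pearsonr(euclid, sd)[0])
    else:
        out.attrs["pearson_r"] = float("nan")
    denom = float(euclid @ euclid)
    out.attrs["slope"] = float(euclid @ sd) / denom if denom > 0 else float("nan")
    return out


def _pairwise(block_a: dict, block_b: dict | None, metric: str, quantizer) -> np.ndarray:
    if metric == "euclidean_mqn":
        return cdist(block_a["X"], (block_b or block_a)["X"], metric="euclidean")
    if metric == "manhattan_mqn":
        return cdist(block_a["X"], (block_b or block_a)["X"], metric="cityblock")
    if metric == "sd_pq":
        return sd_matrix(block_a["codes"], (block_b or block_a)["codes"], quantizer.sd_tables_)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _sample_blocks(
    X: np.ndarray,
    codes: np.ndarray | None,
    assignment: Assignment,
    n_clusters: int,
    n_per_cluster: int,
    seed: int,
) -> tuple[list[dict], np.ndarray]:
    labels = assignment.labels
    counts = np.bincount(labels)
    eligible = np.flatnonzero(counts >= n_per_cluster)
    if len(eligible) < n_clusters:
        raise ValueError(
            f"need {n_clusters} clusters with >= {n_per_cluster} members, "
            f"found {len(eligible)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_clusters, replace=False)
    blocks = []
    for c in chosen:
        members = np.flatnonzero(labels == c)
        pick = rng.choice(members, size=n_per_cluster, replace=False)
        blocks.append(
            {
                "cluster": int(c),
                "X": X[pick],
                "codes": None if codes is None else codes[pick],
                "ids": pick,
            }
        )
    return blocks, chosen


def sample_cluster_distances(
    X: np.ndarray,
    assignment: Assignment,
    n_clusters: int = 100,
    n_per_cluster: int = 10,
    metric: str = "euclidean_mqn",
    seed: int = 0,
    codes: np.ndarray | None = None,
    quantizer: ProductQuantizer | None = None,
) -> DistanceSampleSummary:
    """Within- vs between-cluster distance summary on a fixed sample design.

    Samples ``n_clusters`` clusters with at least ``n_per_cluster`` members,
    then ``n_per_cluster`` members from each. Within-cluster pairs are all
    pairs inside a sampled cluster; between-cluster pairs all pairs across
    different sampled clusters — both exhaustive over the sample.
    """
    if metric == "sd_pq" and (codes is None or quantizer is None):
        raise ValueError("metric 'sd_pq' requires codes and quantizer")
    blocks, chosen = _sample_blocks(X, codes, assignment, n_clusters, n_per_cluster, seed)
    within: list[np.ndarray] = []
    between: list[np.ndarray] = []
    for i, bi in enumerate(blocks):
        d = _pairwise(bi, None, metric, quantizer)
        within.append(d[np.triu_indices_from(d, k=1)])
        for bj in blocks[i + 1 :]:
            between.append(_pairwise(bi, bj, metric, quantizer).ravel())
    w = np.concatenate(within)
    b = np.concatenate(between) if between else np.array([])
    return DistanceSampleSummary(
        metric=metric,
        within_mean=float(w.mean()),
        within_sd=float(w.std()),
        between_mean=float(b.mean()) if b.size else float("nan"),
        between_sd=float(b.std()) if b.size else float("nan"),
        n_clusters=n_clusters,
        n_per_cluster=n_per_cluster,
        seed=seed,
        sampled_clusters=tuple(int(c) for c in chosen),
    )


def distance_heatmap(
    X: np.ndarray,
    assignment: Assignment,
    n_clusters: int = 25,
    n_per_cluster: int = 10,
    metric: str = "euclidean_mqn",
    seed: int = 0,
    codes: np.ndarray | None = None,
    quantizer: ProductQuantizer | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-ordered pairwise-distance matrix over a cluster sample.

    Returns ``(matrix, block_labels)`` where the matrix is
    ``(n_clusters·n_per_cluster)²`` symmetric with zero diagonal and
    ``block_labels`` gives the sampled cluster id of each row/column.
    Diagonal blocks are within-cluster distances.
    """
    if metric == "sd_pq" and (codes is None or quantizer is None):
        raise ValueError("metric 'sd_pq' requires codes and quantizer")
    blocks, _ = _sample_blocks(X, codes, assignment, n_clusters, n_per_cluster, seed)
    stacked = {
        "X": np.vstack([b["X"] for b in blocks]),
        "codes": None if codes is None else np.vstack([b["codes"] for b in blocks]),
    }
    mat = _pairwise(stacked, None, metric, quantizer)
    np.fill_diagonal(mat, 0.0)
    block_labels = np.repeat([b["cluster"] for b in blocks], n_per_cluster)
    return mat, block_labels


def dispersion_stats(
    panels: pd.DataFrame,
    assignment: Assignment,
    min_cluster_size: int = 2,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> pd.DataFrame:
    """Per-descriptor dispersion percentiles across clusters.

    For each cluster with at least ``min_cluster_size`` members and each
    panel descriptor, computes the coefficient of variation (population
    σ/μ), the interquartile range, and the range (max − min, untrimmed).
    Reports the 5th/median/95th percentiles of each statistic across
    clusters (linear interpolation between order statistics). Clusters with
    μ = 0 for a descriptor are excluded from that descriptor's CV; the
    excluded count is reported in the ``cv_excluded`` column.
    """
    labels = assignment.labels
    if len(panels) != len(labels):
        raise ValueError("panels and assignment must cover the same molecules")
    rows = []
    values = panels.to_numpy(dtype=np.float64)
    counts = np.bincount(labels)
    keep_clusters = np.flatnonzero(counts >= min_cluster_size)
    for d, name in enumerate(panels.columns):
        cvs, iqrs, ranges = [], [], []
        excluded = 0
        for c in keep_clusters:
            v = values[labels == c, d]
            mu = v.mean()
            if mu == 0:
                excluded += 1
            else:
                cvs.append(v.std() / mu)
            q75, q25 = np.percentile(v, [75, 25])
            iqrs.append(q75 - q25)
            ranges.append(v.max() - v.min())
        row = {"descriptor": name, "cv_excluded": excluded}
        for stat, arr in (("cv", cvs), ("iqr", iqrs), ("range", ranges)):
            pcts = (
                np.percentile(arr, percentiles) if len(arr) else np.full(3, np.nan)
            )
            for p, val in zip(("p5", "median", "p95"), pcts):
                row[f"{stat}_{p}"] = float(val)
        rows.append(row)
    return pd.DataFrame(rows).set_index("descriptor")


def cluster_size_distribution(assignment: Assignment) -> tuple[np.ndarray, dict]:
    """Cluster sizes sorted descending, plus summary statistics.

    The summary holds mean, sd, min, max and the central 95% interval
    (2.5th–97.5th percentile) of the size distribution; sizes sum to the
    number of molecules.
    """
    counts = np.bincount(assignment.labels)
    counts = counts[counts > 0]
    sizes = np.sort(counts)[::-1]
    lo, hi = np.percentile(sizes, [2.5, 97.5])
    summary = {
        "n_clusters": int(sizes.size),
        "n_molecules": int(sizes.sum()),
        "mean": float(sizes.mean()),
        "sd": float(sizes.std()),
        "min": int(sizes.min()),
        "max": int(sizes.max()),
        "central95": (float(lo), float(hi)),
    }
    return sizes, summary
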