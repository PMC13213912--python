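"""Tree-maps: kNN graph → minimum spanning tree → deterministic 2D layout.

A tree-map summarizes a set of molecules by keeping only the strongest
similarity relations: a k-nearest-neighbor graph is reduced to its minimum
spanning tree, and the tree is drawn in the plane. The atlas is two-level:

* the **primary** map covers one representative per populated cluster,
  with Euclidean distance on MQN vectors as the metric — whole-molecule
  composition trends;
* a **secondary** map per cluster covers that cluster's members, with
  Tanimoto distance on ECFP4 fingerprints — substructural relations at a
  finer grain.

Each primary node carries its cluster id and links to the corresponding
secondary map; together they form a :class:`NestedAtlas` in which every
input molecule appears in exactly one secondary map exactly once.

Only the tree topology and determinism are contractual; coordinates come
from a seeded radial tree embedding and are presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree as _scipy_mst
from scipy.spatial.distance import cdist

__all__ = [
    "NeighborGraph",
    "SpanningTree",
    "TreeMapArtifact",
    "NestedAtlas",
    "knn_graph",
    "minimum_spanning_tree",
    "layout_tree",
    "build_primary",
    "build_secondary",
    "assemble_atlas",
    "save_atlas",
    "load_atlas",
]


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetrized kNN graph: edges (i, j, distance) with i < j."""

    n: int
    edges: np.ndarray  # (E, 3) float: i, j, weight
    k: int
    metric: str
    items: np.ndarray = field(repr=False, default=None)  # kept for exact component joins


@dataclass(frozen=True)
class SpanningTree:
    n: int
    edges: np.ndarray  # (n-1, 3) float: i, j, weight

    @property
    def total_weight(self) -> float:
        return float(self.edges[:, 2].sum()) if self.edges.size else 0.0


@dataclass
class TreeMapArtifact:
    tree: SpanningTree
    coords: np.ndarray  # (n, 2)
    nodes: pd.DataFrame  # metadata; one row per node
    level: str  # "primary" | "secondary"
    cluster_id: int | None = None


@dataclass
class NestedAtlas:
    primary: TreeMapArtifact
    secondaries: dict[int, TreeMapArtifact]
    manifest: dict


def _tanimoto_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return 1.0 - sim


def _pair_distances(items: np.ndarray, rows: np.ndarray, cols: np.ndarray, metric: str):
    if metric == "euclidean":
        return cdist(items[rows], items[cols], metric="euclidean")
    if metric == "tanimoto":
        return _tanimoto_distance_matrix(items[rows], items[cols])
    raise ValueError(f"unknown metric {metric!r}; expected 'euclidean' or 'tanimoto'")


def _knn_exact(
    items: np.ndarray, k: int, metric: str, chunk: int = 2048
) -> tuple[np.ndarray, np.ndarray]:
    """Chunked all-pairs scan; ties break to the lowest index (stable sort)."""
    n = items.shape[0]
    idx = np.empty((n, k), dtype=np.int64)
    dist = np.empty((n, k), dtype=np.float64)
    rows_all = np.arange(n)
    for start in range(0, n, chunk):
        rows = rows_all[start : start + chunk]
        D = _pair_distances(items, rows, rows_all, metric)
        D[np.arange(len(rows)), rows] = np.inf
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        idx[rows] = order
        dist[rows] = np.take_along_axis(D, order, axis=1)
    return idx, dist


def _knn_approximate(
    items: np.ndarray, k: int, metric: str, seed: int = 0, n_trees: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Projection-forest approximate kNN with exact re-ranking.

    Each tree sorts the points along a random direction; candidates are the
    points falling within a window around each query in that ordering. The
    union of candidates over trees is re-ranked with the exact metric.
    """
    X = np.asarray(items, dtype=np.float64)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    window = max(2 * k, 8)
    candidates: list[set[int]] = [set() for _ in range(n)]
    for _ in range(n_trees):
        direction = rng.normal(size=X.shape[1])
        order = np.argsort(X @ direction, kind="stable")
        pos = np.empty(n, dtype=np.int64)
        pos[order] = np.arange(n)
        for i in range(n):
            lo = max(0, pos[i] - window)
            hi = min(n, pos[i] + window + 1)
            candidates[i].update(int(j) for j in order[lo:hi] if j != i)
    idx = np.empty((n, k), dtype=np.int64)
    dist = np.empty((n, k), dtype=np.float64)
    for i in range(n):
        cand = np.fromiter(candidates[i], dtype=np.int64)
        cand.sort()
        d = _pair_distances(items, np.array([i]), cand, metric)[0]
        top = np.argsort(d, kind="stable")[:k]
        idx[i] = cand[top]
        dist[i] = d[top]
    return idx, dist


def knn_graph(
    items: np.ndarray, k: int = 10, metric: str = "euclidean", mode: str = "exact", seed: int = 0
) -> NeighborGraph:
    """Symmetrized k-nearest-neighbor graph.

    An edge (i, j) is kept if either endpoint lists the other among its k
    nearest; weights are metric distances. ``mode='exact'`` is the reference
    contract; ``mode='approximate'`` trades exactness for speed and is
    validated by neighbor recall against exact search.
    """
    items = np.asarray(items)
    n = items.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items for a kNN graph")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    if mode == "exact":
        idx, dist = _knn_exact(items, k, metric)
    elif mode == "approximate":
        idx, dist = _knn_approximate(items, k, metric, seed=seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    edge_map: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j, w in zip(idx[i], dist[i]):
            a, b = (i, int(j)) if i < j else (int(j), i)
            if a == b:
                continue
            edge_map[(a, b)] = min(float(w), edge_map.get((a, b), np.inf))
    edges = np.array([(a, b, w) for (a, b), w in sorted(edge_map.items())], dtype=np.float64)
    return NeighborGraph(n=n, edges=edges, k=k, metric=metric, items=items)


def _components(n: int, edges: np.ndarray) -> np.ndarray:
    if edges.size == 0:
        return np.arange(n)
    adj = csr_matrix(
        (np.ones(len(edges)), (edges[:, 0].astype(int), edges[:, 1].astype(int))), shape=(n, n)
    )
    return connected_components(adj, directed=False)[1]


def _bridge_components(graph: NeighborGraph) -> np.ndarray:
    """Extra edges joining disconnected kNN components.

    The minimum-distance inter-component pair is found by exact search over
    component members; component-level MST selects which bridges to add, so
    two far components gain exactly one bridging edge.
    """
    comp = _components(graph.n, graph.edges)
    n_comp = comp.max() + 1
    if n_comp == 1:
        return np.empty((0, 3))
    members = [np.flatnonzero(comp == c) for c in range(n_comp)]
    best = np.full((n_comp, n_comp), np.inf)
    best_pair = {}
    for a in range(n_comp):
        for b in range(a + 1, n_comp):
            D = _pair_distances(graph.items, members[a], members[b], graph.metric)
            flat = np.argmin(D)
            i, j = np.unravel_index(flat, D.shape)
            best[a, b] = best[b, a] = D[i, j]
            best_pair[(a, b)] = (int(members[a][i]), int(members[b][j]))
    comp_mst = _scipy_mst(csr_matrix(np.triu(best + 1.0, k=1))).tocoo()
    bridges = []
    for a, b in zip(comp_mst.row, comp_mst.col):
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        i, j = best_pair[(a, b)]
        bridges.append((min(i, j), max(i, j), best[a, b]))
    return np.array(bridges, dtype=np.float64)


def minimum_spanning_tree(graph: NeighborGraph) -> SpanningTree:
    """MST of the (bridged) kNN graph: exactly n−1 edges, acyclic, connected.

    Weights are shifted by a constant inside the sparse solver so genuine
    zero-weight edges (duplicate molecules) are not dropped as absent
    entries; the shift cancels since every spanning tree has n−1 edges.
    """
    n = graph.n
    if n == 1:
        return SpanningTree(n=1, edges=np.empty((0, 3)))
    edges = graph.edges
    bridges = _bridge_components(graph)
    if bridges.size:
        edges = np.vstack([edges, bridges])
    rows = edges[:, 0].astype(int)
    cols = edges[:, 1].astype(int)
    adj = csr_matrix((edges[:, 2] + 1.0, (rows, cols)), shape=(n, n))
    mst = _scipy_mst(adj).tocoo()
    out = np.array(
        sorted(
            (min(int(i), int(j)), max(int(i), int(j)), float(w) - 1.0)
            for i, j, w in zip(mst.row, mst.col, mst.data)
        ),
        dtype=np.float64,
    )
    if out.shape[0] != n - 1:
        raise RuntimeError(f"MST has {out.shape[0]} edges for n={n}; graph not connected")
    out[:, 2] = np.maximum(out[:, 2], 0.0)
    return SpanningTree(n=n, edges=out)


def layout_tree(tree: SpanningTree, seed: int = 0) -> np.ndarray:
    """Deterministic radial embedding of a tree.

    The tree is rooted at node 0; each subtree receives an angular wedge
    proportional to its leaf count, nodes sit at radius equal to their
    depth, and a small seeded angular jitter breaks visual regularity.
    Distinct nodes always receive distinct coordinates and the drawing's
    edges are exactly the tree edges.
    """
    n = tree.n
    rng = np.random.default_rng(seed)
    coords = np.zeros((n, 2))
    if n == 1:
        return coords
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j, _ in tree.edges:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    # BFS from node 0 to orient the tree
    parent = np.full(n, -1, dtype=np.int64)
    order = [0]
    seen = np.zeros(n, dtype=bool)
    seen[0] = True
    for node in order:
        for nb in sorted(adj[node]):
            if not seen[nb]:
                seen[nb] = True
                parent[nb] = node
                children[node].append(nb)
                order.append(nb)
    # leaf counts bottom-up
    leaves = np.ones(n, dtype=np.int64)
    for node in reversed(order):
        if children[node]:
            leaves[node] = sum(leaves[c] for c in children[node])
    # wedge assignment top-down
    depth = np.zeros(n, dtype=np.int64)
    wedge = np.zeros((n, 2))
    wedge[0] = (0.0, 2.0 * np.pi)
    jitter = rng.uniform(-0.05, 0.05, size=n)
    for node in order:
        lo, hi = wedge[node]
        span = hi - lo
        cursor = lo
        for c in children[node]:
            frac = leaves[c] / leaves[node]
            wedge[c] = (cursor, cursor + span * frac)
            depth[c] = depth[node] + 1
            cursor += span * frac
    for node in range(1, n):
        lo, hi = wedge[node]
        mid = 0.5 * (lo + hi) + jitter[node] * min(hi - lo, 0.5)
        coords[node] = depth[node] * np.array([np.cos(mid), np.sin(mid)])
    return coords


def _artifact_from_items(
    items: np.ndarray,
    metadata: pd.DataFrame,
    metric: str,
    level: str,
    k: int,
    seed: int,
    cluster_id: int | None = None,
    mode: str = "exact",
) -> TreeMapArtifact:
    n = items.shape[0]
    if n == 1:
        tree = SpanningTree(n=1, edges=np.empty((0, 3)))
    else:
        graph = knn_graph(items, k=min(k, n - 1), metric=metric, mode=mode, seed=seed)
        tree = minimum_spanning_tree(graph)
    coords = layout_tree(tree, seed=seed)
    nodes = metadata.reset_index(drop=True).copy()
    nodes["x"] = coords[:, 0]
    nodes["y"] = coords[:, 1]
    return TreeMapArtifact(tree=tree, coords=coords, nodes=nodes, level=level, cluster_id=cluster_id)


def build_primary(
    representatives: np.ndarray,
    metadata: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    mode: str = "exact",
) -> TreeMapArtifact:
    """Primary map over cluster representatives (Euclidean on MQN vectors).

    ``metadata`` must carry one row per representative including a
    ``cluster_id`` column (the link to the secondary maps) and whatever
    colour channels the caller wants (typically the descriptor panel).
    """
    if representatives.shape[0] < 2:
        raise ValueError("primary map needs at least 2 representatives")
    if "cluster_id" not in metadata.columns:
        raise ValueError("metadata must include a 'cluster_id' column")
    if len(metadata) != representatives.shape[0]:
        raise ValueError("metadata must have one row per representative")
    return _artifact_from_items(
        np.asarray(representatives, dtype=np.float64),
        metadata,
        metric="euclidean",
        level="primary",
        k=k,
        seed=seed,
        mode=mode,
    )


def build_secondary(
    fingerprints: np.ndarray,
    metadata: pd.DataFrame,
    cluster_id: int,
    k: int = 10,
    seed: int = 0,
    mode: str = "exact",
) -> TreeMapArtifact:
    """Secondary map over one cluster's members (Tanimoto on ECFP4).

    Single-member clusters yield a one-node artifact with zero edges.
    """
    if fingerprints.shape[0] < 1:
        raise ValueError("cluster is empty")
    if len(metadata) != fingerprints.shape[0]:
        raise ValueError("metadata must have one row per member")
    return _artifact_from_items(
        np.asarray(fingerprints),
        metadata,
        metric="tanimoto",
        level="secondary",
        k=k,
        seed=seed,
        cluster_id=cluster_id,
        mode=mode,
    )


def assemble_atlas(
    primary: TreeMapArtifact,
    secondaries: dict[int, TreeMapArtifact],
    dataset_size: int | None = None,
) -> NestedAtlas:
    """Link the primary map to its secondary maps and validate conservation.

    Every primary node's cluster id must resolve to exactly one secondary
    artifact, and — when ``dataset_size`` is given — the secondary node
    counts must sum to it (every molecule in exactly one secondary map).
    """
    cluster_ids = [int(c) for c in primary.nodes["cluster_id"]]
    if len(set(cluster_ids)) != len(cluster_ids):
        raise ValueError("duplicated cluster_id in primary map")
    missing = [c for c in cluster_ids if c not in secondaries]
    if missing:
        raise ValueError(f"missing secondary map for cluster(s) {missing}")
    dangling = [c for c in secondaries if c not in set(cluster_ids)]
    if dangling:
        raise ValueError(f"secondary map(s) {dangling} have no primary node")
    total = sum(art.tree.n for art in secondaries.values())
    if dataset_size is not None and total != dataset_size:
        raise ValueError(
            f"conservation violated: secondary maps hold {total} molecules, dataset has {dataset_size}"
        )
    manifest = {
        "n_clusters": len(cluster_ids),
        "n_molecules": total,
        "secondary_sizes": {str(c): secondaries[c].tree.n for c in cluster_ids},
    }
    return NestedAtlas(primary=primary, secondaries=secondaries, manifest=manifest)


# -- persistence ----------------------------------------------------------


def _artifact_to_dict(art: TreeMapArtifact) -> dict:
    return {
        "level": art.level,
        "cluster_id": art.cluster_id,
        "n": art.tree.n,
        "edges": art.tree.edges.tolist(),
        "nodes": art.nodes.to_dict(orient="list"),
    }


def _artifact_from_dict(data: dict) -> TreeMapArtifact:
    edges = np.asarray(data["edges"], dtype=np.float64).reshape(-1, 3)
    tree = SpanningTree(n=int(data["n"]), edges=edges)
    nodes = pd.DataFrame(data["nodes"])
    coords = nodes[["x", "y"]].to_numpy()
    return TreeMapArtifact(
        tree=tree, coords=coords, nodes=nodes, level=data["level"], cluster_id=data["cluster_id"]
    )


def save_atlas(atlas: NestedAtlas, out_dir: str | Path) -> Path:
    """Write the atlas bundle: primary.json, secondary/<cid>.json, manifest.json."""
    out = Path(out_dir)
    (out / "secondary").mkdir(parents=True, exist_ok=True)
    (out / "primary.json").write_text(json.dumps(_artifact_to_dict(atlas.primary)))
    for cid, art in atlas.secondaries.items():
        (out / "secondary" / f"{cid}.json").write_text(json.dumps(_artifact_to_dict(art)))
    (out / "manifest.json").write_text(json.dumps(atlas.manifest, indent=2))
    return out


def load_atlas(out_dir: str | Path) -> NestedAtlas:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    primary = _artifact_from_dict(json.loads((out / "primary.json").read_text()))
    secondaries = {}
    for f in sorted((out / "secondary").glob("*.json")):
        art = _artifact_from_dict(json.loads(f.read_text()))
        secondaries[int(f.stem)] = art
    return NestedAtlas(primary=primary, secondaries=secondaries, manifest=manifest)
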