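"""Skeleton-constrained trajectory inference.

A trajectory is represented by a *skeleton*: a spanning tree over cluster
centroids in the reduced-dimensional embedding, rooted at a user-chosen
cluster.  Each root-to-leaf path is a lineage.  Cells are projected onto the
centroid polyline of every lineage; the arc length from the root to the
projection is the cell's pseudotime on that lineage, and the residual distance
to the polyline is converted to lineage weights with a Gaussian kernel whose
bandwidth is the median nearest-lineage distance.  Per-condition trajectories
are obtained by recomputing centroids from one condition's cells while keeping
the tree structure fixed, so lineages remain mapped across conditions by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Skeleton",
    "TrajectoryFit",
    "fit_skeleton",
    "project_cells",
    "fit_condition_trajectories",
]


@dataclass
class Skeleton:
    """Cluster-centroid tree with root-to-leaf lineages."""

    nodes: Dict[str, np.ndarray]  # cluster label -> centroid coordinates
    edges: List[Tuple[str, str]]
    root: str
    lineages: List[List[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = set(self.nodes)
        if self.root not in labels:
            raise ValueError(f"root {self.root!r} is not a skeleton node")
        g = nx.Graph(self.edges)
        g.add_nodes_from(labels)
        if len(self.edges) != len(labels) - 1 or not nx.is_connected(g):
            raise ValueError("edge set is not a tree over the nodes")
        if not self.lineages:
            self.lineages = _enumerate_lineages(g, self.root)

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def lineage_polyline(self, l: int) -> np.ndarray:
        return np.array([self.nodes[v] for v in self.lineages[l]], dtype=float)

    def with_centroids(self, nodes: Dict[str, np.ndarray]) -> "Skeleton":
        """Same tree structure and lineage order, new centroid coordinates."""
        return Skeleton(
            nodes=dict(nodes),
            edges=list(self.edges),
            root=self.root,
            lineages=[list(p) for p in self.lineages],
        )

    def to_json(self, path) -> None:
        payload = {
            "nodes": {k: list(map(float, v)) for k, v in self.nodes.items()},
            "edges": [list(e) for e in self.edges],
            "root": self.root,
            "lineages": self.lineages,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Skeleton":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            nodes={k: np.asarray(v, float) for k, v in payload["nodes"].items()},
            edges=[tuple(e) for e in payload["edges"]],
            root=payload["root"],
            lineages=payload["lineages"],
        )


@dataclass
class TrajectoryFit:
    """Per-cell pseudotimes T (n x L) and lineage weights W (n x L)."""

    pseudotimes: np.ndarray
    weights: np.ndarray
    skeleton: Skeleton
    condition: Optional[str] = None
    cell_ids: Optional[List[str]] = None
    sigma: float = float("nan")  # kernel bandwidth used for the weights

    @property
    def n_lineages(self) -> int:
        return self.pseudotimes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n, L = self.pseudotimes.shape
        ids = self.cell_ids if self.cell_ids is not None else [str(i) for i in range(n)]
        data = {"cell_id": ids}
        for l in range(L):
            data[f"pseudotime_{l + 1}"] = self.pseudotimes[:, l]
        for l in range(L):
            data[f"weight_{l + 1}"] = self.weights[:, l]
        return pd.DataFrame(data)


def _enumerate_lineages(g: nx.Graph, root: str) -> List[List[str]]:
    leaves = sorted(v for v in g.nodes if g.degree(v) == 1 and v != root)
    if not leaves:  # isolated root (single-node skeleton)
        return [[root]]
    return [nx.shortest_path(g, root, leaf) for leaf in leaves]


def _centroids(embedding: np.ndarray, clusters: np.ndarray) -> Dict[str, np.ndarray]:
    out = {}
    for lab in np.unique(clusters):
        mask = clusters == lab
        out[str(lab)] = embedding[mask].mean(axis=0)
    return out


def fit_skeleton(
    dataset,
    root: str,
    fixed_adjacency: Optional[Sequence[Tuple[str, str]]] = None,
) -> Skeleton:
    """Build the cluster-centroid skeleton.

    Without ``fixed_adjacency`` the tree is the Euclidean minimum spanning
    tree over cluster centroids (Kruskal; equal-length edges broken by
    lexicographic node-label order).  With ``fixed_adjacency`` the given tree
    is kept and only centroids are recomputed.
    """
    clusters = np.asarray(dataset.clusters)
    cents = _centroids(np.asarray(dataset.embedding, float), clusters)
    labels = sorted(cents)
    if str(root) not in cents:
        raise ValueError(f"root {root!r} is not an existing cluster")

    if fixed_adjacency is not None:
        edges = [(str(u), str(v)) for u, v in fixed_adjacency]
        for u, v in edges:
            if u not in cents or v not in cents:
                raise ValueError(f"fixed_adjacency references unknown cluster ({u}, {v})")
        g = nx.Graph(edges)
        g.add_nodes_from(labels)
        if len(edges) != len(labels) - 1 or not nx.is_connected(g):
            raise ValueError("fixed_adjacency is not a tree over the clusters")
        return Skeleton(nodes=cents, edges=edges, root=str(root))

    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, u in enumerate(labels):  # lexicographic insertion fixes tie order
        for v in labels[i + 1 :]:
            g.add_edge(u, v, weight=float(np.linalg.norm(cents[u] - cents[v])))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = [tuple(sorted(e)) for e in sorted(mst.edges())]
    return Skeleton(nodes=cents, edges=edges, root=str(root))


def _project_polyline(X: np.ndarray, poly: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline.

    Returns (arc_length, distance) per point.  Projections are clamped to
    segment ends, except at the far end of the terminal segment, which is
    treated as a ray: cells beyond the last centroid project onto the
    lineage's continuation instead of piling up at the tip (the same
    extension principal-curve methods apply so that terminal cells do not
    collapse onto one atom).  Ties across segments resolve toward the root
    (first minimal segment wins).
    """
    n = X.shape[0]
    if poly.shape[0] == 1:
        d = np.linalg.norm(X - poly[0], axis=1)
        return np.zeros(n), d
    seg_vec = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_seg = seg_vec.shape[0]
    arcs = np.empty((n, n_seg))
    dist2 = np.empty((n, n_seg))
    for s in range(n_seg):
        a, u, ln = poly[s], seg_vec[s], seg_len[s]
        if ln == 0:
            proj = np.broadcast_to(a, X.shape)
            frac = np.zeros(n)
        else:
            hi = np.inf if s == n_seg - 1 else 1.0
            frac = np.clip((X - a) @ u / ln**2, 0.0, hi)
            proj = a + frac[:, None] * u
        dist2[:, s] = np.sum((X - proj) ** 2, axis=1)
        arcs[:, s] = cum[s] + frac * ln
    best = np.argmin(dist2, axis=1)  # first min -> root-ward tie break
    rows = np.arange(n)
    return arcs[rows, best], np.sqrt(dist2[rows, best])


def project_cells(
    dataset,
    skeleton: Skeleton,
    cells: Optional[np.ndarray] = None,
) -> TrajectoryFit:
    """Project cells onto every lineage polyline of the skeleton.

    Pseudotime on lineage l is the root-to-projection arc length; raw weights
    are exp(-d_il^2 / sigma^2) with sigma the median over cells of the
    distance to the nearest lineage, then row-normalised to sum to 1.
    """
    if skeleton.n_lineages == 0:
        raise ValueError("skeleton has zero lineages")
    X = np.asarray(dataset.embedding, float)
    ids = list(dataset.cell_ids)
    if cells is not None:
        cells = np.asarray(cells)
        if cells.dtype == bool:
            idx = np.flatnonzero(cells)
        else:
            idx = cells.astype(int)
        if idx.size == 0:
            raise ValueError("empty cell subset")
        X = X[idx]
        ids = [ids[i] for i in idx]

    L = skeleton.n_lineages
    n = X.shape[0]
    T = np.empty((n, L))
    D = np.empty((n, L))
    for l in range(L):
        T[:, l], D[:, l] = _project_polyline(X, skeleton.lineage_polyline(l))

    d_min = D.min(axis=1)
    sigma = float(np.median(d_min))
    if sigma > 0:
        # shift by the row minimum before exponentiating: identical after
        # normalisation, immune to underflow
        raw = np.exp(-(D**2 - d_min[:, None] ** 2) / sigma**2)
    else:
        tol = 1e-12
        raw = (D <= D.min(axis=1, keepdims=True) + tol).astype(float)
    W = raw / raw.sum(axis=1, keepdims=True)
    return TrajectoryFit(
        pseudotimes=T,
        weights=W,
        skeleton=skeleton,
        cell_ids=ids,
        sigma=sigma,
    )


def fit_condition_trajectories(
    dataset,
    skeleton: Skeleton,
    labels: Optional[np.ndarray] = None,
    allow_missing_cluster: bool = False,
) -> List[TrajectoryFit]:
    """Refit the skeleton per condition and project that condition's cells.

    For each condition, centroids are recomputed from the condition's cells
    only while the tree structure (and hence lineage indexing) is kept, so the
    per-condition trajectories are mapped by construction.  With
    ``allow_missing_cluster`` a condition-empty cluster keeps the all-cell
    centroid instead of raising (used for permutation refits).
    """
    if labels is None:
        labels = np.asarray(dataset.conditions)
    labels = np.asarray(labels)
    emb = np.asarray(dataset.embedding, float)
    clusters = np.asarray(dataset.clusters).astype(str)
    fits = []
    for cond in np.unique(labels):
        mask = labels == cond
        cents = {}
        for node in skeleton.nodes:
            node_mask = mask & (clusters == node)
            if node_mask.sum() == 0:
                if not allow_missing_cluster:
                    raise ValueError(
                        f"condition {cond!r} has no cells in cluster {node!r}; "
                        "remove the cluster or the condition before testing"
                    )
                cents[node] = skeleton.nodes[node]
            else:
                cents[node] = emb[node_mask].mean(axis=0)
        sub = skeleton.with_centroids(cents)
        fit = project_cells(dataset, sub, cells=mask)
        fit.condition = str(cond)
        fits.append(fit)
    return fits
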