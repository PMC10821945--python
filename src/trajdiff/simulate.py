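"""Synthetic multi-condition branching-trajectory generator.

The generator emulates the *outcomes* of a branching differentiation process
in a 2-D embedding: cells advance along a tree of segments, choose branches
with per-condition probabilities, and express genes according to smooth
negative-binomial log-mean curves along their lineage.  Condition effects are
injected directly at the level the downstream tests consume:

- ``progression_shift`` warps the pseudotime distribution of a condition
  (t = u^(1/(1+shift)) on a U(0,1) base, so shift > 0 pushes cells later);
- ``branch_probs`` changes fate proportions per condition;
- ``topology_offset`` displaces a condition's post-branch geometry (the
  differential-topology knob);
- a knock-out multiplier ``m`` scales affected genes' expression rate in the
  perturbed condition (m = 1: no effect).

Gene-regulatory dynamics are not modelled; the tests only see pseudotimes,
weights, geometry and counts.  Defaults: two conditions, two lineages,
1000 cells per condition, 200 genes, NB dispersion phi = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .datasets import CellDataset

__all__ = [
    "SimSpec",
    "SimTruth",
    "NoiseSpec",
    "simulate_dataset",
    "inject_noise",
    "benchmark_metrics",
]

# built-in topologies: node coordinates and root-to-leaf node paths
_TOPOLOGIES = {
    "linear": {
        "nodes": {"O": (0.0, 0.0), "M": (2.0, 0.0), "E": (4.0, 0.0)},
        "lineages": [["O", "M", "E"]],
    },
    # branch angle is wide enough that post-branch cluster centroids are
    # closer to the trunk than to each other, so the centroid MST recovers
    # the generating tree
    "binary": {
        "nodes": {
            "O": (0.0, 0.0),
            "M": (2.0, 0.0),
            "A": (3.0, 2.0),
            "B": (3.0, -2.0),
        },
        "lineages": [["O", "M", "A"], ["O", "M", "B"]],
    },
}


@dataclass
class SimSpec:
    """Scenario description for the simulator; the defaults are the neutral
    (no-effect) condition."""

    topology: str = "binary"
    n_per_condition: int = 1000
    conditions: Sequence[str] = ("WT", "KO")
    branch_probs: Optional[Dict[str, Sequence[float]]] = None
    progression_shift: Optional[Dict[str, float]] = None
    # like progression_shift, but warping only the stretch of a lineage past
    # its last branch point (fate proportions are untouched by construction)
    tip_progression_shift: Optional[Dict[str, float]] = None
    topology_offset: Optional[Dict[str, Dict[str, Sequence[float]]]] = None
    n_genes: int = 200
    de_frac: float = 0.1
    multiplier: float = 1.0  # knock-out multiplier m on DE genes, last condition
    dispersion: float = 2.0  # NB size parameter phi (Var = mu + mu^2/phi)
    emb_noise_sd: float = 0.15
    base_depth: float = 2000.0
    depth_sd: float = 0.3  # lognormal sd of per-cell depth factors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if self.multiplier <= 0:
            raise ValueError("multiplier m must be > 0")
        L = len(_TOPOLOGIES[self.topology]["lineages"])
        if self.branch_probs is None:
            self.branch_probs = {c: [1.0 / L] * L for c in self.conditions}
        for c, bp in self.branch_probs.items():
            if len(bp) != L or not np.isclose(np.sum(bp), 1.0):
                raise ValueError(f"branch_probs for {c!r} must sum to 1 over {L} lineages")
        if self.progression_shift is None:
            self.progression_shift = {c: 0.0 for c in self.conditions}
        if self.tip_progression_shift is None:
            self.tip_progression_shift = {c: 0.0 for c in self.conditions}
        if self.topology_offset is None:
            self.topology_offset = {}


@dataclass
class SimTruth:
    """Ground truth bookkeeping for a simulated dataset."""

    lineage: np.ndarray  # true lineage index per cell
    pseudotime: np.ndarray  # true arc-length pseudotime per cell
    progress: np.ndarray  # unit-scale progress u in [0, 1]
    weights: np.ndarray  # n x L truth weights (equal split on shared prefix)
    condition: np.ndarray
    de_genes: np.ndarray  # boolean flags per gene
    effects: Dict[str, bool] = field(default_factory=dict)
    gene_curves: Dict[str, np.ndarray] = field(default_factory=dict)
    multiplier: float = 1.0
    perturbed_condition: str = ""

    def log_mean_curve(self, gene: int, t, lineage: int = 0,
                       condition: str = "") -> np.ndarray:
        """Generating log-mean curve (per unit depth) for one gene."""
        g = self.gene_curves
        t = np.asarray(t, dtype=float)
        out = (
            g["a"][gene]
            + g["b"][gene] * t
            + g["amp"][gene] * np.sin(np.pi * t + g["phase"][gene])
            + g["lin_eff"][gene, lineage]
        )
        if condition == self.perturbed_condition and self.de_genes[gene]:
            out = out + np.log(self.multiplier)
        return out


@dataclass
class NoiseSpec:
    """Noise-injection protocol: a proportion p of cells get a uniformly
    random lineage and pseudotimes are multiplied by Normal(1, sd) draws."""

    p: float = 0.0
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 0.5:
            raise ValueError("p must be in [0, 0.5]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _polyline(nodes: Dict[str, Sequence[float]], path: List[str]) -> np.ndarray:
    return np.array([nodes[v] for v in path], dtype=float)


def _arc_lengths(poly: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(poly, axis=0), axis=1))])


def _point_at_arc(poly: np.ndarray, arc: float) -> np.ndarray:
    cum = _arc_lengths(poly)
    arc = min(max(arc, 0.0), cum[-1])
    s = int(np.searchsorted(cum, arc, side="right") - 1)
    s = min(s, poly.shape[0] - 2)
    seg = poly[s + 1] - poly[s]
    ln = cum[s + 1] - cum[s]
    frac = 0.0 if ln == 0 else (arc - cum[s]) / ln
    return poly[s] + frac * seg


def _common_prefix_arc(nodes, path1, path2) -> float:
    """Arc length of the shared root prefix of two lineage node paths."""
    k = 0
    while k < min(len(path1), len(path2)) and path1[k] == path2[k]:
        k += 1
    if k < 2:
        return 0.0
    return float(_arc_lengths(_polyline(nodes, path1[:k]))[-1])


def simulate_dataset(spec: SimSpec):
    """Generate a (CellDataset, SimTruth) pair from a scenario spec.

    All randomness flows from ``spec.seed``; the same spec yields bit-identical
    outputs.  Cluster labels bin each tree segment in two, so the cluster-MST
    skeleton recovers the generating topology.
    """
    rng = np.random.default_rng(spec.seed)
    topo = _TOPOLOGIES[spec.topology]
    base_nodes = {k: np.asarray(v, float) for k, v in topo["nodes"].items()}
    paths = topo["lineages"]
    L = len(paths)
    conds = list(spec.conditions)
    C = len(conds)
    n = spec.n_per_condition
    n_tot = n * C

    condition = np.repeat(conds, n)
    lineage = np.empty(n_tot, dtype=int)
    progress = np.empty(n_tot)
    pseudotime = np.empty(n_tot)
    weights = np.zeros((n_tot, L))
    position = np.empty((n_tot, 2))
    cluster = np.empty(n_tot, dtype=object)

    # per-condition node geometry (topology offsets displace selected nodes)
    cond_nodes = {}
    for c in conds:
        nodes_c = {k: v.copy() for k, v in base_nodes.items()}
        for node, off in spec.topology_offset.get(c, {}).items():
            nodes_c[node] = nodes_c[node] + np.asarray(off, float)
        cond_nodes[c] = nodes_c

    def _positions_at(poly: np.ndarray, arcs: np.ndarray) -> np.ndarray:
        cum = _arc_lengths(poly)
        arcs = np.clip(arcs, 0.0, cum[-1])
        s = np.clip(np.searchsorted(cum, arcs, side="right") - 1, 0, poly.shape[0] - 2)
        seg = poly[s + 1] - poly[s]
        ln = cum[s + 1] - cum[s]
        frac = np.where(ln > 0, (arcs - cum[s]) / np.where(ln > 0, ln, 1.0), 0.0)
        return poly[s] + frac[:, None] * seg

    for ci, c in enumerate(conds):
        lin_c = rng.choice(L, size=n, p=np.asarray(spec.branch_probs[c], float))
        u = rng.uniform(size=n)
        shift = spec.progression_shift.get(c, 0.0)
        t = u ** (1.0 / (1.0 + shift))
        off = ci * n
        lineage[off : off + n] = lin_c
        progress[off : off + n] = t
        nodes_c = cond_nodes[c]
        tip_shift = spec.tip_progression_shift.get(c, 0.0)
        for l in range(L):
            rows = off + np.flatnonzero(lin_c == l)
            if rows.size == 0:
                continue
            tl = t[rows - off]
            poly = _polyline(nodes_c, paths[l])
            total = _arc_lengths(poly)[-1]
            if tip_shift != 0.0 and total > 0:
                # warp only past the last branch point of this lineage
                branch_arc = max(
                    _common_prefix_arc(nodes_c, paths[l], paths[l2])
                    for l2 in range(L)
                    if l2 != l
                ) if L > 1 else 0.0
                f = branch_arc / total
                past = tl > f
                excess = (tl[past] - f) / (1.0 - f)
                tl = tl.copy()
                tl[past] = f + (1.0 - f) * excess ** (1.0 / (1.0 + tip_shift))
                progress[rows] = tl
            arcs = tl * total
            pseudotime[rows] = arcs
            position[rows] = _positions_at(poly, arcs)
            # truth weights: equal split among lineages sharing the prefix
            prefix = np.array(
                [
                    np.inf
                    if l2 == l
                    else _common_prefix_arc(nodes_c, paths[l], paths[l2])
                    for l2 in range(L)
                ]
            )
            share = arcs[:, None] <= prefix[None, :]
            weights[rows] = share / share.sum(axis=1, keepdims=True)
            # cluster label: segment of the base geometry, split in two bins
            base_poly = _polyline(base_nodes, paths[l])
            cum = _arc_lengths(base_poly)
            arc_b = tl * cum[-1]
            s = np.clip(
                np.searchsorted(cum, arc_b, side="right") - 1, 0, len(cum) - 2
            )
            half = (arc_b - cum[s]) > 0.5 * (cum[s + 1] - cum[s])
            for i, si, hi in zip(rows, s, half.astype(int)):
                cluster[i] = f"{paths[l][si]}-{paths[l][si + 1]}:{hi}"

    embedding = position + rng.normal(0.0, spec.emb_noise_sd, size=position.shape)

    # gene expression: smooth log-mean curves along unit progress
    J = spec.n_genes
    n_de = int(np.ceil(spec.de_frac * J)) if spec.multiplier != 1.0 else 0
    de_genes = np.zeros(J, dtype=bool)
    if n_de > 0:
        de_genes[rng.choice(J, size=n_de, replace=False)] = True

    a = rng.uniform(np.log(0.5), np.log(5.0), size=J)
    b = rng.uniform(-1.0, 1.0, size=J)
    amp = rng.uniform(0.0, 1.0, size=J)
    phase = rng.uniform(0.0, np.pi, size=J)
    lin_eff = rng.normal(0.0, 0.3, size=(J, L))  # branch-specific expression

    depth = np.exp(rng.normal(0.0, spec.depth_sd, size=n_tot))
    lib_sizes = spec.base_depth * depth

    t01 = progress[None, :]
    log_mu = (
        a[:, None]
        + b[:, None] * t01
        + amp[:, None] * np.sin(np.pi * t01 + phase[:, None])
        + lin_eff[:, lineage]
    )
    if n_de > 0:
        perturbed = condition == conds[-1]
        log_mu[np.ix_(de_genes, perturbed)] += np.log(spec.multiplier)
    mu = np.exp(log_mu) * depth[None, :]
    phi = spec.dispersion
    counts = rng.negative_binomial(phi, phi / (phi + mu))

    dataset = CellDataset(
        counts=counts,
        cell_ids=[f"cell_{i}" for i in range(n_tot)],
        conditions=condition,
        clusters=cluster.astype(str),
        embedding=embedding,
        gene_ids=[f"gene_{j}" for j in range(J)],
        lib_sizes=lib_sizes,
    )
    truth = SimTruth(
        lineage=lineage,
        pseudotime=pseudotime,
        progress=progress,
        weights=weights,
        condition=condition,
        de_genes=de_genes,
        effects={
            "progression": any(v != 0 for v in spec.progression_shift.values()),
            "fate": len({tuple(np.round(v, 12)) for v in map(np.asarray, spec.branch_probs.values())}) > 1,
            "topology": bool(spec.topology_offset),
            "expression": spec.multiplier != 1.0,
        },
        gene_curves={"a": a, "b": b, "amp": amp, "phase": phase, "lin_eff": lin_eff},
        multiplier=spec.multiplier,
        perturbed_condition=conds[-1] if n_de > 0 else "",
    )
    return dataset, truth


def inject_noise(T: np.ndarray, assignments: np.ndarray, noise: NoiseSpec):
    """Perturb hard lineage assignments and pseudotimes.

    A seeded random fraction ``p`` of cells receives a uniformly random
    lineage (so a selected cell keeps its lineage with probability 1/L), and
    every pseudotime is multiplied by an independent Normal(1, sd) draw,
    floored at 0.
    """
    rng = np.random.default_rng(noise.seed)
    T = np.asarray(T, dtype=float)
    assignments = np.asarray(assignments).copy()
    n = assignments.shape[0]
    L = T.shape[1] if T.ndim > 1 else int(assignments.max()) + 1
    n_flip = int(round(noise.p * n))
    if n_flip > 0:
        pick = rng.choice(n, size=n_flip, replace=False)
        assignments[pick] = rng.integers(0, L, size=n_flip)
    if noise.sd > 0:
        T = np.maximum(T * rng.normal(1.0, noise.sd, size=T.shape), 0.0)
    else:
        T = T.copy()
    return T, assignments


def benchmark_metrics(decisions: Sequence[bool], truth: Sequence[bool]) -> dict:
    """Confusion-matrix metrics over simulated datasets.

    ``truth`` flags datasets with a real effect (m != 1); a rejection on such
    a dataset is a true positive.  Zero-denominator metrics are reported as
    None rather than 0.
    """
    d = np.asarray(decisions, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if d.shape != t.shape:
        raise ValueError("decisions and truth must have the same length")
    tp = int(np.sum(d & t))
    fp = int(np.sum(d & ~t))
    fn = int(np.sum(~d & t))
    tn = int(np.sum(~d & ~t))

    def ratio(num, den):
        return num / den if den > 0 else None

    tnr = ratio(tn, tn + fp)
    tpr = ratio(tp, tp + fn)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = (
        2.0 * ppv * tpr / (ppv + tpr)
        if ppv is not None and tpr is not None and (ppv + tpr) > 0
        else None
    )
    return {"TNR": tnr, "TPR": tpr, "PPV": ppv, "NPV": npv, "F1": f1,
            "TP": tp, "FP": fp, "FN": fn, "TN": tn}
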