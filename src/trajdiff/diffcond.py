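"""Trajectory-level differential tests between conditions.

Three questions, three tests:

- ``topology_test``: should a common trajectory be fitted at all?  Condition
  labels are permuted r times on a fixed cluster skeleton, per-condition
  trajectories are refitted each time, and the observed per-cell pseudotimes
  are compared against the per-cell average of the permuted refits.
- ``progression_test``: do pseudotime distributions differ between conditions
  within lineages?  Weighted KS per lineage, combined across lineages with a
  weighted Stouffer Z (default) or a multivariate test.
- ``fate_selection_test``: do lineage-weight distributions differ between
  conditions?  Classifier test (random forest by default) on the weight
  matrix, globally or per lineage pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .trajectory import Skeleton, TrajectoryFit, fit_condition_trajectories
from .twosample import (
    ClassifierSpec,
    DistTestResult,
    WeightedSample,
    classifier_test,
    mmd_test,
    stouffer_combine,
    weighted_ks,
)

__all__ = ["TopologyTestResult", "topology_test", "progression_test", "fate_selection_test"]


@dataclass
class TopologyTestResult:
    method: str
    r: int
    observed_fits: list
    null_pseudotimes: np.ndarray  # per-cell average of permuted pseudotimes
    observed_pseudotimes: np.ndarray
    inner: DistTestResult

    @property
    def p_value(self) -> float:
        return self.inner.p_value

    @property
    def statistic(self) -> float:
        return self.inner.statistic


def _assemble(fits: Sequence[TrajectoryFit], labels: np.ndarray, n: int):
    """Gather per-condition fits into full n x L pseudotime/weight matrices."""
    L = fits[0].n_lineages
    T = np.empty((n, L))
    W = np.empty((n, L))
    for fit in fits:
        mask = labels == fit.condition
        T[mask] = fit.pseudotimes
        W[mask] = fit.weights
    return T, W


def topology_test(
    dataset,
    skeleton: Skeleton,
    r: int = 100,
    method: str = "auto",
    t: float = 0.0,
    alpha: float = 0.05,
    seed: int = 0,
    average: bool = True,
    n_permutations_mmd: int = 100,
) -> TopologyTestResult:
    """Permutation test for a common trajectory topology across conditions.

    The observed per-condition pseudotimes are compared with the per-cell
    average pseudotime over ``r`` label-permuted refits on the same skeleton.
    The comparison uses the weighted KS test when L = 1, the kernel two-sample
    test when C = 2 and L > 1, and the classifier test otherwise (or any of
    these via ``method``).
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    labels = np.asarray(dataset.conditions)
    n = labels.shape[0]
    observed = fit_condition_trajectories(dataset, skeleton, labels)
    T_obs, W_obs = _assemble(observed, labels, n)
    L = T_obs.shape[1]
    C = np.unique(labels).size

    rng = np.random.default_rng(seed)
    acc = np.zeros_like(T_obs)
    for _ in range(r):
        perm = rng.permutation(labels)
        fits = fit_condition_trajectories(
            dataset, skeleton, perm, allow_missing_cluster=True
        )
        T_perm, _ = _assemble(fits, perm, n)
        acc += T_perm
    T_null = acc / r

    if method == "auto":
        method = "weighted_ks" if L == 1 else ("mmd" if C == 2 else "classifier")
    if method == "weighted_ks":
        if L != 1:
            raise ValueError("weighted_ks comparison requires a single lineage")
        inner = weighted_ks(
            WeightedSample(T_obs[:, 0], W_obs[:, 0], group="observed"),
            WeightedSample(T_null[:, 0], W_obs[:, 0], group="permuted"),
            t=t,
            alpha=alpha,
        )
    elif method == "mmd":
        inner = mmd_test(
            WeightedSample(T_obs, group="observed"),
            WeightedSample(T_null, group="permuted"),
            n_permutations=n_permutations_mmd,
            seed=seed,
            alpha=alpha,
        )
    elif method == "classifier":
        spec = ClassifierSpec(kind="knn", seed=seed)
        inner = classifier_test(
            [
                WeightedSample(T_obs, group="observed"),
                WeightedSample(T_null, group="permuted"),
            ],
            spec,
            t=t,
            alpha=alpha,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    inner.extra["average_permutations"] = average
    return TopologyTestResult(
        method=method,
        r=r,
        observed_fits=list(observed),
        null_pseudotimes=T_null,
        observed_pseudotimes=T_obs,
        inner=inner,
    )


def progression_test(
    fit: Optional[TrajectoryFit] = None,
    conditions: Optional[np.ndarray] = None,
    pseudotimes: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
    global_method: str = "stouffer",
    t: float = 0.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> DistTestResult:
    """Test for identical pseudotime distributions between conditions.

    Per lineage l, the pseudotimes T[:, l] are compared between conditions
    with the weighted KS test using lineage weights W[:, l] (classifier test
    when C > 2).  Globally, per-lineage p-values are combined with a weighted
    Stouffer Z with lineage weights W_l = Σ_i W_i[l] (default), or the full
    pseudotime matrix is compared with the classifier/MMD test.
    """
    if fit is not None:
        pseudotimes = fit.pseudotimes
        weights = fit.weights
    T = np.asarray(pseudotimes, dtype=float)
    W = np.asarray(weights, dtype=float)
    labels = np.asarray(conditions).astype(str)
    levels = np.unique(labels)
    C = levels.size
    if C < 2:
        raise ValueError("progression test requires at least two conditions")
    n, L = T.shape

    per_lineage = []
    p_l = np.empty(L)
    W_l = W.sum(axis=0)
    for l in range(L):
        masks = [labels == lev for lev in levels]
        tot = [W[m, l].sum() for m in masks]
        if any(s <= 0 for s in tot):
            warnings.warn(
                f"lineage {l + 1} has zero total weight in some condition; "
                "its p-value is set to 1 and it is excluded from the combination"
            )
            p_l[l] = 1.0
            W_l[l] = 0.0
            per_lineage.append(
                {"lineage": l + 1, "statistic": float("nan"), "p_value": 1.0,
                 "note": "zero weight in a condition"}
            )
            continue
        if C == 2:
            res = weighted_ks(
                WeightedSample(T[masks[0], l], W[masks[0], l], group=levels[0]),
                WeightedSample(T[masks[1], l], W[masks[1], l], group=levels[1]),
                t=t,
                alpha=alpha,
            )
        else:
            res = classifier_test(
                [WeightedSample(T[m, l], group=lev) for m, lev in zip(masks, levels)],
                ClassifierSpec(kind="knn", seed=seed),
                t=t,
                alpha=alpha,
            )
        p_l[l] = res.p_value
        per_lineage.append(
            {"lineage": l + 1, "statistic": float(res.statistic), "p_value": float(res.p_value)}
        )

    if global_method == "stouffer":
        if not np.any(W_l > 0):
            raise ValueError("all lineages degenerate: cannot combine")
        out = stouffer_combine(p_l, W_l, alpha=alpha)
    elif global_method == "classifier":
        out = classifier_test(
            [WeightedSample(T[labels == lev], group=lev) for lev in levels],
            ClassifierSpec(kind="knn", seed=seed),
            t=t,
            alpha=alpha,
        )
    elif global_method == "mmd":
        if C != 2:
            raise ValueError("mmd global method requires exactly two conditions")
        out = mmd_test(
            WeightedSample(T[labels == levels[0]], group=levels[0]),
            WeightedSample(T[labels == levels[1]], group=levels[1]),
            seed=seed,
            alpha=alpha,
        )
    else:
        raise ValueError(f"unknown global method {global_method!r}")
    out.per_lineage = per_lineage
    return out


def fate_selection_test(
    fit: Optional[TrajectoryFit] = None,
    conditions: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
    mode: str = "global",
    spec: Optional[ClassifierSpec] = None,
    t: float = 0.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> DistTestResult:
    """Test for identical lineage-weight distributions between conditions.

    Globally the classifier test (random forest by default) is applied to the
    n x L weight matrix grouped by condition; in pairwise mode each lineage
    pair (l, l') is tested on the two weight columns.  Cells with zero weight
    on both lineages of a pair are retained: non-membership is informative.
    """
    if fit is not None:
        weights = fit.weights
    W = np.asarray(weights, dtype=float)
    labels = np.asarray(conditions).astype(str)
    levels = np.unique(labels)
    if W.shape[1] < 2:
        raise ValueError("fate selection test requires at least two lineages")
    if spec is None:
        spec = ClassifierSpec(kind="random_forest", seed=seed)

    if mode == "global":
        return classifier_test(
            [WeightedSample(W[labels == lev], group=lev) for lev in levels],
            spec,
            t=t,
            alpha=alpha,
        )
    if mode == "pairwise":
        L = W.shape[1]
        per_pair = []
        p_min = None
        for l in range(L):
            for lp in range(l + 1, L):
                res = classifier_test(
                    [
                        WeightedSample(W[labels == lev][:, [l, lp]], group=lev)
                        for lev in levels
                    ],
                    spec,
                    t=t,
                    alpha=alpha,
                )
                per_pair.append(
                    {
                        "pair": [l + 1, lp + 1],
                        "statistic": float(res.statistic),
                        "p_value": float(res.p_value),
                    }
                )
                if p_min is None or res.p_value < p_min.p_value:
                    p_min = res
        out = p_min
        out.per_pair = per_pair
        return out
    raise ValueError(f"unknown mode {mode!r}")
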