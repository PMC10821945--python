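"""Distribution-equality tests used throughout the workflow.

The univariate workhorse is a weighted Kolmogorov-Smirnov test in which each
observation carries a membership weight in [0, 1] (e.g., the probability that a
cell belongs to a lineage).  Following Monahan's treatment of weighted samples,
the ECDFs are weight-normalised and the rejection region uses Kish effective
sample sizes n' = (Σw)²/Σw².  Multivariate comparisons use either a classifier
two-sample test with an exact binomial null, or an MMD permutation test.
Per-lineage p-values are combined with a weighted Stouffer Z, and multiplicity
across genes is handled by Benjamini-Hochberg.

All tests accept an effect-size threshold ``t`` that is folded into the null
hypothesis (a minimum-magnitude requirement), so that only differences larger
than ``t`` count as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WeightedSample",
    "DistTestResult",
    "ClassifierSpec",
    "weighted_ks",
    "classifier_test",
    "mmd_test",
    "stouffer_combine",
    "bh_adjust",
]


@dataclass
class WeightedSample:
    """A (possibly multivariate) sample with per-observation weights in [0, 1]."""

    values: np.ndarray
    weights: Optional[np.ndarray] = None
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.weights is None:
            n = self.values.shape[0]
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.values.shape[0]:
            raise ValueError("values and weights must have the same length")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not np.any(self.weights > 0):
            raise ValueError("at least one weight must be strictly positive")


@dataclass
class DistTestResult:
    """Outcome of a distribution-equality test."""

    method: str
    statistic: float
    p_value: float
    threshold_t: float = 0.0
    decision_at: float = 0.05
    reject: Optional[bool] = None
    n_eff: Optional[tuple] = None
    n_test: Optional[int] = None
    per_lineage: Optional[list] = None
    per_pair: Optional[list] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": float(self.statistic),
            "threshold": float(self.threshold_t),
            "p_value": float(self.p_value),
            "decision_at": float(self.decision_at),
        }
        if self.reject is not None:
            out["reject"] = bool(self.reject)
        if self.n_eff is not None:
            out["n_eff"] = [float(x) for x in self.n_eff]
        if self.n_test is not None:
            out["n_test"] = int(self.n_test)
        if self.per_lineage is not None:
            out["per_lineage"] = self.per_lineage
        if self.per_pair is not None:
            out["per_pair"] = self.per_pair
        out.update(self.extra)
        return out


@dataclass
class ClassifierSpec:
    """Configuration of the classifier two-sample test.

    ``kind`` selects a k-NN or random-forest classifier.  Hyper-parameters are
    chosen by cross-validation on the learning split; a grid of size one skips
    the CV loop.
    """

    kind: str = "knn"
    grid: Optional[Sequence] = None
    test_fraction: float = 0.3
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "random_forest"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.grid is None:
            self.grid = (5, 11, 21) if self.kind == "knn" else (500,)

    def make(self, param):
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=int(param))
        return RandomForestClassifier(
            n_estimators=int(param), random_state=self.seed, n_jobs=1
        )


def _weighted_ecdf_sup(x1, w1, x2, w2) -> float:
    """sup_x |F1(x) - F2(x)| for weight-normalised ECDFs, evaluated at the
    pooled jump points."""
    grid = np.concatenate([x1, x2])
    order = np.argsort(grid, kind="mergesort")
    grid = grid[order]
    s1, s2 = w1.sum(), w2.sum()
    # cumulative weight of sample points <= each pooled grid point
    i1 = np.searchsorted(np.sort(x1), grid, side="right")
    i2 = np.searchsorted(np.sort(x2), grid, side="right")
    c1 = np.concatenate([[0.0], np.cumsum(w1[np.argsort(x1, kind="mergesort")])])
    c2 = np.concatenate([[0.0], np.cumsum(w2[np.argsort(x2, kind="mergesort")])])
    return float(np.max(np.abs(c1[i1] / s1 - c2[i2] / s2)))


def ks_critical_value(n_eff: float, m_eff: float, alpha: float) -> float:
    """Critical value of the two-sided KS rejection region,
    sqrt(-1/2 · log(alpha/2) · (n'+m')/(n'·m'))."""
    return float(np.sqrt(-0.5 * np.log(alpha / 2.0) * (n_eff + m_eff) / (n_eff * m_eff)))


def weighted_ks(
    sample1: WeightedSample,
    sample2: WeightedSample,
    t: float = 0.0,
    alpha: float = 0.05,
) -> DistTestResult:
    """Weighted two-sample Kolmogorov-Smirnov test.

    D = sup |F1 - F2| over the weight-normalised ECDFs; with an effect-size
    threshold the statistic becomes D' = max(D - t, 0).  The null is rejected
    when D' exceeds the critical value evaluated at the Kish effective sample
    sizes, and the reported p-value is the asymptotic Kolmogorov tail
    probability of D'·sqrt(n'm'/(n'+m')).
    """
    if t < 0:
        raise ValueError("effect-size threshold t must be >= 0")
    x1 = np.asarray(sample1.values, dtype=float).ravel()
    x2 = np.asarray(sample2.values, dtype=float).ravel()
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("non-finite values in input samples")
    w1, w2 = sample1.weights, sample2.weights

    d = _weighted_ecdf_sup(x1, w1, x2, w2)
    d_thr = max(d - t, 0.0)
    n_eff = w1.sum() ** 2 / np.sum(w1**2)
    m_eff = w2.sum() ** 2 / np.sum(w2**2)
    crit = ks_critical_value(n_eff, m_eff, alpha)
    lam = d_thr * np.sqrt(n_eff * m_eff / (n_eff + m_eff))
    p = float(special.kolmogorov(lam))
    return DistTestResult(
        method="weighted_ks",
        statistic=d_thr,
        p_value=p,
        threshold_t=t,
        decision_at=alpha,
        reject=bool(d_thr >= crit),
        n_eff=(n_eff, m_eff),
        extra={"D": d, "critical_value": crit},
    )


def _stack_groups(samples: Sequence[WeightedSample]):
    xs, ys = [], []
    for g, s in enumerate(samples):
        v = np.asarray(s.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        xs.append(v)
        ys.append(np.full(v.shape[0], g))
    return xs, ys


def classifier_test(
    samples: Sequence[WeightedSample],
    spec: Optional[ClassifierSpec] = None,
    t: float = 0.0,
    alpha: float = 0.05,
) -> DistTestResult:
    """Classifier two-sample (or C-sample) test with an exact binomial null.

    Groups are downsampled to the smallest group size, a test split of
    ``test_fraction`` per class is held out, hyper-parameters are tuned by
    cross-validation on the learning split, and the number of correct test-set
    assignments Acc is referred to Binom(n_test, 1/C).  With an effect-size
    threshold the null becomes E[Acc] <= n_test/C + t, discretised as
    floor(t · n_test) extra allowed successes.
    """
    if spec is None:
        spec = ClassifierSpec()
    if t < 0:
        raise ValueError("effect-size threshold t must be >= 0")
    C = len(samples)
    if C < 2:
        raise ValueError("need at least two groups")
    xs, _ = _stack_groups(samples)
    rng = np.random.default_rng(spec.seed)

    n_min = min(v.shape[0] for v in xs)
    n_test_per = int(np.floor(spec.test_fraction * n_min))
    if n_test_per < 1 or n_min - n_test_per < spec.cv_folds:
        raise ValueError(
            f"groups too small to split (min group size {n_min}, "
            f"test fraction {spec.test_fraction})"
        )
    X_learn, y_learn, X_test, y_test = [], [], [], []
    for g, v in enumerate(xs):
        idx = rng.permutation(v.shape[0])[:n_min]  # downsample to common size
        test_idx, learn_idx = idx[:n_test_per], idx[n_test_per:]
        X_test.append(v[test_idx])
        X_learn.append(v[learn_idx])
        y_test.append(np.full(n_test_per, g))
        y_learn.append(np.full(learn_idx.size, g))
    X_learn = np.vstack(X_learn)
    y_learn = np.concatenate(y_learn)
    X_test = np.vstack(X_test)
    y_test = np.concatenate(y_test)
    n_test = X_test.shape[0]

    grid = list(spec.grid)
    if len(grid) == 1:
        best = grid[0]
    else:
        cv = StratifiedKFold(
            n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed
        )
        scores = []
        for param in grid:
            acc = 0
            for tr, va in cv.split(X_learn, y_learn):
                clf = spec.make(param)
                clf.fit(X_learn[tr], y_learn[tr])
                acc += np.sum(clf.predict(X_learn[va]) == y_learn[va])
            scores.append(acc)
        best = grid[int(np.argmax(scores))]

    clf = spec.make(best)
    clf.fit(X_learn, y_learn)
    acc = int(np.sum(clf.predict(X_test) == y_test))

    shift = int(np.floor(t * n_test))
    # P(Binom(n_test, 1/C) >= Acc - shift)
    p = float(stats.binom.sf(acc - shift - 1, n_test, 1.0 / C))
    p = min(p, 1.0)
    return DistTestResult(
        method="classifier",
        statistic=float(acc),
        p_value=p,
        threshold_t=t,
        decision_at=alpha,
        reject=bool(p <= alpha),
        n_test=n_test,
        extra={"classifier": spec.kind, "selected_param": best, "C": C},
    )


def _mmd2_from_kernel(K: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    n, m = idx1.size, idx2.size
    kxx = K[np.ix_(idx1, idx1)]
    kyy = K[np.ix_(idx2, idx2)]
    kxy = K[np.ix_(idx1, idx2)]
    sxx = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
    syy = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
    return float(sxx + syy - 2.0 * kxy.mean())


def mmd_test(
    sample1: WeightedSample,
    sample2: WeightedSample,
    n_permutations: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> DistTestResult:
    """Two-sample kernel test: unbiased MMD² with an RBF kernel (median
    pairwise-distance bandwidth) and a permutation p-value."""
    X = np.asarray(sample1.values, dtype=float)
    Y = np.asarray(sample2.values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = X.shape[0], Y.shape[0]
    if n < 2 or m < 2:
        raise ValueError("need at least 2 points per group")
    Z = np.vstack([X, Y])
    d2 = (
        np.sum(Z**2, axis=1)[:, None]
        + np.sum(Z**2, axis=1)[None, :]
        - 2.0 * Z @ Z.T
    )
    d = np.sqrt(np.maximum(d2, 0.0))
    med = np.median(d[np.triu_indices_from(d, k=1)])
    gamma = 1.0 / (2.0 * med**2) if med > 0 else 1.0
    K = np.exp(-gamma * np.maximum(d2, 0.0))

    obs = _mmd2_from_kernel(K, np.arange(n), np.arange(n, n + m))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n + m)
        if _mmd2_from_kernel(K, perm[:n], perm[n:]) >= obs:
            count += 1
    p = (count + 1.0) / (n_permutations + 1.0)
    return DistTestResult(
        method="mmd",
        statistic=obs,
        p_value=float(p),
        decision_at=alpha,
        reject=bool(p <= alpha),
        extra={"n_permutations": n_permutations, "bandwidth_median": float(med)},
    )


def stouffer_combine(
    p_values: Sequence[float],
    lineage_weights: Sequence[float],
    alpha: float = 0.05,
) -> DistTestResult:
    """Weighted Stouffer combination of per-lineage p-values.

    z_l = Phi^-1(1 - p_l), Z = Σ W_l z_l / sqrt(Σ W_l²), p = 1 - Phi(Z).
    The combination is invariant to positive rescaling of the weights.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(lineage_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("all-zero weights")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be in [0, 1]")
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    z = stats.norm.isf(p)
    Z = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    p_glob = float(stats.norm.sf(Z))
    return DistTestResult(
        method="stouffer",
        statistic=Z,
        p_value=p_glob,
        decision_at=alpha,
        reject=bool(p_glob <= alpha),
        extra={"per_lineage_p": [float(x) for x in p_values]},
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
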