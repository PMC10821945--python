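"""Per-cell imbalance score.

For each cell, the condition labels of its k nearest embedding neighbours are
compared against the global condition proportions p with a multinomial
likelihood-ratio statistic G = 2 Σ_c n_c log(n_c / (k p_c)).  Under local
balance G is approximately chi-squared with C - 1 degrees of freedom, so the
raw score is the moment-matched normal transform z = (G - (C-1)) / sqrt(2(C-1)).
Raw scores are then smoothed over the embedding with an additive cubic-spline
regression (s basis functions per dimension); the fitted values are the
imbalance scores.  The score is an exploratory diagnostic, not a formal test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .basis import SplineBasis

__all__ = ["ImbalanceScores", "imbalance_score"]


@dataclass
class ImbalanceScores:
    raw: np.ndarray
    smoothed: np.ndarray
    k: int
    s: int
    global_props: np.ndarray

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        n = self.raw.shape[0]
        ids = cell_ids if cell_ids is not None else [str(i) for i in range(n)]
        return pd.DataFrame({"cell_id": ids, "raw": self.raw, "smoothed": self.smoothed})


def imbalance_score(
    embedding: np.ndarray,
    conditions: np.ndarray,
    k: int = 10,
    s: int = 10,
) -> ImbalanceScores:
    """Compute raw and spline-smoothed imbalance scores.

    Parameters follow the workflow defaults k = s = 10.  Neighbourhoods
    exclude the cell itself; distance ties are broken by cell index.
    """
    X = np.asarray(embedding, dtype=float)
    labels = np.asarray(conditions).astype(str)
    n = X.shape[0]
    levels, codes = np.unique(labels, return_inverse=True)
    C = levels.size
    if C < 2:
        raise ValueError("single condition: imbalance score requires C >= 2")
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of cells {n}")

    p = np.bincount(codes, minlength=C) / n

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = idx[:, 1:]  # drop self (first neighbour at distance 0)

    onehot = np.eye(C)[codes]
    counts = onehot[neigh].sum(axis=1)  # n x C local condition counts
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / (k * p[None, :]))
    terms[counts == 0] = 0.0
    G = 2.0 * terms.sum(axis=1)
    raw = (G - (C - 1)) / np.sqrt(2.0 * (C - 1))

    # additive spline smoother over embedding coordinates
    cols = [np.ones((n, 1))]
    for d in range(X.shape[1]):
        B = SplineBasis(K=max(s, 4)).fit(X[:, d]).design(X[:, d])
        cols.append(B[:, 1:])  # drop one column per smooth to avoid confounding
    D = np.hstack(cols)
    ridge = 1e-8 * np.eye(D.shape[1])
    beta = np.linalg.solve(D.T @ D + ridge, D.T @ raw)
    smoothed = D @ beta
    return ImbalanceScores(raw=raw, smoothed=smoothed, k=k, s=s, global_props=p)
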