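"""Cubic B-spline regression bases with quantile knots.

Shared by the gene-expression smoothers and the imbalance-score smoothing.
A basis of size K is either the constant function (K = 1) or K cubic
B-splines whose K - 4 interior knots sit at quantiles of the fitting data;
K in {2, 3} cannot form a cubic basis and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis"]


@dataclass
class SplineBasis:
    """Evaluation rule for K cubic basis functions b_k with shared knots."""

    K: int = 6
    knots: Optional[np.ndarray] = None  # full knot vector after fit()
    bounds: Optional[tuple] = None
    eval_points: Optional[np.ndarray] = None  # K representative pseudotimes

    def fit(self, t: np.ndarray) -> "SplineBasis":
        t = np.asarray(t, dtype=float)
        lo, hi = float(np.min(t)), float(np.max(t))
        if hi <= lo:
            hi = lo + 1.0
        self.bounds = (lo, hi)
        if self.K == 1:
            self.knots = np.array([lo, hi])
        elif self.K >= 4:
            n_interior = self.K - 4
            if n_interior > 0:
                qs = np.linspace(0, 1, n_interior + 2)[1:-1]
                interior = np.quantile(t, qs)
            else:
                interior = np.array([])
            self.knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
        else:
            raise ValueError("K must be 1 (constant) or >= 4 (cubic B-splines)")
        # representative evaluation points: K quantiles of the fitting data
        self.eval_points = np.quantile(t, np.linspace(0, 1, self.K))
        return self

    def design(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the K basis functions at t (clipped to the fitted range)."""
        if self.knots is None:
            raise RuntimeError("basis not fitted; call fit() first")
        t = np.clip(np.asarray(t, dtype=float), *self.bounds)
        if self.K == 1:
            return np.ones((t.shape[0], 1))
        B = BSpline.design_matrix(t, self.knots, 3).toarray()
        assert B.shape[1] == self.K
        return B
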