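"""Additive piecewise-linear adaptive regression splines.

Forward pass greedily adds mirrored hinge pairs max(x_j - t, 0) /
max(t - x_j, 0) at candidate knots (feature quantiles), refitting by least
squares; the backward pass prunes terms by generalized cross-validation
(GCV). Capped at ``max_terms`` basis columns including the intercept.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

__all__ = ["AdaptiveRegressionSplines"]


class AdaptiveRegressionSplines:
    """MARS-style regressor: forward hinge selection + GCV backward pruning.

    Parameters
    ----------
    max_terms : int
        Maximum basis columns (intercept included).
    max_knots : int
        Candidate knots per feature (interior quantiles of training data).
    penalty : float
        GCV cost per knot (classical default 3 for hinge models).
    """

    def __init__(self, max_terms: int = 21, max_knots: int = 15,
                 penalty: float = 3.0, min_improvement: float = 1e-10):
        self.max_terms = max_terms
        self.max_knots = max_knots
        self.penalty = penalty
        self.min_improvement = min_improvement

    # each term: (feature_index, knot, sign) with sign +1 -> max(x-t,0), -1 -> max(t-x,0)
    def _basis(self, X: np.ndarray, terms) -> np.ndarray:
        cols = [np.ones(X.shape[0])]
        for j, t, sign in terms:
            h = sign * (X[:, j] - t)
            cols.append(np.maximum(h, 0.0))
        return np.column_stack(cols)

    def _gcv(self, sse: float, n: int, m: int) -> float:
        c = m + self.penalty * (m - 1) / 2.0
        denom = (1.0 - c / n) ** 2
        if denom <= 0:
            return np.inf
        return sse / n / denom

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AdaptiveRegressionSplines":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise DataError("X must be 2-D with one row per response value")
        n, p = X.shape
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Z = (X - self._mu) / self._sd
        knots = []
        for j in range(p):
            qs = np.unique(np.quantile(
                Z[:, j], np.linspace(0.05, 0.95, self.max_knots)))
            knots.append(qs)
        terms: list[tuple[int, float, int]] = []
        B = self._basis(Z, terms)
        beta, *_ = np.linalg.lstsq(B, y, rcond=None)
        sse = float(((y - B @ beta) ** 2).sum())
        # forward
        while len(terms) + 2 < self.max_terms:
            best = None
            for j in range(p):
                for t in knots[j]:
                    cand = terms + [(j, t, 1), (j, t, -1)]
                    Bc = self._basis(Z, cand)
                    bc, *_ = np.linalg.lstsq(Bc, y, rcond=None)
                    s = float(((y - Bc @ bc) ** 2).sum())
                    if best is None or s < best[0]:
                        best = (s, j, t)
            if best is None or sse - best[0] <= self.min_improvement * max(sse, 1.0):
                break
            sse = best[0]
            terms.extend([(best[1], best[2], 1), (best[1], best[2], -1)])
        # backward: drop terms while GCV improves
        def _fit_terms(ts):
            Bt = self._basis(Z, ts)
            bt, *_ = np.linalg.lstsq(Bt, y, rcond=None)
            return bt, float(((y - Bt @ bt) ** 2).sum())

        beta, sse = _fit_terms(terms)
        best_gcv = self._gcv(sse, n, len(terms) + 1)
        improved = True
        while improved and terms:
            improved = False
            for k in range(len(terms)):
                trial = terms[:k] + terms[k + 1:]
                _, s = _fit_terms(trial)
                g = self._gcv(s, n, len(trial) + 1)
                if g < best_gcv:
                    best_gcv = g
                    terms = trial
                    improved = True
                    break
        self.terms_ = terms
        self.coef_, self._sse = _fit_terms(terms)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self._mu) / self._sd
        return self._basis(Z, self.terms_) @ self.coef_
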