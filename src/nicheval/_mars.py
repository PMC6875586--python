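"""Adaptive hinge-basis (MARS-style) logistic fitter.

Classic two-stage construction: a forward pass greedily adds reflected
hinge pairs max(0, x - t) / max(0, t - x) chosen by least-squares residual
reduction, a backward pass prunes terms by the generalized cross-validation
(GCV) score, and the surviving basis is refit as a logistic regression so
predictions live on the probability scale. Additive (no hinge products) —
sufficient for smooth unimodal/multimodal niche responses and fast enough
to refit inside repeated hold-out loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression


@dataclass(frozen=True)
class _Hinge:
    var: int
    knot: float
    direction: int  # +1: max(0, x - t); -1: max(0, t - x)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        d = (X[:, self.var] - self.knot) * self.direction
        return np.maximum(d, 0.0)


def _design(hinges: list[_Hinge], X: np.ndarray) -> np.ndarray:
    cols = [np.ones(X.shape[0])]
    cols.extend(h.evaluate(X) for h in hinges)
    return np.column_stack(cols)


def _rss(B: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    r = y - B @ coef
    return float(r @ r)


def _gcv(rss: float, n: int, n_terms: int, penalty: float = 3.0) -> float:
    c = n_terms + penalty * (n_terms - 1) / 2.0
    denom = (1.0 - c / n) ** 2
    if denom <= 0:
        return np.inf
    return rss / n / denom


class MarsClassifier:
    """Hinge-spline logistic model with forward selection and GCV pruning.

    Parameters
    ----------
    max_terms
        Cap on hinge basis functions (excluding the intercept).
    n_knots
        Candidate knots per variable, placed at interior quantiles of the
        training data.
    """

    def __init__(self, max_terms: int = 14, n_knots: int = 10):
        self.max_terms = max_terms
        self.n_knots = n_knots
        self.hinges_: list[_Hinge] = []
        self._logit: LogisticRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MarsClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        qs = np.linspace(0.05, 0.95, self.n_knots)
        candidates: list[_Hinge] = []
        for j in range(p):
            knots = np.unique(np.quantile(X[:, j], qs))
            for t in knots:
                candidates.append(_Hinge(j, float(t), +1))
                candidates.append(_Hinge(j, float(t), -1))

        # forward pass: add reflected pairs while RSS improves
        hinges: list[_Hinge] = []
        best_rss = _rss(_design(hinges, X), y)
        while len(hinges) < self.max_terms:
            best: tuple[float, _Hinge, _Hinge] | None = None
            base = _design(hinges, X)
            for h in candidates:
                if h.direction != +1:
                    continue
                pair = (h, _Hinge(h.var, h.knot, -1))
                if any(g.var == h.var and g.knot == h.knot for g in hinges):
                    continue
                B = np.column_stack([base, pair[0].evaluate(X), pair[1].evaluate(X)])
                rss = _rss(B, y)
                if best is None or rss < best[0]:
                    best = (rss, *pair)
            if best is None or best[0] > best_rss * (1 - 1e-4):
                break
            best_rss = best[0]
            hinges.extend(best[1:])

        # backward pass: prune by GCV
        keep = list(hinges)
        best_gcv = _gcv(_rss(_design(keep, X), y), n, len(keep) + 1)
        improved = True
        while improved and keep:
            improved = False
            for i in range(len(keep)):
                trial = keep[:i] + keep[i + 1:]
                g = _gcv(_rss(_design(trial, X), y), n, len(trial) + 1)
                if g < best_gcv:
                    best_gcv = g
                    keep = trial
                    improved = True
                    break
        self.hinges_ = keep

        # logistic refit on the surviving basis (intercept handled by sklearn)
        B = _design(self.hinges_, X)[:, 1:]
        self._logit = LogisticRegression(C=1e3, max_iter=2000)
        if B.shape[1] == 0:
            B = np.zeros((n, 1))
        self._logit.fit(B, y.astype(int))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._logit is None:
            raise RuntimeError("MarsClassifier is not fitted")
        X = np.asarray(X, dtype=float)
        B = _design(self.hinges_, X)[:, 1:]
        if B.shape[1] == 0:
            B = np.zeros((X.shape[0], 1))
        return self._logit.predict_proba(B)[:, 1]
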