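"""Noise-aware discriminative training on probabilistic labels.

Given soft targets y-tilde in [0,1], the noise-aware loss is the expected
classification loss under those targets,

    sum_i [ y_i~ * l(s_i, +1) + (1 - y_i~) * l(s_i, -1) ],

with l the logistic loss and s_i the model score.  The expectation is
computed exactly by the two-term binary expansion (never by sampling).
With hard targets it reduces exactly to the ordinary supervised logistic
loss, so a fully supervised fit is the degenerate special case.

Training a discriminative model on these labels matters because it
generalizes beyond the labeling functions: the model attends to features
that merely co-occur with the heuristics' triggers, so it can classify
points on which every labeling function abstained.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin

from .matrix import as_votes

__all__ = [
    "noise_aware_loss",
    "NoiseAwareLogisticRegression",
    "fit_noise_aware_linear",
    "coverage_generalization_check",
]


def noise_aware_loss(scores, probs) -> float:
    """Total expected logistic loss of real-valued scores under soft labels.

    Reduces to the plain supervised logistic loss when every probability is
    0 or 1.
    """
    scores = np.asarray(scores, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if scores.shape != probs.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape}, probs {probs.shape}")
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilistic labels must lie in [0,1]")
    loss_pos = np.logaddexp(0.0, -scores)  # l(s, +1)
    loss_neg = np.logaddexp(0.0, scores)  # l(s, -1)
    return float(np.sum(probs * loss_pos + (1.0 - probs) * loss_neg))


class NoiseAwareLogisticRegression(BaseEstimator, ClassifierMixin):
    """Linear classifier trained by exact expected logistic loss.

    Minimizes ``noise_aware_loss + (l2/2) ||coef||^2`` (intercept
    unpenalized) by full-batch L-BFGS with an analytic gradient — a
    deterministic fit, reproducible without any seed.  ``fit`` accepts soft
    targets in [0,1]; hard labels in {-1,+1} or {0,1} are coerced.
    """

    def __init__(self, l2: float = 1e-4, fit_intercept: bool = True, max_iter: int = 1000, tol: float = 1e-12):
        self.l2 = l2
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) <= {-1.0, 1.0}:
            y = (y + 1.0) / 2.0  # hard labels in {-1,+1} -> probabilities
        if y.shape != (X.shape[0],):
            raise ValueError("one target per row required")
        if ((y < 0) | (y > 1)).any():
            raise ValueError("targets must lie in [0,1] (or {-1,+1})")
        m, d = X.shape
        if m < d:
            import warnings

            warnings.warn(f"fewer rows ({m}) than features ({d})", RuntimeWarning)

        k = d + 1 if self.fit_intercept else d

        def objective(theta):
            coef = theta[:d]
            intercept = theta[d] if self.fit_intercept else 0.0
            s = X @ coef + intercept
            loss_pos = np.logaddexp(0.0, -s)
            loss_neg = np.logaddexp(0.0, s)
            obj = float(np.sum(y * loss_pos + (1.0 - y) * loss_neg))
            obj += 0.5 * self.l2 * float(coef @ coef)
            # d/ds [y l(s,+1) + (1-y) l(s,-1)] = sigmoid(s) - y
            resid = 1.0 / (1.0 + np.exp(-s)) - y
            grad_coef = X.T @ resid + self.l2 * coef
            if self.fit_intercept:
                return obj, np.concatenate([grad_coef, [resid.sum()]])
            return obj, grad_coef

        res = minimize(
            objective,
            np.zeros(k),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.tol, "ftol": 1e-15},
        )
        self.coef_ = res.x[:d]
        self.intercept_ = float(res.x[d]) if self.fit_intercept else 0.0
        self.n_features_in_ = d
        self.classes_ = np.array([-1, 1])
        self.n_iter_ = res.nit
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def score(self, X, y) -> float:
        y = np.asarray(y)
        y = np.where(y > 0, 1, -1)
        return float(np.mean(self.predict(X) == y))


def fit_noise_aware_linear(X, probs, l2: float = 1e-4) -> NoiseAwareLogisticRegression:
    """Convenience wrapper: fit the linear model on soft targets."""
    probs = getattr(probs, "values", probs)
    return NoiseAwareLogisticRegression(l2=l2).fit(X, probs)


def coverage_generalization_check(L, gold, model, X) -> float:
    """Accuracy of a trained discriminative model on the rows where *every*
    labeling function abstained — the direct test that it generalizes
    beyond the labeling functions.
    """
    V = as_votes(L)
    gold = np.asarray(gold)
    X = np.asarray(X, dtype=float)
    uncovered = (V != 0).sum(axis=1) == 0
    count = int(uncovered.sum())
    if count == 0:
        raise ValueError("no rows where all labeling functions abstain (0 found)")
    return float(np.mean(model.predict(X[uncovered]) == gold[uncovered]))
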