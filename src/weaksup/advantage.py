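"""Majority vote or generative model?  The modeling-advantage optimizer.

The *modeling advantage* A_w measures how much a weighted vote (weights =
accuracy log-odds, i.e. a perfectly estimated generative model) improves on
the unweighted majority vote: the rate of correct disagreements minus
incorrect disagreements.  Closed-form bounds delimit when the advantage can
matter — it falls quadratically with expected label density d-bar at low
density and exponentially at high density — and an observable surrogate
A-tilde* upper-bounds the expected optimal advantage using only the label
matrix plus an assumed accuracy range.  The strategy optimizer computes
A-tilde* and, if it falls below the advantage tolerance gamma, skips model
fitting and emits majority-vote labels; otherwise it runs correlation
structure selection, fits the generative model, and emits its marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .label_model import (
    EXACT_LIMIT,
    FitConfig,
    ProbLabels,
    fit_cd,
    fit_exact,
    predict_marginals,
)
from .matrix import LabelMatrix, as_votes
from .structure import CorrelationSelector

__all__ = [
    "OptimizerConfig",
    "AdvantageReport",
    "majority_score",
    "weighted_score",
    "modeling_advantage",
    "label_density",
    "predicted_advantage",
    "low_density_bound",
    "high_density_bound",
    "choose_strategy",
    "StrategyOptimizer",
]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class OptimizerConfig:
    """Advantage tolerance and the assumed accuracy range of the sources.

    ``gamma`` is on the fraction scale (0.01 = one accuracy point).  The
    accuracy range maps to weight bounds by log-odds: w_min = logit(acc_min)
    etc.; sources are assumed non-adversarial (accuracies above 1/2).
    """

    gamma: float = 0.01
    acc_min: float = 0.55
    acc_max: float = 0.95
    acc_mean: float = 0.75

    def __post_init__(self):
        if not 0.5 < self.acc_min <= self.acc_mean <= self.acc_max < 1.0:
            raise ValueError("need 0.5 < acc_min <= acc_mean <= acc_max < 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    @property
    def w_min(self) -> float:
        return _logit(self.acc_min)

    @property
    def w_max(self) -> float:
        return _logit(self.acc_max)

    @property
    def w_mean(self) -> float:
        return _logit(self.acc_mean)


@dataclass
class AdvantageReport:
    """Summary the optimizer reports: density, predicted/realized advantage
    (fraction scale), density-regime bounds, and the MV/GM decision."""

    d_lambda: float
    a_tilde: float
    decision: str
    a_w: float | None = None
    low_bound: float | None = None
    high_bound: float | None = None
    gamma: float = 0.01
    n_pairs: int | None = None

    def to_dict(self) -> dict:
        out = {
            "label_density": self.d_lambda,
            "predicted_advantage": self.a_tilde,
            "predicted_advantage_pct": 100.0 * self.a_tilde,
            "decision": self.decision,
            "gamma": self.gamma,
        }
        if self.a_w is not None:
            out["realized_advantage"] = self.a_w
            out["realized_advantage_pct"] = 100.0 * self.a_w
        if self.low_bound is not None:
            out["low_density_bound"] = self.low_bound
        if self.high_bound is not None:
            out["high_density_bound"] = self.high_bound
        if self.n_pairs is not None:
            out["n_correlation_pairs"] = self.n_pairs
        return out


def majority_score(rows) -> np.ndarray | float:
    """Unweighted vote score f_1 = sum_j vote_j (abstain contributes 0)."""
    arr = np.asarray(rows)
    scores = arr.sum(axis=-1)
    return scores


def weighted_score(rows, w) -> np.ndarray | float:
    """Weighted vote score f_w = sum_j w_j * vote_j."""
    arr = np.asarray(rows, dtype=float)
    w = np.asarray(w, dtype=float)
    if arr.shape[-1] != w.shape[0]:
        raise ValueError(f"row width {arr.shape[-1]} != weight length {w.shape[0]}")
    return arr @ w


def modeling_advantage(L, gold, w) -> float:
    """A_w: rate of correct minus incorrect disagreements of the weighted
    vote against the unweighted majority vote.  A tie (score 0) counts as an
    incorrect prediction for either vote."""
    V = as_votes(L)
    gold = np.asarray(gold)
    if gold.shape != (V.shape[0],):
        raise ValueError("gold must have one label per row")
    if not np.isin(gold, (-1, 1)).all():
        raise ValueError("gold labels must lie in {-1,+1}")
    f_w = weighted_score(V, w)
    f_1 = majority_score(V)
    win = (gold * f_w > 0) & (gold * f_1 <= 0)
    lose = (gold * f_w <= 0) & (gold * f_1 > 0)
    return float(win.mean() - lose.mean())


def label_density(L) -> float:
    """d_Lambda: mean number of non-abstention votes per data point."""
    V = as_votes(L)
    if V.shape[0] == 0:
        return 0.0
    return float((V != 0).sum(axis=1).mean())


def predicted_advantage(L, config: OptimizerConfig | None = None) -> float:
    """The observable optimizer surrogate A-tilde*(Lambda).

    For each row and each class y, counts the (sigmoid-weighted) chance
    that a best-case weighted vote could flip a row the majority vote gets
    wrong, where the flip is only possible (Phi = 1) if the class-y votes
    at maximal weight outweigh the opposing votes at minimal weight:

        A-tilde* = (1/m) sum_i sum_y 1{y f_1 <= 0} Phi(row, y)
                   sigma(2 f_wbar(row) y)
    """
    config = config or OptimizerConfig()
    V = as_votes(L)
    m, n = V.shape
    if m == 0:
        raise ValueError("label matrix is empty")
    f_1 = majority_score(V)
    f_mean = config.w_mean * f_1.astype(float)  # equal weights: f_wbar = wbar * f_1
    c_pos = (V == 1).sum(axis=1)
    c_neg = (V == -1).sum(axis=1)
    total = np.zeros(m)
    for y, c_y, c_other in ((1, c_pos, c_neg), (-1, c_neg, c_pos)):
        mv_wrong = y * f_1 <= 0
        phi = c_y * config.w_max > c_other * config.w_min
        total += mv_wrong * phi * expit(2.0 * f_mean * y)
    return float(total.mean())


def low_density_bound(d_bar: float, alpha_bar: float) -> float:
    """Sparse-regime bound on the expected optimal advantage:
    d_bar^2 * alpha_bar * (1 - alpha_bar)."""
    if d_bar < 0:
        raise ValueError("d_bar must be >= 0")
    if not 0.5 < alpha_bar <= 1.0:
        raise ValueError("the bound assumes non-adversarial sources (alpha_bar > 1/2)")
    return d_bar**2 * alpha_bar * (1.0 - alpha_bar)


def high_density_bound(p_l: float, alpha_bar: float, d_bar: float) -> float:
    """Dense-regime (Hoeffding) bound: exp(-2 p_l (alpha_bar - 1/2)^2 d_bar)."""
    if not 0.5 < alpha_bar <= 1.0:
        raise ValueError("the bound assumes alpha_bar > 1/2")
    if not 0.0 <= p_l <= 1.0:
        raise ValueError("p_l must lie in [0, 1]")
    return float(np.exp(-2.0 * p_l * (alpha_bar - 0.5) ** 2 * d_bar))


def _majority_vote_labels(V: np.ndarray) -> np.ndarray:
    f_1 = majority_score(V)
    return np.where(f_1 > 0, 1.0, np.where(f_1 < 0, 0.0, 0.5))


def _choose_strategy_full(
    L,
    config: OptimizerConfig | None = None,
    structure_config: dict | None = None,
    fit_config: FitConfig | None = None,
    gold=None,
):
    config = config or OptimizerConfig()
    V = as_votes(L)
    if V.shape[0] == 0:
        raise ValueError("label matrix is empty")
    row_ids = L.row_ids if isinstance(L, LabelMatrix) else None
    a_tilde = predicted_advantage(V, config)
    report = AdvantageReport(
        d_lambda=label_density(V),
        a_tilde=a_tilde,
        decision="MV",
        gamma=config.gamma,
    )
    if a_tilde < config.gamma:
        labels = ProbLabels(values=_majority_vote_labels(V), row_ids=row_ids)
        return "MV", labels, report, None, None

    selector = CorrelationSelector(**(structure_config or {}))
    selector.fit(V)
    fit_config = fit_config or FitConfig()
    fitter = fit_exact if V.shape[1] <= fit_config.exact_limit else fit_cd
    params = fitter(V, deps=selector.dependencies_, config=fit_config)
    labels = predict_marginals(params, V)
    labels.row_ids = row_ids
    report.decision = "GM"
    report.n_pairs = len(selector.dependencies_)
    if gold is not None:
        report.a_w = modeling_advantage(V, gold, params.w_acc)
    return "GM", labels, report, params, selector


def choose_strategy(
    L,
    config: OptimizerConfig | None = None,
    structure_config: dict | None = None,
    fit_config: FitConfig | None = None,
    gold=None,
):
    """The two-stage optimization: majority vote when the predicted
    advantage is below gamma, otherwise structure selection + generative
    model.

    Returns ``(decision, ProbLabels, AdvantageReport)``.  With ``gold``
    given and the generative branch taken, the report includes the realized
    advantage of the fitted weights.
    """
    decision, labels, report, _, _ = _choose_strategy_full(
        L,
        config=config,
        structure_config=structure_config,
        fit_config=fit_config,
        gold=gold,
    )
    return decision, labels, report


class StrategyOptimizer(BaseEstimator):
    """Estimator facade over :func:`choose_strategy`.

    After ``fit``: ``decision_`` ("MV" or "GM"), ``report_``,
    ``prob_labels_`` and, on the GM branch, ``params_``/``dependencies_``
    via the internal fit.  ``predict_proba`` re-scores new rows under the
    chosen strategy.
    """

    def __init__(
        self,
        gamma: float = 0.01,
        acc_min: float = 0.55,
        acc_max: float = 0.95,
        acc_mean: float = 0.75,
        structure_config: dict | None = None,
        fit_config: FitConfig | None = None,
        seed: int = 0,
    ):
        self.gamma = gamma
        self.acc_min = acc_min
        self.acc_max = acc_max
        self.acc_mean = acc_mean
        self.structure_config = structure_config
        self.fit_config = fit_config
        self.seed = seed

    def fit(self, L, y=None):
        config = OptimizerConfig(
            gamma=self.gamma,
            acc_min=self.acc_min,
            acc_max=self.acc_max,
            acc_mean=self.acc_mean,
        )
        fit_config = self.fit_config or FitConfig(seed=self.seed)
        structure_config = dict(self.structure_config or {})
        structure_config.setdefault("seed", self.seed)
        (
            self.decision_,
            self.prob_labels_,
            self.report_,
            self.params_,
            selector,
        ) = _choose_strategy_full(
            L,
            config=config,
            structure_config=structure_config,
            fit_config=fit_config,
            gold=y,
        )
        self.dependencies_ = selector.dependencies_ if selector is not None else None
        self.classes_ = np.array([-1, 1])
        return self

    def predict_proba(self, L) -> np.ndarray:
        V = as_votes(L)
        if self.decision_ == "MV":
            p = _majority_vote_labels(V)
        else:
            p = predict_marginals(self.params_, V).values
        return np.column_stack([1.0 - p, p])

    def predict(self, L) -> np.ndarray:
        return np.where(self.predict_proba(L)[:, 1] >= 0.5, 1, -1)
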