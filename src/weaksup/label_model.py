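"""Generative model of labeling-function votes with a latent binary label.

The joint model over a vote row lambda in {-1,0,+1}^n and class y in {-1,+1}
is log-linear in three indicator factor families:

* propensity  phi_lab_j  = 1{lambda_j != 0}
* accuracy    phi_acc_j  = 1{lambda_j == y}
* correlation phi_corr_jk = 1{lambda_j == lambda_k}   for modeled pairs (j,k)

Weights are learned *without ground truth* by minimizing the negative log
marginal likelihood of the observed label matrix, either by exact
enumeration of the 2*3^n configuration table (small n; the test oracle) or
by stochastic gradient with persistent Gibbs chains for the model
expectation (contrastive-divergence style).  The class posterior has the
closed form p(y=+1 | lambda) = logistic(sum_j w_acc_j * lambda_j): the
propensity and correlation factors do not involve y and cancel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .matrix import LabelMatrix, as_votes

__all__ = [
    "DependencySet",
    "GenerativeParams",
    "FitConfig",
    "ProbLabels",
    "factor_vector",
    "log_partition_exact",
    "nll_marginal",
    "fit_exact",
    "fit_cd",
    "gibbs_sweep",
    "predict_marginals",
    "weights_to_accuracy",
    "LabelModel",
]

EXACT_LIMIT = 10  # 2 * 3^10 ~ 1.2e5 configurations: cheap enough to enumerate


@dataclass(frozen=True)
class DependencySet:
    """Unordered labeling-function pairs modeled as correlated."""

    pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        norm = []
        seen = set()
        for j, k in self.pairs:
            j, k = int(j), int(k)
            if j == k:
                raise ValueError(f"self-pair ({j},{k})")
            if j > k:
                j, k = k, j
            if (j, k) in seen:
                raise ValueError(f"duplicate pair ({j},{k})")
            seen.add((j, k))
            norm.append((j, k))
        object.__setattr__(self, "pairs", tuple(sorted(norm)))

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, n: int) -> None:
        for j, k in self.pairs:
            if not (0 <= j < n and 0 <= k < n):
                raise ValueError(f"pair ({j},{k}) out of range for n={n}")


@dataclass
class GenerativeParams:
    """Weight vector of length 2n + |C|, segmented into factor blocks."""

    n: int
    deps: DependencySet
    w_lab: np.ndarray
    w_acc: np.ndarray
    w_corr: np.ndarray

    def __post_init__(self):
        self.w_lab = np.asarray(self.w_lab, dtype=float)
        self.w_acc = np.asarray(self.w_acc, dtype=float)
        self.w_corr = np.asarray(self.w_corr, dtype=float)
        self.deps.validate(self.n)
        if self.w_lab.shape != (self.n,) or self.w_acc.shape != (self.n,):
            raise ValueError("propensity/accuracy blocks must have length n")
        if self.w_corr.shape != (len(self.deps),):
            raise ValueError("correlation block must have length |C|")
        for block in (self.w_lab, self.w_acc, self.w_corr):
            if not np.isfinite(block).all():
                raise ValueError("weights must be finite")

    @property
    def w(self) -> np.ndarray:
        return np.concatenate([self.w_lab, self.w_acc, self.w_corr])

    @classmethod
    def from_vector(cls, w: np.ndarray, n: int, deps: DependencySet) -> "GenerativeParams":
        w = np.asarray(w, dtype=float)
        if w.shape != (2 * n + len(deps),):
            raise ValueError("weight vector length must be 2n + |C|")
        return cls(n=n, deps=deps, w_lab=w[:n], w_acc=w[n : 2 * n], w_corr=w[2 * n :])

    def accuracies(self) -> np.ndarray:
        return weights_to_accuracy(self.w_acc)

    # -- versioned JSON round-trip ----------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "format": "weaksup-label-model",
            "version": 1,
            "n": self.n,
            "deps": [list(p) for p in self.deps.pairs],
            "w_lab": self.w_lab.tolist(),
            "w_acc": self.w_acc.tolist(),
            "w_corr": self.w_corr.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GenerativeParams":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "weaksup-label-model":
            raise ValueError("not a weaksup label-model file")
        return cls(
            n=payload["n"],
            deps=DependencySet(tuple((j, k) for j, k in payload["deps"])),
            w_lab=np.array(payload["w_lab"]),
            w_acc=np.array(payload["w_acc"]),
            w_corr=np.array(payload["w_corr"]),
        )


@dataclass
class FitConfig:
    """Learning schedule.  ``seed`` fixes all randomness (restart jitter,
    Gibbs chains); ``exact_limit`` caps the enumerable model size."""

    mode: str = "auto"  # "exact" | "cd" | "auto"
    epochs: int = 800
    step_size: float = 1.0
    l2_penalty: float = 1e-4
    burn_in: int = 10
    samples_per_step: int = 2
    seed: int = 0
    exact_limit: int = EXACT_LIMIT
    max_iter: int = 500
    grad_tol: float = 1e-6
    n_restarts: int = 4
    init_accuracy: float = 0.7
    chains_per_100: int = 1
    min_chains: int = 50
    warmup_frac: float = 0.6
    tail_average: float = 0.25

    def __post_init__(self):
        if self.mode not in ("exact", "cd", "auto"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be >= 0")
        if self.epochs < 1 or self.max_iter < 1:
            raise ValueError("epochs/max_iter must be >= 1")
        if not 0.5 < self.init_accuracy < 1.0:
            raise ValueError("init_accuracy must lie in (0.5, 1)")


@dataclass
class ProbLabels:
    """Per-candidate posterior probabilities p(y_i = +1 | row i)."""

    values: np.ndarray
    row_ids: list[str] | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("probabilistic labels must be a vector in [0,1]")


# ---------------------------------------------------------------------------
# factor algebra
# ---------------------------------------------------------------------------

def _factor_blocks(V: np.ndarray, deps: DependencySet):
    """Indicator blocks for a vote array V (m, n): Lab, Acc(+), Acc(-), Corr."""
    lab = (V != 0).astype(float)
    a_pos = (V == 1).astype(float)
    a_neg = (V == -1).astype(float)
    if len(deps):
        jj = np.array([p[0] for p in deps.pairs])
        kk = np.array([p[1] for p in deps.pairs])
        corr = (V[:, jj] == V[:, kk]).astype(float)
    else:
        corr = np.zeros((V.shape[0], 0))
    return lab, a_pos, a_neg, corr


def factor_vector(row, y: int, deps: DependencySet | None = None) -> np.ndarray:
    """Concatenated (propensity, accuracy, correlation) indicators for one row.

    Joint abstention counts as agreement for the correlation factor: the
    indicator 1{lambda_j == lambda_k} is taken literally.
    """
    deps = deps or DependencySet()
    row = np.asarray(row)
    if row.ndim != 1:
        raise ValueError("row must be 1-D")
    if not np.isin(row, (-1, 0, 1)).all():
        raise ValueError("votes must lie in {-1,0,+1}")
    if y not in (-1, 1):
        raise ValueError("y must be -1 or +1")
    deps.validate(row.size)
    lab, a_pos, a_neg, corr = _factor_blocks(row[None, :], deps)
    acc = a_pos if y == 1 else a_neg
    return np.concatenate([lab[0], acc[0], corr[0]])


@lru_cache(maxsize=8)
def _enumerate_votes(n: int) -> np.ndarray:
    """All 3^n vote rows over {-1,0,+1}, as an int8 array."""
    idx = np.arange(3**n, dtype=np.int64)
    digits = (idx[:, None] // 3 ** np.arange(n, dtype=np.int64)) % 3
    return (digits - 1).astype(np.int8)


def _exact_scores(params: GenerativeParams):
    """Unnormalized log-scores of every (lambda, y) configuration."""
    V = _enumerate_votes(params.n)
    lab, a_pos, a_neg, corr = _factor_blocks(V, params.deps)
    base = lab @ params.w_lab + corr @ params.w_corr
    s_pos = base + a_pos @ params.w_acc
    s_neg = base + a_neg @ params.w_acc
    return V, lab, a_pos, a_neg, corr, s_pos, s_neg


def _check_exact(n: int, limit: int = EXACT_LIMIT) -> None:
    if n > limit:
        raise ValueError(
            f"exact enumeration supports n <= {limit} (got n={n}); use mode='cd'"
        )


def log_partition_exact(params: GenerativeParams, limit: int = EXACT_LIMIT) -> float:
    """log Z: log of sum over all lambda in {-1,0,+1}^n, y in {-1,+1} of
    exp(w . phi(lambda, y)), by direct enumeration."""
    _check_exact(params.n, limit)
    *_, s_pos, s_neg = _exact_scores(params)
    return float(logsumexp(np.concatenate([s_pos, s_neg])))


def _data_terms(params: GenerativeParams, V: np.ndarray):
    lab, a_pos, a_neg, corr = _factor_blocks(V, params.deps)
    base = lab @ params.w_lab + corr @ params.w_corr
    margin = V @ params.w_acc  # s(+1) - s(-1)
    s_pos = base + a_pos @ params.w_acc
    s_neg = base + a_neg @ params.w_acc
    return lab, a_pos, a_neg, corr, margin, s_pos, s_neg


def nll_marginal(params: GenerativeParams, L, l2_penalty: float = 0.0) -> float:
    """Negative log marginal likelihood of the observed label matrix:
    -sum_i log sum_y exp(w . phi_i(y)) + m log Z (+ optional L2 term)."""
    V = as_votes(L)
    if V.shape[0] == 0:
        raise ValueError("label matrix is empty")
    if V.shape[1] != params.n:
        raise ValueError(f"matrix has n={V.shape[1]}, model has n={params.n}")
    *_, s_pos, s_neg = _data_terms(params, V)
    log_z = log_partition_exact(params)
    nll = -float(np.logaddexp(s_pos, s_neg).sum()) + V.shape[0] * log_z
    return nll + l2_penalty * float(params.w @ params.w)


def _objective_and_grad(w, n, deps, V, blocks, l2):
    """Per-datapoint NLL + (l2/2)||w||^2 and its exact gradient."""
    params = GenerativeParams.from_vector(w, n, deps)
    lab, a_pos, a_neg, corr = blocks
    m = V.shape[0]
    base = lab @ params.w_lab + corr @ params.w_corr
    margin = V @ params.w_acc  # log-odds s(+1) - s(-1)
    s_neg = base + a_neg @ params.w_acc
    ll_rows = np.logaddexp(s_neg + margin, s_neg)  # log(e^{s+} + e^{s-})
    p = expit(margin)

    # model expectation by enumeration
    _, e_lab, e_ap, e_an, e_corr, s_pos_e, s_neg_e = _exact_scores(params)
    all_scores = np.concatenate([s_pos_e, s_neg_e])
    log_z = logsumexp(all_scores)
    probs = np.exp(all_scores - log_z)
    q_pos, q_neg = probs[: len(s_pos_e)], probs[len(s_pos_e) :]
    q_cfg = q_pos + q_neg
    model_lab = q_cfg @ e_lab
    model_corr = q_cfg @ e_corr
    model_acc = q_pos @ e_ap + q_neg @ e_an

    data_lab = lab.mean(axis=0)
    data_corr = corr.mean(axis=0)
    data_acc = (p[:, None] * a_pos + (1.0 - p)[:, None] * a_neg).mean(axis=0)

    obj = -float(ll_rows.mean()) + float(log_z) + 0.5 * l2 * float(w @ w)
    grad = np.concatenate(
        [model_lab - data_lab, model_acc - data_acc, model_corr - data_corr]
    ) + l2 * w
    return obj, grad


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _canonicalize(params: GenerativeParams) -> GenerativeParams:
    """Resolve the latent-class relabeling symmetry.

    The marginal likelihood is invariant under (w_lab, w_acc) ->
    (w_lab + w_acc, -w_acc), which swaps the meaning of the latent classes.
    Following the non-adversarial convention (labeling functions are
    better than chance on average), the orientation with nonnegative mean
    accuracy weight is returned.
    """
    if params.w_acc.mean() < 0:
        return GenerativeParams(
            n=params.n,
            deps=params.deps,
            w_lab=params.w_lab + params.w_acc,
            w_acc=-params.w_acc,
            w_corr=params.w_corr.copy(),
        )
    return params


def fit_exact(L, deps: DependencySet | None = None, config: FitConfig | None = None) -> GenerativeParams:
    """Maximum (marginal) likelihood by L-BFGS over the enumerated model.

    The marginal likelihood is multimodal (e.g. the class-flip mode), so the
    optimizer runs from a deterministic better-than-chance initialization
    plus seeded jittered restarts and keeps the best objective.
    """
    deps = deps or DependencySet()
    config = config or FitConfig()
    V = as_votes(L)
    m, n = V.shape
    if m == 0:
        raise ValueError("label matrix is empty")
    deps.validate(n)
    _check_exact(n, config.exact_limit)
    blocks = _factor_blocks(V, deps)

    rng = np.random.default_rng(config.seed)
    w0 = np.zeros(2 * n + len(deps))
    w0[n : 2 * n] = _logit(config.init_accuracy)
    starts = [w0]
    for _ in range(max(0, config.n_restarts - 1)):
        jitter = np.zeros_like(w0)
        jitter[n : 2 * n] = rng.normal(scale=1.0, size=n)
        starts.append(w0 + jitter)

    best = None
    for start in starts:
        res = minimize(
            _objective_and_grad,
            start,
            args=(n, deps, V, blocks, config.l2_penalty),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.max_iter, "gtol": config.grad_tol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if np.max(np.abs(best.jac)) > 1e-4:
        warnings.warn(
            f"fit_exact did not fully converge (grad inf-norm {np.max(np.abs(best.jac)):.2e}); "
            "returning best iterate",
            RuntimeWarning,
        )
    return _canonicalize(GenerativeParams.from_vector(best.x, n, deps))


# ---------------------------------------------------------------------------
# Gibbs / contrastive-divergence fitting
# ---------------------------------------------------------------------------

def gibbs_sweep(params: GenerativeParams, state, clamp_votes: bool = False, rng=None):
    """One full-conditional resampling pass over (lambda, y) chain states.

    ``state`` is a ``(votes, y)`` pair of arrays with shapes (k, n) and (k,);
    it is updated in place and returned.  With ``clamp_votes`` the vote
    entries are held fixed and only y is resampled.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    votes, y = state
    k, n = votes.shape
    if n != params.n:
        raise ValueError("state width does not match model")
    neighbors: dict[int, list[tuple[int, float]]] = {j: [] for j in range(n)}
    for (j, kk), wc in zip(params.deps.pairs, params.w_corr):
        neighbors[j].append((kk, wc))
        neighbors[kk].append((j, wc))

    if not clamp_votes:
        for j in range(n):
            scores = np.zeros((k, 3))  # columns: v = -1, 0, +1
            for col, v in ((0, -1), (2, 1)):
                scores[:, col] = params.w_lab[j] + params.w_acc[j] * (y == v)
            for other, wc in neighbors[j]:
                for col, v in ((0, -1), (1, 0), (2, 1)):
                    scores[:, col] += wc * (votes[:, other] == v)
            scores -= scores.max(axis=1, keepdims=True)
            probs = np.exp(scores)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(k)
            choice = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
            votes[:, j] = choice - 1
    p_pos = expit(votes @ params.w_acc)
    y[:] = np.where(rng.random(k) < p_pos, 1, -1)
    return votes, y


def fit_cd(L, deps: DependencySet | None = None, config: FitConfig | None = None) -> GenerativeParams:
    """Stochastic gradient on the marginal likelihood, interleaving parameter
    steps with Gibbs sweeps on persistent negative chains.

    The data-side ("positive") expectation is computed exactly — the only
    latent variable given a row is y, whose conditional is closed-form — so
    sampling is needed only for the model-side expectation.  Step size decays
    as 1/sqrt(t) and the returned weights are the average of the final
    quarter of iterates, which damps chain noise.
    """
    deps = deps or DependencySet()
    config = config or FitConfig()
    V = as_votes(L)
    m, n = V.shape
    if m == 0:
        raise ValueError("label matrix is empty")
    deps.validate(n)
    lab, a_pos, a_neg, corr = _factor_blocks(V, deps)
    data_lab = lab.mean(axis=0)
    data_corr = corr.mean(axis=0)

    rng = np.random.default_rng(config.seed)
    n_chains = max(config.min_chains, (m * config.chains_per_100) // 100)
    chain_votes = rng.integers(-1, 2, size=(n_chains, n)).astype(np.int8)
    chain_y = np.where(rng.random(n_chains) < 0.5, 1, -1).astype(np.int8)

    w = np.zeros(2 * n + len(deps))
    w[n : 2 * n] = _logit(config.init_accuracy)
    params = GenerativeParams.from_vector(w, n, deps)
    for _ in range(config.burn_in):
        gibbs_sweep(params, (chain_votes, chain_y), rng=rng)

    jj = np.array([p[0] for p in deps.pairs], dtype=int)
    kk = np.array([p[1] for p in deps.pairs], dtype=int)
    tail_start = int(np.ceil(config.epochs * (1.0 - config.tail_average)))
    warmup = int(config.epochs * config.warmup_frac)
    tail_sum = np.zeros_like(w)
    tail_count = 0
    for t in range(1, config.epochs + 1):
        params = GenerativeParams.from_vector(w, n, deps)
        for _ in range(config.samples_per_step):
            gibbs_sweep(params, (chain_votes, chain_y), rng=rng)
        p = expit(V @ params.w_acc)
        pos_acc = (p[:, None] * a_pos + (1.0 - p)[:, None] * a_neg).mean(axis=0)
        neg_lab = (chain_votes != 0).mean(axis=0)
        neg_acc = (chain_votes == chain_y[:, None]).mean(axis=0)
        neg_corr = (
            (chain_votes[:, jj] == chain_votes[:, kk]).mean(axis=0)
            if len(deps)
            else np.zeros(0)
        )
        grad = (
            np.concatenate([data_lab - neg_lab, pos_acc - neg_acc, data_corr - neg_corr])
            - config.l2_penalty * w
        )
        # flat warmup, then 1/sqrt decay: the landscape is ill-conditioned and
        # a decaying-from-the-start schedule stalls far from the optimum
        step = config.step_size / np.sqrt(max(1, t - warmup))
        w += step * grad
        if t >= tail_start:
            tail_sum += w
            tail_count += 1
    return _canonicalize(GenerativeParams.from_vector(tail_sum / tail_count, n, deps))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_marginals(params: GenerativeParams, L) -> ProbLabels:
    """Posterior p(y_i = +1 | row i) = logistic(sum_j w_acc_j * vote_ij).

    Abstentions contribute zero; an all-abstain row yields exactly 0.5.
    """
    V = as_votes(L)
    if V.shape[1] != params.n:
        raise ValueError(f"matrix has n={V.shape[1]}, model has n={params.n}")
    row_ids = L.row_ids if isinstance(L, LabelMatrix) else None
    return ProbLabels(values=expit(V @ params.w_acc), row_ids=row_ids)


def weights_to_accuracy(w):
    """Map an accuracy weight (log-odds) to the implied accuracy alpha = logistic(w)."""
    return expit(np.asarray(w, dtype=float))


class LabelModel(BaseEstimator):
    """Scikit-learn style wrapper around the generative label model.

    ``fit`` takes only the label matrix (votes in {-1,0,+1}; no ground
    truth).  ``predict_proba`` returns columns ordered as ``classes_``
    = (-1, +1).
    """

    def __init__(
        self,
        deps=None,
        mode: str = "auto",
        epochs: int = 500,
        step_size: float = 0.05,
        l2_penalty: float = 1e-4,
        burn_in: int = 10,
        samples_per_step: int = 2,
        exact_limit: int = EXACT_LIMIT,
        n_restarts: int = 4,
        init_accuracy: float = 0.7,
        seed: int = 0,
    ):
        self.deps = deps
        self.mode = mode
        self.epochs = epochs
        self.step_size = step_size
        self.l2_penalty = l2_penalty
        self.burn_in = burn_in
        self.samples_per_step = samples_per_step
        self.exact_limit = exact_limit
        self.n_restarts = n_restarts
        self.init_accuracy = init_accuracy
        self.seed = seed

    def _config(self) -> FitConfig:
        return FitConfig(
            mode=self.mode,
            epochs=self.epochs,
            step_size=self.step_size,
            l2_penalty=self.l2_penalty,
            burn_in=self.burn_in,
            samples_per_step=self.samples_per_step,
            exact_limit=self.exact_limit,
            n_restarts=self.n_restarts,
            init_accuracy=self.init_accuracy,
            seed=self.seed,
        )

    def fit(self, L, y=None):
        V = as_votes(L)
        deps = self.deps if isinstance(self.deps, DependencySet) else DependencySet(tuple(self.deps or ()))
        config = self._config()
        mode = config.mode
        if mode == "auto":
            mode = "exact" if V.shape[1] <= config.exact_limit else "cd"
        fitter = fit_exact if mode == "exact" else fit_cd
        self.params_ = fitter(V, deps=deps, config=config)
        self.accuracies_ = self.params_.accuracies()
        self.n_features_in_ = V.shape[1]
        self.classes_ = np.array([-1, 1])
        return self

    def predict_proba(self, L) -> np.ndarray:
        p = predict_marginals(self.params_, L).values
        return np.column_stack([1.0 - p, p])

    def predict(self, L) -> np.ndarray:
        p = predict_marginals(self.params_, L).values
        return np.where(p >= 0.5, 1, -1)

    def score(self, L, y) -> float:
        return float(np.mean(self.predict(L) == np.asarray(y)))
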