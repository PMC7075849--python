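"""Selection of correlated labeling-function pairs.

Which pairs (j, k) should the generative model treat as correlated?  The
estimator here scores each pair with an L1-penalized *marginal
pseudolikelihood*: the sum, over labeling functions j, of the conditional
log-likelihood of j's votes given all other votes, under a model with the
same factor families as the generative model — propensity, per-LF
accuracy, and pairwise agreement — with the latent class summed out and
the parameters shared across all n conditionals.  The objective and its
gradient are exact (a 3 x 2 table per row; no sampling).

Two design points matter:

* Marginalizing a *shared* latent class is essential: conditionally
  independent labeling functions are strongly correlated marginally (they
  all track the truth), and the class channel absorbs exactly that
  component, so the agreement coefficients pick up only dependence beyond
  the class.
* The class channel is capacity-bounded: accuracy weights are box-
  constrained (default |w| <= 5, i.e. implied accuracy <= ~99.3%).  This
  encodes the non-degeneracy assumption that no real source is arbitrarily
  close to perfect.  Without it, a perfectly correlated block of sources
  can impersonate the class variable and explain its own agreement exactly,
  zeroing the correlation coefficients — the same failure mode that
  corrupts the independence-assuming generative model in the first place.
  With the bound, agreement of exactly 1 always leaves a residual that
  only the correlation channel can absorb.

Pairs are then thresholded at epsilon.  Sweeping epsilon over a descending
grid yields a nested path of pair sets whose size explodes below some
point; the "elbow" — the grid point with the greatest absolute count
difference from its neighbors — is chosen as the operating threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .label_model import DependencySet
from .matrix import as_votes

__all__ = [
    "StructureConfig",
    "CorrelationPath",
    "dependency_scores",
    "select_correlations",
    "correlation_path",
    "select_elbow",
    "CorrelationSelector",
]


@dataclass
class StructureConfig:
    """Threshold grid and penalty for pair selection.

    ``epsilon_grid`` must be strictly decreasing; if omitted, 25
    log-spaced thresholds spanning the observed score range are used.
    """

    epsilon_grid: tuple[float, ...] | None = None
    grid_size: int = 25
    l1_strength: float = 0.01
    max_pairs: int | None = None

    def __post_init__(self):
        if self.epsilon_grid is not None:
            grid = tuple(float(e) for e in self.epsilon_grid)
            if any(e <= 0 for e in grid):
                raise ValueError("epsilon thresholds must be positive")
            if any(a <= b for a, b in zip(grid, grid[1:])):
                raise ValueError("epsilon_grid must be strictly decreasing")
            self.epsilon_grid = grid
        if self.l1_strength < 0:
            raise ValueError("l1_strength must be >= 0")
        if self.grid_size < 3:
            raise ValueError("grid must have at least 3 points")


@dataclass
class CorrelationPath:
    """Per-threshold records of (epsilon, pair count, selected pairs)."""

    records: list[tuple[float, int, DependencySet]] = field(default_factory=list)

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([r[0] for r in self.records])

    @property
    def counts(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])

    def at(self, epsilon: float) -> DependencySet:
        for eps, _, deps in self.records:
            if eps == epsilon:
                return deps
        raise KeyError(f"epsilon {epsilon} not on the path")


_NZ = np.array([1.0, 0.0, 1.0])  # 1{v != 0} per vote state (-1, 0, +1)
# 1{v == y}: rows index v in (-1, 0, +1), columns index y in (+1, -1)
_EYE_VY = np.array([[0.0, 1.0], [0.0, 0.0], [1.0, 0.0]])


def _joint_pseudolikelihood_fit(
    V: np.ndarray,
    l1: float,
    acc_bound: float = 5.0,
    max_iter: int = 400,
    n_restarts: int = 6,
    seed: int = 0,
) -> np.ndarray:
    """Fit the shared-parameter marginal pseudolikelihood; return the
    pairwise agreement coefficients as a symmetric (n, n) array.

    Parameters are one propensity and one (box-bounded) accuracy weight per
    LF plus one L1-penalized agreement coefficient per unordered pair,
    shared across all n per-LF conditionals.  The L1 term is handled by the
    standard positive/negative split so L-BFGS-B box constraints apply.
    """
    m, n = V.shape
    n_pairs = n * (n - 1) // 2
    pair_index: dict[tuple[int, int], int] = {}
    for j in range(n):
        for k in range(j + 1, n):
            pair_index[(j, k)] = len(pair_index)

    rows = np.arange(m)
    per_lf = []
    for j in range(n):
        others = [k for k in range(n) if k != j]
        O = V[:, others]
        vote_mask = np.stack([(O == v).astype(float) for v in (-1, 0, 1)], axis=1)
        per_lf.append(
            (
                others,
                vote_mask,  # (m, 3, n-1)
                (O == 1).astype(float),
                (O == -1).astype(float),
                V[:, j] + 1,  # observed vote as index 0,1,2
                np.array([pair_index[(min(j, k), max(j, k))] for k in others]),
            )
        )

    def objective(theta):
        lab = theta[:n]
        acc = theta[n : 2 * n]
        pos_part = theta[2 * n : 2 * n + n_pairs]
        neg_part = theta[2 * n + n_pairs :]
        corr = pos_part - neg_part
        obj = l1 * (pos_part.sum() + neg_part.sum())
        g_lab = np.zeros(n)
        g_acc = np.zeros(n)
        g_corr = np.zeros(n_pairs)
        for j in range(n):
            others, vote_mask, o_pos, o_neg, obs_idx, pair_ids = per_lf[j]
            a = np.stack([o_pos @ acc[others], o_neg @ acc[others]], axis=1)  # (m, 2)
            base = np.einsum("mvk,k->mv", vote_mask, corr[pair_ids]) + lab[j] * _NZ
            S = base[:, :, None] + acc[j] * _EYE_VY[None, :, :] + a[:, None, :]
            flat = S.reshape(m, 6)
            log_norm = logsumexp(flat, axis=1)
            g = logsumexp(S, axis=2)  # (m, 3): log-score of each vote state
            obj -= float((g[rows, obs_idx] - log_norm).mean())

            R = np.exp(flat - log_norm[:, None]).reshape(m, 3, 2)  # joint (v, y)
            q_v = R.sum(axis=2)
            cond_y = np.exp(S - g[:, :, None])  # p(y | v)
            cond_obs = cond_y[rows, obs_idx, :]
            r_y = R.sum(axis=1)
            g_lab[j] -= float((_NZ[obs_idx] - q_v @ _NZ).mean())
            d_accj = (_EYE_VY[obs_idx] * cond_obs).sum(axis=1) - np.einsum(
                "mvy,vy->m", R, _EYE_VY
            )
            g_acc[j] -= float(d_accj.mean())
            d_rows = cond_obs - r_y
            g_acc[others] -= (o_pos.T @ d_rows[:, 0] + o_neg.T @ d_rows[:, 1]) / m
            d_corr = (
                vote_mask[rows, obs_idx, :].sum(axis=0)
                - np.einsum("mv,mvk->k", q_v, vote_mask)
            ) / m
            np.add.at(g_corr, pair_ids, -d_corr)
        grad = np.concatenate([g_lab, g_acc, g_corr + l1, -g_corr + l1])
        return obj, grad

    theta0 = np.zeros(2 * n + 2 * n_pairs)
    theta0[n : 2 * n] = np.log(0.7 / 0.3)
    bounds = (
        [(None, None)] * n
        + [(-acc_bound, acc_bound)] * n
        + [(0.0, None)] * (2 * n_pairs)
    )
    # The objective is multimodal: a strongly correlated block of sources
    # creates a basin where it impersonates the latent class.  Seeded
    # jittered restarts on the accuracy block find the global optimum.
    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_restarts - 1)):
        jitter = np.zeros_like(theta0)
        jitter[n : 2 * n] = rng.normal(scale=2.0, size=n)
        starts.append(np.clip(theta0 + jitter, [b[0] if b[0] is not None else -np.inf for b in bounds], [b[1] if b[1] is not None else np.inf for b in bounds]))
    res = None
    for start in starts:
        cand = minimize(
            objective,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-13},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    corr = res.x[2 * n : 2 * n + n_pairs] - res.x[2 * n + n_pairs :]
    scores = np.zeros((n, n))
    for (j, k), i in pair_index.items():
        scores[j, k] = scores[k, j] = abs(corr[i])
    return scores


def dependency_scores(
    L,
    l1_strength: float = 0.01,
    acc_bound: float = 5.0,
    n_restarts: int = 6,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric nonnegative pair scores s_jk = |agreement coefficient|.

    Conditionally independent pairs score near zero (their marginal
    agreement is absorbed by the latent-class channel); redundant or copied
    labeling functions score highest.
    """
    V = as_votes(L)
    m, n = V.shape
    if n < 2:
        raise ValueError("dependency scoring needs at least 2 labeling functions")
    return _joint_pseudolikelihood_fit(
        V, l1_strength, acc_bound=acc_bound, n_restarts=n_restarts, seed=seed
    )


def select_correlations(
    scores: np.ndarray, epsilon: float, max_pairs: int | None = None
) -> DependencySet:
    """All pairs with score >= epsilon; nested in epsilon by construction."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    scores = np.asarray(scores)
    n = scores.shape[0]
    pairs = tuple(
        (j, k) for j in range(n) for k in range(j + 1, n) if scores[j, k] >= epsilon
    )
    if max_pairs is not None and len(pairs) > max_pairs:
        raise ValueError(
            f"{len(pairs)} pairs selected at epsilon={epsilon:g}, exceeding the "
            f"cap of {max_pairs}; raise epsilon"
        )
    return DependencySet(pairs)


def default_epsilon_grid(scores: np.ndarray, size: int = 25) -> tuple[float, ...]:
    """Descending log-spaced grid spanning the observed score range."""
    smax = float(np.max(scores)) if np.size(scores) else 0.0
    if smax <= 0:
        return tuple(np.geomspace(1.0, 1e-3, size))
    return tuple(np.geomspace(1.05 * smax, max(5e-4 * smax, 1e-8), size))


def correlation_path(scores: np.ndarray, config: StructureConfig | None = None) -> CorrelationPath:
    """Selected-pair counts along the epsilon grid (descending)."""
    config = config or StructureConfig()
    grid = config.epsilon_grid or default_epsilon_grid(scores, config.grid_size)
    path = CorrelationPath()
    prev = -1
    for eps in grid:
        deps = select_correlations(scores, eps, config.max_pairs)
        if len(deps) < prev:
            raise AssertionError("pair counts must be non-decreasing along the path")
        prev = len(deps)
        path.records.append((float(eps), len(deps), deps))
    return path


def select_elbow(path: CorrelationPath) -> float:
    """The interior grid point with greatest absolute count difference from
    its neighbors; ties break toward the larger epsilon (cheaper model)."""
    counts = path.counts
    if counts.size < 3:
        raise ValueError("elbow selection needs at least 3 grid points")
    diffs = np.abs(counts[1:-1] - counts[:-2]) + np.abs(counts[1:-1] - counts[2:])
    best = int(np.argmax(diffs))  # argmax takes the first (largest epsilon) on ties
    return float(path.epsilons[best + 1])


class CorrelationSelector(BaseEstimator):
    """Estimator facade: score pairs, sweep epsilon, pick the elbow.

    Attributes after ``fit``: ``scores_`` (n x n), ``path_``, ``epsilon_``
    (elbow threshold, or the fixed ``epsilon`` if given) and
    ``dependencies_`` (the selected :class:`DependencySet`).
    """

    def __init__(
        self,
        epsilon: float | None = None,
        epsilon_grid=None,
        grid_size: int = 25,
        l1_strength: float = 0.01,
        acc_bound: float = 5.0,
        n_restarts: int = 6,
        max_pairs: int | None = None,
        seed: int = 0,
    ):
        self.epsilon = epsilon
        self.epsilon_grid = epsilon_grid
        self.grid_size = grid_size
        self.l1_strength = l1_strength
        self.acc_bound = acc_bound
        self.n_restarts = n_restarts
        self.max_pairs = max_pairs
        self.seed = seed

    def fit(self, L, y=None):
        config = StructureConfig(
            epsilon_grid=self.epsilon_grid,
            grid_size=self.grid_size,
            l1_strength=self.l1_strength,
            max_pairs=self.max_pairs,
        )
        self.scores_ = dependency_scores(
            L,
            l1_strength=self.l1_strength,
            acc_bound=self.acc_bound,
            n_restarts=self.n_restarts,
            seed=self.seed,
        )
        self.path_ = correlation_path(self.scores_, config)
        self.epsilon_ = float(self.epsilon) if self.epsilon is not None else select_elbow(self.path_)
        self.dependencies_ = select_correlations(self.scores_, self.epsilon_, self.max_pairs)
        return self
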