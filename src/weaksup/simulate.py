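"""Synthetic weak-supervision data with known ground truth.

Simulates the label-matrix level of the problem directly: a latent binary
class y, labeling functions that vote with per-LF propensity p_l and, when
they vote, are correct with per-LF accuracy alpha_j.  Optional blocks of
perfectly correlated LFs copy a single shared vote, reproducing the
pathological regime where an independence-assuming model mis-allocates
accuracy between a correlated block and genuinely independent LFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .matrix import LabelMatrix

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_independent",
    "simulate_correlated",
    "correlated_block_preset",
    "density_sweep_preset",
    "simulate_features",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic label-matrix draw.

    Attributes
    ----------
    m : number of data points.
    n : number of labeling functions.
    accuracies : per-LF probability that a cast vote equals the true label.
    propensities : per-LF probability of casting a vote at all.
    class_balance : P(y = +1).
    blocks : tuples of LF indices that copy one shared latent vote.
    seed : RNG seed; fixes the draw bit-for-bit.
    """

    m: int
    n: int
    accuracies: tuple[float, ...]
    propensities: tuple[float, ...]
    class_balance: float = 0.5
    blocks: tuple[tuple[int, ...], ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "accuracies", tuple(float(a) for a in np.broadcast_to(self.accuracies, (self.n,))))
        object.__setattr__(self, "propensities", tuple(float(p) for p in np.broadcast_to(self.propensities, (self.n,))))
        object.__setattr__(self, "blocks", tuple(tuple(int(i) for i in b) for b in self.blocks))
        self.validate()

    def validate(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be positive")
        if not all(0.0 < a < 1.0 for a in self.accuracies):
            raise ValueError("accuracies must lie in (0, 1)")
        if not all(0.0 <= p <= 1.0 for p in self.propensities):
            raise ValueError("propensities must lie in [0, 1]")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must lie in [0, 1]")
        seen: set[int] = set()
        for block in self.blocks:
            if not block:
                raise ValueError("empty block")
            if any(j < 0 or j >= self.n for j in block):
                raise ValueError("block index out of range")
            if seen & set(block):
                raise ValueError("blocks must be disjoint")
            seen |= set(block)


@dataclass(frozen=True)
class SimOutput:
    """A simulated label matrix with its ground truth and generating config."""

    matrix: LabelMatrix
    truth: np.ndarray = field(repr=False)
    config: SimConfig


def _draw(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    y = np.where(rng.random(config.m) < config.class_balance, 1, -1).astype(np.int8)
    votes_cast = rng.random((config.m, config.n)) < np.asarray(config.propensities)
    correct = rng.random((config.m, config.n)) < np.asarray(config.accuracies)
    return y, votes_cast, correct


def _assemble(y, votes_cast, correct, config) -> SimOutput:
    sign = np.where(correct, 1, -1).astype(np.int8)
    votes = (y[:, None] * sign) * votes_cast
    return SimOutput(matrix=LabelMatrix(votes), truth=y, config=config)


def simulate_independent(config: SimConfig) -> SimOutput:
    """Draw a matrix of conditionally independent labeling functions."""
    if config.blocks:
        raise ValueError("simulate_independent requires an empty block list")
    y, votes_cast, correct = _draw(config)
    return _assemble(y, votes_cast, correct, config)


def simulate_correlated(config: SimConfig) -> SimOutput:
    """Draw a matrix where each block copies its first member's latent vote.

    Every member of a block shares one propensity draw and one
    correct/incorrect draw per data point, so within-block agreement is
    exactly 1 on every row.  With no blocks the output is draw-for-draw
    identical to :func:`simulate_independent` at the same seed.
    """
    y, votes_cast, correct = _draw(config)
    for block in config.blocks:
        lead = block[0]
        for j in block[1:]:
            votes_cast[:, j] = votes_cast[:, lead]
            correct[:, j] = correct[:, lead]
    return _assemble(y, votes_cast, correct, config)


def correlated_block_preset(m: int = 10_000, seed: int = 0) -> SimConfig:
    """Ten always-voting LFs: a perfectly correlated 5-block at accuracy 0.5
    plus five independent LFs at accuracy 0.99, balanced classes.

    Under an independence-assuming model the maximum-likelihood fit drives
    the block's estimated accuracy to ~100% and the independent LFs' to
    ~50%: the block is mistaken for the true label.
    """
    if m < 1:
        raise ValueError("m must be positive")
    return SimConfig(
        m=m,
        n=10,
        accuracies=(0.5,) * 5 + (0.99,) * 5,
        propensities=(1.0,) * 10,
        class_balance=0.5,
        blocks=((0, 1, 2, 3, 4),),
        seed=seed,
    )


def density_sweep_preset(n: int, m: int = 1000, seed: int = 0) -> SimConfig:
    """Class-balanced m=1000 regime: n independent LFs, accuracy 0.75,
    10% voting propensity; label density sweeps with n."""
    if n < 1:
        raise ValueError("n must be positive")
    return SimConfig(m=m, n=n, accuracies=(0.75,) * n, propensities=(0.1,) * n, seed=seed)


def simulate_features(
    truth: np.ndarray, d: int = 10, bayes_accuracy: float = 0.9, seed: int = 0
) -> np.ndarray:
    """Gaussian features carrying class signal independent of any LF votes.

    Two spherical Gaussians at +/- mu with ||mu|| = Phi^{-1}(bayes_accuracy),
    spread evenly over d dimensions, so the Bayes-optimal linear rule attains
    exactly ``bayes_accuracy``.  Used to test that a discriminative model
    trained on probabilistic labels generalizes to points every LF abstains on.
    """
    truth = np.asarray(truth)
    if not 0.5 < bayes_accuracy < 1.0:
        raise ValueError("bayes_accuracy must lie in (0.5, 1)")
    rng = np.random.default_rng(seed)
    mu = np.full(d, norm.ppf(bayes_accuracy) / np.sqrt(d))
    return truth[:, None] * mu + rng.standard_normal((truth.size, d))
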