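"""Graded response model (GRM) mathematics.

Samejima's graded response model for 5-category items: the probability of
scoring at or above category boundary k (k = 1..4) is a 2PL logistic

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k))),

and category probabilities follow by differencing, ``P_c = P*_c - P*_{c+1}``
with ``P*_0 = 1`` and ``P*_5 = 0`` (internal 0-4 category coding).

The module provides boundary/category probabilities, Fisher information,
pattern likelihoods, expected a posteriori (EAP) scoring on a fixed
quadrature grid, model-conformant response simulation, and the -2LL/AIC/BIC
fit indices. All likelihood work is done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bank import ItemBank, ItemRecord
from .responses import ResponseMatrix

__all__ = [
    "QuadratureGrid",
    "ResponsePattern",
    "ThetaEstimate",
    "boundary_prob",
    "category_probs",
    "item_information",
    "test_information",
    "log_likelihood",
    "eap_estimate",
    "eap_from_loglik",
    "simulate_responses",
    "fit_indices",
    "category_prob_table",
    "information_curve",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature nodes with renormalized standard-normal weights.

    The grid carries the N(0, 1) population prior used for EAP scoring and
    marginal-maximum-likelihood calibration.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be matching 1-d arrays")
        if not np.all(np.diff(nodes) > 0):
            raise ValueError("nodes must be strictly increasing")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def normal(cls, n_nodes: int = 81, bound: float = 4.0) -> "QuadratureGrid":
        """Equally spaced nodes on [-bound, bound], N(0,1) weights renormalized.

        Endpoint weights are halved (trapezoid rule), so posterior moments
        converge quadratically in the node spacing.
        """
        nodes = np.linspace(-bound, bound, n_nodes)
        w = norm.pdf(nodes)
        if n_nodes > 1:
            w = w.copy()
            w[0] *= 0.5
            w[-1] *= 0.5
        return cls(nodes, w / w.sum())

    @property
    def prior_mean(self) -> float:
        return float(np.sum(self.nodes * self.weights))

    @property
    def prior_sd(self) -> float:
        m = self.prior_mean
        return float(np.sqrt(np.sum((self.nodes - m) ** 2 * self.weights)))


DEFAULT_GRID = QuadratureGrid.normal()


@dataclass(frozen=True)
class ResponsePattern:
    """An ordered set of item responses (internal 0-4 coding)."""

    item_ids: tuple[str, ...]
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = tuple(self.item_ids)
        sc = tuple(int(s) for s in self.scores)
        if len(ids) != len(sc):
            raise ValueError("item_ids and scores differ in length")
        if any(s < 0 or s > 4 for s in sc):
            raise ValueError("internal scores must lie in 0..4")
        object.__setattr__(self, "item_ids", ids)
        object.__setattr__(self, "scores", sc)

    @classmethod
    def from_file_coding(
        cls, item_ids: Sequence[str], scores: Sequence[int]
    ) -> "ResponsePattern":
        """Build from the 1-5 questionnaire coding."""
        return cls(tuple(item_ids), tuple(int(s) - 1 for s in scores))

    def __len__(self) -> int:
        return len(self.item_ids)


@dataclass(frozen=True)
class ThetaEstimate:
    """A latent-trait estimate with its posterior-SD standard error."""

    theta: float
    se: float
    n_items_used: int
    trace: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and np.isfinite(self.se)):
            raise ValueError("non-finite theta estimate")
        if self.se <= 0:
            raise ValueError("se must be positive")
        if self.trace and len(self.trace) != self.n_items_used:
            raise ValueError("trace length must equal n_items_used")


# ---------------------------------------------------------------------------
# probabilities and information
# ---------------------------------------------------------------------------

def _expit(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _boundary_curves(a: np.ndarray, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P*(X >= k) for k=1..4; shapes a:(J,), b:(J,4), theta:(T,) -> (J, T, 4)."""
    z = a[:, None, None] * (theta[None, :, None] - b[:, None, :])
    return _expit(z)


def _padded_boundaries(a, b, theta):
    """P*_k for k=0..5 including the constant 1 and 0 ends; (J, T, 6)."""
    core = _boundary_curves(a, b, theta)
    J, T, _ = core.shape
    out = np.empty((J, T, 6))
    out[..., 0] = 1.0
    out[..., 1:5] = core
    out[..., 5] = 0.0
    return out


def category_prob_table(bank: ItemBank, thetas: np.ndarray) -> np.ndarray:
    """Category probabilities for every item at every theta; (J, T, 5)."""
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    star = _padded_boundaries(bank.a_values, bank.b_values, thetas)
    return star[..., :5] - star[..., 1:]


def boundary_prob(item: ItemRecord, theta: float, k: int) -> float:
    """P(X >= category k | theta) for boundary index k in 1..4."""
    if not 1 <= k <= 4:
        raise IndexError(f"boundary index k={k} out of range 1..4")
    return float(_expit(item.a * (theta - item.b[k - 1])))


def category_probs(item: ItemRecord, theta: float) -> np.ndarray:
    """The five category probabilities of ``item`` at ``theta`` (sum to 1)."""
    star = np.empty(6)
    star[0] = 1.0
    star[5] = 0.0
    star[1:5] = _expit(item.a * (theta - np.asarray(item.b)))
    return star[:5] - star[1:]


def _information_from_star(a: np.ndarray, star: np.ndarray) -> np.ndarray:
    """Samejima item information given padded boundaries (J, T, 6) -> (J, T)."""
    # P'_c = a [P*_c (1 - P*_c) - P*_{c+1} (1 - P*_{c+1})]
    w = star * (1.0 - star)
    dP = a[:, None, None] * (w[..., :5] - w[..., 1:])
    P = star[..., :5] - star[..., 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, dP**2 / np.where(P > 0, P, 1.0), 0.0)
    return terms.sum(axis=-1)


def item_information(item: ItemRecord, theta) -> float | np.ndarray:
    """Fisher information of a single item at ``theta``."""
    thetas = np.atleast_1d(np.asarray(theta, dtype=float))
    star = _padded_boundaries(
        np.array([item.a]), np.asarray(item.b)[None, :], thetas
    )
    info = _information_from_star(np.array([item.a]), star)[0]
    return float(info[0]) if np.isscalar(theta) else info


def information_curve(bank: ItemBank, thetas: np.ndarray) -> np.ndarray:
    """Per-item information for every item at every theta; (J, T)."""
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    star = _padded_boundaries(bank.a_values, bank.b_values, thetas)
    return _information_from_star(bank.a_values, star)


def test_information(items: Sequence[ItemRecord], theta) -> float | np.ndarray:
    """Fisher information of an item set (sum over items)."""
    items = list(items)
    if not items:
        raise ValueError("test information of an empty item set is undefined")
    total = sum(item_information(it, theta) for it in items)
    return total


# ---------------------------------------------------------------------------
# likelihood and EAP
# ---------------------------------------------------------------------------

def _pattern_log_prob_table(
    pattern: ResponsePattern, bank: ItemBank, thetas: np.ndarray
) -> np.ndarray:
    """log P(pattern | theta) on each theta; shape (T,)."""
    if len(pattern) == 0:
        return np.zeros(len(thetas))
    sub = bank.subset(pattern.item_ids)
    score_of = dict(zip(pattern.item_ids, pattern.scores))
    table = category_prob_table(sub, thetas)  # (J, T, 5)
    with np.errstate(divide="ignore"):
        log_table = np.log(table)
    total = np.zeros(len(thetas))
    # accumulate in bank order so the sum is bitwise order-invariant
    for i, iid in enumerate(sub.item_ids):
        total += log_table[i, :, score_of[iid]]
    return total


def log_likelihood(pattern: ResponsePattern, bank: ItemBank, theta: float) -> float:
    """Log-likelihood of a response pattern at a single theta."""
    return float(_pattern_log_prob_table(pattern, bank, np.array([theta]))[0])


def eap_from_loglik(
    loglik: np.ndarray, grid: QuadratureGrid
) -> tuple[float, float]:
    """Posterior mean and SD of theta given log-likelihood values on the grid."""
    loglik = np.asarray(loglik, dtype=float)
    shifted = loglik - loglik.max()
    post = np.exp(shifted) * grid.weights
    total = post.sum()
    post /= total
    theta = float(np.sum(grid.nodes * post))
    var = float(np.sum((grid.nodes - theta) ** 2 * post))
    return theta, float(np.sqrt(max(var, 0.0)))


def eap_estimate(
    pattern: ResponsePattern, bank: ItemBank, grid: QuadratureGrid = DEFAULT_GRID
) -> ThetaEstimate:
    """Expected a posteriori estimate: posterior mean and SD on the grid.

    With an empty pattern the posterior is the prior, so the estimate is the
    prior mean with the prior SD. Invariant to item order.
    """
    loglik = _pattern_log_prob_table(pattern, bank, grid.nodes)
    theta, se = eap_from_loglik(loglik, grid)
    return ThetaEstimate(theta, se, len(pattern), tuple(pattern.item_ids))


# ---------------------------------------------------------------------------
# simulation and fit indices
# ---------------------------------------------------------------------------

def simulate_responses(
    bank: ItemBank,
    thetas: np.ndarray,
    seed: int | np.random.Generator = 0,
    covariates=None,
) -> ResponseMatrix:
    """Draw model-conformant responses for each person at their true theta.

    Each response is a single draw from the item's category distribution at
    the person's theta; identical seeds give identical matrices.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    thetas = np.asarray(thetas, dtype=float)
    if not np.all(np.isfinite(thetas)):
        raise ValueError("true thetas must be finite")
    table = category_prob_table(bank, thetas)  # (J, n, 5)
    cum = np.cumsum(table, axis=-1)
    u = rng.random((len(thetas), len(bank)))  # (n, J)
    scores = (u.T[..., None] > cum).sum(axis=-1).T  # (n, J)
    cov = covariates if covariates is not None else pd.DataFrame()
    return ResponseMatrix(bank.item_ids, scores, cov)


def fit_indices(neg2ll: float, n_params: int, n_persons: int) -> dict[str, float]:
    """-2LL with the AIC and BIC penalties: AIC = -2LL + 2p, BIC = -2LL + p ln N."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    return {
        "neg2ll": float(neg2ll),
        "aic": float(neg2ll + 2 * n_params),
        "bic": float(neg2ll + n_params * np.log(n_persons)),
    }
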