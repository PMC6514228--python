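"""Marginal-maximum-likelihood (MML-EM) calibration of the GRM.

Item parameters are estimated by the EM algorithm with a fixed-node
quadrature prior: the E-step computes each person's posterior weight on the
quadrature nodes under the current parameters, and the M-step maximizes the
expected complete-data log-likelihood item by item with a quasi-Newton
optimizer and analytic gradients.

Thresholds are parameterized as (b1, log-increments), which keeps
``b1 < b2 < b3 < b4`` at every step; discrimination is optimized on the log
scale to keep ``a > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .bank import ItemBank, ItemRecord, SOURCE_SCALES, DOMAINS
from .grm import QuadratureGrid, DEFAULT_GRID, category_prob_table, fit_indices
from .responses import ResponseMatrix

__all__ = ["EMControls", "CalibrationResult", "calibrate_grm", "observed_neg2ll"]

_TINY = 1e-300


@dataclass(frozen=True)
class EMControls:
    """EM convergence settings.

    max_cycles : EM cycle cap; non-convergence is flagged, never silent.
    tol : absolute change in -2LL that counts as converged.
    """

    max_cycles: int = 500
    tol: float = 1e-4


@dataclass(frozen=True)
class CalibrationResult:
    bank: ItemBank
    neg2ll: float
    n_cycles: int
    converged: bool
    fit: dict


def observed_neg2ll(
    responses: ResponseMatrix, bank: ItemBank, grid: QuadratureGrid = DEFAULT_GRID
) -> float:
    """Observed-data -2 log marginal likelihood of ``responses`` under ``bank``."""
    log_table = _log_prob_table(bank, grid)
    ll = _person_loglik(responses.scores, log_table)
    return float(-2.0 * logsumexp(ll + np.log(grid.weights), axis=1).sum())


def _log_prob_table(bank: ItemBank, grid: QuadratureGrid) -> np.ndarray:
    table = category_prob_table(bank, grid.nodes)  # (J, Q, 5)
    return np.log(np.maximum(table, _TINY))


def _person_loglik(scores: np.ndarray, log_table: np.ndarray) -> np.ndarray:
    """Sum item log-probabilities; scores (n, J), log_table (J, Q, 5) -> (n, Q)."""
    n, J = scores.shape
    out = np.zeros((n, log_table.shape[1]))
    for j in range(J):
        out += log_table[j, :, scores[:, j]]
    return out


def _item_neg_ell_grad(params: np.ndarray, r: np.ndarray, nodes: np.ndarray):
    """Negative expected log-likelihood and gradient for one item.

    params = (log a, b1, log d2, log d3, log d4); r is the (Q, 5) table of
    expected category counts at each node.
    """
    a = np.exp(params[0])
    d = np.exp(params[2:])
    b = params[1] + np.concatenate(([0.0], np.cumsum(d)))
    z = a * (nodes[:, None] - b[None, :])  # (Q, 4)
    star = 0.5 * (1.0 + np.tanh(0.5 * z))
    star_pad = np.concatenate(
        [np.ones((len(nodes), 1)), star, np.zeros((len(nodes), 1))], axis=1
    )
    P = np.maximum(star_pad[:, :5] - star_pad[:, 1:], 1e-10)
    f = -np.sum(r * np.log(P))

    # dL/dP*_k = r_k / P_k - r_{k-1} / P_{k-1}   (categories 0-indexed)
    ratio = r / P
    g_star = ratio[:, 1:] - ratio[:, :4]  # (Q, 4), for k = 1..4
    w = star * (1.0 - star)
    common = g_star * w
    dL_da = np.sum(common * (nodes[:, None] - b[None, :]))
    dL_db = -a * common.sum(axis=0)  # (4,)
    grad = np.empty(5)
    grad[0] = -dL_da * a  # chain rule to log a
    grad[1] = -dL_db.sum()  # b1 shifts every threshold
    for m in range(3):  # log d_{m+2} shifts thresholds m+1..3
        grad[2 + m] = -dL_db[m + 1 :].sum() * d[m]
    return f, grad


def _start_values(scores_j: np.ndarray) -> np.ndarray:
    """Moment-based starting parameters for one item."""
    n = len(scores_j)
    b = []
    for k in range(1, 5):
        p = np.clip(np.mean(scores_j >= k), 1e-3, 1 - 1e-3)
        b.append(-np.log(p / (1 - p)))
    b = np.array(b)
    # enforce a minimum gap so log-increments are defined
    for k in range(1, 4):
        b[k] = max(b[k], b[k - 1] + 0.05)
    d = np.diff(b)
    return np.concatenate(([0.0], [b[0]], np.log(d)))


def calibrate_grm(
    responses: ResponseMatrix,
    grid: QuadratureGrid = DEFAULT_GRID,
    controls: EMControls = EMControls(),
    template: ItemBank | None = None,
) -> CalibrationResult:
    """Fit GRM item parameters to a response matrix by MML-EM.

    Parameters
    ----------
    responses : ResponseMatrix
        At least two items; every item must show at least two observed
        categories (an item with a single observed category is rejected).
    grid : QuadratureGrid
        Quadrature prior (N(0,1) by default).
    controls : EMControls
        Convergence settings.
    template : ItemBank, optional
        Carries item metadata (source scale, domain, label) into the
        calibrated bank. Without a template, metadata is assigned
        round-robin from the closed vocabularies as a placeholder.

    Returns
    -------
    CalibrationResult
        Calibrated bank (thresholds strictly ordered by construction),
        final -2LL, cycle count, convergence flag, and -2LL/AIC/BIC.
    """
    scores = responses.scores
    n, J = scores.shape
    if J < 2:
        raise ValueError("calibration requires at least 2 items")
    for j, iid in enumerate(responses.item_ids):
        observed = np.unique(scores[:, j])
        if len(observed) < 2:
            raise ValueError(
                f"item {iid!r}: only category {int(observed[0]) + 1} observed; "
                "cannot calibrate a single-category item"
            )

    params = np.stack([_start_values(scores[:, j]) for j in range(J)])
    nodes, log_w = grid.nodes, np.log(grid.weights)
    Q = len(nodes)

    prev_neg2ll = np.inf
    converged = False
    cycle = 0
    for cycle in range(1, controls.max_cycles + 1):
        bank_now = _bank_from_params(responses.item_ids, params, template)
        log_table = _log_prob_table(bank_now, grid)
        ll = _person_loglik(scores, log_table)  # (n, Q)
        marg = logsumexp(ll + log_w[None, :], axis=1)
        neg2ll = float(-2.0 * marg.sum())
        post = np.exp(ll + log_w[None, :] - marg[:, None])  # (n, Q)

        if abs(prev_neg2ll - neg2ll) < controls.tol:
            converged = True
            break
        prev_neg2ll = neg2ll

        # expected category counts r[j] of shape (Q, 5), then per-item M-step
        for j in range(J):
            r = np.zeros((Q, 5))
            for c in range(5):
                mask = scores[:, j] == c
                if mask.any():
                    r[:, c] = post[mask].sum(axis=0)
            res = minimize(
                _item_neg_ell_grad,
                params[j],
                args=(r, nodes),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 50},
            )
            params[j] = res.x

    bank = _bank_from_params(responses.item_ids, params, template)
    neg2ll = observed_neg2ll(responses, bank, grid)
    fit = fit_indices(neg2ll, n_params=5 * J, n_persons=n)
    return CalibrationResult(bank, neg2ll, cycle, converged, fit)


def _bank_from_params(
    item_ids, params: np.ndarray, template: ItemBank | None
) -> ItemBank:
    items = []
    for j, iid in enumerate(item_ids):
        a = float(np.exp(params[j, 0]))
        d = np.exp(params[j, 2:])
        b = params[j, 1] + np.concatenate(([0.0], np.cumsum(d)))
        if template is not None:
            ref = template[iid]
            scale, domain, label = ref.source_scale, ref.domain, ref.label
        else:
            scale = SOURCE_SCALES[j % len(SOURCE_SCALES)]
            domain = DOMAINS[j % len(DOMAINS)]
            label = ""
        items.append(
            ItemRecord(iid, scale, domain, label, a, tuple(float(x) for x in b))
        )
    return ItemBank(tuple(items))
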