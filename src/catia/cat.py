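"""Adaptive test administration.

The CAT loop: a random (exposure-controlling) first item, expected a
posteriori (EAP) trait update after every response, maximum-information
(MIC) selection of the next item at the current estimate, and termination
when the posterior-SD standard error falls at or below a threshold — or
when the bank is exhausted. A ``None`` stopping rule administers the whole
bank, which reproduces non-adaptive full-bank scoring exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bank import ItemBank
from .grm import (
    DEFAULT_GRID,
    QuadratureGrid,
    ThetaEstimate,
    category_probs,
    eap_from_loglik,
    information_curve,
)

__all__ = [
    "CATConfig",
    "CATRecord",
    "CATStep",
    "SimulatedResponder",
    "ObservedResponder",
    "select_initial_item",
    "select_next_item_mic",
    "administer_cat",
]

_TINY = 1e-300


@dataclass(frozen=True)
class CATConfig:
    """Adaptive-administration settings.

    stopping_rule : float or None
        SE threshold (stop once SE <= value); ``None`` administers the
        entire bank. The estimator is EAP and the selection rule MIC.
    initial_item : str or None
        Fixed first item id, or ``None`` for a uniformly random first item.
    max_items : int or None
        Optional length cap; default off (bank exhaustion is the only cap).
    """

    stopping_rule: float | None = None
    initial_item: str | None = None
    grid: QuadratureGrid = DEFAULT_GRID
    seed: int = 0
    max_items: int | None = None
    min_items: int = 1

    def __post_init__(self) -> None:
        if self.stopping_rule is not None and self.stopping_rule <= 0:
            raise ValueError("SE stopping threshold must be positive")


@dataclass(frozen=True)
class CATStep:
    item_id: str
    response: int  # internal 0-4
    theta: float
    se: float


@dataclass(frozen=True)
class CATRecord:
    estimate: ThetaEstimate
    steps: tuple[CATStep, ...]
    stop_reason: str  # se_reached | bank_exhausted | none_rule_complete | max_items

    @property
    def n_items_used(self) -> int:
        return len(self.steps)


class SimulatedResponder:
    """Answers items by sampling the GRM at a fixed true theta."""

    def __init__(self, true_theta: float, seed: int | np.random.Generator = 0):
        self.true_theta = float(true_theta)
        self._rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )

    def respond(self, item) -> int:
        p = category_probs(item, self.true_theta)
        return int(np.searchsorted(np.cumsum(p), self._rng.random(), side="right"))


class ObservedResponder:
    """Answers items from a fixed, fully observed response vector (0-4)."""

    def __init__(self, responses: Mapping[str, int]):
        self.responses = {k: int(v) for k, v in responses.items()}

    def respond(self, item) -> int:
        try:
            return self.responses[item.item_id]
        except KeyError:
            raise KeyError(
                f"observed response vector has no entry for item {item.item_id!r}"
            ) from None


def select_initial_item(
    bank: ItemBank, config: CATConfig, rng: np.random.Generator | None = None
) -> str:
    """First item: uniform over the bank (seeded) or the configured fixed id."""
    if config.initial_item is not None:
        if config.initial_item not in bank.item_ids:
            raise KeyError(f"initial item {config.initial_item!r} not in bank")
        return config.initial_item
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return bank.item_ids[int(rng.integers(len(bank)))]


def select_next_item_mic(
    bank: ItemBank, administered: set[str] | Sequence[str], theta_hat: float
) -> str:
    """The unadministered item with maximum Fisher information at ``theta_hat``.

    Exact information ties are broken toward the lexicographically smallest
    item id.
    """
    administered = set(administered)
    remaining = [i for i, iid in enumerate(bank.item_ids) if iid not in administered]
    if not remaining:
        raise ValueError("bank exhausted: no unadministered items remain")
    info = information_curve(bank, np.array([theta_hat]))[:, 0]
    best = max(info[remaining])
    candidates = [bank.item_ids[i] for i in remaining if info[i] == best]
    return min(candidates)


def administer_cat(
    bank: ItemBank,
    responder,
    config: CATConfig,
    rng: np.random.Generator | None = None,
    _log_table: np.ndarray | None = None,
) -> CATRecord:
    """Run one adaptive administration and return its full trace.

    The stop check runs after each EAP update (at least ``min_items`` items
    are administered); MIC selection follows if the test continues.
    """
    from .grm import category_prob_table

    grid = config.grid
    if _log_table is None:
        _log_table = np.log(np.maximum(category_prob_table(bank, grid.nodes), _TINY))
    idx = {iid: j for j, iid in enumerate(bank.item_ids)}

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cum_loglik = np.zeros(len(grid.nodes))
    steps: list[CATStep] = []
    administered: set[str] = set()

    current = select_initial_item(bank, config, rng)
    stop_reason = None
    while True:
        item = bank[current]
        resp = responder.respond(item)
        administered.add(current)
        cum_loglik += _log_table[idx[current], :, resp]
        theta, se = eap_from_loglik(cum_loglik, grid)
        steps.append(CATStep(current, resp, theta, se))

        if (
            config.stopping_rule is not None
            and len(steps) >= config.min_items
            and se <= config.stopping_rule
        ):
            stop_reason = "se_reached"
            break
        if len(administered) == len(bank):
            stop_reason = (
                "none_rule_complete" if config.stopping_rule is None else "bank_exhausted"
            )
            break
        if config.max_items is not None and len(steps) >= config.max_items:
            stop_reason = "max_items"
            break
        current = select_next_item_mic(bank, administered, theta)

    # recompute the final estimate with bank-order accumulation so it agrees
    # bit-for-bit with non-adaptive scoring of the same responses
    from .grm import ResponsePattern, _pattern_log_prob_table

    pattern = ResponsePattern(
        tuple(s.item_id for s in steps), tuple(s.response for s in steps)
    )
    theta, se = eap_from_loglik(_pattern_log_prob_table(pattern, bank, grid.nodes), grid)
    est = ThetaEstimate(theta, se, len(steps), tuple(s.item_id for s in steps))
    return CATRecord(est, tuple(steps), stop_reason)
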