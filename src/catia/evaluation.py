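"""Monte-Carlo evaluation of the adaptive test.

Simulation analytics: conditional error indices of the estimated trait
(CBIAS, CMAE, CRMSE, CSEE), marginal reliability ``MR = 1 - (mean SE)^2``,
item savings and cross-rule correlations, Pearson concurrent validity
against questionnaire sum scores, and ROC-based predictive validity with
the Youden index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .bank import ItemBank
from .cat import CATConfig, CATRecord, SimulatedResponder, administer_cat
from .grm import DEFAULT_GRID, QuadratureGrid, category_prob_table
from .responses import ResponseMatrix

__all__ = [
    "SimulationDesign",
    "ConditionalStats",
    "EvaluationSummary",
    "DiagnosticRule",
    "run_mc_simulation",
    "conditional_stats",
    "marginal_reliability",
    "savings_and_correlations",
    "concurrent_validity",
    "roc_predictive_validity",
    "apply_diagnostic_rule",
    "rule_label",
]

_TINY = 1e-300


@dataclass(frozen=True)
class SimulationDesign:
    """Monte-Carlo design: simulee count, N(0,1) trait population, seed."""

    n_persons: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")


def rule_label(rule: float | None) -> str:
    return "none" if rule is None else f"se<={rule:g}"


def run_mc_simulation(
    bank: ItemBank,
    design: SimulationDesign,
    rules: Sequence[float | None] = (None, 0.2, 0.3, 0.4, 0.5),
    grid: QuadratureGrid = DEFAULT_GRID,
) -> dict:
    """Simulate one trait population and administer the CAT under each rule.

    True traits are drawn once from N(0, 1) and shared across rules; each
    (person, rule) administration gets an independent, seed-derived response
    and first-item stream. Returns ``{"true_theta": ..., "records": {label:
    [CATRecord, ...]}}``.
    """
    root = np.random.SeedSequence(design.seed)
    theta_rng = np.random.default_rng(root.spawn(1)[0])
    true_theta = theta_rng.standard_normal(design.n_persons)

    log_table = np.log(np.maximum(category_prob_table(bank, grid.nodes), _TINY))
    records: dict[str, list[CATRecord]] = {}
    for r_i, rule in enumerate(rules):
        rule_seed = np.random.SeedSequence(entropy=design.seed, spawn_key=(1, r_i))
        person_seeds = rule_seed.spawn(design.n_persons)
        recs = []
        for i in range(design.n_persons):
            rng = np.random.default_rng(person_seeds[i])
            config = CATConfig(stopping_rule=rule, grid=grid)
            responder = SimulatedResponder(true_theta[i], rng)
            recs.append(
                administer_cat(bank, responder, config, rng=rng, _log_table=log_table)
            )
        records[rule_label(rule)] = recs
    return {"true_theta": true_theta, "records": records}


@dataclass(frozen=True)
class ConditionalStats:
    """Overall and per-bin error indices of the trait estimates.

    Overall values are person-level means over all simulees; per-bin values
    condition on the true-theta bin. Empty bins are reported as NaN.
    """

    cbias: float
    cmae: float
    crmse: float
    csee: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    bin_cbias: np.ndarray
    bin_cmae: np.ndarray
    bin_crmse: np.ndarray
    bin_csee: np.ndarray


def conditional_stats(
    true_thetas: np.ndarray,
    estimates: np.ndarray,
    ses: np.ndarray,
    bin_edges: np.ndarray | None = None,
) -> ConditionalStats:
    """CBIAS / CMAE / CRMSE / CSEE, overall and within true-theta bins."""
    true_thetas = np.asarray(true_thetas, float)
    estimates = np.asarray(estimates, float)
    ses = np.asarray(ses, float)
    if not (len(true_thetas) == len(estimates) == len(ses)):
        raise ValueError("input vectors must have equal length")
    if bin_edges is None:
        bin_edges = np.arange(-4.0, 4.0 + 1e-9, 0.5)
    bin_edges = np.asarray(bin_edges, float)

    err = estimates - true_thetas
    nbins = len(bin_edges) - 1
    which = np.clip(np.digitize(true_thetas, bin_edges) - 1, 0, nbins - 1)
    counts = np.zeros(nbins, int)
    b_bias = np.full(nbins, np.nan)
    b_mae = np.full(nbins, np.nan)
    b_rmse = np.full(nbins, np.nan)
    b_see = np.full(nbins, np.nan)
    for k in range(nbins):
        m = (which == k) & (true_thetas >= bin_edges[0]) & (true_thetas <= bin_edges[-1])
        counts[k] = m.sum()
        if counts[k]:
            b_bias[k] = err[m].mean()
            b_mae[k] = np.abs(err[m]).mean()
            b_rmse[k] = np.sqrt((err[m] ** 2).mean())
            b_see[k] = ses[m].mean()
    return ConditionalStats(
        cbias=float(err.mean()),
        cmae=float(np.abs(err).mean()),
        crmse=float(np.sqrt((err**2).mean())),
        csee=float(ses.mean()),
        bin_edges=bin_edges,
        bin_counts=counts,
        bin_cbias=b_bias,
        bin_cmae=b_mae,
        bin_crmse=b_rmse,
        bin_csee=b_see,
    )


def marginal_reliability(ses: Sequence[float]) -> float:
    """MR = 1 - (mean SE)^2, the single-number reliability of a stopping rule."""
    ses = np.asarray(ses, float)
    if ses.size == 0:
        raise ValueError("no standard errors given")
    if (ses < 0).any():
        raise ValueError("standard errors must be non-negative")
    return float(1.0 - ses.mean() ** 2)


@dataclass(frozen=True)
class EvaluationSummary:
    """Per-rule efficiency/reliability table (one entry per stopping rule)."""

    rows: tuple[dict, ...]

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(list(self.rows))


def savings_and_correlations(
    records: Mapping[str, Sequence[CATRecord]],
    bank_size: int,
    reference: str = "none",
) -> EvaluationSummary:
    """Items used, mean SE, marginal reliability, savings, and r vs full bank.

    ``savings = 1 - mean_items_used / bank_size``; the correlation column is
    the Pearson r between each rule's estimates and the reference (full
    bank) rule's estimates over the same persons.
    """
    if reference not in records:
        raise KeyError(f"reference rule {reference!r} missing from records")
    n = len(records[reference])
    ref_theta = np.array([r.estimate.theta for r in records[reference]])
    rows = []
    for label, recs in records.items():
        if len(recs) != n:
            raise ValueError(f"rule {label!r} evaluated on a different person set")
        used = np.array([r.n_items_used for r in recs], float)
        ses = np.array([r.estimate.se for r in recs])
        thetas = np.array([r.estimate.theta for r in recs])
        rows.append(
            {
                "rule": label,
                "mean_items_used": float(used.mean()),
                "sd_items_used": float(used.std(ddof=1)) if n > 1 else 0.0,
                "mean_se": float(ses.mean()),
                "marginal_reliability": marginal_reliability(ses),
                "savings_pct": float(100.0 * (1.0 - used.mean() / bank_size)),
                "r_vs_full_bank": float(np.corrcoef(thetas, ref_theta)[0, 1]),
            }
        )
    return EvaluationSummary(tuple(rows))


def concurrent_validity(
    theta_hats: np.ndarray,
    responses: ResponseMatrix,
    scale_map: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, dict]:
    """Pearson r (two-tailed p) of trait estimates vs each scale's sum score.

    ``scale_map`` maps a scale name to its item ids; by default items are
    grouped by the prefix before the hyphen in their id. Sum scores use the
    1-5 questionnaire coding.
    """
    theta_hats = np.asarray(theta_hats, float)
    if scale_map is None:
        scale_map = {}
        for iid in responses.item_ids:
            scale_map.setdefault(iid.split("-")[0], []).append(iid)
    out = {}
    for scale, items in scale_map.items():
        cols = np.array([responses.column(i) + 1 for i in items])
        sums = cols.sum(axis=0).astype(float)
        if np.std(sums) == 0 or np.std(theta_hats) == 0:
            out[scale] = {"r": np.nan, "p": np.nan, "undefined": True}
            continue
        r, p = stats.pearsonr(theta_hats, sums)
        out[scale] = {"r": float(r), "p": float(p), "undefined": False}
    return out


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with half-credit for ties."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)  # midranks: ties get half credit
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_predictive_validity(
    theta_hats: np.ndarray, labels: np.ndarray, ci_method: str = "hanley-mcneil"
) -> dict:
    """AUC with 95% CI, Youden-optimal cut-off, sensitivity and specificity.

    AUC uses the rank (Mann-Whitney) formulation with tie half-credit; the
    CI uses the Hanley-McNeil variance (or DeLong if requested). The
    cut-off maximizes the Youden index over midpoints between consecutive
    sorted estimates; ties resolve toward higher specificity.
    """
    theta_hats = np.asarray(theta_hats, float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both diagnostic classes must be present")

    auc = _auc_rank(theta_hats, labels)
    if ci_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
            n1 * n0
        )
    elif ci_method == "delong":
        pos, neg = theta_hats[labels == 1], theta_hats[labels == 0]
        v10 = np.array(
            [(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n0 for x in pos]
        )
        v01 = np.array(
            [(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / n1 for x in neg]
        )
        var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))

    # Youden scan over midpoints between consecutive sorted unique estimates
    uniq = np.unique(theta_hats)
    cuts = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else uniq
    best = None
    for cut in cuts:
        pred = theta_hats > cut
        sens = np.sum(pred & (labels == 1)) / n1
        spec = np.sum(~pred & (labels == 0)) / n0
        yi = sens + spec - 1
        if best is None or yi > best["youden"] + 1e-12 or (
            abs(yi - best["youden"]) <= 1e-12 and spec > best["specificity"]
        ):
            best = {
                "cutoff": float(cut),
                "sensitivity": float(sens),
                "specificity": float(spec),
                "youden": float(yi),
            }
    return {
        "auc": auc,
        "ci95": (float(max(auc - half, 0.0)), float(min(auc + half, 1.0))),
        **best,
    }


@dataclass(frozen=True)
class DiagnosticRule:
    """A questionnaire-based binary diagnosis.

    kind ``"sum_gt"``: positive when the sum of ``items`` (1-5 coding)
    strictly exceeds ``threshold`` (the IAT rule uses threshold 39).
    kind ``"count_ge"``: positive when at least ``count`` of ``items`` score
    at or above ``score`` (the GAS rule: >= 4 items scoring 4 or 5).
    """

    kind: str
    items: tuple[str, ...]
    threshold: float = 39
    score: int = 4
    count: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("sum_gt", "count_ge"):
            raise ValueError(f"unknown rule kind {self.kind!r}")


def apply_diagnostic_rule(responses: ResponseMatrix, rule: DiagnosticRule) -> np.ndarray:
    """Apply a diagnostic rule; returns a boolean label per person."""
    missing = [i for i in rule.items if i not in responses.item_ids]
    if missing:
        raise KeyError(f"rule item(s) missing from responses: {missing}")
    cols = np.array([responses.column(i) + 1 for i in rule.items])  # (J, n), 1-5
    if rule.kind == "sum_gt":
        return cols.sum(axis=0) > rule.threshold
    return (cols >= rule.score).sum(axis=0) >= rule.count
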