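"""Item-bank construction and quality control.

The six-step screening pipeline used to build the bank from a raw item
pool:

1. unidimensionality (EFA first-factor variance >= 20%, first/second
   eigenvalue ratio >= 4, first-factor loadings >= 0.40),
2. local independence (Yen's Q3 residual correlations <= 0.36),
3. monotonicity (Mokken scalability: item H >= 0.30),
4. differential item functioning (ordinal logistic regression, McFadden
   pseudo-R2 change <= 0.02),
5. item fit (Orlando-Thissen S-X2, p >= 0.01),
6. discrimination (a >= 1.00),

iterated — with recalibration between exclusion waves — until no item is
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from .bank import ItemBank
from .calibrate import (
    CalibrationResult,
    EMControls,
    _log_prob_table,
    _person_loglik,
    calibrate_grm,
)
from .grm import DEFAULT_GRID, QuadratureGrid, category_prob_table, eap_from_loglik
from .responses import ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "GroupingVariable",
    "QCReport",
    "efa_screen",
    "q3_matrix",
    "mokken_scalability",
    "sx2_itemfit",
    "dif_ordinal_logistic",
    "discrimination_filter",
    "run_qc_pipeline",
    "lord_wingersky",
    "eap_thetas",
]

#: Exclusion reason codes, in pipeline order.
REASONS = (
    "unidimensionality",
    "local_dependence",
    "monotonicity",
    "dif",
    "item_fit",
    "discrimination",
)


@dataclass(frozen=True)
class QCThresholds:
    """Cut-offs of the six screening steps (defaults per the instrument)."""

    efa_first_factor_min: float = 0.20
    efa_ratio_min: float = 4.0
    loading_min: float = 0.40
    q3_max: float = 0.36
    h_min: float = 0.30
    sx2_alpha: float = 0.01
    dif_r2_change_max: float = 0.02
    a_min: float = 1.00

    def __post_init__(self) -> None:
        for name in ("efa_first_factor_min", "loading_min", "q3_max", "h_min",
                     "sx2_alpha", "dif_r2_change_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.efa_ratio_min <= 0 or self.a_min < 0:
            raise ValueError("efa_ratio_min must be > 0 and a_min >= 0")


@dataclass(frozen=True)
class GroupingVariable:
    """A two-level person grouping (e.g. gender, age group, region)."""

    name: str
    codes: np.ndarray  # 0/1 per person

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        levels = np.unique(codes)
        if not np.all(np.isin(levels, [0, 1])) or len(levels) != 2:
            raise ValueError(f"grouping {self.name!r} must have exactly two levels 0/1")
        object.__setattr__(self, "codes", codes.astype(int))

    @classmethod
    def from_covariate(cls, responses: ResponseMatrix, name: str) -> "GroupingVariable":
        return cls(name, responses.group_codes(name))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def eap_thetas(
    responses: ResponseMatrix, bank: ItemBank, grid: QuadratureGrid = DEFAULT_GRID
) -> np.ndarray:
    """EAP trait estimate for every person (posterior mean on the grid)."""
    sub = responses.subset_items(bank.item_ids)
    ll = _person_loglik(sub.scores, _log_prob_table(bank, grid))
    log_post = ll + np.log(grid.weights)[None, :]
    post = np.exp(log_post - logsumexp(log_post, axis=1)[:, None])
    return post @ grid.nodes


def lord_wingersky(prob_table: np.ndarray) -> np.ndarray:
    """Summed-score distribution by the Lord-Wingersky recursion.

    ``prob_table`` has shape (J, Q, 5): category probabilities of J
    5-category items at Q ability points. Returns (Q, 4J + 1): the
    probability of each summed score at each ability point.
    """
    J = prob_table.shape[0]
    Q = prob_table.shape[1]
    f = np.ones((Q, 1))
    for j in range(J):
        S_old = f.shape[1]
        new = np.zeros((Q, S_old + 4))
        for c in range(5):
            new[:, c : c + S_old] += prob_table[j, :, c][:, None] * f
        f = new
    return f


# ---------------------------------------------------------------------------
# step 1: unidimensionality (EFA screen)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EFAResult:
    first_factor_proportion: float
    eigenvalue_ratio: float
    loadings: dict
    excluded: tuple[str, ...]
    passed: bool


def efa_screen(responses: ResponseMatrix, thresholds: QCThresholds = QCThresholds()) -> EFAResult:
    """Eigen screen of the inter-item Pearson correlation matrix.

    The first principal factor must explain at least
    ``efa_first_factor_min`` of the variance with a first/second eigenvalue
    ratio of at least ``efa_ratio_min``; items whose first-factor loading
    falls below ``loading_min`` are listed for exclusion.
    """
    X = responses.scores.astype(float)
    n, p = X.shape
    if p < 3 or n < 2:
        raise ValueError("EFA screen needs >= 3 items and >= 2 persons")
    sd = X.std(axis=0)
    for j, iid in enumerate(responses.item_ids):
        if sd[j] == 0:
            raise ValueError(f"item {iid!r} is constant; correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    v1 = evecs[:, 0]
    if v1.sum() < 0:
        v1 = -v1
    loadings = np.sqrt(max(evals[0], 0.0)) * v1
    excluded = tuple(
        iid
        for iid, ld in zip(responses.item_ids, loadings)
        if ld < thresholds.loading_min
    )
    proportion = float(evals[0] / p)
    ratio = float(evals[0] / evals[1]) if evals[1] > 0 else np.inf
    return EFAResult(
        proportion,
        ratio,
        dict(zip(responses.item_ids, map(float, loadings))),
        excluded,
        passed=(proportion >= thresholds.efa_first_factor_min)
        and (ratio >= thresholds.efa_ratio_min),
    )


# ---------------------------------------------------------------------------
# step 3: local independence (Q3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Q3Result:
    item_ids: tuple[str, ...]
    matrix: np.ndarray  # symmetric, NaN diagonal / undefined pairs
    flagged_pairs: tuple[tuple[str, str, float], ...]
    undefined_pairs: tuple[tuple[str, str], ...]


def q3_matrix(
    responses: ResponseMatrix,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
    q3_max: float = 0.36,
) -> Q3Result:
    """Yen's Q3: pairwise correlations of score residuals given EAP theta.

    Residuals are ``x_j - E[x_j | theta_hat]`` with the expected score from
    the calibrated GRM. Pairs with Q3 above ``q3_max`` are flagged;
    zero-variance residual vectors make a pair undefined (reported, never
    silently zero).
    """
    sub = responses.subset_items(bank.item_ids)
    theta = eap_thetas(sub, bank, grid)
    table = category_prob_table(bank, theta)  # (J, n, 5)
    expected = np.tensordot(table, np.arange(5), axes=([2], [0]))  # (J, n)
    resid = sub.scores.T - expected  # (J, n)
    sd = resid.std(axis=1)
    J = len(bank)
    q3 = np.full((J, J), np.nan)
    undefined = []
    flagged = []
    ids = bank.item_ids
    for j in range(J):
        for k in range(j + 1, J):
            if sd[j] == 0 or sd[k] == 0:
                undefined.append((ids[j], ids[k]))
                continue
            r = float(np.corrcoef(resid[j], resid[k])[0, 1])
            q3[j, k] = q3[k, j] = r
            if r > q3_max:
                flagged.append((ids[j], ids[k], r))
    flagged.sort(key=lambda t: -t[2])
    return Q3Result(ids, q3, tuple(flagged), tuple(undefined))


# ---------------------------------------------------------------------------
# step 4: monotonicity (Mokken scalability)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MokkenResult:
    scale_h: float
    item_h: dict
    pair_h: np.ndarray
    excluded: tuple[str, ...]


def mokken_scalability(
    responses: ResponseMatrix, h_min: float = 0.30
) -> MokkenResult:
    """Mokken scalability coefficients H_jk, H_j, and scale H.

    ``H_jk = cov(X_j, X_k) / cov_max(X_j, X_k)`` where the maximum
    covariance given the observed margins comes from the comonotone (sorted)
    joint distribution; H_j and the scale H are the matching
    ratio-of-sums. Items with ``H_j < h_min`` are listed for exclusion.
    """
    X = responses.scores.astype(float)
    n, J = X.shape
    if J < 2:
        raise ValueError("Mokken scalability needs >= 2 items")
    for j, iid in enumerate(responses.item_ids):
        if X[:, j].std() == 0:
            raise ValueError(f"item {iid!r} has zero variance")
    sorted_X = np.sort(X, axis=0)
    means = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=0)
    covmax = np.empty((J, J))
    for j in range(J):
        for k in range(j + 1, J):
            emax = float(np.mean(sorted_X[:, j] * sorted_X[:, k]))
            covmax[j, k] = covmax[k, j] = emax - means[j] * means[k]
    pair_h = np.full((J, J), np.nan)
    iu = np.triu_indices(J, 1)
    pair_h[iu] = cov[iu] / covmax[iu]
    pair_h.T[iu] = pair_h[iu]
    mask = ~np.eye(J, dtype=bool)
    item_h = {
        iid: float(cov[j, mask[j]].sum() / covmax[j, mask[j]].sum())
        for j, iid in enumerate(responses.item_ids)
    }
    scale_h = float(cov[iu].sum() / covmax[iu].sum())
    excluded = tuple(iid for iid, h in item_h.items() if h < h_min)
    return MokkenResult(scale_h, item_h, pair_h, excluded)


# ---------------------------------------------------------------------------
# step 5a: item fit (S-X2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemFitResult:
    stats: dict  # item_id -> {"sx2", "df", "p"} or {"untestable": True}
    flagged: tuple[str, ...]


def _collapse_cells(O: np.ndarray, E: np.ndarray, min_expected: float):
    """Collapse score-group rows, then category cells, with small expecteds.

    Adjacent rows are merged until every row's expected total reaches
    ``5 * min_expected``; within each row, adjacent category cells with
    expected < ``min_expected`` merge toward their neighbor. Returns lists
    of (observed, expected) cell arrays per surviving row.
    """
    rows_O, rows_E = [], []
    accO = np.zeros(O.shape[1])
    accE = np.zeros(E.shape[1])
    for s in range(O.shape[0]):
        accO += O[s]
        accE += E[s]
        if accE.sum() >= 5 * min_expected:
            rows_O.append(accO.copy())
            rows_E.append(accE.copy())
            accO[:] = 0.0
            accE[:] = 0.0
    if accE.sum() > 0 and rows_O:
        rows_O[-1] += accO
        rows_E[-1] += accE
    out = []
    for ro, re in zip(rows_O, rows_E):
        cells_o, cells_e = [], []
        co, ce = 0.0, 0.0
        for c in range(len(ro)):
            co += ro[c]
            ce += re[c]
            if ce >= min_expected:
                cells_o.append(co)
                cells_e.append(ce)
                co, ce = 0.0, 0.0
        if ce > 0:
            if cells_o:
                cells_o[-1] += co
                cells_e[-1] += ce
            else:
                cells_o, cells_e = [co], [ce]
        out.append((np.array(cells_o), np.array(cells_e)))
    return out


def sx2_itemfit(
    responses: ResponseMatrix,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
    min_expected: float = 1.0,
    alpha: float = 0.01,
) -> ItemFitResult:
    """Orlando-Thissen S-X2 item fit within summed rest-score groups.

    Expected frequencies come from the Lord-Wingersky score distribution of
    the remaining items integrated against the quadrature prior; cells with
    expected counts under ``min_expected`` are collapsed toward adjacent
    cells. Items whose collapsed table leaves no degrees of freedom are
    reported untestable.
    """
    sub = responses.subset_items(bank.item_ids)
    scores = sub.scores
    n, J = scores.shape
    if J < 2:
        raise ValueError("S-X2 needs >= 2 items")
    table = category_prob_table(bank, grid.nodes)  # (J, Q, 5)
    w = grid.weights
    totals = scores.sum(axis=1)
    stats: dict[str, dict] = {}
    flagged = []
    for j, iid in enumerate(bank.item_ids):
        rest_idx = [i for i in range(J) if i != j]
        f_rest = lord_wingersky(table[rest_idx])  # (Q, S+1)
        S = f_rest.shape[1]
        rest_scores = totals - scores[:, j]
        # observed counts per (rest score, category)
        O = np.zeros((S, 5))
        np.add.at(O, (rest_scores, scores[:, j]), 1.0)
        # model joint pi(s, c) and conditional expected counts
        joint = np.einsum("q,qs,qc->sc", w, f_rest, table[j])  # (S, 5)
        row_mass = joint.sum(axis=1, keepdims=True)
        N_s = O.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            E = np.where(row_mass > 0, N_s * joint / row_mass, 0.0)
        cells = _collapse_cells(O, E, min_expected)
        x2 = 0.0
        n_cells = 0
        n_rows = 0
        for co, ce in cells:
            keep = ce > 0
            x2 += float(np.sum((co[keep] - ce[keep]) ** 2 / ce[keep]))
            n_cells += int(keep.sum())
            n_rows += 1
        df = (n_cells - n_rows) - 5  # 5 free parameters per item
        if df <= 0:
            stats[iid] = {"untestable": True, "df": df}
            continue
        p = float(chi2.sf(x2, df))
        stats[iid] = {"sx2": x2, "df": df, "p": p}
        if p < alpha:
            flagged.append(iid)
    return ItemFitResult(stats, tuple(flagged))


# ---------------------------------------------------------------------------
# step 5b: DIF by ordinal logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DIFResult:
    group: str
    stats: dict  # item_id -> {"r2_m1", "r2_m3", "delta_r2", ...} or untestable
    flagged: tuple[str, ...]


def _ordinal_loglik(y: np.ndarray, X: np.ndarray | None) -> float:
    """Maximized log-likelihood of a proportional-odds cumulative-logit model."""
    if X is None:  # intercepts-only model: MLE = observed proportions
        _, counts = np.unique(y, return_counts=True)
        return float(np.sum(counts * np.log(counts / len(y))))
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    model = OrderedModel(y, X, distr="logit")
    res = model.fit(method="bfgs", disp=False, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("ordinal logistic fit did not converge")
    return float(res.llf)


def dif_ordinal_logistic(
    responses: ResponseMatrix,
    group: GroupingVariable,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
    r2_change_max: float = 0.02,
    include_m2: bool = False,
) -> DIFResult:
    """DIF screen: McFadden pseudo-R2 change between nested ordinal models.

    For each item, proportional-odds models M1 (theta-hat) and M3
    (theta-hat + group + interaction) are compared; the matching variable
    is the EAP estimate from the current surviving bank. An item is flagged
    when ``R2(M3) - R2(M1)`` exceeds ``r2_change_max``. With ``include_m2``
    the group-main-effect model M2 is also reported.
    """
    sub = responses.subset_items(bank.item_ids)
    theta = eap_thetas(sub, bank, grid)
    g = group.codes.astype(float)
    stats: dict[str, dict] = {}
    flagged = []
    for j, iid in enumerate(bank.item_ids):
        y = sub.scores[:, j]
        try:
            ll0 = _ordinal_loglik(y, None)
            ll1 = _ordinal_loglik(y, theta[:, None])
            X3 = np.column_stack([theta, g, theta * g])
            ll3 = _ordinal_loglik(y, X3)
            entry = {
                "r2_m1": 1 - ll1 / ll0,
                "r2_m3": 1 - ll3 / ll0,
                "delta_r2": (ll3 - ll1) / (-ll0),
            }
            if include_m2:
                ll2 = _ordinal_loglik(y, np.column_stack([theta, g]))
                entry["r2_m2"] = 1 - ll2 / ll0
                entry["delta_r2_uniform"] = (ll2 - ll1) / (-ll0)
                entry["delta_r2_nonuniform"] = (ll3 - ll2) / (-ll0)
            stats[iid] = entry
            if entry["delta_r2"] > r2_change_max:
                flagged.append(iid)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            stats[iid] = {"untestable": True, "diagnostic": str(exc)}
    return DIFResult(group.name, stats, tuple(flagged))


# ---------------------------------------------------------------------------
# step 6: discrimination
# ---------------------------------------------------------------------------

def discrimination_filter(
    bank: ItemBank, thresholds: QCThresholds = QCThresholds()
) -> tuple[str, ...]:
    """Item ids with discrimination below ``a_min``."""
    return tuple(it.item_id for it in bank if it.a < thresholds.a_min)


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    thresholds: QCThresholds
    excluded: dict  # item_id -> reason code
    surviving: tuple[str, ...]
    iterations: list  # one dict per wave
    final_bank: ItemBank | None
    final_calibration: CalibrationResult | None

    def to_dict(self) -> dict:
        return {
            "thresholds": asdict(self.thresholds),
            "excluded": dict(self.excluded),
            "surviving": list(self.surviving),
            "n_waves": len(self.iterations),
            "iterations": self.iterations,
        }

    def to_markdown(self) -> str:
        lines = ["# Item-bank QC report", ""]
        lines.append(f"Surviving items: {len(self.surviving)}")
        lines.append(f"Excluded items: {len(self.excluded)}")
        lines.append("")
        if self.excluded:
            lines.append("| item | reason |")
            lines.append("|------|--------|")
            for iid, reason in sorted(self.excluded.items()):
                lines.append(f"| {iid} | {reason} |")
        return "\n".join(lines)


def _pick_q3_victim(pair, item_h: Mapping[str, float], bank: ItemBank) -> str:
    """Lower item H loses; ties broken by lower a, then lexicographic id."""
    a_id, b_id, _ = pair
    return min((a_id, b_id), key=lambda iid: (item_h[iid], bank[iid].a, iid))


def run_qc_pipeline(
    responses: ResponseMatrix,
    groups: Sequence[GroupingVariable] = (),
    thresholds: QCThresholds = QCThresholds(),
    grid: QuadratureGrid = DEFAULT_GRID,
    controls: EMControls = EMControls(),
    max_waves: int = 10,
) -> QCReport:
    """Run the six screening steps to a fixed point.

    Steps run in order (unidimensionality, local independence,
    monotonicity, DIF, item fit, discrimination) with recalibration after
    each exclusion wave; the pipeline repeats until a full wave excludes
    nothing. Without grouping variables the DIF step is skipped. Raises if
    the screens exhaust the pool.
    """
    surviving = list(responses.item_ids)
    excluded: dict[str, str] = {}
    iterations: list[dict] = []
    calib: CalibrationResult | None = None

    def drop(ids, reason, wave_log):
        for iid in ids:
            excluded[iid] = reason
            surviving.remove(iid)
            wave_log["exclusions"].append({"item": iid, "reason": reason})
        if ids:
            logger.info("QC wave %d: excluded %s (%s)", len(iterations) + 1, list(ids), reason)
        if len(surviving) < 3:
            raise RuntimeError("no bank survives: pipeline exhausted the item pool")

    for wave in range(1, max_waves + 1):
        wave_log = {"wave": wave, "exclusions": []}
        changed = False

        # -- step 1: unidimensionality --------------------------------------
        while True:
            efa = efa_screen(responses.subset_items(surviving), thresholds)
            if not efa.excluded:
                break
            drop(efa.excluded, "unidimensionality", wave_log)
            changed = True
        wave_log["efa"] = {
            "first_factor_proportion": efa.first_factor_proportion,
            "eigenvalue_ratio": efa.eigenvalue_ratio,
            "passed": efa.passed,
        }

        calib = calibrate_grm(
            responses.subset_items(surviving), grid, controls
        )

        # -- step 3: local independence (Q3) --------------------------------
        while True:
            q3 = q3_matrix(
                responses.subset_items(surviving), calib.bank, grid, thresholds.q3_max
            )
            if not q3.flagged_pairs:
                break
            item_h = mokken_scalability(
                responses.subset_items(surviving), thresholds.h_min
            ).item_h
            victims = []
            alive = set(surviving)
            for pair in q3.flagged_pairs:
                if pair[0] in alive and pair[1] in alive:
                    v = _pick_q3_victim(pair, item_h, calib.bank)
                    victims.append(v)
                    alive.discard(v)
            drop(victims, "local_dependence", wave_log)
            changed = True
            calib = calibrate_grm(responses.subset_items(surviving), grid, controls)

        # -- step 4: monotonicity (Mokken) ----------------------------------
        while True:
            mok = mokken_scalability(responses.subset_items(surviving), thresholds.h_min)
            if not mok.excluded:
                break
            drop(mok.excluded, "monotonicity", wave_log)
            changed = True
        wave_log["scale_h"] = mok.scale_h
        if changed:
            calib = calibrate_grm(responses.subset_items(surviving), grid, controls)

        # -- step 5: DIF then item fit, step 6: discrimination --------------
        while groups:
            dif_flagged: list[str] = []
            for gv in groups:
                res = dif_ordinal_logistic(
                    responses.subset_items(surviving), gv, calib.bank, grid,
                    thresholds.dif_r2_change_max,
                )
                dif_flagged += [i for i in res.flagged if i not in dif_flagged]
            if not dif_flagged:
                break
            drop(dif_flagged, "dif", wave_log)
            changed = True
            calib = calibrate_grm(responses.subset_items(surviving), grid, controls)

        while True:
            fit = sx2_itemfit(
                responses.subset_items(surviving), calib.bank, grid,
                alpha=thresholds.sx2_alpha,
            )
            if not fit.flagged:
                break
            drop(fit.flagged, "item_fit", wave_log)
            changed = True
            calib = calibrate_grm(responses.subset_items(surviving), grid, controls)

        while True:
            low = discrimination_filter(calib.bank, thresholds)
            if not low:
                break
            drop(low, "discrimination", wave_log)
            changed = True
            calib = calibrate_grm(responses.subset_items(surviving), grid, controls)

        iterations.append(wave_log)
        if not changed:
            break

    return QCReport(
        thresholds=thresholds,
        excluded=excluded,
        surviving=tuple(surviving),
        iterations=iterations,
        final_bank=calib.bank if calib else None,
        final_calibration=calib,
    )
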