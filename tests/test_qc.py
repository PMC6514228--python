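"""Bank-construction QC: EFA screen, Q3, Mokken H, S-X2, DIF, pipeline."""

import itertools

import numpy as np
import pytest

from catia.bank import ItemBank, ItemRecord
from catia.calibrate import calibrate_grm
from catia.grm import QuadratureGrid, category_prob_table, simulate_responses
from catia.qc import (
    GroupingVariable,
    QCThresholds,
    dif_ordinal_logistic,
    discrimination_filter,
    efa_screen,
    eap_thetas,
    lord_wingersky,
    mokken_scalability,
    q3_matrix,
    run_qc_pipeline,
    sx2_itemfit,
)
from catia.responses import ResponseMatrix
from catia.synthetic import (
    DependentPair,
    DIFItem,
    NoiseItem,
    SecondFactor,
    SyntheticDesign,
    generate_bank,
    generate_population,
    generate_responses,
)


def synth(seed, n_persons=1000, n_items=12, defects=()):
    d = SyntheticDesign(n_persons=n_persons, n_items=n_items, seed=seed, defects=defects)
    bank = generate_bank(d)
    rm = generate_responses(bank, generate_population(d), d)
    return bank, rm


class TestEFAScreen:
    def test_one_factor_data_passes_cleanly(self, clean_responses):
        res = efa_screen(clean_responses)
        assert res.passed
        assert res.first_factor_proportion > 0.20
        assert res.eigenvalue_ratio > 4
        assert res.excluded == ()

    def test_two_independent_factors_fail_the_ratio(self):
        d1 = SyntheticDesign(n_persons=1500, n_items=10, seed=31)
        d2 = SyntheticDesign(n_persons=1500, n_items=10, seed=32)
        b1, b2 = generate_bank(d1), generate_bank(d2)
        rm1 = generate_responses(b1, generate_population(d1), d1)
        rm2 = generate_responses(b2, generate_population(d2), d2)
        ids = tuple(f"F{k}-{i}" for k in (1, 2) for i in range(10))
        combined = ResponseMatrix(ids, np.hstack([rm1.scores, rm2.scores]))
        res = efa_screen(combined)
        assert res.eigenvalue_ratio < 2
        assert not res.passed

    def test_noise_item_is_flagged_by_low_loading(self):
        _, rm = synth(33, defects=(NoiseItem(5),))
        res = efa_screen(rm)
        assert res.loadings["SYN-06"] < 0.4
        assert "SYN-06" in res.excluded

    def test_constant_item_raises_naming_item(self):
        ids = ("A-1", "A-2", "A-3")
        scores = np.random.default_rng(0).integers(0, 5, (50, 3))
        scores[:, 1] = 2
        with pytest.raises(ValueError, match="A-2"):
            efa_screen(ResponseMatrix(ids, scores))


class TestQ3:
    def test_symmetry_and_clean_data_below_cutoff(self, clean_bank, clean_responses, grid):
        cal = calibrate_grm(clean_responses, grid)
        res = q3_matrix(clean_responses, cal.bank, grid)
        np.testing.assert_allclose(res.matrix, res.matrix.T, equal_nan=True)
        off = res.matrix[~np.isnan(res.matrix)]
        assert np.all(np.abs(off) < 0.36)
        assert off.mean() < 0  # residual correlations are slightly negative on average
        assert res.flagged_pairs == ()

    def test_planted_dependent_pair_is_flagged(self, grid):
        bank, rm = synth(35, defects=(DependentPair(2, 3, 0.1),))
        cal = calibrate_grm(rm, grid)
        res = q3_matrix(rm, cal.bank, grid)
        flagged_ids = {frozenset(p[:2]) for p in res.flagged_pairs}
        assert frozenset(("SYN-03", "SYN-04")) in flagged_ids


class TestMokken:
    def test_perfect_guttman_scale_has_h_of_one(self):
        # comonotone polytomous data: item j scores clip(t - j, 0, 4)
        t = np.repeat(np.arange(9), 30)
        scores = np.stack([np.clip(t - j, 0, 4) for j in range(4)], axis=1)
        res = mokken_scalability(ResponseMatrix(("G-1", "G-2", "G-3", "G-4"), scores))
        assert res.scale_h == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_scale_near_zero(self):
        scores = np.random.default_rng(41).integers(0, 5, (5000, 10))
        res = mokken_scalability(ResponseMatrix(tuple(f"R-{j}" for j in range(10)), scores))
        assert abs(res.scale_h) < 0.05

    def test_grm_data_is_scalable(self, clean_responses):
        res = mokken_scalability(clean_responses)
        assert res.scale_h > 0.3
        assert res.excluded == ()

    def test_zero_variance_item_raises(self):
        scores = np.random.default_rng(4).integers(0, 5, (40, 3))
        scores[:, 0] = 1
        with pytest.raises(ValueError, match="Z-1"):
            mokken_scalability(ResponseMatrix(("Z-1", "Z-2", "Z-3"), scores))


class TestSX2:
    def test_lord_wingersky_equals_exhaustive_enumeration(self, packaged_bank, grid):
        """Score distribution of 4 five-category items vs all 625 combinations."""
        sub = packaged_bank.subset(packaged_bank.item_ids[:4])
        nodes = np.array([-1.3, 0.0, 0.9])
        table = category_prob_table(sub, nodes)
        lw = lord_wingersky(table)
        brute = np.zeros((len(nodes), 17))
        for combo in itertools.product(range(5), repeat=4):
            p = np.ones(len(nodes))
            for j, c in enumerate(combo):
                p *= table[j, :, c]
            brute[:, sum(combo)] += p
        np.testing.assert_allclose(lw, brute, atol=1e-12)

    def test_type_one_error_near_nominal(self, clean_bank, grid):
        """Rejection rate at alpha = 0.01 on model-conformant data."""
        rng = np.random.default_rng(2024)
        rej = tot = 0
        for _ in range(50):
            rm = simulate_responses(clean_bank, rng.standard_normal(1000), rng)
            res = sx2_itemfit(rm, clean_bank, grid)
            for s in res.stats.values():
                if "p" in s:
                    tot += 1
                    rej += s["p"] < 0.01
        assert 0.002 <= rej / tot <= 0.03

    def test_power_against_misstated_slope(self, clean_bank, grid):
        """Item generated with slope 3.0 but scored with slope 1.0 must misfit."""
        rng = np.random.default_rng(7)
        target = clean_bank.items[0]
        gen = list(clean_bank.items)
        gen[0] = ItemRecord(target.item_id, target.source_scale, target.domain, "", 3.0, target.b)
        forced = list(clean_bank.items)
        forced[0] = ItemRecord(target.item_id, target.source_scale, target.domain, "", 1.0, target.b)
        hits = 0
        for _ in range(10):
            rm = simulate_responses(ItemBank(tuple(gen)), rng.standard_normal(1000), rng)
            res = sx2_itemfit(rm, ItemBank(tuple(forced)), grid)
            hits += res.stats[target.item_id]["p"] < 0.01
        assert hits >= 8


class TestDIF:
    def test_coin_flip_groups_rarely_flagged(self, grid):
        """Null flag rate stays at or below 5% when groups carry no signal."""
        rng = np.random.default_rng(51)
        d = SyntheticDesign(n_persons=500, n_items=6, seed=52)
        bank = generate_bank(d)
        flags = tot = 0
        for _ in range(50):
            rm = simulate_responses(bank, rng.standard_normal(500), rng)
            gv = GroupingVariable("coin", rng.integers(0, 2, 500))
            res = dif_ordinal_logistic(rm, gv, bank, grid)
            tot += len(res.stats)
            flags += len(res.flagged)
        assert flags / tot <= 0.05

    def test_planted_threshold_shift_detected(self, grid):
        """DIF with a 0.8 threshold shift is flagged at n = 1,000 (power >= 0.8)."""
        hits = 0
        for seed in range(10):
            bank, rm = synth(100 + seed, n_items=10, defects=(DIFItem(0, "gender", 0.8),))
            gv = GroupingVariable.from_covariate(rm, "gender")
            res = dif_ordinal_logistic(rm, gv, bank, grid)
            hits += "SYN-01" in res.flagged
        assert hits >= 8

    def test_duplicated_persons_give_zero_r2_change(self, grid):
        bank, rm = synth(61, n_persons=300, n_items=6)
        doubled = ResponseMatrix(rm.item_ids, np.vstack([rm.scores, rm.scores]))
        gv = GroupingVariable("copy", np.r_[np.zeros(300, int), np.ones(300, int)])
        res = dif_ordinal_logistic(doubled, gv, bank, grid)
        for s in res.stats.values():
            assert abs(s["delta_r2"]) < 1e-4


class TestDiscrimination:
    def test_packaged_bank_has_no_low_slopes(self, packaged_bank):
        assert discrimination_filter(packaged_bank) == ()

    def test_boundary_slope_excluded(self):
        items = (
            ItemRecord("L-1", "IAT", "salience", "", 0.99, (-1, 0, 1, 2)),
            ItemRecord("L-2", "IAT", "salience", "", 1.01, (-1, 0, 1, 2)),
        )
        assert discrimination_filter(ItemBank(items)) == ("L-1",)

    def test_zero_floor_excludes_nothing(self, packaged_bank):
        assert discrimination_filter(packaged_bank, QCThresholds(a_min=0.0)) == ()


class TestPipeline:
    def test_clean_data_passes_untouched(self):
        bank, rm = synth(71, n_persons=800, n_items=12)
        gv = GroupingVariable.from_covariate(rm, "gender")
        report = run_qc_pipeline(rm, [gv])
        assert report.excluded == {}
        assert len(report.iterations) == 1
        assert set(report.surviving) == set(bank.item_ids)

    def test_planted_defects_get_their_reason_codes(self):
        defects = (NoiseItem(0), DependentPair(2, 3, 0.1), DIFItem(5, "gender", 0.8))
        bank, rm = synth(73, n_persons=1000, n_items=14, defects=defects)
        gv = GroupingVariable.from_covariate(rm, "gender")
        report = run_qc_pipeline(rm, [gv])
        assert report.excluded.get("SYN-01") == "unidimensionality"
        assert report.excluded.get("SYN-06") == "dif"
        pair = {k: v for k, v in report.excluded.items() if k in ("SYN-03", "SYN-04")}
        assert list(pair.values()) == ["local_dependence"]

    def test_fixed_point_is_idempotent(self):
        defects = (NoiseItem(0), DependentPair(2, 3, 0.1))
        _, rm = synth(75, n_persons=800, n_items=12, defects=defects)
        first = run_qc_pipeline(rm, [])
        again = run_qc_pipeline(rm.subset_items(first.surviving), [])
        assert again.excluded == {}
        assert again.surviving == first.surviving

    def test_exhausted_pool_raises(self):
        scores = np.random.default_rng(0).integers(0, 5, (300, 4))
        rm = ResponseMatrix(tuple(f"N-{j}" for j in range(4)), scores)
        with pytest.raises(RuntimeError, match="no bank survives"):
            run_qc_pipeline(rm, [])


def test_eap_thetas_track_true_traits(clean_bank, clean_responses, grid):
    d = SyntheticDesign(n_persons=1000, n_items=20, seed=11)
    pop = generate_population(d)
    theta_hat = eap_thetas(clean_responses, clean_bank, grid)
    assert np.corrcoef(theta_hat, pop.theta)[0, 1] > 0.9
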