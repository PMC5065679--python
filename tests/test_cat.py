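"""Adaptive-testing engine: EAP, item selection, stopping, simulation."""

import numpy as np
import pytest

import catbank as cb
from catbank.cat import (
    CatConfig,
    _GridBank,
    eap_estimate,
    first_item,
    reliability_matched_comparison,
    reliability_to_se,
    run_cat,
    se_to_reliability,
    select_next_item,
    simulate_cat,
)
from catbank.synthetic import simulate_responses

from conftest import make_item


@pytest.fixture(scope="module")
def config():
    return CatConfig(stopping_se=0.32, seed=5)


class TestEap:
    def test_no_responses_returns_prior(self, cat_bank, config):
        est = eap_estimate({}, cat_bank, config)
        assert est.theta == pytest.approx(0.0, abs=1e-3)
        assert est.se == pytest.approx(1.0, abs=1e-3)

    def test_mirrored_patterns_symmetric(self, config):
        # a bank symmetric about zero: mirrored responses mirror theta
        items = [
            make_item("a", 5, -1.0),
            make_item("b", 5, 0.0),
            make_item("c", 5, 1.0),
        ]
        bank = cb.ItemBank(items=items)
        est1 = eap_estimate({"a": 4, "b": 3, "c": 2}, bank, config)
        est2 = eap_estimate({"a": 2, "b": 1, "c": 0}, bank, config)
        assert est1.theta == pytest.approx(-est2.theta, abs=1e-9)

    def test_unknown_item_rejected(self, cat_bank, config):
        with pytest.raises(cb.InvalidInputError):
            eap_estimate({"nope": 1}, cat_bank, config)

    def test_matches_dense_grid_oracle_single_item(self, config):
        """Brute-force numerical integration on a 10,001-point grid."""
        item = make_item("d", 2, 0.0)
        bank = cb.ItemBank(items=[item])
        est = eap_estimate({"d": 1}, bank, config)
        grid = np.linspace(-4.5, 4.5, 10001)
        from scipy import stats

        w = stats.norm.pdf(grid)
        lik = cb.category_probabilities(grid, item, config.D)[:, 1]
        post = w * lik
        post /= post.sum()
        theta = post @ grid
        se = np.sqrt(post @ (grid - theta) ** 2)
        assert est.theta == pytest.approx(theta, abs=1e-4)
        assert est.se == pytest.approx(se, abs=1e-4)


class TestSelection:
    def test_point_mass_posterior_equals_mfi(self, cat_bank, config):
        gb = _GridBank(cat_bank, config.grid(), config.D)
        q0 = 40
        point = np.zeros(config.n_grid)
        point[q0] = 1.0
        mpwi = select_next_item(cat_bank, point, cat_bank.item_ids, "MPWI",
                                config=config)
        mfi = select_next_item(cat_bank, point, cat_bank.item_ids, "MFI",
                               theta=float(gb.grid[q0]), config=config)
        assert mpwi == mfi

    def test_tie_break_by_bank_order(self, config):
        items = [make_item("first", 5, 0.0), make_item("second", 5, 0.0)]
        bank = cb.ItemBank(items=items)
        flat = np.full(config.n_grid, 1.0 / config.n_grid)
        assert select_next_item(bank, flat, bank.item_ids, "MPWI",
                                config=config) == "first"

    def test_flat_posterior_matches_brute_force(self, config):
        """Exhaustive oracle: average information over every grid node."""
        rng = np.random.default_rng(91)
        items = []
        for i in range(5):
            thr = np.sort(rng.normal(0, 1.2, 4))
            items.append(make_item(f"t{i}", 5, float(rng.uniform(-2, 2)),
                                   thr - thr.mean()))
        bank = cb.ItemBank(items=items)
        flat = np.full(config.n_grid, 1.0 / config.n_grid)
        chosen = select_next_item(bank, flat, bank.item_ids, "MPWI",
                                  config=config)
        grid = config.grid()
        best, best_val = None, -np.inf
        for it in items:
            val = float(np.mean(cb.item_information(grid, it, config.D)))
            if val > best_val:
                best, best_val = it.item_id, val
        assert chosen == best

    def test_empty_pool_rejected(self, cat_bank, config):
        flat = np.full(config.n_grid, 1.0 / config.n_grid)
        with pytest.raises(cb.InvalidInputError):
            select_next_item(cat_bank, flat, [], "MPWI", config=config)


class TestFirstItem:
    def test_item_at_prior_mean_wins(self, config):
        items = [make_item("far1", 5, -2.5), make_item("mid", 5, 0.0),
                 make_item("far2", 5, 2.5)]
        bank = cb.ItemBank(items=items)
        assert first_item(bank, config) == "mid"

    def test_follows_shifted_prior_mean(self):
        items = [make_item("low", 5, 0.0), make_item("high", 5, 2.0)]
        bank = cb.ItemBank(items=items)
        cfg = CatConfig(stopping_se=0.32, prior_mean=2.0, grid_range=(-4.5, 8.0),
                        n_grid=101)
        assert first_item(bank, cfg) == "high"

    def test_consistent_with_selection_under_prior_posterior(self, cat_bank, config):
        # the first item maximises information at the prior mean, i.e. MFI
        # selection under the zero-response posterior
        est = eap_estimate({}, cat_bank, config)
        via_select = select_next_item(
            cat_bank, est.posterior, cat_bank.item_ids, "MFI",
            theta=config.prior_mean, config=config,
        )
        assert first_item(cat_bank, config) == via_select


class TestRunCat:
    def test_loose_rule_stops_after_mandatory_first_item(self, cat_bank):
        cfg = CatConfig(stopping_se=10.0, seed=1)
        res = run_cat(0.0, cat_bank, cfg)
        assert res.n_items == 1
        assert res.stop_reason == "se_met"

    def test_unreachable_rule_exhausts_pool(self, cat_bank):
        cfg = CatConfig(stopping_se=0.0, seed=1)
        res = run_cat(0.0, cat_bank, cfg)
        assert res.n_items == cat_bank.n_items
        assert res.stop_reason == "pool_exhausted"
        assert len(set(res.administered)) == cat_bank.n_items

    def test_stricter_rule_needs_at_least_as_many_items(self, cat_bank):
        rng = np.random.default_rng(7)
        for seed in range(10):
            theta = float(rng.standard_normal())
            vec_resp = simulate_responses(
                cat_bank, [theta], seed=seed, D=1.7
            )
            vec = {i: int(vec_resp.data.iloc[0][i]) for i in cat_bank.item_ids}
            counts = []
            for se in (0.55, 0.45, 0.32):
                res = run_cat(vec, cat_bank, CatConfig(stopping_se=se))
                counts.append(res.n_items)
            assert counts[0] <= counts[1] <= counts[2]

    def test_full_pool_equals_nonadaptive_eap(self, cat_bank):
        cfg = CatConfig(stopping_se=0.0, seed=3)
        vec_resp = simulate_responses(cat_bank, [0.7], seed=4, D=1.7)
        vec = {i: int(vec_resp.data.iloc[0][i]) for i in cat_bank.item_ids}
        res = run_cat(vec, cat_bank, cfg)
        full = eap_estimate(vec, cat_bank, cfg)
        assert res.final_theta == pytest.approx(full.theta, abs=1e-10)
        assert res.final_se == pytest.approx(full.se, abs=1e-10)

    def test_se_trajectory_mostly_decreasing(self, cat_bank):
        cfg = CatConfig(stopping_se=0.0, seed=11)
        rng = np.random.default_rng(11)
        steps = 0
        decreases = 0
        for _ in range(60):
            res = run_cat(float(rng.standard_normal()), cat_bank, cfg,
                          rng=rng)
            ses = np.array(res.ses)
            steps += len(ses) - 1
            decreases += int((np.diff(ses) <= 1e-12).sum())
        assert decreases / steps >= 0.99


class TestSimulateCat:
    def test_saturation_when_rule_unreachable(self, cat_bank):
        cfg = CatConfig(stopping_se=0.01, seed=13)
        summary = simulate_cat(cat_bank, None, cfg, n_iterations=25)
        row = summary.table.loc[0.01]
        assert row["items_mean"] == cat_bank.n_items
        assert row["n_pool_exhausted"] == 25

    def test_mean_se_below_threshold_when_pool_not_exhausted(self, cat_bank):
        cfg = CatConfig(stopping_se=0.45, seed=14)
        summary = simulate_cat(cat_bank, None, cfg, n_iterations=100)
        per = summary.per_rule[0.45]
        ok = ~per["exhausted"]
        assert ok.any()
        assert per["final_se"][ok].max() < 0.45

    def test_reliability_identity_and_correlation_bounds(self, cat_bank):
        cfg = CatConfig(stopping_se=0.45, seed=15)
        summary = simulate_cat(cat_bank, None, cfg, n_iterations=100,
                               stopping_rules=[0.45, 0.55])
        for _, row in summary.table.iterrows():
            assert row["reliability"] == pytest.approx(
                1 - row["mean_se"] ** 2
            )
            assert -1 <= row["correlation_with_full"] <= 1
            assert row["items_min"] <= row["items_mean"] <= row["items_max"]

    def test_explicit_theta_list_accepted(self, cat_bank):
        cfg = CatConfig(stopping_se=0.55, seed=16)
        thetas = [-1.0, 0.0, 1.0]
        summary = simulate_cat(cat_bank, thetas, cfg, n_iterations=3)
        assert np.allclose(summary.per_rule[0.55]["theta_true"], thetas)


class TestReliabilityConversion:
    def test_round_trip_identity(self):
        for alpha in (0.0, 0.3, 0.7, 0.9, 0.99):
            assert se_to_reliability(reliability_to_se(alpha)) == pytest.approx(alpha)

    def test_zero_reliability_gives_prior_sd(self):
        assert reliability_to_se(0.0) == 1.0

    def test_domain_error(self):
        with pytest.raises(cb.InvalidInputError):
            reliability_to_se(1.0)
        with pytest.raises(cb.InvalidInputError):
            reliability_to_se(-0.1)


class TestReliabilityMatched:
    def test_matched_se_and_reduction_arithmetic(self, cat_bank):
        cfg = CatConfig(seed=17)
        table = reliability_matched_comparison(
            cat_bank, [("psych", 6, 0.82)], cfg, n_iterations=40
        )
        row = table.loc["psych"]
        assert row["matched_se"] == 0.42
        expect = 100 * (6 - row["items_median"]) / 6
        assert row["percent_reduction"] == pytest.approx(expect)

    def test_saturated_reliability_needs_full_bank(self, cat_bank):
        # reliability beyond what the bank can deliver: every test runs long
        cfg = CatConfig(seed=18)
        table = reliability_matched_comparison(
            cat_bank, [("dream", cat_bank.n_items, 0.97)], cfg, n_iterations=25
        )
        assert table.loc["dream", "items_median"] == cat_bank.n_items
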