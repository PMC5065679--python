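"""Residuals, item fit, threshold repair, dependency, DIF, dimensionality."""

import numpy as np
import pandas as pd
import pytest

import catbank as cb
from catbank import diagnostics as dx
from catbank.diagnostics import SemanticMergeError
from catbank.pcm import abilities_frame
from catbank.synthetic import (
    GeneratorSpec,
    generate_item_bank,
    inject_pathology,
    simulate_responses,
)

from conftest import make_item


@pytest.fixture(scope="module")
def big_clean():
    """n=2000 model-true responses for residual-moment checks."""
    bank = generate_item_bank(GeneratorSpec(seed=31), n_items=12)
    rng = np.random.default_rng(32)
    thetas = rng.standard_normal(2000)
    resp = simulate_responses(bank, thetas, seed=33)
    ab = cb.estimate_person_locations(resp, bank, "WL")
    return bank, resp, ab


class TestStandardizedResiduals:
    def test_model_true_moments(self, big_clean):
        bank, resp, ab = big_clean
        resid = dx.standardized_residuals(resp, bank, ab)
        z = resid.values.to_numpy()
        assert abs(np.nanmean(z)) <= 0.05
        assert abs(np.nanstd(z) - 1.0) <= 0.1

    def test_sign_follows_deviation(self):
        item = make_item("s", 5, 0.0)
        bank = cb.ItemBank(items=[item, make_item("t", 5, 0.0)])
        resp = cb.ResponseMatrix.from_array(
            np.array([[4.0, 0.0]]), item_ids=["s", "t"]
        )
        ab = [cb.PersonAbility("P0001", 0.0, 0.5, "WL")]
        resid = dx.standardized_residuals(resp, bank, ab)
        assert resid.values.iloc[0]["s"] > 0  # above conditional expectation
        assert resid.values.iloc[0]["t"] < 0

    def test_duplicated_item_gives_identical_columns(self, bank12, clean_responses):
        resp, _ = clean_responses
        dup, truth = inject_pathology(resp, "dependency", {"noise": 0.0}, seed=1)
        bank = cb.ItemBank(
            items=list(bank12.items)
            + [make_item(truth["new_item"], 5,
                         bank12[truth["source_item"]].location,
                         bank12[truth["source_item"]].thresholds)]
        )
        ab = cb.estimate_person_locations(dup, bank, "WL")
        resid = dx.standardized_residuals(dup, bank, ab)
        a = resid.values[truth["source_item"]]
        b = resid.values[truth["new_item"]]
        assert np.allclose(a, b, equal_nan=True)

    def test_person_mismatch_rejected(self, bank12, clean_responses):
        resp, _ = clean_responses
        ab = [cb.PersonAbility("ghost", 0.0, 0.5, "WL")]
        with pytest.raises(cb.InvalidInputError):
            dx.standardized_residuals(resp, bank12, ab)


class TestItemFit:
    def test_df_arithmetic_minimal_intervals(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        report = dx.item_fit(resp, bank12, clean_abilities, n_class_intervals=2)
        assert (report.table["df"] == 1).all()
        report5 = dx.item_fit(resp, bank12, clean_abilities, n_class_intervals=5)
        assert (report5.table["df"] == 4).all()
        assert report5.total_df == 12 * 4

    def test_pvalues_valid(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        report = dx.item_fit(resp, bank12, clean_abilities)
        p = report.table["p_value"]
        assert ((p >= 0) & (p <= 1)).all()

    def test_overdiscriminating_item_negative_fit_residual(self):
        """An item steeper than the PCM predicts yields residuals that are
        too small, hence a negative fit residual, flagged beyond -2.5."""
        bank = generate_item_bank(GeneratorSpec(seed=41), n_items=10)
        rng = np.random.default_rng(42)
        thetas = rng.standard_normal(2000)
        resp = simulate_responses(bank, thetas, seed=43)
        steep = bank.items[0]
        p = cb.category_probabilities(thetas, steep, 2.5)  # slope 2.5, not 1
        u = rng.random(len(thetas))
        resp.data[steep.item_id] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        ab = cb.estimate_person_locations(resp, bank, "WL")
        report = dx.item_fit(resp, bank, ab)
        fr = report.table.loc[steep.item_id, "fit_residual"]
        assert fr < -2.5
        assert report.table.loc[steep.item_id, "flagged_reason"] != "none"


class TestThresholds:
    @pytest.mark.parametrize(
        "thresholds,expected_status,expected_pair",
        [
            ((-1.5, -0.5, 0.5, 1.5), "ordered", None),
            ((-1.0, 1.0, 0.5, -0.5), "disordered", (2, 3)),
            ((0.0,), "ordered", None),  # dichotomous: vacuously ordered
        ],
    )
    def test_detection(self, thresholds, expected_status, expected_pair):
        thr = np.asarray(thresholds) - np.mean(thresholds)
        item = make_item("x", len(thresholds) + 1, 0.0, thr)
        status, pair = dx.detect_disordered_thresholds(item)
        assert status == expected_status
        assert pair == expected_pair

    def test_collapse_matches_published_rescoring(self, clean_responses):
        """Five categories disordered between thresholds 3 and 4 rescore
        1-2-3-4-5 to 1-2-3-3-4."""
        resp, _ = clean_responses
        thr = np.array([-1.5, -0.5, 1.0, 0.2])
        item = make_item("item001", 5, 0.0, thr - thr.mean())
        status, pair = dx.detect_disordered_thresholds(item)
        assert status == "disordered" and pair == (3, 4)
        result = dx.collapse_categories(item, resp)
        assert result.merge_map == {0: 0, 1: 1, 2: 2, 3: 2, 4: 3}
        assert result.refit_required
        col = result.responses.data["item001"]
        assert set(col.dropna().unique()) <= {0, 1, 2, 3}

    def test_collapse_noop_when_ordered(self, clean_responses):
        resp, _ = clean_responses
        item = make_item("item001", 5, 0.0)
        with pytest.warns(UserWarning, match="already ordered"):
            result = dx.collapse_categories(item, resp)
        assert not result.refit_required

    def test_collapse_rejected_across_semantic_boundary(self, clean_responses):
        resp, _ = clean_responses
        thr = np.array([-1.5, -0.5, 1.0, 0.2])  # merge 3 -> 2 proposed
        item = make_item("item001", 5, 0.0, thr - thr.mean())
        groups = [[0, 1], [2], [3, 4]]  # negative / neutral / positive anchors
        with pytest.raises(SemanticMergeError):
            dx.collapse_categories(item, resp, semantic_groups=groups)


class TestLocalDependency:
    def test_duplicate_flagged_with_unit_correlation(self, bank12, clean_responses):
        resp, _ = clean_responses
        dup, truth = inject_pathology(resp, "dependency", {"noise": 0.0}, seed=2)
        bank = cb.ItemBank(
            items=list(bank12.items)
            + [make_item(truth["new_item"], 5,
                         bank12[truth["source_item"]].location,
                         bank12[truth["source_item"]].thresholds)]
        )
        ab = cb.estimate_person_locations(dup, bank, "WL")
        resid = dx.standardized_residuals(dup, bank, ab)
        report = dx.local_dependency(resid, cutoff=0.2)
        top = report.flagged_pairs[0]
        assert {top[0], top[1]} == {truth["source_item"], truth["new_item"]}
        assert top[2] == pytest.approx(1.0)

    def test_unit_cutoff_flags_nothing(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        resid = dx.standardized_residuals(resp, bank12, clean_abilities)
        assert dx.local_dependency(resid, cutoff=1.0).flagged_pairs == []

    def test_zero_variance_column_excluded(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        resid = dx.standardized_residuals(resp, bank12, clean_abilities)
        resid.values["item001"] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            report = dx.local_dependency(resid)
        assert "item001" in report.excluded_items
        assert report.correlations.shape == (11, 11)

    def test_symmetry_and_unit_diagonal(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        resid = dx.standardized_residuals(resp, bank12, clean_abilities)
        c = dx.local_dependency(resid).correlations.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)


class TestDifAnova:
    def test_single_level_factor_skipped(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        resid = dx.standardized_residuals(resp, bank12, clean_abilities)
        factors = pd.DataFrame({"site": ["uk"] * len(resp.person_ids)},
                               index=resp.person_ids)
        with pytest.warns(UserWarning, match="one level"):
            report = dx.dif_anova(resid, factors)
        assert len(report.table) == 0

    def test_clean_data_pvalues_and_bonferroni_subset(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        rng = np.random.default_rng(51)
        factors = pd.DataFrame(
            {"sex": rng.choice(["f", "m"], size=len(resp.person_ids))},
            index=resp.person_ids,
        )
        resid = dx.standardized_residuals(resp, bank12, clean_abilities)
        report = dx.dif_anova(resid, factors)
        t = report.table
        assert len(t) == 12
        for col in ("p_uniform", "p_nonuniform"):
            assert ((t[col] >= 0) & (t[col] <= 1)).all()
        # Bonferroni flags are a subset of unadjusted flags
        assert (t["p_uniform_adj"] >= t["p_uniform"] - 1e-15).all()
        unadj = t["p_uniform"] < report.alpha
        assert (t["flag_uniform"] <= unadj).all()


class TestUnidimensionality:
    def test_forced_identical_subsets_give_zero_t(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        half = bank12.item_ids[:6]
        report = dx.unidimensionality_test(
            resp, bank12, clean_abilities, subsets=(half, half)
        )
        assert np.allclose(report.t_stats.to_numpy(), 0.0)
        assert report.percent_significant == 0.0

    def test_ci_contains_percent_and_partition(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        report = dx.unidimensionality_test(resp, bank12, clean_abilities)
        assert report.computable
        lo, hi = report.ci
        assert lo <= report.percent_significant <= hi
        both = set(report.subset_positive) | set(report.subset_negative)
        assert both == set(bank12.item_ids)

    def test_two_dimensional_data_flags(self, bank12):
        rng = np.random.default_rng(61)
        thetas = rng.standard_normal(500)
        fixture, truth = inject_pathology((bank12, thetas), "multidim", seed=62)
        ab = cb.estimate_person_locations(fixture, bank12, "WL")
        report = dx.unidimensionality_test(fixture, bank12, ab)
        assert report.ci[0] > 5.0  # lower CI bound above the nominal 5%

    def test_small_subset_reported_not_crashed(self, bank12, clean_responses, clean_abilities):
        resp, _ = clean_responses
        report = dx.unidimensionality_test(
            resp, bank12, clean_abilities,
            subsets=(bank12.item_ids[:1], bank12.item_ids[1:]),
        )
        assert not report.computable


class TestPercentExtreme:
    def test_all_maximum_is_hundred(self, bank12):
        vals = np.full((5, 12), 4.0)
        resp = cb.ResponseMatrix.from_array(vals, item_ids=bank12.item_ids)
        assert dx.percent_extreme(resp, bank12) == 100.0

    def test_three_of_320_matches_published_rounding(self, bank12):
        rng = np.random.default_rng(71)
        vals = rng.integers(1, 4, size=(320, 12)).astype(float)  # interior
        vals[0] = 0.0
        vals[1] = 0.0
        vals[2] = 4.0
        resp = cb.ResponseMatrix.from_array(vals, item_ids=bank12.item_ids)
        assert round(dx.percent_extreme(resp, bank12), 2) == 0.94

    def test_no_extremes_is_zero(self, bank12, clean_responses):
        resp, _ = clean_responses
        assert dx.percent_extreme(resp, bank12) == 0.0
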