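"""Agreement statistics against hand-worked values and independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sstats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss
from statsmodels.stats.proportion import proportions_ztest

from milscore.agreement import (
    PanelScores,
    cohen_kappa,
    compare_model_vs_panel,
    confusion_and_kappa,
    fleiss_kappa,
    modal_score,
    odds_ratio_ci,
    two_proportion_z,
    wilson_interval,
)


def _labels_from_counts(counts):
    ref, pred = [], []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            ref.extend([i] * c)
            pred.extend([j] * c)
    return ref, pred


class TestCohenKappa:
    def test_hand_worked_binary_matrix(self):
        """[[40,10],[5,45]]: p_o = 0.85, p_e = 0.5, kappa = 0.70."""
        ref, pred = _labels_from_counts([[40, 10], [5, 45]])
        report = confusion_and_kappa(ref, pred)
        assert report.accuracy == pytest.approx(0.85)
        assert report.kappa == pytest.approx(0.70)
        assert report.confusion.counts.tolist() == [[40, 10], [5, 45]]

    def test_perfect_and_chance_agreement(self):
        ref, pred = _labels_from_counts([[25, 0], [0, 25]])
        assert confusion_and_kappa(ref, pred).kappa == pytest.approx(1.0)
        ref, pred = _labels_from_counts([[25, 25], [25, 25]])
        assert confusion_and_kappa(ref, pred).kappa == pytest.approx(0.0)

    def test_degenerate_single_class_gives_nan_sentinel(self):
        report = confusion_and_kappa([1, 1, 1], [1, 1, 1])
        assert math.isnan(report.kappa)
        assert report.accuracy == 1.0

    def test_matches_sklearn_on_fuzzed_inputs(self, rng):
        for _ in range(200):
            n = rng.integers(5, 60)
            k = rng.integers(2, 5)
            ref = rng.integers(0, k, n)
            pred = rng.integers(0, k, n)
            if len(set(ref) | set(pred)) < 2:
                continue
            ours = cohen_kappa(ref.tolist(), pred.tolist())
            theirs = cohen_kappa_score(ref, pred)
            if math.isnan(theirs):
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(theirs, abs=1e-9)

    def test_linear_weighted_matches_sklearn(self, rng):
        for _ in range(50):
            ref = rng.integers(0, 4, 40)
            pred = rng.integers(0, 4, 40)
            ours = cohen_kappa(ref.tolist(), pred.tolist(), weighted="linear")
            theirs = cohen_kappa_score(ref, pred, weights="linear")
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestFleissKappa:
    def test_hand_worked_three_item_panel(self):
        """Counts [3,0],[0,3],[2,1] -> kappa = (7/9 - 41/81)/(1 - 41/81)."""
        panel = PanelScores(np.array([[0, 0, 0], [1, 1, 1], [0, 0, 1]]))
        expected = (7 / 9 - 41 / 81) / (1 - 41 / 81)
        assert fleiss_kappa(panel) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.55, abs=0.01)

    def test_unanimous_panel(self):
        panel = PanelScores(np.array([[0, 0], [1, 1], [2, 2]]))
        assert fleiss_kappa(panel) == pytest.approx(1.0)

    def test_single_category_is_undefined(self):
        assert math.isnan(fleiss_kappa(PanelScores(np.zeros((4, 3)))))

    def test_items_with_single_rater_dropped_with_warning(self):
        ratings = np.array([[0.0, np.nan], [0.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="fewer than 2 raters"):
            kappa = fleiss_kappa(PanelScores(ratings))
        assert np.isfinite(kappa)

    def test_matches_statsmodels_on_fuzzed_complete_panels(self, rng):
        for _ in range(100):
            items, raters, k = rng.integers(4, 20), rng.integers(2, 6), rng.integers(2, 4)
            ratings = rng.integers(0, k, (items, raters)).astype(float)
            cats = np.unique(ratings)
            if cats.size < 2:
                continue
            table = np.stack(
                [(ratings == c).sum(axis=1) for c in cats], axis=1
            )
            ours = fleiss_kappa(PanelScores(ratings))
            theirs = sm_fleiss(table)
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestModalScore:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([1, 2, 2, 3, 3], 3),  # tied modes resolve upward
            ([0, 0, 1], 0),
            ([0, 1, 2, 3, 3], 3),
            ([2], 2),
        ],
    )
    def test_mode_with_upward_tie_break(self, scores, expected):
        assert modal_score(scores) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            modal_score([])


class TestTwoProportionZ:
    def test_hand_worked_example(self):
        """74/100 vs 93/100: pooled p = 0.835, z ~ -3.62, p ~ 0.0003."""
        res = two_proportion_z(74, 100, 93, 100)
        se = math.sqrt(0.835 * 0.165 * 0.02)
        assert res.z == pytest.approx((0.74 - 0.93) / se, abs=1e-12)
        assert abs(res.z) == pytest.approx(3.62, abs=0.01)
        assert res.p_value == pytest.approx(0.0003, abs=1e-4)
        assert res.significant

    def test_equal_proportions_and_symmetry(self):
        res = two_proportion_z(50, 100, 50, 100)
        assert res.z == 0.0 and res.p_value == pytest.approx(1.0)
        a = two_proportion_z(30, 90, 50, 80)
        b = two_proportion_z(50, 80, 30, 90)
        assert a.z == pytest.approx(-b.z)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_pooled_proportion(self):
        res = two_proportion_z(0, 10, 0, 20)
        assert res.degenerate and res.z == 0.0 and res.p_value == 1.0

    def test_matches_statsmodels_on_fuzzed_inputs(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(5, 200, 2)
            s1, s2 = rng.integers(1, n1), rng.integers(1, n2)
            if s1 == n1 or s2 == n2:
                continue
            ours = two_proportion_z(int(s1), int(n1), int(s2), int(n2))
            z, p = proportions_ztest([s1, s2], [n1, n2])
            assert ours.z == pytest.approx(z, abs=1e-9)
            assert ours.p_value == pytest.approx(p, abs=1e-9)


class TestOddsRatio:
    def test_hand_worked_example(self):
        """[[20,5],[10,40]]: OR = 16, Woolf CI ~ (4.8, 53.1)."""
        res = odds_ratio_ci([[20, 5], [10, 40]])
        assert res.odds_ratio == pytest.approx(16.0)
        se = math.sqrt(1 / 20 + 1 / 5 + 1 / 10 + 1 / 40)
        z = sstats.norm.ppf(0.975)
        assert res.ci_low == pytest.approx(math.exp(math.log(16) - z * se), abs=1e-9)
        assert res.ci_high == pytest.approx(math.exp(math.log(16) + z * se), abs=1e-9)
        assert res.ci_low == pytest.approx(4.8, abs=0.05)
        assert res.ci_high == pytest.approx(53.1, abs=0.1)
        assert res.p_value == pytest.approx(
            sstats.fisher_exact([[20, 5], [10, 40]])[1], abs=1e-12
        )

    def test_balanced_table(self):
        res = odds_ratio_ci([[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_haldane_correction(self):
        res = odds_ratio_ci([[5, 0], [3, 7]])
        assert res.corrected and np.isfinite(res.odds_ratio)
        expected = (5.5 * 7.5) / (0.5 * 3.5)
        assert res.odds_ratio == pytest.approx(expected)

    def test_transposition_invariance(self, rng):
        for _ in range(100):
            t = rng.integers(0, 40, (2, 2))
            if t.sum() == 0:
                continue
            a, b = odds_ratio_ci(t), odds_ratio_ci(t.T)
            assert a.odds_ratio == pytest.approx(b.odds_ratio, abs=1e-9)
            assert a.ci_low == pytest.approx(b.ci_low, abs=1e-9)


class TestWilsonAndPanelComparison:
    def test_wilson_interval_contains_proportion(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            s = int(rng.integers(0, n + 1))
            lo, hi = wilson_interval(s, n)
            assert 0.0 <= lo <= s / n <= hi <= 1.0

    def test_model_identical_to_panel_mode_is_not_significant(self):
        ref = {f"i{k}": k % 2 for k in range(40)}
        model = dict(ref)
        panel = {k: [v, v, 1 - v] for k, v in ref.items()}  # mode == v
        rep = compare_model_vs_panel(ref, model, panel)
        assert rep.model_accuracy == rep.panel_accuracy == 1.0
        assert rep.test.z == 0.0 and not rep.test.significant

    def test_item_set_mismatch_names_missing_ids(self):
        ref = {"a": 1, "b": 0}
        with pytest.raises(KeyError, match="b"):
            compare_model_vs_panel(ref, {"a": 1}, {"a": [1], "b": [0]})


class TestOracleEquivalence:
    """Direct-formula recomputation of every statistic on fuzzed inputs."""

    def test_cohen_kappa_direct_formula(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 50))
            ref = rng.integers(0, 3, n)
            pred = rng.integers(0, 3, n)
            labels = sorted(set(ref) | set(pred))
            k = len(labels)
            C = np.zeros((k, k))
            for r, p in zip(ref, pred):
                C[labels.index(r), labels.index(p)] += 1
            po = np.trace(C) / n
            pe = float(C.sum(1) @ C.sum(0)) / n**2
            ours = cohen_kappa(ref.tolist(), pred.tolist())
            if pe == 1.0:
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx((po - pe) / (1 - pe), abs=1e-9)

    def test_fleiss_kappa_direct_formula(self, rng):
        for _ in range(150):
            items, raters = int(rng.integers(3, 15)), int(rng.integers(2, 6))
            ratings = rng.integers(0, 3, (items, raters)).astype(float)
            cats = np.unique(ratings)
            if cats.size < 2:
                continue
            counts = np.stack([(ratings == c).sum(1) for c in cats], 1)
            pi = (np.sum(counts * (counts - 1), 1)) / (raters * (raters - 1))
            pbar = pi.mean()
            pj = counts.sum(0) / counts.sum()
            pe = np.sum(pj**2)
            assert fleiss_kappa(PanelScores(ratings)) == pytest.approx(
                (pbar - pe) / (1 - pe), abs=1e-9
            )

    def test_odds_ratio_direct_formula(self, rng):
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(1, 40, 4))
            res = odds_ratio_ci([[a, b], [c, d]])
            assert res.odds_ratio == pytest.approx(a * d / (b * c), abs=1e-9)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            z = sstats.norm.ppf(0.975)
            assert res.ci_low == pytest.approx(
                math.exp(math.log(a * d / (b * c)) - z * se), rel=1e-9
            )
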