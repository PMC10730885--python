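"""Nonparametric group tests, correlation, ROC/Youden, odds ratios, logistic fits."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from choriflow.stats import (
    NotAValue,
    SchemaError,
    build_report,
    fit_logistic,
    group_compare,
    odds_ratio_2x2,
    pearson_r,
    roc_auc,
)


class TestGroupCompare:
    def test_exact_mann_whitney_on_tiny_groups(self):
        # {1,2} vs {3,4}: U = 0; 1 of the C(4,2)=6 equally likely rank
        # splits is as extreme, so the exact two-sided p is 2/6
        df = pd.DataFrame({"group": ["a", "a", "b", "b"], "v": [1.0, 2.0, 3.0, 4.0]})
        res = group_compare(df, "v")
        pw = res.pairwise[("a", "b")]
        assert pw["u"] == 0.0
        assert pw["method"] == "exact"
        assert pw["p"] == pytest.approx(2 / 6, abs=1e-12)

    def test_identical_groups_h_zero(self):
        df = pd.DataFrame({"group": list("aabbcc"), "v": [5.0, 5.0] * 3})
        res = group_compare(df, "v")
        assert res.kruskal_h == pytest.approx(0.0, abs=1e-9)
        assert res.kruskal_p == pytest.approx(1.0, abs=1e-9)

    def test_row_permutation_invariance(self, rng):
        df = pd.DataFrame(
            {"group": ["a"] * 10 + ["b"] * 12, "v": rng.normal(size=22)}
        )
        shuffled = df.sample(frac=1.0, random_state=7)
        r1, r2 = group_compare(df, "v"), group_compare(shuffled, "v")
        assert r1.kruskal_p == pytest.approx(r2.kruskal_p, rel=1e-12)
        assert r1.pairwise[("a", "b")]["p"] == pytest.approx(
            r2.pairwise[("a", "b")]["p"], rel=1e-12
        )

    def test_degenerate_group_skipped(self):
        df = pd.DataFrame({"group": ["a", "b", "b"], "v": [1.0, 2.0, 3.0]})
        res = group_compare(df, "v")
        assert res.skipped is not None

    def test_missing_column_raises_schema_error(self):
        with pytest.raises(SchemaError):
            group_compare(pd.DataFrame({"group": ["a"]}), "v")

    def test_two_group_kruskal_matches_mann_whitney_normal_approx(self, rng):
        """Chi-square(1) KW statistic and the two-sided normal MWU p agree
        (no ties), an identity between the two tests."""
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1.0, size=25)
        h, hp = sps.kruskal(x, y)
        _, mp = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert hp == pytest.approx(mp, abs=1e-6)


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        r, p = pearson_r([1, 2, 3], [2, 4, 5])
        assert r == pytest.approx(3 / math.sqrt(2 * 4.0 + 2 * 0.6666666667), abs=1e-6)
        assert r == pytest.approx(0.98198, abs=5e-6)

    def test_zero_variance_flagged(self):
        res = pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert isinstance(res, NotAValue) and res.reason == "zero_variance"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 4, 5, 6], [True, True, True, False, False, False], "low")
        assert res.auc == 1.0

    def test_interleaved_pairs(self):
        # disease {1,3} vs control {2,4}, low flags disease: 3 of 4
        # (disease, control) pairs are concordant
        res = roc_auc([1, 3, 2, 4], [True, True, False, False], "low")
        assert res.auc == 0.75

    def test_label_flip_symmetry(self, rng):
        v = rng.normal(size=40)
        lab = rng.random(40) < 0.4
        a1 = roc_auc(v, lab, "low").auc
        a2 = roc_auc(v, ~lab, "low").auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_mann_whitney_identity_on_random_data(self, rng):
        """AUC computed here equals U/(n1*n0) from scipy's Mann-Whitney on
        the same data, across 50 random datasets with ties."""
        for _ in range(50):
            v = rng.integers(0, 12, size=30).astype(float)  # heavy ties
            lab = rng.random(30) < 0.5
            if lab.all() or (~lab).all():
                continue
            res = roc_auc(v, lab, "high")
            u, _ = sps.mannwhitneyu(v[lab], v[~lab], alternative="two-sided")
            assert res.auc == pytest.approx(u / (lab.sum() * (~lab).sum()), abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            v = rng.normal(size=50)
            lab = rng.random(50) < 0.5
            if lab.all() or (~lab).all():
                continue
            assert roc_auc(v, lab, "high").auc == pytest.approx(
                roc_auc_score(lab, v), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True], "low")

    def test_youden_cutoff_separates(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [True] * 3 + [False] * 3, "low")
        assert 3 < res.youden_cutoff <= 10
        assert res.sensitivity == 1.0 and res.specificity == 1.0


class TestOddsRatio:
    def test_published_style_table(self):
        # (24, 9, 2, 10): OR = 240/18 = 13.333
        res = odds_ratio_2x2(24, 9, 2, 10)
        assert res.odds_ratio == pytest.approx(13.333, abs=1e-3)
        assert res.p < 0.01

    def test_unit_table(self):
        assert odds_ratio_2x2(1, 1, 1, 1).odds_ratio == 1.0

    def test_haldane_zero_cell_policy(self):
        res = odds_ratio_2x2(5, 0, 2, 10)
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((5.5 * 10.5) / (0.5 * 2.5), rel=1e-12)

    def test_swap_rows_and_columns_invariance(self):
        base = odds_ratio_2x2(8, 3, 4, 9).odds_ratio
        swapped = odds_ratio_2x2(9, 4, 3, 8).odds_ratio  # both rows and cols
        assert swapped == pytest.approx(base, rel=1e-12)

    def test_swap_rows_only_inverts(self):
        base = odds_ratio_2x2(8, 3, 4, 9).odds_ratio
        rows = odds_ratio_2x2(4, 9, 8, 3).odds_ratio
        assert rows == pytest.approx(1.0 / base, rel=1e-12)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 0, 0, 0)


class TestLogistic:
    def test_null_recovery_large_n(self, rng):
        n = 5000
        x = (rng.random(n) < 0.4).astype(float)
        age = rng.normal(50, 8, n)
        y = rng.random(n) < 0.3
        res = fit_logistic(y, pd.DataFrame({"x": x, "age": age}))
        assert 0.85 <= res[0].odds_ratio <= 1.18

    def test_known_or_recovery(self, rng):
        n = 5000
        x = (rng.random(n) < 0.4).astype(float)
        age = rng.normal(0, 1, n)
        logit = -1.0 + math.log(5.0) * x + 0.1 * age
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = fit_logistic(y, pd.DataFrame({"x": x, "age": age}))
        assert res[0].odds_ratio == pytest.approx(5.0, rel=0.15)
        assert res[0].ci_low < 5.0 < res[0].ci_high

    def test_perfect_separation_flagged(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = x > 0.5
        res = fit_logistic(y, pd.DataFrame({"x": x}))
        assert res[0].separation
        assert res[0].ci_low is None

    def test_rank_deficiency_raises(self):
        x = np.ones(20)
        y = np.random.default_rng(0).random(20) < 0.5
        with pytest.raises(ValueError):
            fit_logistic(y, pd.DataFrame({"x": x}))


class TestBuildReport:
    @staticmethod
    def _toy_inputs(n=30, seed=0):
        rng = np.random.default_rng(seed)
        groups = ["control"] * (n // 3) + ["dm_no_dr"] * (n // 3) + ["dr"] * (n - 2 * (n // 3))
        cohort = pd.DataFrame(
            {
                "eye_id": [f"e{i}" for i in range(n)],
                "group": groups,
                "age": rng.normal(50, 8, n),
                "pros_length": rng.normal(60, 5, n),
                "rpe_volume": rng.normal(0.39, 0.02, n),
                "hba1c": rng.normal(7, 1, n),
                "hba1c_exceed": rng.random(n) < 0.4,
            }
        )
        metrics = pd.DataFrame(
            {
                "eye_id": cohort["eye_id"],
                "group": groups,
                "ccfa_ratio": rng.normal(64, 6, n),
                "cv_ccfa": rng.normal(0.15, 0.03, n),
                "vld": rng.normal(20, 1.5, n),
            }
        )
        return cohort, metrics

    def test_report_has_all_sections_and_is_json(self):
        import json

        cohort, metrics = self._toy_inputs()
        report = build_report(cohort, metrics)
        for section in (
            "characteristics",
            "flow_group_stats",
            "correlations",
            "roc",
            "classification",
            "logistic",
        ):
            assert section in report
        json.dumps(report, default=float)

    def test_deterministic_on_identical_input(self):
        import json

        cohort, metrics = self._toy_inputs()
        r1 = build_report(cohort, metrics)
        r2 = build_report(cohort.copy(), metrics.copy())
        assert json.dumps(r1, default=float) == json.dumps(r2, default=float)

    def test_missing_columns_named(self):
        cohort, metrics = self._toy_inputs()
        with pytest.raises(SchemaError, match="group"):
            build_report(cohort.drop(columns=["group"]), metrics)

    def test_empty_group_degrades_gracefully(self):
        cohort, metrics = self._toy_inputs()
        keep = cohort["group"] != "control"
        report = build_report(cohort[keep], metrics[keep])
        assert "skipped" in report["classification"]
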