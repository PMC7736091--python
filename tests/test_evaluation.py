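"""Agreement statistics: published-table oracles and independent
library cross-checks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hipmorph.errors import ParameterError, UndefinedMetricError
from hipmorph.evaluation import (
    ConfusionTable,
    bowker,
    cohen_kappa,
    confusion_table,
    cronbach_alpha,
    diagnostic_metrics,
    mcnemar,
    multiclass_accuracy,
    pearson_r,
    per_class_recall,
    roc,
)
from hipmorph.phantom import CohortParams, simulate_cohort


class TestConfusionTable:
    def test_perfect_agreement_is_diagonal(self):
        t = confusion_table(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        assert np.array_equal(t.counts, [[2, 0], [0, 1]])

    def test_published_tonnis_marginals(self, tonnis_table):
        assert tonnis_table.counts.sum(axis=1).tolist() == [163, 85]
        assert tonnis_table.counts.sum(axis=0).tolist() == [174, 74]
        assert tonnis_table.n == 248

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            confusion_table([], [], ["a", "b"])

    def test_label_outside_classes_rejected(self):
        with pytest.raises(ParameterError):
            confusion_table(["a"], ["c"], ["a", "b"])


class TestDiagnosticMetrics:
    def test_published_tonnis_percentages(self, tonnis_table):
        m = diagnostic_metrics(tonnis_table, positive="dysplasia")
        assert 100 * m["accuracy"] == pytest.approx(89.1, abs=0.1)
        assert 100 * m["sensitivity"] == pytest.approx(77.7, abs=0.1)
        assert 100 * m["specificity"] == pytest.approx(95.1, abs=0.1)
        assert 100 * m["fpr"] == pytest.approx(4.9, abs=0.1)

    def test_published_sharp_percentages(self, sharp_table):
        m = diagnostic_metrics(sharp_table, positive="dysplasia")
        assert 100 * m["accuracy"] == pytest.approx(93.1, abs=0.1)
        assert 100 * m["sensitivity"] == pytest.approx(77.1, abs=0.1)
        assert 100 * m["specificity"] == pytest.approx(95.8, abs=0.1)
        assert 100 * m["fpr"] == pytest.approx(4.2, abs=0.1)

    def test_all_correct(self):
        t = ConfusionTable(("normal", "dysplasia"), [[10, 0], [0, 5]])
        m = diagnostic_metrics(t, positive="dysplasia")
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0, "fpr": 0.0}

    def test_zero_row_is_undefined(self):
        t = ConfusionTable(("normal", "dysplasia"), [[10, 2], [0, 0]])
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            diagnostic_metrics(t, positive="dysplasia")


class TestMulticlassAccuracy:
    def test_published_ce_three_class(self, ce3_table):
        assert 100 * multiclass_accuracy(ce3_table) == pytest.approx(82.3, abs=0.1)

    def test_published_borderline_recall(self, ce3_table):
        recall = per_class_recall(ce3_table)
        assert 100 * recall["borderline"] == pytest.approx(57.4, abs=0.1)

    def test_identity_table(self):
        t = ConfusionTable(("a", "b", "c"), np.diag([3, 4, 5]))
        assert multiclass_accuracy(t) == 1.0


class TestCohenKappa:
    def test_published_sharp_kappa(self, sharp_table):
        assert cohen_kappa(sharp_table) == pytest.approx(0.721, abs=0.0005)

    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionTable(("a", "b"), [[7, 0], [0, 3]])) == 1.0

    def test_independence_is_zero(self):
        # counts proportional to the outer product of the marginals
        t = ConfusionTable(("a", "b"), np.outer([30, 70], [40, 60]) // 10)
        assert cohen_kappa(t) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(0)
        for _ in range(20):
            ref = rng.integers(0, 3, 60)
            pred = rng.integers(0, 3, 60)
            t = confusion_table(ref, pred, [0, 1, 2])
            assert cohen_kappa(t) == pytest.approx(
                cohen_kappa_score(ref, pred), abs=1e-12
            )


class TestMcNemar:
    def test_published_tonnis_pvalue(self, tonnis_table):
        # discordants (8, 19): 2 * sum_{k<=8} C(27, k) / 2^27
        res = mcnemar(tonnis_table)
        assert res["p"] == pytest.approx(0.0522, abs=0.0005)
        assert res["p"] == pytest.approx(0.052, abs=0.001)

    def test_published_ce_dichotomous_pvalue(self, ce2_table):
        res = mcnemar(ce2_table)
        assert res["p"] == pytest.approx(0.009, abs=0.001)

    def test_balanced_discordants_p_one(self):
        t = ConfusionTable(("a", "b"), [[10, 5], [5, 10]])
        assert mcnemar(t)["p"] == 1.0

    def test_no_discordants(self):
        t = ConfusionTable(("a", "b"), [[10, 0], [0, 10]])
        res = mcnemar(t)
        assert res["p"] == 1.0 and "note" in res

    def test_transpose_symmetric(self, tonnis_table):
        tt = ConfusionTable(tonnis_table.classes, tonnis_table.counts.T)
        assert mcnemar(tt)["p"] == mcnemar(tonnis_table)["p"]

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 30, (2, 2))
            if counts[0, 1] + counts[1, 0] == 0 or counts.sum() == 0:
                continue
            t = ConfusionTable(("a", "b"), counts)
            ours = mcnemar(t)["p"]
            ref = sm_mcnemar(counts, exact=True).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_chi2_variant_available(self, tonnis_table):
        res = mcnemar(tonnis_table, exact=False)
        assert res["method"] == "chi2-continuity"
        assert 0 < res["p"] < 1


class TestBowker:
    def test_published_ce_three_class(self, ce3_table):
        res = bowker(ce3_table)
        # 2^2/2 + 12^2/24 + 10^2/18
        assert res["statistic"] == pytest.approx(13.556, abs=0.001)
        assert res["df"] == 3
        assert res["p"] == pytest.approx(0.004, abs=0.001)

    def test_symmetric_table(self):
        t = ConfusionTable(("a", "b", "c"), [[5, 2, 1], [2, 5, 3], [1, 3, 5]])
        res = bowker(t)
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_2x2_delegates_to_mcnemar(self, tonnis_table):
        assert bowker(tonnis_table)["p"] == mcnemar(tonnis_table)["p"]

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import SquareTable
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = rng.integers(1, 25, (3, 3))
            t = ConfusionTable(("a", "b", "c"), counts)
            ours = bowker(t)
            ref = SquareTable(counts).symmetry(method="bowker")
            assert ours["statistic"] == pytest.approx(ref.statistic, abs=1e-9)
            assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-9)


class TestPearson:
    def test_identity_line(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)["r"] == pytest.approx(1.0)

    def test_antiline(self):
        x = np.arange(10.0)
        assert pearson_r(x, -x)["r"] == pytest.approx(-1.0)

    def test_calibrated_simulation_band(self):
        df = simulate_cohort(CohortParams(seed=4))
        for angle in ("tonnis", "sharp", "ce"):
            r = pearson_r(df[f"{angle}_physician"], df[f"{angle}_cad"])["r"]
            assert 0.85 <= r <= 0.95

    def test_constant_rejected(self):
        with pytest.raises(ParameterError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCronbachAlpha:
    def test_identical_measurements(self):
        x = np.arange(20.0)
        assert cronbach_alpha(x, x) == pytest.approx(1.0)

    def test_independent_measurements_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=5000)
        b = rng.normal(size=5000)
        assert abs(cronbach_alpha(a, b)) < 0.1

    def test_small_noise_high_alpha(self):
        rng = np.random.default_rng(6)
        base = rng.normal(10.0, 6.0, 500)
        repeat = base + rng.normal(0.0, 0.5, 500)
        assert cronbach_alpha(base, repeat) > 0.95

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(7)
        a = rng.normal(size=80)
        b = a + rng.normal(0, 0.7, 80)
        ours = cronbach_alpha(a, b)
        ref = pg.cronbach_alpha(pd.DataFrame({"m1": a, "m2": b}))[0]
        assert ours == pytest.approx(ref, abs=1e-9)


class TestROC:
    def test_perfect_separation(self):
        res = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert 3.0 < res.optimal_threshold < 10.0

    def test_auc_equals_pair_counting(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.normal(size=n), 1)  # force some ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            res = roc(scores, labels)
            pos = scores[labels][:, None]
            neg = scores[~labels][None, :]
            pairs = (pos > neg).sum() + 0.5 * (pos == neg).sum()
            assert res.auc == pytest.approx(pairs / (pos.size * neg.size), abs=1e-12)

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        assert roc(scores, labels.astype(bool)).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000).astype(bool)
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    @given(st.integers(0, 10))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50).astype(bool)
        if labels.all() or not labels.any():
            return
        base = roc(scores, labels).auc
        assert roc(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert roc(3 * scores - 7, labels).auc == pytest.approx(base, abs=1e-12)

    def test_lower_is_positive_orientation(self):
        # CE-angle style: smaller values indicate disease
        scores = np.array([30.0, 28.0, 26.0, 18.0, 15.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        res = roc(scores, labels, orientation="lower_is_positive")
        assert res.auc == 1.0
        assert 18.0 < res.optimal_threshold < 26.0

    def test_curve_monotone_in_fpr(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100).astype(bool)
        res = roc(scores, labels)
        fpr = 1.0 - res.specificity
        order = np.argsort(res.thresholds)
        assert np.all(np.diff(fpr[order]) <= 1e-12)
        assert np.all(np.diff(res.sensitivity[order]) <= 1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc([1.0, 2.0], [True, True])

    def test_youden_threshold_between_observations(self):
        res = roc([1.0, 2.0, 5.0, 6.0], [0, 0, 1, 1])
        assert res.optimal_threshold == pytest.approx(3.5)
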