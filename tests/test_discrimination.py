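"""AUROC, Mann-Whitney, cross-validated logistic scoring and DeLong tests."""

import numpy as np
import pandas as pd
import pytest

from femofall.discrimination import (
    ScoreVector,
    auroc,
    build_reports,
    cv_auroc,
    delong_test,
    delong_variance,
    fit_logistic,
    group_difference_test,
    loocv_logistic,
    mann_whitney_u,
)
from femofall.synthetic_cohort import group_specs_from_reference, sample_descriptor_cohort


def brute_force_auroc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    x = scores[labels == 1]
    y = scores[labels == 0]
    wins = (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
    return wins / (len(x) * len(y))


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),
            ([5, 5, 5, 5], [0, 0, 1, 1], 0.5),
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert auroc(scores, labels) == pytest.approx(expected)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(6, 40)
            scores = rng.integers(0, 10, n).astype(float)  # ties included
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)  # continuous, tie-free
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)

    def test_equals_trapezoidal_roc_area(self):
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(2)
        scores = rng.normal(size=300) + np.repeat([0.0, 0.7], 150)
        labels = np.repeat([0, 1], 150)
        fpr, tpr, _ = roc_curve(labels, scores)
        assert auroc(scores, labels) == pytest.approx(
            np.trapezoid(tpr, fpr), abs=1e-12
        )


class TestMannWhitney:
    def test_pairwise_win_count(self):
        # {1,3,5} vs {2,4,6}: second sample wins 6 of the 9 pairings
        assert mann_whitney_u([1, 3, 5], [2, 4, 6]) == 6.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.integers(0, 8, rng.integers(3, 12)).astype(float)
            y = rng.integers(0, 8, rng.integers(3, 12)).astype(float)
            brute = ((y[:, None] > x[None, :]).sum() + 0.5 * (y[:, None] == x[None, :]).sum())
            assert mann_whitney_u(x, y) == pytest.approx(brute)


class TestGroupDifference:
    def test_identical_samples_give_p_one(self):
        v = np.concatenate([np.arange(10.0), np.arange(10.0)])
        labels = np.repeat([0, 1], 10)
        p, test = group_difference_test(v, labels)
        assert p == pytest.approx(1.0)
        assert test.startswith("t-")

    def test_complete_separation_significant(self):
        v = np.array([1.0, 2, 3, 101, 102, 103])
        labels = np.array([0, 0, 0, 1, 1, 1])
        p, _ = group_difference_test(v, labels)
        assert p < 0.01

    def test_constant_group_routes_to_mann_whitney(self):
        v = np.concatenate([np.full(5, 3.0), np.arange(5.0)])
        labels = np.repeat([0, 1], 5)
        _, test = group_difference_test(v, labels)
        assert test == "mann-whitney"

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.lognormal(0, 1.5, 40), rng.lognormal(0.3, 1.5, 40)])
        labels = np.repeat([0, 1], 40)
        _, test = group_difference_test(v, labels)
        assert test == "mann-whitney"


class TestLogisticScoring:
    def test_fit_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = rng.normal(size=(80, 2))
        eta = 0.5 + x @ [1.0, -0.7]
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-eta))).astype(float)
        beta = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(beta, ref.params, rtol=1e-5, atol=1e-6)

    def test_loocv_emits_one_probability_per_subject(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        sv = loocv_logistic(x, y)
        assert len(sv.scores) == 30
        assert np.all((sv.scores > 0) & (sv.scores < 1))

    def test_separation_capped_not_diverging(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = np.repeat([0, 1], 10)
        with pytest.warns(UserWarning, match="capped"):
            beta = fit_logistic(x[:, None], y)
        assert np.all(np.abs(beta) <= 50.0)

    def test_monotone_feature_lpo_equals_raw_auroc(self):
        # every leave-pair-out comparison scores both pair members with the
        # same fold model, so with stable positive fold slopes the pair
        # decisions reduce to raw-feature comparisons exactly
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.5, 1, 10)])
        y = np.repeat([0, 1], 10)
        assert cv_auroc(x, y, method="leave_pair_out") == pytest.approx(auroc(x, y))
        # pooled LOOCV probabilities are only approximately monotone in the
        # feature (each fold's fit is dragged by the left-out subject)
        sv = loocv_logistic(x, y)
        assert auroc(sv.scores, y) == pytest.approx(auroc(x, y), abs=0.15)

    def test_leave_pair_out_null_is_unbiased(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(60):
            x = rng.normal(size=40)
            y = np.repeat([0, 1], 20)
            vals.append(cv_auroc(x, y, method="leave_pair_out"))
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_pooled_loo_is_pessimistic_under_null(self):
        # the known pooling artifact: each left-out subject drags the fold
        # fit away from itself; documents why leave-pair-out is the default
        rng = np.random.default_rng(9)
        pooled, lpo = [], []
        for _ in range(30):
            x = rng.normal(size=40)
            y = np.repeat([0, 1], 20)
            pooled.append(cv_auroc(x, y, method="pooled_loo"))
            lpo.append(cv_auroc(x, y, method="leave_pair_out"))
        assert np.mean(pooled) < np.mean(lpo)
        assert np.mean(pooled) < 0.45

    def test_lpo_close_to_raw_auroc_for_strong_feature(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(0, 1, 64), rng.normal(1.1, 1, 64)])
        y = np.repeat([0, 1], 64)
        assert cv_auroc(x, y) == pytest.approx(auroc(x, y), abs=0.05)


class TestDeLong:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=60)
        labels = np.repeat([0, 1], 30)
        a, b, z, p = delong_test(s, s, labels)
        assert a == b
        assert p == 1.0

    def test_antithetic_scores_mirror_auc(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=60) + np.repeat([0, 1.0], 30)
        labels = np.repeat([0, 1], 30)
        a, b, _, _ = delong_test(s, -s, labels)
        assert b == pytest.approx(1.0 - a)

    def test_variance_matches_stratified_bootstrap(self):
        rng = np.random.default_rng(13)
        n = 200
        scores = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(0.8, 1, n // 2)])
        labels = np.repeat([0, 1], n // 2)
        var_dl = delong_variance(scores, labels)
        cases = scores[labels == 1]
        ctrls = scores[labels == 0]
        boot = np.empty(2000)
        for b in range(2000):
            cs = rng.choice(cases, len(cases))
            ct = rng.choice(ctrls, len(ctrls))
            boot[b] = auroc(
                np.concatenate([ct, cs]), np.repeat([0, 1], n // 2)
            )
        assert var_dl == pytest.approx(boot.var(ddof=1), rel=0.15)

    def test_variance_shrinks_with_sample_size(self):
        rng = np.random.default_rng(14)
        prev = np.inf
        for n in (50, 200, 800):
            scores = np.concatenate([rng.normal(0, 1, n), rng.normal(0.6, 1, n)])
            labels = np.repeat([0, 1], n)
            v = delong_variance(scores, labels)
            assert v < prev
            prev = v


class TestReports:
    def _cohort(self, n=64, seed=0, cols=("aBMD_gcm2", "vBMD_trab_mgcm3", "F0_N", "D3_mm", "E_nl_Nmm")):
        control, fracture = group_specs_from_reference(columns=list(cols), n=n)
        return sample_descriptor_cohort(control, fracture, seed=seed)

    def test_report_shapes_and_columns(self):
        df = self._cohort()
        rep = build_reports(df, combinations=("F0_N+D3_mm",))
        assert len(rep.summary) == 5
        assert len(rep.auroc_table) == 5 + 1
        assert {"descriptor", "AUROC", "p_vs_aBMD_gcm2", "p_vs_vBMD_trab_mgcm3"} <= set(
            rep.auroc_table.columns
        )
        assert ((rep.auroc_table["AUROC"] >= 0) & (rep.auroc_table["AUROC"] <= 1)).all()

    def test_missing_column_named_in_error(self):
        df = self._cohort()
        with pytest.raises(KeyError, match="D2_mm"):
            build_reports(df, combinations=("F0_N+D2_mm",))
        with pytest.raises(KeyError, match="nope"):
            build_reports(df, references=("nope",))

    def test_null_cohort_aurocs_near_half(self):
        control, _ = group_specs_from_reference(columns=["F0_N", "aBMD_gcm2", "vBMD_trab_mgcm3"], n=200)
        import copy

        null_fracture = copy.deepcopy(control)
        null_fracture.label = "fracture"
        df = sample_descriptor_cohort(control, null_fracture, seed=31)
        rep = build_reports(df)
        assert np.allclose(rep.auroc_table["AUROC"], 0.5, atol=0.1)

    def test_qualitative_auroc_ordering_matches_binormal_prediction(self):
        # binormal AUROC Phi(dmu / sqrt(s0^2+s1^2)) from the fixture ranks
        # residual displacement > strength > nonlinear energy
        vals = {"D3_mm": [], "F0_N": [], "E_nl_Nmm": []}
        control, fracture = group_specs_from_reference(columns=list(vals), n=64)
        for rep_i in range(20):
            df = sample_descriptor_cohort(control, fracture, seed=100 + rep_i)
            y = (df.group == "fracture").astype(int).to_numpy()
            for col in vals:
                vals[col].append(cv_auroc(df[col].to_numpy(), y))
        means = {c: np.mean(v) for c, v in vals.items()}
        assert means["D3_mm"] > means["F0_N"] > means["E_nl_Nmm"]
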