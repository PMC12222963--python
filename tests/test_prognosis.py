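import numpy as np
import pandas as pd
import pytest

from glomkit.prognosis import (
    FEATURE_SETS,
    IMAGE_FEATURES,
    assemble_features,
    delong_ci,
    delong_test,
    delong_variance,
    filter_cohort,
    fit_and_evaluate,
    importance_report,
    label_outcome,
    mann_whitney_auc,
    roc_points,
)


def _followup(points):
    return pd.DataFrame(points, columns=["months", "egfr", "krt_flag"])


class TestOutcomeLabel:
    def test_halving_triggers_event(self):
        fu = _followup([(6, 80, False), (12, 49, False), (18, 40, False)])
        lab = label_outcome(fu, baseline_egfr=100)
        assert lab.event == 1 and lab.time_months == 12

    def test_stable_function_censored(self):
        fu = _followup([(12, 70, False), (24, 65, False), (36, 60, False)])
        lab = label_outcome(fu, baseline_egfr=100)
        assert lab.event == 0 and lab.time_months == 36

    def test_eskd_threshold_applies_even_above_half_baseline(self):
        fu = _followup([(6, 14, False)])
        lab = label_outcome(fu, baseline_egfr=24)
        assert lab.event == 1 and lab.time_months == 6

    def test_krt_flag_triggers(self):
        fu = _followup([(6, 80, False), (12, 70, True)])
        assert label_outcome(fu, 100).event == 1

    def test_empty_followup_rejected(self):
        with pytest.raises(ValueError):
            label_outcome(_followup([]), 100)


class TestFilterCohort:
    def _patients(self, n):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "baseline_egfr": [100.0] * n,
            }
        )

    def test_short_followup_excluded_with_reason(self):
        patients = self._patients(2)
        fu = pd.DataFrame(
            {
                "patient_id": ["P0", "P1"],
                "months": [5.0, 12.0],
                "egfr": [90.0, 90.0],
                "krt_flag": [False, False],
            }
        )
        kept, excl = filter_cohort(patients, fu)
        assert list(kept["patient_id"]) == ["P1"]
        assert excl.iloc[0]["reason"] == "follow-up<6m"

    def test_missing_followup_excluded(self):
        patients = self._patients(1)
        fu = pd.DataFrame(columns=["patient_id", "months", "egfr", "krt_flag"])
        kept, excl = filter_cohort(patients, fu)
        assert len(kept) == 0
        assert excl.iloc[0]["reason"] == "no-outcome"

    def test_planted_short_followups_counted(self):
        n = 100
        patients = self._patients(n)
        rows = []
        for i in range(n):
            months = 5.0 if i < 20 else 24.0
            rows.append({"patient_id": f"P{i}", "months": months, "egfr": 90.0, "krt_flag": False})
        kept, excl = filter_cohort(patients, pd.DataFrame(rows))
        assert len(kept) == 80 and len(excl) == 20


class TestAssembleFeatures:
    def _frames(self):
        rng = np.random.default_rng(0)
        n = 8
        feats = pd.DataFrame(rng.random((n, len(IMAGE_FEATURES))), columns=IMAGE_FEATURES)
        feats.insert(0, "slide_id", [f"s{i}" for i in range(n)])
        patients = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "slide_id": [f"s{i}" for i in range(n)],
                "event": [0, 1] * (n // 2),
            }
        )
        for col in FEATURE_SETS["clinical"]:
            patients[col] = rng.random(n)
        return patients, feats

    def test_image_set_schema(self):
        patients, feats = self._frames()
        X, y = assemble_features(patients, feats, "image")
        assert list(X.columns) == IMAGE_FEATURES
        assert len(X.columns) == 46  # 41 core + 5 presence flags

    def test_combined_set_is_union_without_duplicates(self):
        patients, feats = self._frames()
        X, _ = assemble_features(patients, feats, "image+clinical")
        assert list(X.columns) == IMAGE_FEATURES + FEATURE_SETS["clinical"]
        assert len(set(X.columns)) == len(X.columns)

    def test_row_order_stable_under_shuffle(self):
        patients, feats = self._frames()
        X1, y1 = assemble_features(patients, feats, "image")
        shuffled = patients.sample(frac=1, random_state=3).reset_index(drop=True)
        X2, y2 = assemble_features(shuffled, feats, "image")
        pd.testing.assert_frame_equal(X1, X2)
        pd.testing.assert_series_equal(y1, y2)

    def test_unjoinable_patient_reported(self):
        patients, feats = self._frames()
        patients.loc[0, "slide_id"] = "nope"
        with pytest.raises(ValueError, match="P0"):
            assemble_features(patients, feats, "image")

    def test_unknown_feature_set_rejected(self):
        patients, feats = self._frames()
        with pytest.raises(ValueError, match="unknown feature set"):
            assemble_features(patients, feats, "everything")


class TestAucMachinery:
    def test_perfect_separation(self):
        assert mann_whitney_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_four_pair_example(self):
        assert mann_whitney_auc([0.9, 0.8, 0.85, 0.7], [1, 1, 0, 0]) == 0.75

    def test_roc_sweep_matches_mann_whitney(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        pts = roc_points(scores, labels)
        trap = np.trapezoid(pts[:, 1], pts[:, 0])
        assert abs(trap - mann_whitney_auc(scores, labels)) < 1e-9


class TestDeLong:
    def test_self_comparison_z_zero_p_one(self):
        scores = np.array([0.9, 0.8, 0.85, 0.7, 0.6, 0.3])
        labels = np.array([1, 1, 0, 0, 1, 0])
        z, p = delong_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_variance_matches_structural_components_double_loop(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(int)
        auc, var = delong_variance(scores, labels)

        pos = scores[labels == 1]
        neg = scores[labels == 0]
        m, n = len(pos), len(neg)

        def psi(x, y):
            return 1.0 if y < x else (0.5 if y == x else 0.0)

        auc_bf = np.mean([[psi(x, y) for y in neg] for x in pos])
        v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
        v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
        var_bf = v10.var(ddof=1) / m + v01.var(ddof=1) / n
        assert abs(auc - auc_bf) < 1e-9
        assert abs(var - var_bf) < 1e-9

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.random(60)
        b = rng.random(60)
        labels = (rng.random(60) < 0.5).astype(int)
        z1, p1 = delong_test(a, b, labels)
        z2, p2 = delong_test(-a, -b, 1 - labels)
        assert abs(abs(z1) - abs(z2)) < 1e-9
        assert abs(p1 - p2) < 1e-9

    def test_ci_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(10)
        widths = []
        for n in (100, 400, 1600):
            scores = np.concatenate([rng.normal(1, 1, n // 2), rng.normal(0, 1, n // 2)])
            labels = np.array([1] * (n // 2) + [0] * (n // 2))
            lo, hi = delong_ci(scores, labels)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.35)


class TestFitAndEvaluate:
    def _synthetic_matrix(self, n, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
        logit = 2.0 * X["f0"] if informative else pd.Series(np.zeros(n))
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int))
        return X, y

    def test_perfectly_separated_scores_auc_one(self):
        X = pd.DataFrame({"f": np.r_[np.ones(30), np.zeros(30)]})
        y = pd.Series(np.r_[np.ones(30), np.zeros(30)].astype(int))
        r = fit_and_evaluate(X, y, X, y, model_family="logistic_regression", seed=0)
        assert r.auc == 1.0

    def test_single_class_test_set_rejected(self):
        X, y = self._synthetic_matrix(40)
        with pytest.raises(ValueError, match="single class"):
            fit_and_evaluate(X, y, X, pd.Series(np.zeros(40, dtype=int)), "logistic_regression")

    @pytest.mark.parametrize("family", ["xgboost", "random_forest", "logistic_regression"])
    def test_informative_feature_ranked_first(self, family):
        X, y = self._synthetic_matrix(2000, informative=True, seed=4)
        r = fit_and_evaluate(X[:1000], y[:1000], X[1000:], y[1000:], family, seed=1)
        assert r.importances[0][0] == "f0"

    def test_deterministic_under_seed(self):
        X, y = self._synthetic_matrix(400, seed=5)
        a = fit_and_evaluate(X[:200], y[:200], X[200:], y[200:], "xgboost", seed=3)
        b = fit_and_evaluate(X[:200], y[:200], X[200:], y[200:], "xgboost", seed=3)
        assert a.auc == b.auc
        assert a.importances == b.importances

    def test_noise_columns_barely_change_logistic_auc(self):
        X, y = self._synthetic_matrix(2000, seed=6)
        r1 = fit_and_evaluate(X[:1000], y[:1000], X[1000:], y[1000:], "logistic_regression")
        rng = np.random.default_rng(7)
        Xn = X.copy()
        for i in range(10):
            Xn[f"noise{i}"] = rng.normal(size=len(X))
        r2 = fit_and_evaluate(Xn[:1000], y[:1000], Xn[1000:], y[1000:], "logistic_regression")
        assert abs(r1.auc - r2.auc) < 0.03


class TestImportanceReport:
    def test_top_k_and_clamping(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(200, 3)), columns=list("abc"))
        y = pd.Series((X["a"] > 0).astype(int))
        r = fit_and_evaluate(X[:100], y[:100], X[100:], y[100:], "logistic_regression")
        report = importance_report([r], k=2)
        assert len(report) == 2
        assert list(report["rank"]) == [1, 2]
        big = importance_report([r], k=99)
        assert len(big) == 3
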