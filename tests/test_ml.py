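import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegression

import tavica
from tavica.ml import (
    BASE_ALGORITHMS,
    BaggedEnsemble,
    CohortPreprocessor,
    EvaluationReport,
    MajorityVoteClassifier,
    auc_trapezoid,
    continuous_score,
    correlation_screen,
    evaluate,
    f1_score_from,
    filter_ppi,
    preprocess,
    run_ablation,
    run_protocol,
    select_best,
    split_cohort,
    train_base,
)
from sklearn.metrics import roc_curve


class TestPreprocessing:
    def test_minmax_scaling_on_training_rows_only(self, small_cohort):
        train = small_cohort.index[:280]
        X, prep = preprocess(small_cohort, train)
        scaled_train = X.loc[train, [c for c in X.columns if not c.startswith("device_")]]
        assert (scaled_train.min() >= -1e-12).all().all()
        assert (scaled_train.max() <= 1 + 1e-12).all().all()

    def test_scaling_example_and_no_clipping(self):
        df = pd.DataFrame({
            "doi": [0.0, 10.0, 5.0, 12.0],
            "device_type": ["CV", "LT", "ER/EPRO", "CV"],
        })
        prep = CohortPreprocessor(numeric_features=["doi"]).fit(df.iloc[:2])
        out = prep.transform(df)
        assert out.loc[2, "doi"] == pytest.approx(0.5)
        assert out.loc[3, "doi"] == pytest.approx(1.2)  # beyond train max, not clipped

    def test_one_hot_encoding(self):
        df = pd.DataFrame({"doi": [1.0, 2.0, 3.0], "device_type": ["CV", "ER/EPRO", "LT"]})
        out = CohortPreprocessor(numeric_features=["doi"]).fit(df).transform(df)
        assert out.loc[2, ["device_CV", "device_ER/EPRO", "device_LT"]].tolist() == [0, 0, 1]
        onehot = out[["device_CV", "device_ER/EPRO", "device_LT"]].to_numpy()
        assert (onehot.sum(axis=1) == 1).all()

    def test_constant_column_scaled_to_zero_with_warning(self):
        df = pd.DataFrame({"doi": [4.0, 4.0, 4.0], "device_type": ["CV", "CV", "LT"]})
        with pytest.warns(UserWarning, match="constant"):
            prep = CohortPreprocessor(numeric_features=["doi"]).fit(df)
        assert (prep.transform(df)["doi"] == 0.0).all()

    def test_missing_feature_column_named(self):
        df = pd.DataFrame({"device_type": ["CV", "LT"]})
        with pytest.raises(ValueError, match="doi"):
            CohortPreprocessor(numeric_features=["doi"]).fit(df)


class TestCorrelationScreen:
    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        assert correlation_screen(df) == ["a", "c"]

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(1000, 5)), columns=list("abcde"))
        assert correlation_screen(df) == list("abcde")

    def test_default_cohort_retains_all_features(self, small_cohort):
        numeric = [f for f in tavica.synth.FEATURE_COLUMNS if f != "device_type"]
        assert correlation_screen(small_cohort[numeric]) == numeric

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            correlation_screen(pd.DataFrame({"a": [1.0, 2.0]}))


class TestSplit:
    def test_sizes_for_n151(self, fixture_cohort):
        train, val = split_cohort(fixture_cohort, seed=0)
        assert len(train) == 106 and len(val) == 45

    def test_partition_properties(self, fixture_cohort):
        train, val = split_cohort(fixture_cohort, seed=1)
        assert len(np.intersect1d(train, val)) == 0
        assert len(np.union1d(train, val)) == len(fixture_cohort)
        for ids in (train, val):
            assert set(fixture_cohort.loc[ids, "device_type"]) == {"CV", "ER/EPRO", "LT"}

    def test_outcome_stratification(self, fixture_cohort):
        train, _ = split_cohort(fixture_cohort, seed=2)
        frac = fixture_cohort.loc[train, "ca"].mean()
        assert frac == pytest.approx(89 / 151, abs=0.01)

    def test_reproducible(self, fixture_cohort):
        a = split_cohort(fixture_cohort, seed=3)
        b = split_cohort(fixture_cohort, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_thin_device_category_rejected(self, fixture_cohort):
        thin = fixture_cohort[fixture_cohort["device_type"] != "LT"].copy()
        thin.loc[thin.index[0], "device_type"] = "LT"  # a single LT row
        with pytest.raises(ValueError, match="LT"):
            split_cohort(thin, seed=0)


def _separable_toy(n_per_class=20):
    rng = np.random.default_rng(4)
    X0 = rng.normal(loc=-5.0, scale=0.1, size=(n_per_class, 3))
    X1 = rng.normal(loc=5.0, scale=0.1, size=(n_per_class, 3))
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestBaseClassifiers:
    def test_registry_has_eight_algorithms(self):
        assert len(BASE_ALGORITHMS) == 8

    def test_unknown_algorithm(self):
        X, y = _separable_toy()
        with pytest.raises(KeyError):
            train_base(X, y, "mlp")

    @pytest.mark.parametrize("algo", BASE_ALGORITHMS)
    def test_separable_toy_perfect_training_accuracy(self, algo):
        X, y = _separable_toy()
        model, cv_acc = train_base(X, y, algo, seed=0)
        assert (model.predict(X) == y).all()
        assert cv_acc >= 0.9

    def test_label_shuffled_cv_accuracy_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 5))
        y = rng.permutation([0, 1] * 200)
        _, cv_acc = train_base(X, y, "logreg", seed=0)
        assert cv_acc == pytest.approx(0.5, abs=0.1)


class TestEnsembles:
    def test_degenerate_bagging_equals_base(self):
        X, y = _separable_toy()
        base = LogisticRegression().fit(X, y)
        bag = BaggedEnsemble(LogisticRegression(), n_estimators=1, bootstrap=False,
                             random_state=0).fit(X, y)
        assert np.allclose(bag.predict_score(X), continuous_score(base, X))

    def test_score_is_mean_of_member_scores(self):
        class Stub:
            def __init__(self, value):
                self.value = value

            def predict_proba(self, X):
                p = np.full(len(X), self.value)
                return np.column_stack([1 - p, p])

        bag = BaggedEnsemble(LogisticRegression())
        bag.estimators_ = [Stub(0.2), Stub(0.4), Stub(0.9)]
        bag.classes_ = np.array([0, 1])
        assert bag.predict_score(np.zeros((3, 2)))[0] == pytest.approx(0.5)

    def test_bagging_reduces_score_variance_over_bootstrap_draws(self):
        # fixed training set; randomness comes from the bootstrap resampling:
        # averaging B members must shrink the score variance at a fixed point
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + 0.8 * rng.normal(size=60) > 0).astype(int)
        x_test = np.zeros((1, 2))
        singles = [
            BaggedEnsemble(LogisticRegression(), n_estimators=1,
                           random_state=w).fit(X, y).predict_score(x_test)[0]
            for w in range(40)
        ]
        bags = [
            BaggedEnsemble(LogisticRegression(), n_estimators=8,
                           random_state=1000 + w).fit(X, y).predict_score(x_test)[0]
            for w in range(40)
        ]
        assert np.var(bags) <= np.var(singles)

    def test_majority_vote_rules(self):
        class Const:
            def __init__(self, label):
                self.label = label

            def predict_proba(self, X):
                p = np.full(len(X), float(self.label))
                return np.column_stack([1 - p, p])

        X = np.zeros((2, 2))
        vote = MajorityVoteClassifier([Const(1), Const(1), Const(0)]).fit()
        assert vote.predict(X).tolist() == [1, 1]
        tie = MajorityVoteClassifier([Const(1), Const(0)]).fit()
        assert tie.predict(X).tolist() == [1, 1]  # ties go to the positive class
        unanimous = MajorityVoteClassifier([Const(0), Const(0)]).fit()
        assert unanimous.predict(X).tolist() == [0, 0]

    def test_voting_needs_two_members(self):
        with pytest.raises(ValueError):
            MajorityVoteClassifier([LogisticRegression()]).fit()


class TestF1Properties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        ppv=st.floats(0.01, 1.0),
        sens=st.floats(0.01, 1.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_harmonic_mean_bounded_by_its_arguments(self, ppv, sens):
        f1 = f1_score_from(ppv, sens)
        assert min(ppv, sens) - 1e-12 <= f1 <= max(ppv, sens) + 1e-12
        # harmonic mean never exceeds the arithmetic mean
        assert f1 <= (ppv + sens) / 2 + 1e-12

    @given(v=st.floats(0.01, 1.0))
    @settings(deadline=None, derandomize=True)
    def test_harmonic_mean_idempotent(self, v):
        assert f1_score_from(v, v) == pytest.approx(v, abs=1e-12)


class _ScoreModel:
    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_score(self, X):
        return self.scores


class TestEvaluation:
    def test_f1_is_harmonic_mean_of_ppv_and_sensitivity(self):
        assert f1_score_from(0.71, 1.00) == pytest.approx(0.83, abs=0.005)
        assert f1_score_from(1.0, 1.0) == 1.0
        assert np.isnan(f1_score_from(0.0, 0.0))

    def test_perfect_classifier(self):
        y = np.array([0, 0, 1, 1, 1])
        rep = evaluate(_ScoreModel([0.1, 0.2, 0.8, 0.9, 0.7]), np.zeros((5, 1)), y,
                       n_boot=100)
        assert rep.accuracy == 1.0 and rep.auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_metric_identities(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=200)
        scores = rng.random(200)
        rep = evaluate(_ScoreModel(scores), np.zeros((200, 1)), y, n_boot=50)
        n = rep.tp + rep.tn + rep.fp + rep.fn
        assert n == 200
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / n, abs=1e-12)
        assert rep.ppv == pytest.approx(rep.tp / (rep.tp + rep.fp), abs=1e-12)
        assert rep.npv == pytest.approx(rep.tn / (rep.tn + rep.fn), abs=1e-12)
        assert rep.f1 == pytest.approx(
            2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity), abs=1e-12
        )

    def test_auc_equals_mann_whitney_normalization(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            y = np.array([0] * 7 + [1] * 5)
            scores = rng.random(12)
            fpr, tpr, _ = roc_curve(y, scores)
            u = mannwhitneyu(scores[y == 1], scores[y == 0], alternative="two-sided")
            assert auc_trapezoid(fpr, tpr) == pytest.approx(u.statistic / (7 * 5), abs=1e-12)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=4000)
        rep = evaluate(_ScoreModel(rng.random(4000)), np.zeros((4000, 1)), y, n_boot=20)
        assert rep.auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_validation_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_ScoreModel([0.5, 0.6]), np.zeros((2, 1)), np.array([1, 1]))


class TestSelection:
    @staticmethod
    def _report(mid, acc, auc, cv=None):
        return EvaluationReport(
            model_id=mid, tp=1, fp=1, tn=1, fn=1, accuracy=acc, sensitivity=0.5,
            specificity=0.5, ppv=0.5, npv=0.5, f1=0.5, auc=auc, auc_ci=(0, 1),
            cv_accuracy=cv,
        )

    def test_argmax_accuracy(self):
        reports = [self._report("a", 0.83, 0.8), self._report("b", 0.80, 0.9),
                   self._report("c", 0.78, 0.95)]
        assert select_best(reports) == "a"

    def test_tie_broken_by_auc_then_id(self):
        assert select_best([self._report("a", 0.8, 0.84), self._report("b", 0.8, 0.80)]) == "a"
        assert select_best([self._report("b", 0.8, 0.84), self._report("a", 0.8, 0.80)]) == "b"
        assert select_best([self._report("b", 0.8, 0.8), self._report("a", 0.8, 0.8)]) == "a"

    def test_single_report(self):
        assert select_best([self._report("only", 0.7, 0.7)]) == "only"


class TestProtocol:
    FAST = dict(algorithms=["logreg", "gnb"], n_bagging=5, n_boot=50)

    def test_leakage_guard_validation_permutation_invariance(self, small_cohort):
        train = small_cohort.index[:280]
        X1, prep1 = preprocess(small_cohort, train)
        shuffled = pd.concat(
            [small_cohort.loc[train],
             small_cohort.loc[small_cohort.index[280:]].sample(frac=1, random_state=0)]
        )
        X2, prep2 = preprocess(shuffled, train)
        assert np.allclose(prep1.scaler_.data_min_, prep2.scaler_.data_min_)
        assert np.allclose(prep1.scaler_.data_max_, prep2.scaler_.data_max_)
        common = small_cohort.index[280:]
        assert np.allclose(X1.loc[common].to_numpy(), X2.loc[common].to_numpy())

    def test_deterministic_given_seed(self, small_cohort):
        a = run_protocol(small_cohort, seed=13, **self.FAST)
        b = run_protocol(small_cohort, seed=13, **self.FAST)
        assert a.selected_id == b.selected_id
        assert a.selected_report.auc == b.selected_report.auc
        assert np.array_equal(a.train_ids, b.train_ids)

    def test_ablation_uses_six_features(self, small_cohort):
        res = run_ablation(small_cohort, seed=13, **self.FAST)
        assert len(res.retained_features) == 6
        assert "cpmax" not in res.retained_features
        assert "cpi" not in res.retained_features

    def test_null_outcome_accuracy_near_base_rate(self, small_cohort):
        null = small_cohort.copy()
        rng = np.random.default_rng(10)
        null["ca"] = rng.permutation(null["ca"].to_numpy())
        null["lbbb_rbbb"] = null["ca"]
        null["ppi"] = 0
        res = run_protocol(null, seed=21, **self.FAST)
        base_rate = max(null["ca"].mean(), 1 - null["ca"].mean())
        assert res.selected_report.accuracy == pytest.approx(base_rate, abs=0.12)

    def test_missing_column_is_named(self, small_cohort):
        with pytest.raises(ValueError, match="cpi"):
            run_protocol(small_cohort.drop(columns=["cpi"]), seed=0, **self.FAST)

    def test_summary_table_shape(self, small_cohort):
        res = run_protocol(small_cohort, seed=13, **self.FAST)
        table = res.summary_table(top=4)
        assert list(table.columns)[:3] == ["model", "accuracy", "sensitivity"]
        assert len(table) == 4
        assert (table["accuracy"].diff().dropna() <= 1e-12).all()


class TestSubcohort:
    def test_ppi_filter(self, fixture_cohort):
        sub = filter_ppi(fixture_cohort)
        assert len(sub) == 119
        assert (sub["ppi"] == 0).all()

    def test_no_ppi_cohort_identical_to_primary_on_lbbb(self, small_cohort):
        free = small_cohort.copy()
        free["ppi"] = 0
        free["lbbb_rbbb"] = free["ca"]
        from tavica.ml import run_subcohort_lbbb

        a = run_subcohort_lbbb(free, seed=17, **TestProtocol.FAST)
        b = run_protocol(free, seed=17, outcome="lbbb_rbbb", **TestProtocol.FAST)
        assert a.selected_id == b.selected_id
        assert a.selected_report.accuracy == b.selected_report.accuracy
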