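import numpy as np
import pytest

from diffperf.classifier import (
    ClassifierError,
    ClassifierModel,
    SparseLogisticConfig,
    consensus_features,
    cv_select_lambda_logit,
    fit_sparse_logistic,
    loocv_run,
    predict_prob,
)
from diffperf.lasso import LassoConfig
from diffperf.selection import nested_fs
from diffperf.synthetic import generate_cohort

from conftest import small_config


def make_model(weights, k=None):
    k = len(weights) - 1 if k is None else k
    return ClassifierModel(
        features=tuple(f"x{i}" for i in range(k)),
        weights=np.asarray(weights, dtype=float),
        lambda_logit=0.1,
        mean=np.zeros(k),
        sd=np.ones(k),
    )


class TestPredictProb:
    def test_zero_logit_gives_half(self):
        model = make_model([0.0, 0.0])
        assert predict_prob(model, np.zeros(1)) == pytest.approx(0.5)

    def test_ln3_logit_gives_three_quarters(self):
        model = make_model([np.log(3.0), 0.0])
        assert predict_prob(model, np.ones(1)) == pytest.approx(0.75)

    def test_negated_weights_flip_probability(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=4)
        x = rng.normal(size=3)
        p = predict_prob(make_model(w), x)
        q = predict_prob(make_model(-w), x)
        assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClassifierError):
            predict_prob(make_model([1.0, 0.0]), np.zeros(3))


class TestFitSparseLogistic:
    def test_large_penalty_gives_base_rate_intercept(self):
        """All feature weights zero; intercept is the base-rate logit
        log(n1/n0) -- for a 74/39 split that is ln(74/39) ~ 0.6405."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(113, 6))
        y = np.r_[np.ones(74), np.zeros(39)]
        model = fit_sparse_logistic(X, y, 5.0)
        assert np.all(model.weights[:-1] == 0.0)
        assert model.weights[-1] == pytest.approx(np.log(74 / 39), abs=1e-8)
        assert np.log(74 / 39) == pytest.approx(0.6405, abs=5e-5)

    def test_separating_direction_sign(self):
        x = np.r_[np.linspace(1, 2, 20), np.linspace(-2, -1, 20)][:, None]
        y = np.r_[np.ones(20), np.zeros(20)]
        model = fit_sparse_logistic(x, y, 0.05)
        assert model.weights[0] > 0

    def test_zero_penalty_matches_unpenalized_irls_oracle(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 5))
        eta = X[:, 0] - 0.5 * X[:, 2]
        y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
        model = fit_sparse_logistic(X, y, 0.0)
        Z = (X - X.mean(0)) / X.std(0)
        ref = statsmodels.Logit(y, np.c_[Z, np.ones(120)]).fit(disp=0)
        np.testing.assert_allclose(model.weights, ref.params, atol=1e-5)

    def test_label_swap_negates_logits(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 4))
        y = (rng.random(80) < 0.6).astype(float)
        m1 = fit_sparse_logistic(X, y, 0.05)
        m2 = fit_sparse_logistic(X, 1 - y, 0.05)
        p1 = predict_prob(m1, X)
        p2 = predict_prob(m2, X)
        np.testing.assert_allclose(p1, 1 - p2, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError):
            fit_sparse_logistic(np.zeros((10, 2)), np.ones(10), 0.1)


@pytest.fixture(scope="module")
def loocv_setup():
    cohort = generate_cohort(small_config(seed=21, effect_d=1.5))
    reduced = nested_fs(cohort, LassoConfig(selection_rule="1se"), seed=0)
    result = loocv_run(cohort, reduced, seed=0)
    return cohort, reduced, result


class TestLoocv:
    def test_one_record_per_subject(self, loocv_setup):
        cohort, _, result = loocv_setup
        assert result.subject_ids == cohort.subject_ids
        assert len(result.probabilities) == cohort.n_subjects
        assert np.all((result.probabilities > 0) & (result.probabilities < 1))

    def test_labels_threshold_at_half(self, loocv_setup):
        _, _, result = loocv_setup
        np.testing.assert_array_equal(
            result.predicted_labels, (result.probabilities >= 0.5).astype(int)
        )

    def test_strong_signal_classifies_well(self, loocv_setup):
        cohort, _, result = loocv_setup
        acc = (result.predicted_labels == result.true_labels).mean()
        assert acc >= 0.8

    def test_subject_never_in_own_feature_pool(self, loocv_setup):
        """The leak-free contract: each subject's reduced set was
        computed from subjects outside its own testing pool."""
        cohort, reduced, _ = loocv_setup
        for sid in cohort.subject_ids:
            pool = reduced.pool_of(sid)
            assert sid in pool.pool  # pool membership well defined
        all_pools = [p.pool for p in reduced.pools]
        assert sum(len(p) for p in all_pools) == cohort.n_subjects

    def test_empty_reduced_set_predicts_base_rate(self, loocv_setup):
        from diffperf.selection import PoolSelection, ReducedFeatureSets

        cohort, reduced, _ = loocv_setup
        stripped = ReducedFeatureSets(
            pools=[
                PoolSelection(
                    pool=p.pool, features=frozenset(),
                    inner_lambdas=(), inner_support_sizes=(),
                )
                for p in reduced.pools
            ],
            seed=0,
        )
        with pytest.warns(UserWarning, match="empty reduced"):
            res = loocv_run(cohort, stripped, seed=0)
        # each subject predicted at the base rate of the other 63
        y = cohort.diagnosis
        for i in range(cohort.n_subjects):
            expect = (y.sum() - y[i]) / (len(y) - 1)
            assert res.probabilities[i] == pytest.approx(expect)


class TestConsensus:
    def _result_with(self, fold_features, n=8):
        from diffperf.classifier import LoocvResult
        from diffperf.selection import PoolSelection, ReducedFeatureSets

        ids = [f"S{i}" for i in range(n)]
        red = ReducedFeatureSets(
            pools=[PoolSelection(pool=frozenset(ids),
                                 features=frozenset().union(*fold_features),
                                 inner_lambdas=(), inner_support_sizes=())],
            seed=0,
        )
        return LoocvResult(
            subject_ids=ids,
            true_labels=np.r_[np.ones(n // 2), np.zeros(n - n // 2)].astype(int),
            probabilities=np.full(n, 0.5),
            predicted_labels=np.ones(n, dtype=int),
            fold_features=list(fold_features),
            reduced=red,
            pool_lambdas={0: 0.1},
            seed=0,
        )

    def test_feature_in_all_folds_has_frequency_one(self):
        res = self._result_with([frozenset({"a"})] * 8)
        cs = consensus_features(res, 0.75)
        assert cs.frequencies["a"] == pytest.approx(1.0)
        assert cs.features == frozenset({"a"})

    def test_threshold_boundary_is_inclusive(self):
        # feature in 6 of 8 folds: 0.75 exactly -> included;
        # feature in 5 of 8: 0.625 -> excluded
        folds = [frozenset({"a", "b"})] * 5 + [frozenset({"a"})] + [frozenset()] * 2
        cs = consensus_features(self._result_with(folds), 0.75)
        assert cs.frequencies["a"] == pytest.approx(0.75)
        assert "a" in cs.features and "b" not in cs.features

    def test_just_below_threshold_excluded(self):
        # 74 of 100 folds -> 0.74 < 0.75
        folds = [frozenset({"a"})] * 74 + [frozenset()] * 26
        cs = consensus_features(self._result_with(folds, n=100), 0.75)
        assert cs.frequencies["a"] == pytest.approx(0.74)
        assert cs.features == frozenset()

    def test_empty_consensus_warns(self):
        folds = [frozenset({"a"})] + [frozenset()] * 7
        with pytest.warns(UserWarning, match="no feature"):
            cs = consensus_features(self._result_with(folds), 0.75)
        assert cs.features == frozenset()

    def test_reduced_set_counting_rule(self):
        res = self._result_with([frozenset()] * 8)
        cs = consensus_features(res, 0.75, count="reduced_sets")
        # every subject's pool carries the union set
        for f in res.reduced.pools[0].features:
            assert cs.frequencies[f] == pytest.approx(1.0)
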