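import warnings

import numpy as np
import pytest

from isletdx import TargetEncoding, make_classifier, classify, kernel_eval
from isletdx.classifiers import (BLDCClassifier, CLASSIFIER_NAMES,
                                 EMClassifier, GMMClassifier, LoRClassifier,
                                 LRClassifier, NLRClassifier, SDCClassifier,
                                 SVMClassifier, lm_damped_step, fit_mixture)
from isletdx.data import LabelVector, LABEL_DIABETIC, LABEL_NON_DIABETIC
from tests.conftest import two_class_labels

SANITY_KW = {"svm_rbf": {"gamma": 0.1}, "svm_poly": {"gamma": 1.0}}


class TestTargetEncoding:
    def test_printed_targets_accepted(self):
        enc = TargetEncoding(0.1, 0.85)
        assert abs(enc.t_dia - enc.t_nd) >= 0.5
        assert enc.decision_threshold == pytest.approx(0.475)

    def test_insufficient_separation_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            TargetEncoding(0.4, 0.6)

    def test_score_at_threshold_is_non_diabetic(self):
        enc = TargetEncoding()
        lab = enc.decide(np.array([enc.decision_threshold]))
        assert lab[0] == LABEL_NON_DIABETIC

    def test_classify_validates_encoding(self, blob_task):
        xtr, ytr, xte, _ = blob_task
        m = make_classifier("sdc").fit(xtr, ytr)
        assert len(classify(m, xte)) == len(xte)


class TestAllClassifiers:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_perfect_on_separated_task(self, blob_task, name):
        xtr, ytr, xte, yte = blob_task
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = make_classifier(name, **SANITY_KW.get(name, {})).fit(xtr, ytr)
        assert (m.predict(xte) == yte).mean() == 1.0

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_predict_deterministic(self, blob_task, name):
        xtr, ytr, xte, _ = blob_task
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = make_classifier(name, **SANITY_KW.get(name, {})).fit(xtr, ytr)
        np.testing.assert_array_equal(m.predict(xte), m.predict(xte))

    def test_chance_level_on_null_data(self):
        """~50% +/- 10 points on label-free noise, averaged over 10 seeds."""
        ytr = two_class_labels(20, 50)
        yte = np.asarray([LABEL_DIABETIC] * 20 + [LABEL_NON_DIABETIC] * 20,
                         dtype=object)
        means = {}
        for name in CLASSIFIER_NAMES:
            accs = []
            for seed in range(10):
                rng = np.random.default_rng(100 + seed)
                xtr = rng.normal(size=(70, 2))
                xte = rng.normal(size=(40, 2))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = make_classifier(name, **SANITY_KW.get(name, {}))
                    m.fit(xtr, ytr)
                accs.append((m.predict(xte) == yte).mean())
            means[name] = np.mean(accs)
        for name, acc in means.items():
            assert 0.4 <= acc <= 0.6, f"{name}: {acc}"


class TestNLR:
    def test_recovers_noiseless_model(self, rng):
        theta = np.array([0.1, 0.8, -0.5, 2.0])
        x = rng.normal(size=(60, 1))
        y = theta[0] + theta[1] / (1 + np.exp(-(theta[2] + x[:, 0] * theta[3])))
        m = NLRClassifier().fit(x, y)
        assert np.mean((m.continuous(x) - y) ** 2) < 1e-6

    def test_objective_trace_non_increasing(self, blob_task):
        xtr, ytr, _, _ = blob_task
        m = NLRClassifier().fit(xtr, ytr)
        assert all(b <= a + 1e-12 for a, b in
                   zip(m.training_log, m.training_log[1:]))

    def test_heavy_damping_shrinks_step_toward_gradient(self, rng):
        jac = rng.normal(size=(20, 2))
        resid = rng.normal(size=20)
        free = lm_damped_step(jac, resid, 0.0)
        damped = lm_damped_step(jac, resid, 1e6)
        np.testing.assert_allclose(damped, jac.T @ resid / 1e6, rtol=1e-3)
        assert np.linalg.norm(damped) < 1e-3 * np.linalg.norm(free)


class TestLR:
    def test_noiseless_slope_recovered(self):
        x = np.linspace(-1, 1, 50)[:, None]
        y = 2.0 * x[:, 0]
        m = LRClassifier(learning_rate=0.5, iters=4000, standardize=False)
        m.fit(x, y)
        assert m.theta_[1] == pytest.approx(2.0, abs=1e-3)

    def test_cost_trace_non_increasing_at_default_rate(self, rng):
        x = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        m = LRClassifier(iters=500).fit(x, y)
        assert all(b <= a + 1e-12 for a, b in
                   zip(m.training_log, m.training_log[1:]))

    def test_zero_iterations_keeps_zero_parameters(self, rng):
        m = LRClassifier(iters=0).fit(rng.normal(size=(10, 2)),
                                      rng.normal(size=10))
        np.testing.assert_array_equal(m.theta_, 0)


class TestMixtures:
    def test_gmm_mixing_weights_normalized(self, blob_task):
        xtr, ytr, _, _ = blob_task
        m = GMMClassifier(g=2).fit(xtr, ytr)
        for cls, (w, _, _) in m.models_.items():
            assert w.sum() == pytest.approx(1.0)

    def test_em_loglik_trace_non_decreasing(self, rng):
        x = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(5, 1, (40, 2))])
        _, _, _, trace, _ = fit_mixture(x, 2, rng)
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_gmm_agrees_with_sklearn_on_separated_blobs(self, rng):
        from sklearn.mixture import GaussianMixture
        x = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(8, 1, (60, 2))])
        w, means, covs, _, _ = fit_mixture(x, 2, rng)
        ref = GaussianMixture(2, random_state=0).fit(x)
        ours = sorted(np.round(m[0], 0) for m in means)
        theirs = sorted(np.round(m[0], 0) for m in ref.means_)
        assert ours == theirs

    def test_em_component_class_mapping(self, blob_task):
        xtr, ytr, xte, yte = blob_task
        m = EMClassifier().fit(xtr, ytr)
        assert set(m.component_class_.values()) == {LABEL_DIABETIC,
                                                    LABEL_NON_DIABETIC}
        assert (m.predict(xte) == yte).mean() == 1.0

    def test_em_degenerate_mapping_falls_back_with_warning(self, rng):
        # one tight blob: both components overlap the majority class
        x = rng.normal(size=(70, 2))
        y = two_class_labels(20, 50)
        m = EMClassifier().fit(x, y)
        preds = set(m.predict(rng.normal(size=(10, 2))))
        assert len(preds | set(m.component_class_.values())) <= 2


class TestBLDC:
    def test_large_beta_matches_least_squares(self, rng):
        x = rng.normal(size=(30, 3))
        t = x @ np.array([1.0, -2.0, 0.5]) + 0.3
        m = BLDCClassifier(alpha=1e-8, beta=1e8).fit(x, t)
        a = np.hstack([x, np.ones((30, 1))])
        ols = np.linalg.lstsq(a, t, rcond=None)[0]
        np.testing.assert_allclose(m.mean_, ols, atol=1e-4)

    def test_posterior_covariance_positive_definite(self, blob_task):
        xtr, ytr, _, _ = blob_task
        m = BLDCClassifier().fit(xtr, ytr)
        np.linalg.cholesky(m.cov_)          # raises if not SPD

    def test_strong_prior_shrinks_weights(self, rng):
        x = rng.normal(size=(30, 3))
        t = x @ np.array([1.0, -2.0, 0.5])
        m = BLDCClassifier(alpha=1e8, beta=1.0).fit(x, t)
        assert np.linalg.norm(m.mean_[:-1]) < 1e-4

    def test_predictive_variance_positive(self, blob_task):
        xtr, ytr, xte, _ = blob_task
        m = BLDCClassifier().fit(xtr, ytr)
        assert np.all(m.predictive_variance(xte) > 0)


class TestLoR:
    def test_separable_data_training_accuracy(self, blob_task):
        xtr, ytr, _, _ = blob_task
        m = LoRClassifier(tau=100.0).fit(xtr, ytr)
        assert (m.predict(xtr) == ytr.as_array()).mean() == 1.0

    def test_strong_penalty_shrinks_to_intercept(self, blob_task):
        xtr, ytr, _, _ = blob_task
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = LoRClassifier(tau=1e-4, max_iter=500).fit(xtr, ytr)
        assert np.linalg.norm(m.coef_[1:]) < 1e-3

    def test_probabilities_strictly_inside_unit_interval(self, blob_task):
        xtr, ytr, xte, _ = blob_task
        p = LoRClassifier().fit(xtr, ytr).predict_proba(xte)
        assert np.all(p > 0) and np.all(p < 1)


class TestSDC:
    def test_training_sample_recovers_its_class(self, blob_task):
        xtr, ytr, _, _ = blob_task
        m = SDCClassifier(lam=1e3).fit(xtr, ytr)
        assert m.predict(xtr[:1])[0] == ytr.labels[0]
        assert m.predict(xtr[-1:])[0] == ytr.labels[-1]

    def test_lambda_zero_predicts_larger_class(self, rng):
        x = rng.normal(size=(30, 2))
        y = two_class_labels(10, 20)
        m = SDCClassifier(lam=0.0).fit(x, y)
        # every score is log(class size), so the larger class always wins
        assert set(m.predict(rng.normal(size=(5, 2)))) == {LABEL_NON_DIABETIC}

    def test_exact_tie_goes_to_lower_class_index(self):
        x = np.array([[1.0], [-1.0]])
        y = LabelVector(["a", "b"], [LABEL_DIABETIC, LABEL_NON_DIABETIC])
        m = SDCClassifier(lam=0.5).fit(x, y)
        # the origin is equidistant from both training points
        assert m.predict(np.array([[0.0]]))[0] == LABEL_DIABETIC


class TestKernels:
    def test_poly_arithmetic(self):
        assert kernel_eval("poly", [1, 0], [1, 0], gamma=1, degree=2) == 4.0

    def test_rbf_zero_distance(self):
        assert kernel_eval("rbf", [1.0, 2.0], [1.0, 2.0], gamma=5.0) == 1.0

    def test_rbf_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 4))
            assert kernel_eval("rbf", a, b, 0.5) == \
                pytest.approx(kernel_eval("rbf", b, a, 0.5))


class TestSVM:
    def two_point(self):
        x = np.array([[-1.0], [1.0]])
        y = LabelVector(["n", "d"], [LABEL_NON_DIABETIC, LABEL_DIABETIC])
        return x, y

    def test_two_point_analytic_hard_margin(self):
        # w = 1, b = 0, alpha_1 = alpha_2 = 1/2 solve the 2-point dual
        x, y = self.two_point()
        m = SVMClassifier(kernel="linear", C=1e6).fit(x, y)
        np.testing.assert_allclose(np.abs(m.svc_.dual_coef_[0]), 0.5,
                                   atol=1e-6)
        assert m.svc_.intercept_[0] == pytest.approx(0.0, abs=1e-6)
        assert m.decision_function(np.array([[2.0]]))[0] == pytest.approx(2.0,
                                                                          abs=1e-6)

    def test_dual_equality_constraint(self, blob_task):
        xtr, ytr, _, _ = blob_task
        m = SVMClassifier(kernel="linear", C=0.85).fit(xtr, ytr)
        z = np.where(ytr.as_array() == LABEL_DIABETIC, 1, -1)[m.svc_.support_]
        assert abs(m.svc_.dual_coef_[0].sum()) < 1e-8
        assert np.all(np.sign(m.svc_.dual_coef_[0]) == z)

    def test_dual_objective_matches_projected_gradient_oracle(self, rng):
        x = rng.normal(size=(20, 3))
        z = np.where(rng.random(20) < 0.4, 1, -1)
        z[:2] = [1, -1]
        y = LabelVector([f"s{i}" for i in range(20)],
                        [LABEL_DIABETIC if t > 0 else LABEL_NON_DIABETIC
                         for t in z])
        c = 1.0
        m = SVMClassifier(kernel="linear", C=c).fit(x, y)
        q = np.outer(z, z) * (x @ x.T)

        def project(v):
            # exact projection onto {0 <= a <= C, z.a = 0} by bisection on
            # the multiplier of the equality constraint
            lo, hi = -1e3, 1e3
            for _ in range(100):
                lam = 0.5 * (lo + hi)
                a = np.clip(v - lam * z, 0, c)
                if z @ a > 0:
                    lo = lam
                else:
                    hi = lam
            return np.clip(v - 0.5 * (lo + hi) * z, 0, c)

        a = project(np.zeros(20))
        for _ in range(50_000):
            a = project(a + 1e-3 * (1 - q @ a))
        oracle = a.sum() - 0.5 * a @ q @ a
        assert m.dual_objective(x, y) == pytest.approx(oracle, abs=1e-4)

    def test_single_class_rejected(self, rng):
        y = LabelVector(["a", "b"], [LABEL_DIABETIC, LABEL_DIABETIC])
        with pytest.raises(ValueError):
            SVMClassifier().fit(rng.normal(size=(2, 2)), y)

    def test_support_reduction_retrains_on_six_points(self, blob_task):
        xtr, ytr, xte, yte = blob_task
        m = SVMClassifier(kernel="linear", C=1.0,
                          reduce_supports=True, seed=0).fit(xtr, ytr)
        assert m.svc_.support_vectors_.shape[0] <= 6
        # well-separated blobs survive the severe thinning
        assert (m.predict(xte) == yte).mean() == 1.0
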