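import numpy as np
import pytest

from twinpcg import TrainingSet, TwinSVM, gaussian_kernel
from oracles import primal_twsvm_brute


def _random_instance(seed, m1, m2, n=2, spread=2.0):
    rng = np.random.default_rng(seed)
    A = rng.normal(loc=0.0, scale=1.0, size=(m1, n))
    B = rng.normal(loc=spread, scale=1.0, size=(m2, n))
    X = np.vstack([A, B])
    y = np.array([1] * m1 + [-1] * m2)
    return X, y


class TestGaussianKernel:
    def test_identical_rows_give_one(self):
        X = np.array([[1.0, 2.0, 3.0]])
        assert gaussian_kernel(X, X, sigma=0.7)[0, 0] == pytest.approx(1.0)

    def test_closed_form_value(self):
        sigma = 1.3
        K = gaussian_kernel(np.array([[0.0]]),
                            np.array([[sigma * np.sqrt(2.0)]]), sigma)
        assert K[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_gram_matrix_is_psd_and_symmetric(self, rng):
        X = rng.standard_normal((30, 5))
        K = gaussian_kernel(X, X, sigma=2.0)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-10
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.eye(2), np.eye(2), sigma=0.0)


class TestTrainingSet:
    def test_partition_by_class(self):
        X, y = _random_instance(0, 3, 4)
        ts = TrainingSet(X, y)
        assert ts.A.shape == (3, 2) and ts.B.shape == (4, 2)
        np.testing.assert_array_equal(ts.C, X)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            TrainingSet(np.eye(3), np.array([1, 1, 1]))


class TestFitAgainstPrimalBruteForce:
    """The dual-path solution must match a generic primal QP solve."""

    @pytest.mark.parametrize("seed,m1,m2,kernel,sigma", [
        (0, 3, 3, "linear", None),
        (1, 4, 6, "linear", None),
        (2, 8, 12, "linear", None),
        (3, 5, 5, "rbf", 1.5),
        (4, 9, 11, "rbf", 2.0),
    ])
    def test_objective_gap_and_predictions(self, seed, m1, m2, kernel, sigma):
        X, y = _random_instance(seed, m1, m2)
        c = 1.0
        kw = dict(c1=c, c2=c, kernel=kernel, standardize=False)
        if kernel == "rbf":
            kw.update(sigma1=sigma, sigma2=sigma)
        model = TwinSVM(**kw).fit(X, y)
        j1, j2 = model.primal_objectives()
        # include the ridge term the dual path regularizes with
        ridge = model.ridge
        j1 += 0.5 * ridge * (float(model.u1_ @ model.u1_) + model.b1_**2)
        j2 += 0.5 * ridge * (float(model.u2_ @ model.u2_) + model.b2_**2)

        A, B = X[y == 1], X[y == -1]
        if kernel == "linear":
            KA, KB = A @ X.T, B @ X.T
        else:
            KA = gaussian_kernel(A, X, sigma)
            KB = gaussian_kernel(B, X, sigma)
        v1, obj1 = primal_twsvm_brute(KA, KB, c, ridge)
        # plane 2 under [u2; b2] -> -[u; b] is exactly the oracle's form
        # with the class roles swapped
        v2, obj2 = primal_twsvm_brute(KB, KA, c, ridge)

        assert abs(j1 - obj1) <= 1e-5 * max(1.0, abs(obj1))
        assert abs(j2 - obj2) <= 1e-5 * max(1.0, abs(obj2))

        brute = TwinSVM(**kw)
        brute.fit(X, y)  # same preprocessing path
        brute.u1_, brute.b1_ = v1[:-1], float(v1[-1])
        brute.u2_, brute.b2_ = -v2[:-1], float(-v2[-1])
        K1 = brute._kernel(X, X, brute.sigma1)
        brute.denom1_ = float(np.sqrt(brute.u1_ @ K1 @ brute.u1_))
        brute.denom2_ = float(np.sqrt(brute.u2_ @ K1 @ brute.u2_))
        np.testing.assert_array_equal(model.predict(X), brute.predict(X))

    def test_separable_toy_set_classified_exactly(self, toy_separable):
        X, y = toy_separable
        model = TwinSVM(c1=1.0, c2=1.0, kernel="linear",
                        standardize=False).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)


class TestDualFeasibility:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_box_constraints_hold(self, seed):
        X, y = _random_instance(seed, 6, 8)
        c1, c2 = 0.7, 1.3
        model = TwinSVM(c1=c1, c2=c2, sigma1=1.0, sigma2=1.0).fit(X, y)
        sd = model.slack_duals_
        assert np.all(sd.alpha >= -1e-10) and np.all(sd.alpha <= c1 + 1e-10)
        assert np.all(sd.gamma >= -1e-10) and np.all(sd.gamma <= c2 + 1e-10)
        assert np.all(sd.zeta >= 0.0) and np.all(sd.eta >= 0.0)


class TestSymmetries:
    def test_mirror_symmetric_data_gives_mirror_planes(self):
        A = np.array([[1.0, 2.0], [2.0, 1.0], [1.5, 1.5]])
        X = np.vstack([A, -A])
        y = np.array([1, 1, 1, -1, -1, -1])
        m = TwinSVM(c1=1.0, c2=1.0, kernel="linear", standardize=False).fit(X, y)
        # with B = -A the second problem is the first one under x -> -x
        assert abs(m.b1_) == pytest.approx(abs(m.b2_), abs=1e-6)
        np.testing.assert_allclose(
            np.sort(np.abs(m.u1_)), np.sort(np.abs(m.u2_)), atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_class_swap_flips_every_prediction(self, seed):
        X, y = _random_instance(seed, 7, 9)
        m = TwinSVM(c1=0.8, c2=1.2, sigma1=1.0, sigma2=1.5).fit(X, y)
        swapped = TwinSVM(c1=1.2, c2=0.8, sigma1=1.5, sigma2=1.0).fit(X, -y)
        Xtest = np.random.default_rng(seed).normal(1.0, 2.0, size=(40, 2))
        np.testing.assert_array_equal(m.predict(Xtest), -swapped.predict(Xtest))

    def test_training_order_permutation_invariance(self, rng):
        X, y = _random_instance(11, 8, 8)
        perm = rng.permutation(len(y))
        m1 = TwinSVM(c1=1.0, c2=1.0, sigma1=1.0, sigma2=1.0).fit(X, y)
        m2 = TwinSVM(c1=1.0, c2=1.0, sigma1=1.0, sigma2=1.0).fit(X[perm], y[perm])
        Xtest = rng.normal(1.0, 2.0, size=(50, 2))
        np.testing.assert_array_equal(m1.predict(Xtest), m2.predict(Xtest))


class TestDecisionRule:
    def test_distances_match_explicit_kernel_loop(self, rng):
        X, y = _random_instance(21, 10, 12)
        m = TwinSVM(c1=1.0, c2=1.0, sigma1=1.2, sigma2=0.9).fit(X, y)
        x = rng.standard_normal(2)
        xs = (x - m.mean_) / m.scale_
        k1 = np.array([np.exp(-np.sum((xs - row) ** 2) / (2 * m.sigma1**2))
                       for row in m.C_train_])
        k2 = np.array([np.exp(-np.sum((xs - row) ** 2) / (2 * m.sigma2**2))
                       for row in m.C_train_])
        d = m.decision_distances(x[None, :])[0]
        assert d[0] == pytest.approx(
            abs(k1 @ m.u1_ + m.b1_) / m.denom1_, rel=1e-10)
        assert d[1] == pytest.approx(
            abs(k2 @ m.u2_ + m.b2_) / m.denom2_, rel=1e-10)

    def test_point_on_plane_has_zero_distance(self):
        # linear kernel: solve for a point x with w . x + b = 0
        X = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 4.0], [4.0, 5.0]])
        y = np.array([1, 1, -1, -1])
        m = TwinSVM(c1=1.0, c2=1.0, kernel="linear", standardize=False).fit(X, y)
        w = X.T @ m.u1_  # effective linear weight vector
        x0 = np.array([1.0, 0.0])
        x0 = x0 - w * (w @ x0 + m.b1_) / (w @ w)
        d = m.decision_distances(x0[None, :])[0]
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_tie_goes_to_negative_class(self, toy_separable):
        X, y = toy_separable
        m = TwinSVM(c1=1.0, c2=1.0, kernel="linear", standardize=False).fit(X, y)
        m.denom1_ = m.denom2_ = 1.0
        m.u1_ = m.u2_ = np.zeros_like(m.u1_)
        m.b1_ = m.b2_ = 1.0  # forces d1 == d2 exactly
        assert np.all(m.predict(X) == -1)

    def test_dimension_mismatch_rejected(self, toy_separable):
        X, y = toy_separable
        m = TwinSVM(kernel="linear", standardize=False).fit(X, y)
        with pytest.raises(ValueError):
            m.predict(np.ones((1, 5)))


class TestRegularizationAndMoons:
    def test_slack_vanishes_on_separable_data_as_c_grows(self, toy_separable):
        # both planes can satisfy the unit-margin constraints exactly once
        # the penalty outweighs the closeness term
        X, y = toy_separable
        slack = []
        for c in (1e-3, 1.0, 1e3):
            m = TwinSVM(c1=c, c2=c, kernel="linear", standardize=False).fit(X, y)
            sd = m.slack_duals_
            slack.append(float(sd.zeta.sum() + sd.eta.sum()))
        assert slack[-1] <= slack[0] + 1e-9
        assert slack[-1] < 1e-6

    def test_two_moons_accuracy(self):
        from sklearn.datasets import make_moons
        X, y01 = make_moons(n_samples=200, noise=0.15, random_state=0)
        y = np.where(y01 == 1, 1, -1)
        m = TwinSVM(c1=1.0, c2=1.0, sigma1=1.0, sigma2=1.0).fit(X, y)
        assert np.mean(m.predict(X) == y) >= 0.95


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path, toy_separable):
        X, y = toy_separable
        m = TwinSVM(c1=2.0, c2=0.5, sigma1=1.1, sigma2=0.8).fit(X, y)
        m.save(tmp_path / "model.joblib")
        back = TwinSVM.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(m.predict(X), back.predict(X))
        np.testing.assert_allclose(
            m.decision_distances(X), back.decision_distances(X), rtol=1e-12)
        assert back.c1 == 2.0 and back.sigma2 == 0.8
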