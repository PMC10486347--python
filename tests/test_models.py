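"""The six calibration models: oracles, contracts, and shared invariants."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from hsitex import (
    fit_bipls,
    fit_bpann,
    fit_ipls,
    fit_lssvm,
    fit_plsr,
    fit_sipls,
    load_model,
    predict,
    save_model,
)
from hsitex.errors import BudgetError, DegenerateTargetError, ParameterError


def _linear_problem(rng, n=60, p=12, noise=0.0):
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestPLSR:
    def test_single_band_exact_fit(self):
        X = np.linspace(0, 1, 20).reshape(-1, 1)
        y = 2.0 * X[:, 0]
        m = fit_plsr(X, y, n_latent=1)
        np.testing.assert_allclose(predict(m, X), y, atol=1e-10)

    def test_full_rank_equals_ols_normal_equations(self, rng):
        X, y = _linear_problem(rng, n=30, p=8, noise=0.1)
        m = fit_plsr(X, y, n_latent=8)
        Xc = np.c_[np.ones(30), X]
        ols = Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        np.testing.assert_allclose(predict(m, X), ols, rtol=1e-8, atol=1e-8)

    def test_matches_sklearn_pls(self, rng):
        """Independent cross-check against sklearn's PLS implementation."""
        X, y = _linear_problem(rng, n=50, p=20, noise=0.3)
        for A in (1, 3, 5):
            ours = predict(fit_plsr(X, y, n_latent=A), X)
            theirs = PLSRegression(n_components=A, scale=True).fit(X, y).predict(X).ravel()
            np.testing.assert_allclose(ours, theirs, rtol=1e-6, atol=1e-6)

    def test_duplicated_column_leaves_full_rank_predictions_unchanged(self, rng):
        """Duplicating a band does not change the spanned column space, so
        at full rank the fitted predictions are identical."""
        X, y = _linear_problem(rng, n=40, p=6, noise=0.2)
        Xdup = np.hstack([X, X[:, [2]]])
        a = predict(fit_plsr(X, y, n_latent=6), X)
        b = predict(fit_plsr(Xdup, y, n_latent=6), Xdup)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_score_vectors_orthogonal(self, rng):
        X, y = _linear_problem(rng, n=50, p=15, noise=0.5)
        T = fit_plsr(X, y, n_latent=5).params["x_scores"]
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_excessive_latent_count_rejected(self, rng):
        X, y = _linear_problem(rng, n=10, p=4)
        with pytest.raises(ParameterError):
            fit_plsr(X, y, n_latent=10)

    def test_constant_target_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(DegenerateTargetError):
            fit_plsr(X, np.ones(20), n_latent=2)

    def test_cv_selection_is_deterministic(self, rng):
        X, y = _linear_problem(rng, n=60, p=30, noise=0.5)
        m1 = fit_plsr(X, y, n_latent="cv")
        m2 = fit_plsr(X, y, n_latent="cv")
        assert m1.hyperparams == m2.hyperparams
        assert np.array_equal(m1.params["beta"], m2.params["beta"])


class TestIntervalFamily:
    def _interval_signal(self, rng, intervals=(3,), n=80, p=100):
        X = rng.standard_normal((n, p))
        y = np.zeros(n)
        for iv in intervals:
            y = y + X[:, iv * 10 + 3] + 0.5 * X[:, iv * 10 + 6]
        return X, y + 0.05 * rng.standard_normal(n)

    def test_ipls_finds_informative_interval(self, rng):
        X, y = self._interval_signal(rng, intervals=(3,))
        assert fit_ipls(X, y, 10).meta["interval"] == 3

    def test_ipls_single_interval_equals_full_plsr(self, rng):
        X, y = _linear_problem(rng, n=50, p=30, noise=0.3)
        a = predict(fit_ipls(X, y, 1), X)
        b = predict(fit_plsr(X, y, n_latent="cv", max_latent=10), X)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_ipls_identical_intervals_tie_to_lowest_index(self, rng):
        X = rng.standard_normal((60, 20))
        X[:, 10:] = X[:, :10]  # intervals 0 and 1 identical
        y = X[:, 3] + 0.05 * rng.standard_normal(60)
        assert fit_ipls(X, y, 2).meta["interval"] == 0

    def test_sipls_finds_informative_pair(self, rng):
        X, y = self._interval_signal(rng, intervals=(2, 7))
        assert fit_sipls(X, y, 10, 2).meta["combination"] == [2, 7]

    def test_sipls_all_intervals_equals_full_plsr(self, rng):
        X, y = _linear_problem(rng, n=50, p=30, noise=0.3)
        a = predict(fit_sipls(X, y, 5, 5, max_latent=10), X)
        b = predict(fit_plsr(X, y, n_latent="cv", max_latent=10), X)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_sipls_combo_one_equals_ipls(self, rng):
        X, y = self._interval_signal(rng)
        a = fit_sipls(X, y, 10, 1)
        b = fit_ipls(X, y, 10)
        assert a.meta["combination"] == [b.meta["interval"]]
        np.testing.assert_allclose(predict(a, X), predict(b, X), atol=1e-10)

    def test_sipls_budget_guard(self, rng):
        X, y = _linear_problem(rng, n=30, p=100)
        with pytest.raises(BudgetError):
            fit_sipls(X, y, 40, 10, budget=1000)

    def test_bipls_eliminates_noise_intervals_first(self, rng):
        X, y = self._interval_signal(rng, intervals=(4,))
        m = fit_bipls(X, y, 10)
        dropped = [t["dropped"] for t in m.meta["trace"]]
        assert 4 in m.meta["surviving_intervals"] or dropped.index(4) >= 9
        assert 4 in m.meta["surviving_intervals"]

    def test_bipls_two_intervals_keeps_informative(self, rng):
        X, y = self._interval_signal(rng, intervals=(1,), p=20)
        m = fit_bipls(X, y, 2)
        assert m.meta["surviving_intervals"] == [1]

    def test_selected_subset_is_family_minimum(self, rng):
        """The iPLS winner matches brute-force enumeration of the family."""
        from hsitex.models import _score_bands
        from hsitex.selection import make_intervals

        X, y = self._interval_signal(rng, intervals=(5,), n=60)
        scores = [_score_bands(X, y, np.arange(lo, hi), 10, 5)[0]
                  for lo, hi in make_intervals(100, 10)]
        assert fit_ipls(X, y, 10, max_latent=10).meta["interval"] == int(np.argmin(scores))


class TestLSSVM:
    def test_matches_independent_kkt_solve(self, rng):
        """Predictions equal a dense KKT solve built from scratch here."""
        for n in (3, 10, 30):
            X = rng.standard_normal((n, 4))
            y = rng.standard_normal(n)
            gamma, sigma2 = 12.0, 3.5
            m = fit_lssvm(X, y, gamma=gamma, sigma2=sigma2)
            # independent oracle on standardized variables
            mu, sd = X.mean(0), np.where(X.std(0) > 0, X.std(0), 1.0)
            Xs = (X - mu) / sd
            ymu, ysd = y.mean(), y.std()
            ys = (y - ymu) / ysd
            D = ((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(-1)
            K = np.exp(-D / sigma2)
            A = np.zeros((n + 1, n + 1))
            A[0, 1:] = 1
            A[1:, 0] = 1
            A[1:, 1:] = K + np.eye(n) / gamma
            sol = np.linalg.solve(A, np.r_[0.0, ys])
            oracle = (K @ sol[1:] + sol[0]) * ysd + ymu
            np.testing.assert_allclose(predict(m, X), oracle, rtol=1e-8, atol=1e-8)

    def test_huge_gamma_interpolates_training_targets(self, rng):
        X = rng.standard_normal((15, 3))
        y = rng.standard_normal(15)
        m = fit_lssvm(X, y, gamma=1e9, sigma2=2.0)
        np.testing.assert_allclose(predict(m, X), y, atol=1e-5)

    def test_kernel_locality(self, rng):
        X = rng.standard_normal((20, 3)) * 3.0
        y = rng.standard_normal(20)
        m = fit_lssvm(X, y, gamma=1e6, sigma2=1e-3)
        # querying exactly at a training point with a tiny kernel width
        # returns (approximately) that training target
        assert predict(m, X[[5]])[0] == pytest.approx(y[5], abs=1e-3)

    def test_nonpositive_hyperparams_rejected(self, rng):
        X, y = _linear_problem(rng, n=10, p=3)
        with pytest.raises(ParameterError):
            fit_lssvm(X, y, gamma=-1.0, sigma2=1.0)


class TestBPANN:
    def test_learns_linear_target(self, rng):
        X = rng.standard_normal((80, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        m = fit_bpann(X, y, hidden_size=8, seed=0, max_epochs=20000)
        r = np.corrcoef(predict(m, X), y)[0, 1]
        assert r**2 >= 0.99

    def test_same_seed_reproduces_weights_and_predictions(self, rng):
        X, y = _linear_problem(rng, n=40, p=10, noise=0.2)
        m1 = fit_bpann(X, y, seed=7)
        m2 = fit_bpann(X, y, seed=7)
        assert np.array_equal(m1.params["W1"], m2.params["W1"])
        assert np.array_equal(predict(m1, X), predict(m2, X))

    def test_epoch_cap_respected(self, rng):
        X, y = _linear_problem(rng, n=30, p=5, noise=0.5)
        m = fit_bpann(X, y, seed=1, max_epochs=50)
        assert m.hyperparams["epochs_run"] <= 50


class TestSharedContracts:
    @pytest.mark.parametrize("fitter", [
        lambda X, y: fit_plsr(X, y, n_latent=3),
        lambda X, y: fit_ipls(X, y, 4, max_latent=3),
        lambda X, y: fit_sipls(X, y, 4, 2, max_latent=3),
        lambda X, y: fit_bipls(X, y, 4, max_latent=3),
        lambda X, y: fit_lssvm(X, y, gamma=50.0, sigma2=20.0),
        lambda X, y: fit_bpann(X, y, hidden_size=5, seed=3, max_epochs=200),
    ], ids=["plsr", "ipls", "sipls", "bipls", "lssvm", "bpann"])
    def test_target_scale_equivariance(self, rng, fitter):
        """Fitting on c*y yields c times the predictions on y (c > 0)."""
        X, y = _linear_problem(rng, n=40, p=16, noise=0.3)
        c = 37.5
        base = fitter(X, y)
        scaled = fitter(X, c * y)
        np.testing.assert_allclose(predict(scaled, X), c * predict(base, X),
                                   rtol=1e-7, atol=1e-7)

    @pytest.mark.parametrize("fitter", [
        lambda X, y: fit_plsr(X, y, n_latent=4),
        lambda X, y: fit_lssvm(X, y, gamma=10.0, sigma2=50.0),
        lambda X, y: fit_bpann(X, y, hidden_size=4, seed=2, max_epochs=100),
    ], ids=["plsr", "lssvm", "bpann"])
    def test_serialization_round_trip_bitwise(self, rng, tmp_path, fitter):
        X, y = _linear_problem(rng, n=30, p=10, noise=0.2)
        m = fitter(X, y)
        save_model(m, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        assert np.array_equal(predict(back, X), predict(m, X))

    def test_future_archive_version_refused(self, rng, tmp_path):
        import json

        import numpy as np
        X, y = _linear_problem(rng, n=20, p=5)
        save_model(fit_plsr(X, y, n_latent=2), tmp_path / "m.npz")
        with np.load(tmp_path / "m.npz") as a:
            arrays = {k: a[k] for k in a.files}
        header = json.loads(bytes(arrays["header"]).decode())
        header["archive_version"] = 999
        arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
        np.savez(tmp_path / "m.npz", **arrays)
        from hsitex.errors import FormatError
        with pytest.raises(FormatError):
            load_model(tmp_path / "m.npz")

    def test_predict_row_permutation_equivariant(self, rng):
        X, y = _linear_problem(rng, n=30, p=8, noise=0.2)
        m = fit_plsr(X, y, n_latent=3)
        perm = rng.permutation(30)
        np.testing.assert_allclose(predict(m, X[perm]), predict(m, X)[perm], atol=1e-12)

    def test_predict_on_training_design_reproduces_training_fit(self, rng):
        X, y = _linear_problem(rng, n=25, p=6, noise=0.1)
        m = fit_lssvm(X, y, gamma=20.0, sigma2=10.0)
        a = predict(m, X)
        b = predict(m, X)
        assert np.array_equal(a, b)

    def test_nonlinear_regime_favours_kernel_or_network(self):
        """On quadratic-driven indicators, LS-SVM or the network beats PLSR
        out of sample in most seeds."""
        from hsitex import GeneratorConfig, SplitSpec, generate_dataset, split_dataset
        from hsitex.evaluation import rmsep

        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = GeneratorConfig(n_samples=150, n_bands=100, regions=("dorsal",),
                                  noise_sd_texture=0.05, nonlinearity=1.0, seed=seed)
            spectra, table, _ = generate_dataset(cfg)
            X = spectra["dorsal"].X
            _, y = table.indicator_vector("dorsal", "springiness")
            cal, prd = split_dataset(150, SplitSpec(seed=seed))
            pls = fit_plsr(X[cal], y[cal], n_latent="cv", max_latent=8)
            svm = fit_lssvm(X[cal], y[cal], grid=tuple(np.logspace(-2, 3, 6)))
            e_pls = rmsep(y[prd], predict(pls, X[prd]))
            e_svm = rmsep(y[prd], predict(svm, X[prd]))
            if e_svm < e_pls:
                wins += 1
        assert wins / n_seeds >= 0.7
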