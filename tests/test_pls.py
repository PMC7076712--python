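"""PLS1/NIPALS calibration, prediction and latent-variable selection."""

import numpy as np
import pytest

from patvis.pls import (fit_pls1, load_model, predict, r2, rmse, save_model,
                        select_n_lv)


def four_component_system(rng, n=150, m=80, noise=1e-3):
    """y plus three spectral interferents: four latent dimensions needed."""
    lam = np.linspace(0, 1, m)
    shapes = np.vstack([
        np.exp(-0.5 * ((lam - c) / 0.08) ** 2)
        for c in (0.2, 0.4, 0.6, 0.8)
    ])
    y = rng.uniform(10, 20, n)
    factors = np.column_stack([y,
                               rng.uniform(0, 5, n),
                               rng.uniform(0, 5, n),
                               rng.uniform(0, 5, n)])
    X = factors @ shapes + rng.normal(0, noise, (n, m))
    return X, y


class TestFitPredict:
    def test_exact_rank_one_system(self, rng):
        X = np.zeros((20, 6))
        X[:, 2] = rng.uniform(5, 9, 20)
        y = 2.0 * X[:, 2]
        model = fit_pls1(X, y, n_lv=1)
        assert model.training_summary["RMSEC"] == pytest.approx(0.0, abs=1e-10)
        assert model.training_summary["R2_c"] == pytest.approx(1.0)

    def test_full_rank_matches_pseudoinverse(self, rng):
        # with n_lv = rank(X), b is the minimum-norm least-squares solution
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        model = fit_pls1(X, y, n_lv=10)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_ls = np.linalg.pinv(Xc) @ yc
        np.testing.assert_allclose(model.b, b_ls, rtol=1e-6, atol=1e-9)

    def test_matches_sklearn_oracle(self, rng):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(60, 25))
        y = X @ rng.normal(size=25) + rng.normal(0, 0.1, 60)
        for n_lv in (2, 4):
            model = fit_pls1(X, y, n_lv=n_lv)
            oracle = sklearn_pls.PLSRegression(n_components=n_lv,
                                               scale=False).fit(X, y)
            np.testing.assert_allclose(model.b, oracle.coef_.ravel(),
                                       rtol=1e-6, atol=1e-10)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(40, 15))
        y = X @ rng.normal(size=15)
        model = fit_pls1(X, y, n_lv=5)
        Xc = X - model.x_mean
        T = np.zeros((40, 5))
        Xr = Xc.copy()
        for a in range(5):
            T[:, a] = Xr @ model.weights[a]
            Xr = Xr - np.outer(T[:, a], model.x_loadings[a])
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_rmsec_non_increasing_in_lv(self, rng):
        X = rng.normal(size=(50, 20))
        y = X @ rng.normal(size=20) + rng.normal(0, 0.5, 50)
        errors = [fit_pls1(X, y, n_lv=a).training_summary["RMSEC"]
                  for a in range(1, 8)]
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_predict_training_mean_gives_y_mean(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.uniform(10, 20, 25)
        model = fit_pls1(X, y, n_lv=3)
        assert predict(model, model.x_mean)[0] == pytest.approx(model.y_mean)

    def test_predict_reproduces_fitted_values(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.uniform(10, 20, 25)
        model = fit_pls1(X, y, n_lv=4)
        fitted = predict(model, X)
        assert rmse(y, fitted) == pytest.approx(
            model.training_summary["RMSEC"])

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fit_pls1(rng.normal(size=(10, 4)), np.full(10, 3.0), n_lv=1)

    def test_grid_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 6))
        model = fit_pls1(X, rng.uniform(1, 2, 20), n_lv=2)
        with pytest.raises(ValueError, match="wavelengths"):
            predict(model, rng.normal(size=(3, 5)))

    def test_json_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(20, 6))
        y = rng.uniform(10, 20, 20)
        model = fit_pls1(X, y, n_lv=2)
        again = load_model(save_model(model, tmp_path / "m.json"))
        np.testing.assert_allclose(again.b, model.b, rtol=1e-12)
        np.testing.assert_allclose(predict(again, X), predict(model, X),
                                   rtol=1e-12)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_hand_computed_values(self):
        y_true = np.array([0.0, 1.0])
        y_pred = np.array([0.0, 0.0])
        assert rmse(y_true, y_pred) == pytest.approx(1 / np.sqrt(2))
        assert r2(y_true, y_pred) == pytest.approx(-1.0)

    def test_rmse_translation_invariant(self, rng):
        y = rng.normal(size=12)
        yhat = y + rng.normal(0, 0.3, 12)
        assert rmse(y + 5.0, yhat + 5.0) == pytest.approx(rmse(y, yhat))

    def test_zero_variance_r2_rejected(self):
        with pytest.raises(ValueError):
            r2(np.array([2.0, 2.0]), np.array([1.0, 2.0]))


class TestSelectNLv:
    def test_noiseless_rank_one_picks_one(self, rng):
        c = np.repeat(np.linspace(10, 20, 5), 10)
        eps = np.exp(-0.5 * ((np.linspace(0, 1, 40) - 0.5) / 0.1) ** 2)
        X = np.outer(c, eps)
        report = select_n_lv(X, c, max_lv=5, seed=0)
        assert report.chosen_n_lv == 1

    def test_four_effect_system_picks_four(self):
        hits = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            X, y = four_component_system(rng)
            report = select_n_lv(X, y, max_lv=8, seed=seed)
            hits += report.chosen_n_lv == 4
        assert hits >= 13  # ~90% of seeds

    def test_chosen_never_worse_than_one_lv(self, rng):
        X = rng.normal(size=(60, 12))
        y = X @ rng.normal(size=12) + rng.normal(0, 0.2, 60)
        report = select_n_lv(X, y, max_lv=6, seed=3)
        tbl = report.table.set_index("n_lv")["RMSECV"]
        assert tbl[report.chosen_n_lv] <= tbl[1] + 1e-12

    def test_max_lv_truncated_to_rank(self, rng):
        X = np.outer(rng.normal(size=30), rng.normal(size=10))
        y = X[:, 0] + rng.normal(0, 1e-3, 30)
        with pytest.warns(UserWarning, match="rank"):
            report = select_n_lv(X, y, max_lv=10, seed=0)
        assert report.table["n_lv"].max() == 1

    def test_repeated_splits_are_deterministic(self, rng):
        X = rng.normal(size=(80, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.2, 80)
        a = select_n_lv(X, y, max_lv=4, seed=7, n_repeats=5)
        b = select_n_lv(X, y, max_lv=4, seed=7, n_repeats=5)
        assert a.chosen_n_lv == b.chosen_n_lv
        np.testing.assert_array_equal(a.table["RMSECV"], b.table["RMSECV"])


class TestEndToEndRecovery:
    def test_held_out_level_predicted_within_tolerance(self, fitted_model,
                                                       cie_tables):
        """Pipeline parameter recovery on a held-out concentration."""
        from patvis.io_spectra import RunMeta
        from patvis.preprocessing import normalise_to_reference, to_absorbance
        from patvis.synth import SynthConfig, simulate_run
        model, report = fitted_model
        config = SynthConfig(seed=77)
        rng = np.random.default_rng(77)
        held_out = 15.45
        sample, _ = simulate_run(config, held_out, 40, start_conc=held_out,
                                 rng=rng, meta=RunMeta(day_id="hd"))
        poly, _ = simulate_run(config, 0.0, 40, start_conc=0.0, rng=rng,
                               meta=RunMeta(day_id="hd",
                                            is_polymer_reference=True))
        absorb = to_absorbance(normalise_to_reference(sample, poly))
        i0, i1 = absorb.grid.index_range(model.band.lo_nm, model.band.hi_nm)
        preds = predict(model, absorb.values[:, i0:i1 + 1])
        assert abs(preds.mean() - held_out) <= 0.2
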