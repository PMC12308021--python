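"""Grid-search tuning estimation and split-half cross-validation."""

import numpy as np
import pandas as pd
import pytest

from numtune.design import build_timeline
from numtune.prf import (
    GridPredictions,
    NumerosityPRF,
    ParameterGrid,
    crossval_fit,
    gaussian_loglik,
    grid_fit,
    ols_scaling,
)
from numtune.signals import RunMatrix
from numtune.synthetic import make_mesh, plant_maps, simulate_dataset, MapSpec


class TestParameterGrid:
    def test_default_size(self):
        grid = ParameterGrid()
        assert grid.mu.size == 89
        assert grid.sigma.size == 60
        assert grid.n_combinations == 5340

    def test_default_bounds(self):
        grid = ParameterGrid()
        assert grid.mu[0] == pytest.approx(0.8)
        assert grid.mu[-1] == pytest.approx(5.2)
        assert grid.sigma[0] == pytest.approx(0.05)
        assert grid.sigma[-1] == pytest.approx(3.0)

    def test_combination_ordering_breaks_ties_toward_small_sigma(self):
        mu, sig = ParameterGrid().combinations()
        assert sig[0] == sig[1]  # sigma is the slow axis
        assert mu[1] > mu[0]
        assert np.all(np.diff(sig) >= 0)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(mu=np.array([1.0, 1.0, 2.0]))

    def test_linear_grid_spans_same_fwhm_range(self):
        from numtune.tuning import FWHM_FACTOR, fwhm_from_sigma_log

        lin = ParameterGrid.linear_default()
        assert lin.linear
        omega = 2 * FWHM_FACTOR * lin.sigma
        assert omega[0] == pytest.approx(fwhm_from_sigma_log(1.0, 0.05))
        assert omega[-1] == pytest.approx(fwhm_from_sigma_log(1.0, 3.0))


class TestOlsScaling:
    def test_exact_linear_relation(self, rng):
        s = rng.normal(size=100)
        beta, beta0, rss, rss0, ll = ols_scaling(2 * s + 1, s)
        assert beta == pytest.approx(2.0)
        assert beta0 == pytest.approx(1.0)
        assert rss == pytest.approx(0.0, abs=1e-20)
        assert rss0 > 0

    def test_orthogonal_predictor(self, rng):
        s = np.tile([1.0, -1.0], 50)
        y = np.tile([1.0, 1.0, -1.0, -1.0], 25)  # zero-mean, orthogonal to s
        beta, _, rss, rss0, _ = ols_scaling(y, s)
        assert beta == pytest.approx(0.0, abs=1e-12)
        assert rss == pytest.approx(rss0)

    def test_loglik_increases_as_rss_decreases(self):
        n = 145
        rss = np.array([10.0, 5.0, 1.0, 0.1])
        ll = gaussian_loglik(rss, n)
        assert np.all(np.diff(ll) > 0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_scaling(np.arange(10.0), np.ones(10))


class TestGridFit:
    def test_noiseless_on_grid_recovery(self, grid_predictions):
        preds = grid_predictions
        i = np.flatnonzero(
            np.isclose(preds.mu_flat, 3.0) & np.isclose(preds.sigma_flat, 0.4)
        )[0]
        y = 2.0 * preds.signals[:, i] + 0.5
        fit = grid_fit(y, predictions=preds)
        assert fit.mu_hat == pytest.approx(3.0)
        assert fit.sigma_hat == pytest.approx(0.4)
        assert fit.beta_hat == pytest.approx(2.0, abs=1e-9)
        assert fit.beta0_hat == pytest.approx(0.5, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-8)

    def test_off_grid_mu_snaps_to_neighbor(self, timeline, grid_predictions):
        from numtune.forward import canonical_hrf, neuronal_timecourse, predicted_bold
        from numtune.tuning import TuningParams

        z = neuronal_timecourse(timeline, TuningParams(3.02, 0.4), span=304.5)
        y = predicted_bold(z, canonical_hrf(), 2.1, 145).values
        fit = grid_fit(y, predictions=grid_predictions)
        assert fit.mu_hat in (3.00, 3.05)

    def test_result_always_on_grid(self, grid_predictions, rng):
        grid = grid_predictions.grid
        for _ in range(5):
            y = rng.normal(size=145)
            fit = grid_fit(y, predictions=grid_predictions)
            assert np.any(np.isclose(grid.mu, fit.mu_hat))
            assert np.any(np.isclose(grid.sigma, fit.sigma_hat))

    def test_argmax_loglik_equals_argmin_rss(self, grid_predictions, rng):
        from numtune.prf import _grid_rss

        Y = rng.normal(size=(100, 145))
        rss, _, _ = _grid_rss(Y, grid_predictions)
        ll = gaussian_loglik(rss, 145)
        rows = np.arange(100)
        # the two criteria pick combinations of identical fit quality
        # (indices may differ only on floating-point near-ties)
        assert np.allclose(
            rss[rows, np.argmax(ll, axis=1)],
            rss[rows, np.argmin(rss, axis=1)],
            rtol=1e-10,
        )

    def test_matches_per_combination_ols_oracle(self, grid_predictions, rng):
        # brute-force: loop ols_scaling over a subgrid, take the best
        preds = grid_predictions
        sub = np.arange(0, preds.grid.n_combinations, 25)
        for _ in range(5):
            y = rng.normal(size=145)
            lls = np.array(
                [ols_scaling(y, preds.signals[:, j])[4] for j in sub]
            )
            oracle_j = sub[np.argmax(lls)]
            from numtune.prf import _grid_rss

            rss, _, _ = _grid_rss(y[None], preds)
            assert rss[0, oracle_j] == pytest.approx(np.min(rss[0, sub]), rel=1e-12)

    def test_all_nan_input_gives_missing_result(self, grid_predictions):
        fit = grid_fit(np.full(145, np.nan), predictions=grid_predictions)
        assert np.isnan(fit.mu_hat)


class TestCrossvalFit:
    def test_identical_noiseless_halves(self, grid_predictions):
        preds = grid_predictions
        i = np.flatnonzero(
            np.isclose(preds.mu_flat, 2.5) & np.isclose(preds.sigma_flat, 0.5)
        )[0]
        y = 1.5 * preds.signals[:, i]
        fit = crossval_fit(y, y, predictions=preds)
        assert fit.cv_r2 == pytest.approx(1.0)
        assert fit.mu_hat == pytest.approx(2.5)

    def test_pure_noise_below_threshold(self, grid_predictions, rng):
        from numtune.selection import r2_threshold

        cv = np.array(
            [
                crossval_fit(
                    rng.normal(size=145), rng.normal(size=145),
                    predictions=grid_predictions,
                ).cv_r2
                for _ in range(200)
            ]
        )
        thresh = r2_threshold(0.05, 145, 2, 100_000)
        assert np.median(cv) < thresh
        assert abs(np.median(cv)) < 0.05

    def test_cv_r2_shows_less_optimism_than_training_r2(self, grid_predictions, rng):
        preds = grid_predictions
        i = np.flatnonzero(
            np.isclose(preds.mu_flat, 3.0) & np.isclose(preds.sigma_flat, 0.5)
        )[0]
        s = preds.signals[:, i]
        sigma = s.std()  # training R^2 around 0.5
        train_r2, cv_r2 = [], []
        for _ in range(40):
            odd = s + sigma * rng.normal(size=145)
            even = s + sigma * rng.normal(size=145)
            fit = crossval_fit(odd, even, predictions=preds)
            cv_r2.append(fit.cv_r2)
            train_r2.append(fit.r2)
        assert np.mean(cv_r2) < np.mean(train_r2)

    def test_mismatched_halves_rejected(self, grid_predictions):
        with pytest.raises(ValueError):
            crossval_fit(np.zeros(145), np.zeros(100), predictions=grid_predictions)


@pytest.fixture(scope="module")
def fitted():
    mesh = make_mesh(8, 8, spacing=2.0)
    spec = MapSpec(name="NPO", box=(0.0, 14.0, 0.0, 14.0), mu_range=(1.0, 5.0))
    truth = plant_maps(mesh, [spec], seed=0)
    timeline = build_timeline()
    runs, confs = simulate_dataset(truth, timeline, seed=0)
    model = NumerosityPRF(runs, timeline, confounds=confs)
    return truth, model.fit()


class TestNumerosityPRFModel:
    def test_frame_schema(self, fitted):
        _, res = fitted
        expected = {"vertex_id", "mu", "sigma", "fwhm", "beta", "beta0",
                    "log_likelihood", "rss", "rss0", "cv_r2"}
        assert expected <= set(res.frame.columns)
        assert len(res.frame) == 64

    def test_estimates_correlate_with_truth(self, fitted):
        truth, res = fitted
        sel = truth.selective
        r = np.corrcoef(truth.mu[sel], res.frame["mu"].to_numpy()[sel])[0, 1]
        assert r > 0.9

    def test_summary_mentions_counts(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "5340" in text
        assert "cvR2" in text

    def test_to_tsv_round_trip(self, fitted, tmp_path):
        _, res = fitted
        path = tmp_path / "fits.tsv"
        res.to_tsv(path, hemi="L")
        back = pd.read_csv(path, sep="\t")
        assert np.allclose(back["mu"], res.frame["mu"])
        assert set(back["hemi"]) == {"L"}

    def test_run_shape_mismatch_rejected(self, timeline):
        with pytest.raises(ValueError):
            NumerosityPRF(
                [RunMatrix(np.zeros((2, 145))), RunMatrix(np.zeros((3, 145)))],
                timeline,
            )

    def test_masked_vertex_propagates_nan(self, timeline, rng):
        y = rng.normal(size=(2, 145)) + 100.0
        y[0] = 0.0  # zero-mean vertex cannot be standardized
        runs = [RunMatrix(y + rng.normal(size=y.shape)) for _ in range(2)]
        runs[0].values[0] = 0.0
        with pytest.warns(UserWarning):
            res = NumerosityPRF(runs, timeline).fit()
        assert np.isnan(res.frame.loc[0, "mu"])
        assert np.isfinite(res.frame.loc[1, "mu"])
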