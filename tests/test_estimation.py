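"""Synthetic progress curves, bi-exponential fitting, rate recovery."""

import numpy as np
import pytest

from pfokinetics import (
    IdentifiabilityError,
    ProgressCurveModel,
    ReactionParameters,
    build_matrices,
    eigenstructure,
    fit_biexponential,
    generate_synthetic,
    linear_time_grid,
    recover_rate_constants,
)
from conftest import draw_params


class TestGenerateSynthetic:
    def test_noiseless_equals_model(self, all_ones):
        p = all_ones()
        ds = generate_synthetic(p, observable="c", noise_sd=0.0)
        lin = ds.clean
        np.testing.assert_array_equal(ds.y, lin.c)

    def test_seed_reproducibility(self, all_ones):
        a = generate_synthetic(all_ones(), observable="s", noise_sd=0.01, seed=3)
        b = generate_synthetic(all_ones(), observable="s", noise_sd=0.01, seed=3)
        np.testing.assert_array_equal(a.y, b.y)
        c = generate_synthetic(all_ones(), observable="s", noise_sd=0.01, seed=4)
        assert not np.array_equal(a.y, c.y)

    def test_unknown_observable_rejected(self, all_ones):
        with pytest.raises(ValueError, match="observable"):
            generate_synthetic(all_ones(), observable="p")

    def test_noise_sd_calibrated(self, all_ones):
        """Pooled noise across seeds matches the requested sd (chi-squared
        bounds at ~99.9% for the pooled sample size)."""
        p = all_ones()
        t = linear_time_grid(p, n_points=200)
        draws = []
        for seed in range(20):
            ds = generate_synthetic(p, t, "c", noise_sd=0.001, seed=seed)
            draws.append(ds.y - ds.clean.c)
        sd = np.std(np.concatenate(draws))
        assert 0.00095 < sd < 0.00105

    def test_truncation_flag(self, all_ones):
        p = all_ones(s0=0.01)
        ds = generate_synthetic(p, observable="c", noise_sd=0.01, seed=0,
                                truncate_at_zero=True)
        assert np.all(ds.y >= 0.0)
        raw = generate_synthetic(p, observable="c", noise_sd=0.01, seed=0)
        assert np.any(raw.y < 0.0)

    def test_full_model_channel(self, all_ones):
        ds = generate_synthetic(all_ones(s0=0.4), observable="total",
                                model="full")
        assert ds.y[0] == pytest.approx(0.4)
        assert np.all(np.diff(ds.y) <= 1e-9)


class TestFitBiexponential:
    def test_noiseless_complex_exact(self, all_ones):
        """c(t) from the all-ones linearization is exactly representable:
        rates (-3 +/- sqrt 5)/2, amplitude s0/sqrt(5)."""
        p = all_ones(s0=0.1)
        ds = generate_synthetic(p, observable="c")
        fit = fit_biexponential(ds.t, ds.y, "c", s0=0.1, e0=1.0)
        assert fit.converged
        assert fit.lambda_slow_hat == pytest.approx((-3 + np.sqrt(5)) / 2,
                                                    abs=1e-9)
        assert fit.lambda_fast_hat == pytest.approx((-3 - np.sqrt(5)) / 2,
                                                    abs=1e-9)
        assert fit.amplitudes[0] == pytest.approx(0.1 / np.sqrt(5), abs=1e-10)
        assert fit.residual_rms < 1e-9

    def test_noiseless_substrate_amplitudes(self, all_ones):
        """s(t) amplitudes match the closed-form coefficients
        s0*(-alpha+gamma+/-sqrt(Delta))/(2*sqrt(Delta))."""
        p = all_ones(s0=0.1)
        ds = generate_synthetic(p, observable="s")
        fit = fit_biexponential(ds.t, ds.y, "s", s0=0.1, e0=1.0)
        M = build_matrices(p)["linear"]
        sq = np.sqrt(eigenstructure(M).Delta)
        a, g = M.alpha, M.gamma
        expected = 0.1 / (2 * sq) * np.array([-a + g + sq, a - g + sq])
        np.testing.assert_allclose(fit.amplitudes, expected, atol=1e-6)

    def test_degenerate_input_rejected(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(ValueError, match="degenerate"):
            fit_biexponential(t, np.zeros_like(t), "c", 0.1, 1.0)
        with pytest.raises(ValueError, match="8 samples"):
            fit_biexponential(t[:5], np.exp(-t[:5]), "c", 0.1, 1.0)

    def test_total_and_product_fit_same_rates(self, all_ones):
        p = all_ones(s0=0.1)
        rates = {}
        for obs in ("total", "product"):
            ds = generate_synthetic(p, observable=obs)
            fit = fit_biexponential(ds.t, ds.y, obs, s0=0.1, e0=1.0)
            assert fit.converged and fit.residual_rms < 1e-9
            rates[obs] = (fit.lambda_slow_hat, fit.lambda_fast_hat)
        np.testing.assert_allclose(rates["total"], rates["product"], rtol=1e-7)


class TestRecovery:
    def test_all_ones_exact(self, all_ones):
        ds = generate_synthetic(all_ones(s0=0.1), observable="c")
        fit = fit_biexponential(ds.t, ds.y, "c", s0=0.1, e0=1.0)
        k1, km1, k2 = recover_rate_constants(fit, 0.1, 1.0)
        assert k1 == pytest.approx(1.0, rel=1e-6)
        assert km1 == pytest.approx(1.0, rel=1e-6)
        assert k2 == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("observable", ["s", "c"])
    def test_roundtrip_random_parameters(self, observable):
        """generate (linear, noiseless) -> fit -> recover reproduces the
        truth to 1e-6 relative, for both identifiable observables."""
        rng = np.random.default_rng(101)
        done = 0
        while done < 15:
            p = draw_params(rng, s0_fraction=0.3)
            eta = 4 * (p.k2 / p.k1) * p.e0 / ((p.k_minus1 + p.k2) / p.k1 + p.e0) ** 2
            if eta > 0.8:
                continue
            ds = generate_synthetic(p, observable=observable)
            fit = fit_biexponential(ds.t, ds.y, observable, p.s0, p.e0)
            k1, km1, k2 = recover_rate_constants(fit, p.s0, p.e0)
            assert k1 == pytest.approx(p.k1, rel=1e-6)
            assert km1 == pytest.approx(p.k_minus1, rel=1e-6)
            assert k2 == pytest.approx(p.k2, rel=1e-6)
            done += 1

    def test_total_observable_not_identifiable(self, all_ones):
        ds = generate_synthetic(all_ones(s0=0.1), observable="total")
        fit = fit_biexponential(ds.t, ds.y, "total", 0.1, 1.0)
        with pytest.raises(IdentifiabilityError, match="k1"):
            recover_rate_constants(fit, 0.1, 1.0)

    def test_error_shrinks_with_noise(self, all_ones):
        """Median relative recovery error decreases across noise levels."""
        p = all_ones(s0=0.1)
        t = linear_time_grid(p, n_points=200)
        medians = []
        for noise in (0.004, 0.001, 0.00025):
            errs = []
            for seed in range(15):
                ds = generate_synthetic(p, t, "c", noise_sd=noise, seed=seed)
                fit = fit_biexponential(ds.t, ds.y, "c", 0.1, 1.0)
                try:
                    ks = recover_rate_constants(fit, 0.1, 1.0)
                except ValueError:
                    errs.append(np.inf)
                    continue
                errs.append(max(abs(np.array(ks) - 1.0)))
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]

    def test_misspecification_bias_shrinks_with_s0(self, all_ones):
        """Fitting the linear closed form to data from the full nonlinear
        model gives a bias that decreases as s0/K decreases."""
        biases = []
        for s0 in (0.5, 0.125, 0.03125):  # K/2, K/8, K/32
            ds = generate_synthetic(all_ones(s0=s0), observable="c",
                                    model="full")
            fit = fit_biexponential(ds.t, ds.y, "c", s0, 1.0)
            ks = np.array(recover_rate_constants(fit, s0, 1.0))
            biases.append(np.max(np.abs(ks - 1.0)))
        assert biases[0] > biases[1] > biases[2]


class TestModelResults:
    def test_from_dataframe_and_summary(self, all_ones):
        ds = generate_synthetic(all_ones(s0=0.1), observable="c",
                                noise_sd=0.001, seed=1)
        model = ProgressCurveModel.from_dataframe(ds.to_dataframe(), "c",
                                                  s0=0.1, e0=1.0)
        res = model.fit()
        assert res.converged
        assert res.params["k1"] == pytest.approx(1.0, rel=0.05)
        assert res.params["k2"] == pytest.approx(1.0, rel=0.05)
        assert res.params["k_minus1"] == pytest.approx(1.0, rel=0.15)
        assert np.all(res.bse[["k1", "k_minus1", "k2"]] > 0)
        assert len(res.resid) == res.nobs
        text = res.summary()
        for token in ("k1", "k_minus1", "k2", "lambda_slow", "Converged"):
            assert token in text

    def test_bse_tracks_noise_scale(self, all_ones):
        """Standard errors are on the scale of the actual seed-to-seed
        scatter (within a factor of ~3)."""
        p = all_ones(s0=0.1)
        t = linear_time_grid(p, n_points=200)
        k1_hats, bses = [], []
        for seed in range(12):
            ds = generate_synthetic(p, t, "c", noise_sd=0.001, seed=seed)
            res = ProgressCurveModel(ds.t, ds.y, "c", 0.1, 1.0).fit()
            k1_hats.append(res.params["k1"])
            bses.append(res.bse["k1"])
        empirical = np.std(k1_hats, ddof=1)
        assert np.median(bses) == pytest.approx(empirical, rel=2.0)
        assert empirical / 3 < np.median(bses) < empirical * 3

    def test_predict_and_fittedvalues(self, all_ones):
        ds = generate_synthetic(all_ones(s0=0.1), observable="s")
        model = ProgressCurveModel(ds.t, ds.y, "s", 0.1, 1.0)
        res = model.fit()
        np.testing.assert_allclose(res.fittedvalues, ds.y, atol=1e-8)
        half = model.predict(res.fit_result, t=ds.t[:10])
        np.testing.assert_allclose(half, ds.y[:10], atol=1e-8)

    def test_unidentifiable_observable_reports_nan_params(self, all_ones):
        ds = generate_synthetic(all_ones(s0=0.1), observable="total")
        res = ProgressCurveModel(ds.t, ds.y, "total", 0.1, 1.0).fit()
        assert res.converged
        assert np.isnan(res.params).all()
        assert res.rates["lambda_slow"] == pytest.approx(
            (-3 + np.sqrt(5)) / 2, abs=1e-8)
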