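"""Whiteness screening, residual spectra, and stability diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.diagnostic import acorr_ljungbox

from fastwhiten.basis import build_ar1_plus_white, build_fast_components
from fastwhiten.design import assemble_design
from fastwhiten.diagnostics import (
    benjamini_hochberg,
    ljung_box_q,
    precision_stability,
    residual_power_spectrum,
    whiteness_screen,
)
from fastwhiten.glm import fit_glm, whitening_matrix
from fastwhiten.simulate import (
    SimulationConfig,
    sample_noise_with_covariance,
    simulate_block_series,
)


class TestLjungBox:
    def test_zero_autocorrelation_gives_zero_q(self):
        # lag-1 sample autocorrelation of this pattern is exactly zero
        x = np.tile([1.0, 0.0, -1.0, 0.0], 25)
        Q, p = ljung_box_q(x, 1)
        assert Q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_alternating_series_hand_value(self):
        x = np.tile([1.0, -1.0], 50)
        Q, p = ljung_box_q(x, 1)
        # rho_1 = -0.99 for +-1 alternation of length 100; Q ~ 101
        m = 100
        rho1 = -0.99
        expected = m * (m + 2) * rho1**2 / (m - 1)
        assert Q == pytest.approx(expected, rel=1e-10)
        assert p < 1e-12

    @pytest.mark.parametrize("lag", [1, 5, 20])
    def test_matches_statsmodels(self, rng, lag):
        x = rng.standard_normal(120)
        Q, p = ljung_box_q(x, lag)
        ref = acorr_ljungbox(x - x.mean(), lags=[lag])
        assert Q == pytest.approx(float(ref["lb_stat"].iloc[0]), rel=1e-10)
        assert p == pytest.approx(float(ref["lb_pvalue"].iloc[0]), rel=1e-8)

    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            _, p = ljung_box_q(rng.standard_normal(100), 20)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.08

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            ljung_box_q(np.ones(50), 5)

    def test_lag_bounds(self, rng):
        with pytest.raises(ValueError):
            ljung_box_q(rng.standard_normal(10), 10)


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        mask = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.5]), 0.05)
        np.testing.assert_array_equal(mask, [True, True, True, False])

    def test_all_ones_none_rejected(self):
        assert not benjamini_hochberg(np.ones(10), 0.05).any()

    def test_single_small_p_rejected(self):
        assert benjamini_hochberg(np.array([0.04]), 0.05)[0]

    def test_empty_input(self):
        assert benjamini_hochberg(np.array([])).size == 0

    @settings(deadline=None, max_examples=30)
    @given(
        pvals=st.lists(st.floats(0, 1), min_size=1, max_size=40),
        q1=st.floats(0.01, 0.2),
        q2=st.floats(0.01, 0.2),
    )
    def test_monotone_in_q(self, pvals, q1, q2):
        lo, hi = sorted([q1, q2])
        p = np.array(pvals)
        r_lo = benjamini_hochberg(p, lo)
        r_hi = benjamini_hochberg(p, hi)
        assert np.all(r_hi[r_lo])  # rejections at lo are a subset

    def test_null_false_rejection_control(self):
        rng = np.random.default_rng(17)
        rates = []
        for _ in range(200):
            p = rng.uniform(size=100)
            rates.append(benjamini_hochberg(p, 0.05).mean())
        assert np.mean(rates) <= 0.05 + 0.02


class TestWhitenessScreen:
    n, v = 300, 300

    def _ar_noise(self, seed=0):
        basis = build_ar1_plus_white(self.n, 0.4)
        return basis, sample_noise_with_covariance(
            basis, [0.0, 1.0], self.v, seed
        )

    def test_white_residuals_controlled(self):
        rng = np.random.default_rng(1)
        rep = whiteness_screen(rng.standard_normal((self.n, self.v)))
        assert rep.proportion_rejected <= 0.08

    def test_unwhitened_ar_noise_detected(self, intercept_design):
        basis, Y = self._ar_noise()
        fit = fit_glm(Y, intercept_design(self.n))
        rep = whiteness_screen(fit.residuals)
        assert rep.proportion_rejected >= 0.5

    def test_true_whitening_restores_whiteness(self, intercept_design):
        basis, Y = self._ar_noise()
        W = whitening_matrix(basis.components[1].matrix)
        fit = fit_glm(Y, intercept_design(self.n), W)
        rep = whiteness_screen(fit.residuals)
        assert rep.proportion_rejected <= 0.10

    def test_model_ordering(self, intercept_design):
        # rejection proportion: none >= AR(1)+white >= generating FAST model
        from fastwhiten.reml import pooled_sample_covariance, reml_fit

        n = self.n
        fb = build_fast_components(n, 3)
        lam = np.zeros(9)
        lam[[0, 3, 6]] = [0.2, 0.5, 0.6]
        Y = sample_noise_with_covariance(fb, lam, self.v, 23)
        X = intercept_design(n)
        props = {}
        props["none"] = whiteness_screen(
            fit_glm(Y, X).residuals
        ).proportion_rejected
        S = pooled_sample_covariance(Y)
        for label, basis in (("ar1", build_ar1_plus_white(n)), ("fast", fb)):
            res = reml_fit(S, basis, X)
            fit = fit_glm(Y, X, whitening_matrix(res.V))
            props[label] = whiteness_screen(fit.residuals).proportion_rejected
        assert props["none"] >= props["ar1"] >= props["fast"]
        assert props["none"] > 0.2  # the screen has power under no model

    def test_constant_voxels_excluded(self, rng):
        R = rng.standard_normal((150, 5))
        R[:, 2] = 1.0
        rep = whiteness_screen(R, n_points=100, max_lag=10)
        assert rep.n_excluded == 1
        assert not rep.rejected[2]

    def test_requires_enough_points(self, rng):
        with pytest.raises(ValueError):
            whiteness_screen(rng.standard_normal((50, 3)), n_points=100)


class TestResidualSpectrum:
    def test_white_noise_flat(self):
        rng = np.random.default_rng(6)
        R = rng.standard_normal((512, 2000))
        freqs, power = residual_power_spectrum(R, tr=1.0)
        bins = np.array_split(power[1:], 20)
        means = np.array([b.mean() for b in bins])
        assert means.max() / means.min() < 3

    def test_sinusoid_peak_located(self):
        tr = 0.35
        n = 512
        t = np.arange(n) * tr
        rng = np.random.default_rng(9)
        R = 0.3 * rng.standard_normal((n, 50)) + 2.0 * np.sin(
            2 * np.pi * 0.3 * t
        )[:, None]
        freqs, power = residual_power_spectrum(R, tr=tr)
        assert abs(freqs[np.argmax(power)] - 0.3) <= freqs[1] - freqs[0]

    def test_ar_noise_decreasing_trend(self):
        n = 512
        basis = build_ar1_plus_white(n, 0.4)
        R = sample_noise_with_covariance(basis, [0.0, 1.0], 500, 4)
        freqs, power = residual_power_spectrum(R, tr=1.0)
        bins = np.array_split(power, 8)
        means = np.array([b.mean() for b in bins])
        assert np.all(np.diff(means) < 0)

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            residual_power_spectrum(np.zeros((4, 2)), tr=1.0)


class TestPrecisionStability:
    def test_generating_model_is_stable(self):
        cfg = SimulationConfig(
            n_voxels=40, n_samples=400, n_blocks=6, seed=5
        )
        s = simulate_block_series(cfg)
        res = precision_stability(
            s.Y, s.design(), lambda m: build_ar1_plus_white(m), n_total=400
        )
        assert res.r_squared >= 0.95
        assert res.sample_grid.size == 5
        assert np.all(np.diff(res.sample_grid) > 0)

    def test_white_noise_matches_theoretical_line(self):
        # identity whitening on unit white noise: precision ~ sqrt(n)/sigma
        rng = np.random.default_rng(12)
        n = 400
        Y = 50 + rng.standard_normal((n, 60))
        X = assemble_design(None, n, 1.0)
        res = precision_stability(
            Y, X, lambda m: build_ar1_plus_white(m), n_total=n
        )
        theory = np.sqrt(res.sample_grid)
        np.testing.assert_allclose(res.precision, theory, rtol=0.1)
        assert res.r_squared >= 0.98

    def test_overparameterised_basis_flagged(self):
        cfg = SimulationConfig(
            n_voxels=30, n_samples=256, n_blocks=4, seed=6
        )
        s = simulate_block_series(cfg)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            res = precision_stability(
                s.Y,
                s.design(),
                lambda m: build_fast_components(m, 9),
                n_total=256,
            )
        assert 0.0 <= res.r_squared <= 1.0

    def test_grid_needs_room(self, rng, intercept_design):
        with pytest.raises(ValueError):
            precision_stability(
                rng.standard_normal((110, 5)),
                intercept_design(110),
                lambda m: build_ar1_plus_white(m),
            )
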