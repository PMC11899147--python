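"""Attenuation estimators: confocal PSF, noise floor, tail fit, DR/ODRE."""

import numpy as np
import pytest

from oacd.attenuation import (
    ConfocalParams,
    confocal_correct,
    confocal_psf,
    estimate_noise_floor,
    fit_tail,
    oac_bscan,
    oac_dr,
    oac_odre,
)
from oacd.phantom import PhantomSpec, make_phantom


class TestConfocal:
    def test_focus_plane_unchanged(self):
        p = ConfocalParams(zcf=0.5, zR=0.2)
        assert confocal_psf(0.5, p) == 1.0

    def test_one_rayleigh_length_doubles(self):
        p = ConfocalParams(zcf=0.5, zR=0.2)
        out = confocal_correct(np.array([100.0]), p, z_axis=np.array([0.7]))
        assert out[0] == pytest.approx(200.0)

    def test_rayleigh_from_beam_parameters(self):
        # diffuse reflection, n=1, w0=10 um, lambda=1310 nm -> zR ~ 0.48 mm
        p = ConfocalParams.from_beam(w0=0.01, wavelength=0.00131, zcf=0.0)
        assert p.zR == pytest.approx(2 * np.pi * 1e-4 / 0.00131, rel=1e-12)

    def test_nonpositive_rayleigh_rejected(self):
        with pytest.raises(ValueError):
            ConfocalParams(zcf=0.0, zR=0.0)


class TestNoiseFloor:
    def test_five_db_rule(self):
        """Floor of 100 puts the boundary at the last sample >= 316.2."""
        nz = 100
        aline = np.full(nz, 100.0)
        aline[:40] = 10000.0
        aline[40:60] = np.linspace(5000, 320, 20)
        bscan = np.tile(aline[:, None], (1, 8))
        res = estimate_noise_floor(bscan, avg_width=8, tail_fraction=0.1)
        assert res.floor_level[0] == pytest.approx(100.0)
        threshold = 100 * 10 ** 0.5
        expected = np.nonzero(aline >= threshold)[0][-1]
        assert res.boundary_index[0] == expected

    def test_zero_floor_keeps_every_signal_sample(self):
        """With a floor of exactly zero nothing is trimmed: the boundary is
        the deepest sample that carries signal."""
        aline = np.zeros(80)
        aline[:72] = 10.0 * np.exp(-0.05 * np.arange(72))
        res = estimate_noise_floor(aline[:, None], avg_width=1)
        assert res.floor_level[0] == 0.0
        assert res.boundary_index[0] == 71

    def test_all_floor_aline_flagged_absent(self):
        res = estimate_noise_floor(np.full((50, 4), 7.0), avg_width=4)
        assert np.all(res.boundary_index == -1)

    def test_all_zero_aline_flagged_absent(self):
        res = estimate_noise_floor(np.zeros((50, 4)), avg_width=4)
        assert np.all(res.boundary_index == -1)


class TestTailFit:
    def test_noiseless_recovery_to_high_precision(self):
        z = np.linspace(0.0, 0.5, 50)
        y = 5.0 * np.exp(-2.0 * 3.0 * z) + 0.1
        tf = fit_tail(y, z)
        assert tf.converged
        assert tf.a == pytest.approx(5.0, rel=1e-6)
        assert tf.mu_N == pytest.approx(3.0, rel=1e-6)
        assert tf.b == pytest.approx(0.1, rel=1e-6)

    def test_constant_signal_does_not_converge(self):
        tf = fit_tail(np.full(40, 2.0), np.linspace(0, 1, 40))
        assert not tf.converged

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(42)
        z = np.linspace(0.0, 1.0, 200)
        y = (4.0 * np.exp(-2.0 * 2.5 * z) + 0.05) * (1 + 0.01 * rng.standard_normal(200))
        tf = fit_tail(y, z)
        assert tf.converged
        assert tf.mu_N == pytest.approx(2.5, rel=0.05)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            fit_tail(np.ones(20), np.linspace(0, 1, 20), window=(0, 5))


class TestEstimators:
    def test_dr_four_pixel_example(self):
        mu = oac_dr(np.array([8.0, 4.0, 2.0, 1.0]), delta=0.01)
        assert mu[0, 0] == pytest.approx(8 / (2 * 0.01 * 7))

    def test_dr_all_equal_signal(self):
        n, c, delta = 16, 3.0, 0.01
        mu = oac_dr(np.full(n, c), delta)
        assert mu[0, 0] == pytest.approx(1 / (2 * delta * (n - 1)))

    def test_dr_geometric_series_closed_form(self):
        """On an infinite exponential with 2*mu*delta=0.02 the estimator is
        (e^{2 mu delta}-1)/(2 delta), slightly above the true mu."""
        mu_true, delta = 2.0, 0.005
        z = np.arange(4096)
        I = np.exp(-2 * mu_true * delta * z)
        est = oac_dr(I, delta)[:200, 0]
        closed = (np.exp(2 * mu_true * delta) - 1) / (2 * delta)
        assert np.allclose(est, closed, rtol=1e-12)

    def test_odre_four_pixel_example(self):
        mu = oac_odre(np.array([8.0, 4.0, 2.0, 1.0]), delta=0.01, mu_N=50.0)
        assert mu[0, 0] == pytest.approx(50.0)

    def test_odre_with_zero_tail_intensity_reduces_to_dr(self):
        I = np.array([8.0, 4.0, 2.0, 0.0])
        assert np.allclose(oac_odre(I, 0.01, mu_N=50.0)[:3],
                           oac_dr(I, 0.01)[:3])

    def test_odre_true_tail_recovers_mu_within_two_percent(self):
        mu_true, delta = 2.0, 0.005
        I = np.exp(-2 * mu_true * delta * np.arange(300))
        est = oac_odre(I, delta, mu_N=mu_true)[:, 0]
        assert np.all(np.abs(est / mu_true - 1) < 0.02)

    def test_odre_deep_bias_smaller_than_dr(self):
        """Truncation at finite N biases DR upward at depth; the tail term
        removes most of it (homogeneous noiseless slab)."""
        mu_true, delta, n = 3.0, 0.0075, 200
        I = np.exp(-2 * mu_true * delta * np.arange(n))
        dr = oac_dr(I, delta)[:, 0]
        z_axis = np.arange(n) * delta
        tf = fit_tail(I, z_axis, window=(n - 40, n - 1))
        odre = oac_odre(I, delta, mu_N=tf.mu_N)[:, 0]
        deep = slice(3 * n // 4, n - 1)
        bias_dr = np.abs(dr[deep] - mu_true).mean()
        bias_odre = np.abs(odre[deep] - mu_true).mean()
        assert bias_odre < bias_dr

    def test_scale_invariance_below_a_depth_is_exact(self):
        """Multiplying I[i] for all i >= z0 by a constant leaves mu[z0:]
        unchanged bit for bit — the core of tail suppression."""
        rng = np.random.default_rng(3)
        I = np.exp(-0.02 * np.arange(150)) * (1 + 0.2 * rng.random(150))
        z0 = 60
        for est in (lambda x: oac_dr(x, 0.0075),
                    lambda x: oac_odre(x, 0.0075, mu_N=2.0)):
            # power-of-two factor: scaling commutes with IEEE addition and
            # division, so the cancellation is bit-exact
            I_scaled = I.copy()
            I_scaled[z0:] *= 4.0
            assert np.array_equal(est(I)[z0:, 0], est(I_scaled)[z0:, 0])
            # arbitrary factor: cancellation to machine precision
            I_scaled = I.copy()
            I_scaled[z0:] *= 3.7
            assert np.allclose(est(I)[z0:, 0], est(I_scaled)[z0:, 0], rtol=1e-12)

    def test_mu_nonnegative_and_finite_on_noisy_input(self):
        rng = np.random.default_rng(4)
        bscan = np.abs(rng.standard_normal((120, 32))) * np.exp(
            -0.03 * np.arange(120))[:, None]
        mu = oac_bscan(bscan, 0.0075, method="odre")
        assert np.all(np.isfinite(mu)) and np.all(mu >= 0)


def test_confocal_correction_improves_recovery():
    """With a strong confocal gate, correcting h(z) before estimation brings
    the recovered attenuation closer to truth than skipping the correction."""
    params = ConfocalParams(zcf=0.3, zR=0.15)
    spec = PhantomSpec(grid=(2, 160, 16, 2), pixel_size_axial=0.0075, tissue_mu=2.0,
                       surface_depth=10, speckle_sd=0.0, noise_floor_level=0.0,
                       confocal=params, seed=5)
    vol, truth = make_phantom(spec)
    bscan = vol.data[0, :, :, 0]
    z = np.arange(160) * 0.0075
    corrected = confocal_correct(bscan, params, z_axis=z)
    mid = slice(30, 120)
    err_corr = np.abs(oac_odre(corrected, 0.0075, mu_N=2.0)[mid] - 2.0).mean()
    err_raw = np.abs(oac_odre(bscan, 0.0075, mu_N=2.0)[mid] - 2.0).mean()
    assert err_corr < err_raw
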