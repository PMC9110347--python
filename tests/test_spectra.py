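"""Pigment templates, Fourier filtering, λ_max/bandwidth, mixture fitting."""
import numpy as np
import pytest

from conemosaic import (
    Spectrum,
    SpectrumSpec,
    estimate_lambda_max,
    fit_mixture,
    fourier_filter,
    gen_spectrum,
    half_max_bandwidth_wavenumber,
    mixture_response,
    template_absorbance,
)

GRID = np.arange(350.0, 751.0, 2.0)
FINE = np.arange(330.0, 781.0, 1.0)


class TestTemplate:
    def test_unit_peak_at_lambda_max(self):
        t = template_absorbance(491.0, FINE)
        idx = int(np.flatnonzero(t.wavelengths == 491.0)[0])
        assert t.values[idx] == pytest.approx(1.0, abs=1e-9)
        assert t.values.max() == pytest.approx(1.0, abs=1e-6)

    def test_red_shifted_template_absorbs_more_at_long_wavelengths(self):
        t550 = template_absorbance(550.0, FINE)
        t431 = template_absorbance(431.0, FINE)
        idx = int(np.flatnonzero(FINE == 650.0)[0])
        assert t550.values[idx] > t431.values[idx]

    def test_beta_band_present_in_short_wavelengths(self):
        t = template_absorbance(550.0, FINE)
        short = t.values[(FINE >= 330) & (FINE <= 420)]
        assert short.max() > 0.2  # β-band shoulder

    @pytest.mark.parametrize("bad", [300.0, 700.0])
    def test_lambda_max_outside_validity_rejected(self, bad):
        with pytest.raises(ValueError):
            template_absorbance(bad, FINE)


class TestBandwidth:
    def test_gaussian_in_wavenumber_closed_form(self):
        sigma = 1800.0  # cm^-1
        nu0 = 2e7 / 1000  # centred at 500 nm
        lam = np.arange(380.0, 701.0, 1.0)
        nu = 1e7 / lam
        y = np.exp(-((nu - 1e7 / 500.0) ** 2) / (2 * sigma**2))
        bw = half_max_bandwidth_wavenumber(Spectrum(lam, y))
        assert bw == pytest.approx(2 * sigma * np.sqrt(2 * np.log(2)),
                                   rel=1e-3)

    def test_rod_template_bandwidth_matches_a1_chromophore(self):
        t = template_absorbance(491.0, FINE)
        assert half_max_bandwidth_wavenumber(t) == pytest.approx(4170, abs=234)

    def test_truncated_red_flank_raises(self):
        t = template_absorbance(491.0, np.arange(350.0, 501.0, 2.0))
        with pytest.raises(ValueError, match="red"):
            half_max_bandwidth_wavenumber(t)

    def test_truncated_blue_flank_raises(self):
        t = template_absorbance(431.0, np.arange(420.0, 751.0, 2.0))
        with pytest.raises(ValueError, match="blue"):
            half_max_bandwidth_wavenumber(t)


class TestFourierFilter:
    def test_constant_spectrum_unchanged(self):
        s = Spectrum(GRID, np.full(GRID.size, 0.42))
        out = fourier_filter(s, 40.0)
        np.testing.assert_allclose(out.absorbance, 0.42, atol=1e-12)

    def test_high_frequency_sinusoid_removed(self):
        # period 6 nm on a 2 nm grid spanning 402 nm: exactly representable
        y = np.sin(2 * np.pi * GRID / 6.0)
        out = fourier_filter(Spectrum(GRID, y), 40.0)
        assert np.max(np.abs(out.absorbance)) < 1e-10

    def test_noise_suppression_on_template(self):
        clean = template_absorbance(500.0, GRID).values
        rng = np.random.default_rng(7)
        noisy = Spectrum(GRID, clean + rng.normal(0, 0.05, GRID.size))
        out = fourier_filter(noisy, 40.0)
        rms_before = np.sqrt(np.mean((noisy.absorbance - clean) ** 2))
        rms_after = np.sqrt(np.mean((out.absorbance - clean) ** 2))
        # periodic filtering keeps a Gibbs-ringing floor from the spectrum's
        # unequal endpoints, so the attainable reduction is just under half
        assert rms_after <= 0.6 * rms_before

    def test_mean_preserved(self):
        rng = np.random.default_rng(3)
        s = Spectrum(GRID, rng.uniform(0, 1, GRID.size))
        out = fourier_filter(s, 40.0)
        assert out.absorbance.mean() == pytest.approx(s.absorbance.mean(),
                                                      abs=1e-12)

    def test_non_uniform_grid_rejected(self):
        lam = np.concatenate([GRID[:50], GRID[50:] + 0.5])
        with pytest.raises(ValueError):
            fourier_filter(Spectrum(lam, np.ones(lam.size)), 40.0)

    def test_cutoff_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fourier_filter(Spectrum(GRID, np.ones(GRID.size)), 3.0)


class TestLambdaMax:
    def test_noiseless_self_recovery(self):
        s = gen_spectrum(SpectrumSpec((514.0,), (1.0,), p=2.0))
        est = estimate_lambda_max(s)
        assert est.lambda_max_nm == pytest.approx(514.0, abs=0.5)

    def test_noisy_recovery_mean_absolute_error(self):
        """λ_max recovery across the seven measured pigments under noise
        stays well inside the few-nm inter-cell spread of real records."""
        errors = []
        for lmax in (431, 457, 491, 500, 514, 527, 550):
            for seed in range(8):
                s = gen_spectrum(SpectrumSpec((float(lmax),), (1.0,), p=2.0,
                                              noise_sd=0.02, seed=seed))
                est = estimate_lambda_max(s)
                errors.append(abs(est.lambda_max_nm - lmax))
        assert np.mean(errors) <= 3.0

    def test_flat_spectrum_rejected(self):
        with pytest.raises(ValueError):
            estimate_lambda_max(Spectrum(GRID, np.zeros(GRID.size)))


class TestMixtureResponse:
    def test_single_pigment_identity_for_any_exponent(self):
        t = template_absorbance(500.0, GRID).values
        for p in (1.0, 2.0, 5.523):
            r = mixture_response([1.0], p, [500.0], GRID)
            np.testing.assert_allclose(r.absorbance, t, atol=1e-12)

    def test_p_one_reduces_to_weighted_sum(self):
        a1 = template_absorbance(431.0, GRID).values
        a2 = template_absorbance(500.0, GRID).values
        r = mixture_response([0.7, 0.3], 1.0, [431.0, 500.0], GRID)
        np.testing.assert_allclose(r.absorbance, 0.7 * a1 + 0.3 * a2,
                                   atol=1e-12)

    def test_permutation_symmetry(self):
        r1 = mixture_response([1.398, 0.061], 5.523, [431.0, 500.0], GRID)
        r2 = mixture_response([0.061, 1.398], 5.523, [500.0, 431.0], GRID)
        np.testing.assert_allclose(r1.absorbance, r2.absorbance, atol=1e-12)

    def test_pointwise_nondecreasing_in_each_k(self):
        lo = mixture_response([1.0, 0.05], 3.0, [431.0, 500.0], GRID)
        hi = mixture_response([1.0, 0.10], 3.0, [431.0, 500.0], GRID)
        assert np.all(hi.absorbance >= lo.absorbance - 1e-15)

    def test_coexpression_hump_relative_to_pure_pigment(self):
        """The measured S(431) curve's secondary elevation between 450 and
        550 nm is reproduced by the fitted two-pigment mixture: the mixture
        lies at or above the pure 431 template, strictly above mid-band."""
        mix = mixture_response([1.398, 0.061], 5.523, [431.0, 500.0], GRID)
        pure = template_absorbance(431.0, GRID).values
        assert np.all(mix.absorbance >= pure - 1e-12)
        band = (GRID >= 460) & (GRID <= 540)
        assert np.all(mix.absorbance[band] > pure[band])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mixture_response([1.0], 2.0, [431.0, 500.0], GRID)


class TestFitMixture:
    def test_reported_ss_matches_recomputation(self):
        s = gen_spectrum(SpectrumSpec((431.0, 500.0), (1.398, 0.061), 5.523,
                                      noise_sd=0.01, seed=1))
        fits = fit_mixture(s, [(431.0, 500.0)])
        f = fits[0]
        recomputed = mixture_response(f.k, f.p, f.pigment_set, s.wavelengths)
        ss = float(np.sum((recomputed.absorbance - s.absorbance) ** 2))
        assert f.ss == pytest.approx(ss, abs=1e-10)

    def test_pure_single_pigment_fit(self):
        s = gen_spectrum(SpectrumSpec((431.0,), (1.0,), p=2.0))
        f = fit_mixture(s, [(431.0,)])[0]
        assert f.k[0] == pytest.approx(1.0, rel=1e-3)
        assert f.ss <= 1e-10

    def test_empty_candidates_rejected(self):
        s = gen_spectrum(SpectrumSpec((431.0,), (1.0,), p=2.0))
        with pytest.raises(ValueError):
            fit_mixture(s, [])
        with pytest.raises(ValueError):
            fit_mixture(s, [()])
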