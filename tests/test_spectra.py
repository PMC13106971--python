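"""Spectral-phasor transform, BRET mixtures, band ratios, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lumiphasor as lp
from lumiphasor.spectra import spectral_phasor, trapezoid_weights

WIN = lp.SpectralWindow(400.0, 700.0)


def gauss(center, sd, n=601):
    return lp.EmissionSpectrum.gaussian(center, sd, WIN.grid(n))


class TestSpectralPhasor:
    def test_delta_at_window_start_is_one_zero(self):
        lam = WIN.grid(301)
        inten = np.zeros_like(lam)
        inten[0] = 5.0
        g, s = spectral_phasor(lp.EmissionSpectrum(lam, inten), WIN)
        assert g == pytest.approx(1.0, abs=1e-12)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_flat_spectrum_over_full_period_is_origin(self):
        g, s = spectral_phasor(lp.EmissionSpectrum.flat(WIN.grid(256)), WIN)
        assert abs(g) < 1e-12 and abs(s) < 1e-12

    def test_gaussian_against_dense_quadrature_oracle(self):
        # frozen oracle: trapezoid quadrature at 0.01 nm steps of
        # exp(-((lambda-518)/15)^2/2) over 400-700 nm
        g, s = spectral_phasor(gauss(518.0, 15.0), WIN)
        assert g == pytest.approx(-0.7459584663921637, abs=1e-9)
        assert s == pytest.approx(0.5912393950057628, abs=1e-9)

    def test_zero_spectrum_raises(self):
        lam = WIN.grid(64)
        with pytest.raises(lp.UndefinedPhasorError):
            spectral_phasor(lp.EmissionSpectrum(lam, np.zeros_like(lam)), WIN)

    def test_support_outside_window_raises(self):
        lam = np.linspace(350.0, 450.0, 101)
        with pytest.raises(lp.DomainError):
            spectral_phasor(lp.EmissionSpectrum(lam, np.ones_like(lam)), WIN)

    def test_second_harmonic_doubles_rotation_rate(self):
        # a delta at quarter-window: harmonic 1 -> angle pi/2, harmonic 2 -> pi
        lam = WIN.grid(401)
        inten = np.zeros_like(lam)
        inten[100] = 1.0  # 475 nm = start + L/4
        spec = lp.EmissionSpectrum(lam, inten)
        g1, s1 = spectral_phasor(spec, WIN)
        g2, s2 = spectral_phasor(spec, lp.SpectralWindow(400.0, 700.0, harmonic=2))
        assert (g1, s1) == pytest.approx((0.0, 1.0), abs=1e-12)
        assert (g2, s2) == pytest.approx((-1.0, 0.0), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        center=st.floats(430.0, 660.0),
        sd=st.floats(5.0, 60.0),
        amp=st.floats(0.1, 100.0),
    )
    def test_boundedness_property(self, center, sd, amp):
        g, s = spectral_phasor(gauss(center, sd) * amp, WIN)
        assert g * g + s * s <= 1.0 + 1e-12

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        c1=st.floats(430.0, 650.0), c2=st.floats(430.0, 650.0),
        w1=st.floats(0.1, 10.0), w2=st.floats(0.1, 10.0),
    )
    def test_linearity_property(self, c1, c2, w1, w2):
        """phasor(A+B) is the intensity-weighted mean of the phasors."""
        a, b = gauss(c1, 20.0) * w1, gauss(c2, 30.0) * w2
        ga, sa = spectral_phasor(a, WIN)
        gb, sb = spectral_phasor(b, WIN)
        gm, sm = spectral_phasor(a + b, WIN)
        wa, wb = a.total, b.total
        assert gm == pytest.approx((wa * ga + wb * gb) / (wa + wb), abs=1e-12)
        assert sm == pytest.approx((wa * sa + wb * sb) / (wa + wb), abs=1e-12)

    def test_shift_covariance_on_delta_spectrum(self):
        """Translating a spectrum rotates its phasor by 2*pi*dlam/L."""
        lam = WIN.grid(601)  # 0.5 nm spacing
        inten = np.zeros_like(lam)
        inten[200] = 1.0  # 500 nm
        spec = lp.EmissionSpectrum(lam, inten)
        dlam = 30.0  # 60 grid steps, keeps the delta on-grid
        z0 = complex(*spectral_phasor(spec, WIN))
        z1 = complex(*spectral_phasor(spec.shifted(dlam), WIN))
        expected = z0 * np.exp(1j * 2 * np.pi * dlam / WIN.length)
        assert z1.real == pytest.approx(expected.real, abs=1e-9)
        assert z1.imag == pytest.approx(expected.imag, abs=1e-9)


class TestTrapezoidWeights:
    def test_matches_numpy_trapezoid_on_nonuniform_grid(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 10, 40))
        f = np.sin(x) + 2
        assert np.dot(trapezoid_weights(x), f) == pytest.approx(np.trapezoid(f, x))


class TestMixBret:
    @pytest.fixture()
    def model(self):
        return lp.ReporterModel("m", gauss(460, 20), gauss(560, 20), efficiency=0.5)

    def test_efficiency_zero_is_donor(self, model):
        mix = lp.mix_bret(model.with_efficiency(0.0))
        donor = model.donor_spectrum.normalized()
        np.testing.assert_allclose(mix.intensities, donor.intensities, atol=1e-12)

    def test_efficiency_one_is_acceptor(self, model):
        mix = lp.mix_bret(model.with_efficiency(1.0))
        acc = model.acceptor_spectrum.normalized()
        np.testing.assert_allclose(mix.intensities, acc.intensities, atol=1e-12)

    def test_half_mixture_phasor_is_chord_midpoint(self, model):
        gd, sd_ = spectral_phasor(model.donor_spectrum, WIN)
        ga, sa = spectral_phasor(model.acceptor_spectrum, WIN)
        gm, sm = spectral_phasor(lp.mix_bret(model), WIN)
        assert gm == pytest.approx((gd + ga) / 2, abs=1e-12)
        assert sm == pytest.approx((sd_ + sa) / 2, abs=1e-12)

    def test_invalid_efficiency_rejected(self, model):
        with pytest.raises(lp.ParameterError):
            model.with_efficiency(1.2)


class TestBretRatio:
    def test_symmetric_spectrum_equal_bands(self):
        spec = gauss(510.0, 40.0)
        ratio = lp.bret_ratio(spec, donor_lambda=480.0, acceptor_lambda=540.0, bandwidth=20.0)
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_pure_donor_far_from_acceptor_band(self):
        spec = gauss(460.0, 10.0)
        ratio = lp.bret_ratio(spec, donor_lambda=460.0, acceptor_lambda=650.0, bandwidth=20.0)
        assert ratio < 1e-12

    def test_half_mix_of_nonoverlapping_gaussians_is_unity(self):
        model = lp.ReporterModel("m", gauss(460, 8), gauss(620, 8), efficiency=0.5)
        mix = lp.mix_bret(model)
        ratio = lp.bret_ratio(mix, donor_lambda=460.0, acceptor_lambda=620.0, bandwidth=30.0)
        # direct band-integration oracle on the mixture itself
        oracle = mix.band_integral(620.0, 30.0) / mix.band_integral(460.0, 30.0)
        assert ratio == pytest.approx(oracle, rel=1e-12)
        assert ratio == pytest.approx(1.0, rel=1e-6)

    def test_zero_donor_band_raises(self):
        spec = gauss(650.0, 5.0)
        with pytest.raises(lp.DomainError):
            lp.bret_ratio(spec, donor_lambda=420.0, acceptor_lambda=650.0, bandwidth=10.0)


class TestSpectralDecompose:
    donor = None

    def setup_method(self):
        self.donor = gauss(460, 25).normalized()
        self.acceptor = gauss(560, 25).normalized()

    def test_pure_donor_recovered_exactly(self):
        fd, fa, rms = lp.spectral_decompose(self.donor, self.donor, self.acceptor)
        assert (fd, fa) == pytest.approx((1.0, 0.0), abs=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_constructed_mixture_recovered(self):
        mix = 0.3 * self.donor + 0.7 * self.acceptor
        fd, fa, rms = lp.spectral_decompose(mix, self.donor, self.acceptor)
        assert fd == pytest.approx(0.3, abs=1e-9)
        assert fa == pytest.approx(0.7, abs=1e-9)

    def test_noisy_mixture_mean_error_below_two_percent(self):
        """Monte-Carlo: 1%-of-peak Gaussian noise, fractions within 0.02."""
        rng = np.random.default_rng(7)
        mix = 0.4 * self.donor + 0.6 * self.acceptor
        sd = 0.01 * mix.intensities.max()
        errs = []
        for _ in range(100):
            noisy = np.clip(mix.intensities + rng.normal(0, sd, mix.intensities.shape), 0, None)
            fd, fa, _ = lp.spectral_decompose(
                lp.EmissionSpectrum(mix.wavelengths, noisy), self.donor, self.acceptor
            )
            errs.append(abs(fd - 0.4))
        assert np.mean(errs) < 0.02

    def test_collinear_references_rejected(self):
        with pytest.raises(lp.IllPosedError):
            lp.spectral_decompose(self.donor, self.donor, self.donor)

    def test_decompose_inverts_mix_bret(self):
        """decompose(mix_bret(E)) == E for separated references."""
        for e in (0.0, 0.25, 0.5, 0.9):
            model = lp.ReporterModel("m", self.donor, self.acceptor, efficiency=e)
            fd, fa, _ = lp.spectral_decompose(lp.mix_bret(model), self.donor, self.acceptor)
            assert fa == pytest.approx(e, abs=1e-9)


class TestCsvRoundTrip:
    def test_spectrum_csv_round_trip(self, tmp_path):
        spec = gauss(500, 30, n=101)
        path = tmp_path / "spec.csv"
        lp.write_spectrum_csv(path, spec)
        back = lp.read_spectrum_csv(path)
        np.testing.assert_allclose(back.wavelengths, spec.wavelengths)
        np.testing.assert_allclose(back.intensities, spec.intensities)

    def test_long_format_library(self, tmp_path):
        import pandas as pd

        rows = []
        for name, center in (("a", 460.0), ("b", 560.0)):
            lam = np.linspace(400, 700, 31)
            for l, i in zip(lam, np.exp(-((lam - center) / 30) ** 2)):
                rows.append({"reporter": name, "wavelength_nm": l, "intensity": i})
        path = tmp_path / "lib.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        lib = lp.read_spectra_long_csv(path)
        assert set(lib) == {"a", "b"}
        assert lib["a"].wavelengths.size == 31
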