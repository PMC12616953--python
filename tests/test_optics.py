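"""Spectral products, calibration ratios and gains against fine-grid oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fretquant.optics import (
    CalibrationError,
    ChannelConfig,
    ChannelSpectralProducts,
    FluorophoreModel,
    SensorOpticalModel,
    SpectralRatios,
    calibrate_rxt,
    channel_gain,
    compute_ratios,
    compute_rp,
    spectral_products,
)
from fretquant.spectra import SpectrumTable


def flat(lo, hi, value=1.0, step=1.0):
    wl = np.arange(lo, hi + step, step)
    return SpectrumTable(wl, np.full(wl.size, value))


def gauss(peak, sigma, lo, hi, step=1.0):
    wl = np.arange(lo, hi + step, step)
    return SpectrumTable(wl, np.exp(-0.5 * ((wl - peak) / sigma) ** 2))


def simple_sensor(**kw):
    defaults = dict(
        donor=FluorophoreModel("D", gauss(645, 20, 560, 740), gauss(670, 20, 590, 800)),
        acceptor=FluorophoreModel("A", gauss(700, 25, 600, 800), gauss(720, 20, 640, 830)),
        light_source=flat(620, 650),
    )
    defaults.update(kw)
    return SensorOpticalModel(**defaults)


def simple_channels(em_d=(660, 680), em_f=(710, 750)):
    ex = flat(620, 650)
    return (
        ChannelConfig("D", ex, flat(*em_d)),
        ChannelConfig("F", ex, flat(*em_f)),
    )


class TestSpectralProducts:
    def test_unit_filters_reproduce_fluorophore_spectra(self):
        sensor = simple_sensor(light_source=flat(500, 900))
        d = ChannelConfig("D", flat(500, 900), flat(500, 900))
        f = ChannelConfig("F", flat(500, 900), flat(500, 900))
        p = spectral_products(sensor, d, f)
        grid = p.X[("D", "D")].wavelength_nm
        np.testing.assert_allclose(
            p.X[("D", "D")].value, sensor.donor.absorption.interp(grid), atol=1e-12
        )
        np.testing.assert_allclose(
            p.M[("D", "D")].value, sensor.donor.emission.interp(grid), atol=1e-12
        )

    def test_zero_emission_filter_zeroes_channel_m_products(self):
        sensor = simple_sensor()
        d, _ = simple_channels()
        f = ChannelConfig("F", flat(620, 650), flat(710, 750, value=0.0))
        p = spectral_products(sensor, d, f)
        assert np.all(p.M[("F", "D")].value == 0)
        assert np.all(p.M[("F", "A")].value == 0)

    def test_products_match_pointwise_multiplication_oracle(self):
        sensor = simple_sensor()
        d, f = simple_channels()
        p = spectral_products(sensor, d, f)
        grid = p.X[("F", "A")].wavelength_nm
        oracle = (
            sensor.light_source.interp(grid)
            * f.excitation_filter.interp(grid)
            * sensor.acceptor.absorption.interp(grid)
            * sensor.acceptor.extinction_coefficient
        )
        np.testing.assert_allclose(p.X[("F", "A")].value, oracle, atol=1e-12)

    def test_disjoint_supports_raise_calibration_error(self):
        sensor = simple_sensor(light_source=flat(400, 450))  # no overlap with absorption
        d, f = simple_channels()
        with pytest.raises(CalibrationError, match="measure"):
            spectral_products(sensor, ChannelConfig("D", flat(400, 450), flat(660, 680)), f)


class TestComputeRatios:
    def test_zero_fret_channel_donor_product_gives_zero_rxt(self):
        sensor = simple_sensor()
        d, _ = simple_channels()
        # FRET emission filter beyond the donor emission support
        f = ChannelConfig("F", flat(620, 650), flat(810, 830))
        r = compute_ratios(spectral_products(sensor, d, f))
        assert r.r_xt == 0.0

    def test_identical_products_give_unit_ratios(self):
        s = gauss(670, 15, 600, 740)
        products = ChannelSpectralProducts(
            X={(c, fl): s for c in "DF" for fl in "DA"},
            M={(c, fl): s for c in "DF" for fl in "DA"},
            grid_step_nm=1.0,
        )
        r = compute_ratios(products)
        assert (r.r_xt, r.r_chan, r.r_fret) == (1.0, 1.0, 1.0)

    def test_matches_fine_grid_riemann_oracle(self):
        # at the oracle's own step the two integration routes must coincide
        sensor = simple_sensor(light_source=gauss(635, 12, 590, 680))
        d = ChannelConfig("D", gauss(635, 10, 600, 670), gauss(667, 14, 630, 710))
        f = ChannelConfig("F", gauss(635, 10, 600, 670), gauss(730, 18, 680, 790))
        r = compute_ratios(spectral_products(sensor, d, f, step_nm=0.01))

        # independent oracle: 0.01-nm Riemann sums of each factorized integral
        grid = np.arange(500.0, 900.0, 0.01)

        def riemann(curve):
            return np.sum(curve) * 0.01

        def X(ch, fl):
            fluor = sensor.donor if fl == "D" else sensor.acceptor
            return riemann(
                sensor.light_source.interp(grid)
                * ch.excitation_filter.interp(grid)
                * fluor.absorption.interp(grid)
                * fluor.extinction_coefficient
            )

        def M(ch, fl):
            fluor = sensor.donor if fl == "D" else sensor.acceptor
            return riemann(
                fluor.emission.interp(grid)
                * ch.emission_filter.interp(grid)
                * fluor.quantum_yield
            )

        denom = X(d, "D") * M(d, "D")
        assert r.r_xt == pytest.approx(X(f, "D") * M(f, "D") / denom, rel=1e-6)
        assert r.r_chan == pytest.approx(X(f, "A") * M(f, "A") / denom, rel=1e-6)
        assert r.r_fret == pytest.approx(X(f, "D") * M(f, "A") / denom, rel=1e-6)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_common_spectrum_rescaling_leaves_ratios_unchanged(self, c):
        sensor = simple_sensor()
        d, f = simple_channels()
        r1 = compute_ratios(spectral_products(sensor, d, f))
        scaled = SensorOpticalModel(
            donor=FluorophoreModel(
                "D", sensor.donor.absorption * c, sensor.donor.emission * c,
                sensor.donor.extinction_coefficient, sensor.donor.quantum_yield,
            ),
            acceptor=FluorophoreModel(
                "A", sensor.acceptor.absorption * c, sensor.acceptor.emission * c,
                sensor.acceptor.extinction_coefficient, sensor.acceptor.quantum_yield,
            ),
            light_source=sensor.light_source * c,
        )
        r2 = compute_ratios(spectral_products(scaled, d, f))
        np.testing.assert_allclose(
            [r2.r_xt, r2.r_chan, r2.r_fret], [r1.r_xt, r1.r_chan, r1.r_fret], rtol=1e-9
        )


class TestGainsAndRp:
    def test_identical_gains_give_unit_rp(self):
        assert compute_rp(3.7, 3.7) == 1.0

    def test_double_gain_gives_rp_two(self):
        assert compute_rp(5.0, 2.5) == 2.0

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(CalibrationError):
            compute_rp(0.0, 1.0)

    def test_channel_gain_matches_fine_grid_oracle(self):
        fluor = FluorophoreModel(
            "D", gauss(435, 25, 350, 520), gauss(475, 20, 400, 600),
            extinction_coefficient=30000.0, quantum_yield=0.93,
        )
        ch = ChannelConfig("CFP", gauss(436, 9, 400, 470), gauss(470, 11, 430, 510),
                           relative_power=2.0, exposure_s=0.5)
        source = gauss(450, 60, 300, 650)
        g = channel_gain(fluor, ch, source, step_nm=0.01)
        grid = np.arange(300.0, 700.0, 0.01)
        x = np.sum(source.interp(grid) * ch.excitation_filter.interp(grid)
                   * fluor.absorption.interp(grid)) * 0.01 * fluor.extinction_coefficient
        m = np.sum(fluor.emission.interp(grid) * ch.emission_filter.interp(grid)) * 0.01 \
            * fluor.quantum_yield
        assert g == pytest.approx(ch.relative_power * ch.exposure_s * x * m, rel=1e-6)


class TestCalibrateRxt:
    def test_constant_normalized_ratio_recovered_exactly(self):
        d, f = simple_channels()
        i_donor = np.array([100.0, 250.0, 900.0])
        i_fret = 0.578 * i_donor
        assert calibrate_rxt(i_fret, i_donor, d, f) == pytest.approx(0.578)

    def test_zero_fret_intensities_give_zero(self):
        d, f = simple_channels()
        assert calibrate_rxt([0.0, 0.0], [10.0, 20.0], d, f) == 0.0

    def test_power_exposure_normalization_applied(self):
        ex = flat(620, 650)
        d = ChannelConfig("D", ex, flat(660, 680), relative_power=1.0, exposure_s=1.0)
        f = ChannelConfig("F", ex, flat(710, 750), relative_power=2.0, exposure_s=1.0)
        # doubled FRET-channel power must be divided back out
        assert calibrate_rxt([1.0], [1.0], d, f) == pytest.approx(0.5)

    def test_noisy_pairs_recover_true_ratio_within_three_standard_errors(self):
        d, f = simple_channels()
        rng = np.random.default_rng(7)
        true = 0.45
        n = 400
        i_donor = rng.lognormal(5.0, 0.3, n)
        ratio_noise = rng.lognormal(0.0, 0.05, n)
        i_fret = i_donor * true * ratio_noise
        est = calibrate_rxt(i_fret, i_donor, d, f)
        se = true * 0.05 / np.sqrt(n)
        assert abs(est - true * np.exp(0.05**2 / 2)) < 3 * se

    def test_empty_input_rejected(self):
        d, f = simple_channels()
        with pytest.raises(CalibrationError):
            calibrate_rxt([], [], d, f)

    def test_measured_value_overrides_computed(self):
        r = SpectralRatios(0.5, 0.1, 0.2)
        r2 = r.with_measured_rxt(0.578)
        assert r2.source == "measured" and r2.r_xt == 0.578
        assert r.source == "computed"  # original untouched
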