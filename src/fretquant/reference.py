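"""Synthetic reference instrument and fluorophores.

Everything in this module is SYNTHETIC: smooth parametric stand-ins for a
near-infrared FRET instrument (shared 635/22 nm excitation, 667/30 and
730/39 nm emission channels) and for miRFP670nano3-like / miRFP720-like
fluorophores, plus a CFP/YFP-like arm for the two-filter configuration.
No vendor or published spectra are tabulated here; shapes are Gaussian
absorption bands and skewed (exponential-tailed) emission bands with
literature-typical peak positions, widths, extinction coefficients and
quantum yields.  The long red emission tails are what make donor
bleed-through into the FRET channel (R_XT) substantial for this pair.

These objects serve as fixtures for tests, demos and the calibration
walk-through; real analyses should load measured spectra instead.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .optics import (
    ChannelConfig,
    FluorophoreModel,
    SensorOpticalModel,
    SpectralRatios,
    calibrate_rxt,
    compute_ratios,
    compute_rp_from_model,
    spectral_products,
)
from .spectra import SpectrumTable

__all__ = [
    "gaussian_band",
    "skewed_emission",
    "band_filter",
    "reference_sensor",
    "reference_channels",
    "reference_ratios",
    "reference_rp",
    "simulate_donor_only_calibration",
]


def gaussian_band(
    peak_nm: float, fwhm_nm: float, name: str = "", step_nm: float = 1.0
) -> SpectrumTable:
    """Gaussian absorption-type band, tabulated out to ~4 sigma."""
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lo, hi = peak_nm - 4.0 * sigma, peak_nm + 4.0 * sigma
    wl = np.arange(lo, hi + step_nm, step_nm)
    return SpectrumTable(wl, np.exp(-0.5 * ((wl - peak_nm) / sigma) ** 2), name)


def skewed_emission(
    peak_nm: float,
    rise_sigma_nm: float,
    tail_scale_nm: float,
    name: str = "",
    step_nm: float = 1.0,
) -> SpectrumTable:
    """Emission band: Gaussian rise below the peak, exponential tail above.

    Fluorescent-protein emission is strongly red-skewed; the exponential
    tail (scale ``tail_scale_nm``) controls how much light leaks into
    far-red emission filters.
    """
    lo = peak_nm - 4.0 * rise_sigma_nm
    hi = peak_nm + 6.0 * tail_scale_nm
    wl = np.arange(lo, hi + step_nm, step_nm)
    val = np.where(
        wl <= peak_nm,
        np.exp(-0.5 * ((wl - peak_nm) / rise_sigma_nm) ** 2),
        np.exp(-(wl - peak_nm) / tail_scale_nm),
    )
    return SpectrumTable(wl, val, name)


def band_filter(
    center_nm: float, width_nm: float, name: str = "", edge_nm: float = 2.0, step_nm: float = 0.5
) -> SpectrumTable:
    """Bandpass transmissivity: unit passband with logistic edges of scale ``edge_nm``."""
    lo_edge = center_nm - width_nm / 2.0
    hi_edge = center_nm + width_nm / 2.0
    wl = np.arange(lo_edge - 8.0 * edge_nm, hi_edge + 8.0 * edge_nm + step_nm, step_nm)
    val = 1.0 / (1.0 + np.exp(-(wl - lo_edge) / edge_nm))
    val *= 1.0 / (1.0 + np.exp((wl - hi_edge) / edge_nm))
    return SpectrumTable(wl, val, name)


# -- red/far-red arm ---------------------------------------------------------

#: a priori emission-tail scales (nm); the "measured" instrument in
#: simulate_donor_only_calibration carries a slightly longer donor tail,
#: the error mechanism that makes a direct crosstalk calibration worthwhile.
_DONOR_TAIL_NM = 45.0
_TAIL_ERROR_FRACTION = 0.025


def _donor_like(tail_scale_nm: float = _DONOR_TAIL_NM) -> FluorophoreModel:
    return FluorophoreModel(
        name="miRFP670nano3-like (synthetic)",
        absorption=gaussian_band(645.0, 50.0, "donor absorption"),
        emission=skewed_emission(670.0, 10.0, tail_scale_nm, "donor emission"),
        extinction_coefficient=94_000.0,
        quantum_yield=0.185,
    )


def _acceptor_like() -> FluorophoreModel:
    return FluorophoreModel(
        name="miRFP720-like (synthetic)",
        absorption=gaussian_band(702.0, 70.0, "acceptor absorption"),
        emission=skewed_emission(720.0, 12.0, 45.0, "acceptor emission"),
        extinction_coefficient=98_000.0,
        quantum_yield=0.061,
    )


def reference_sensor(k: float = 1.0) -> SensorOpticalModel:
    """Synthetic single-chain red/far-red sensor on the synthetic light engine."""
    return SensorOpticalModel(
        donor=_donor_like(),
        acceptor=_acceptor_like(),
        light_source=band_filter(635.0, 22.0, "635/22 source band"),
        concentration_ratio_k=k,
    )


def reference_channels() -> tuple[ChannelConfig, ChannelConfig]:
    """(donor channel, FRET channel): shared 635/22 excitation, 667/30 vs 730/39 emission."""
    ex = band_filter(635.0, 22.0, "ex 635/22")
    donor = ChannelConfig("RFP670", ex, band_filter(667.0, 30.0, "em 667/30"))
    fret = ChannelConfig("FRET720", ex, band_filter(730.0, 39.0, "em 730/39"))
    return donor, fret


@lru_cache(maxsize=None)
def reference_ratios(step_nm: float = 1.0) -> SpectralRatios:
    """Computed spectral ratios of the synthetic reference instrument."""
    donor_ch, fret_ch = reference_channels()
    products = spectral_products(reference_sensor(), donor_ch, fret_ch, step_nm)
    return compute_ratios(products)


# -- CFP/YFP-like arm --------------------------------------------------------


def _cfp_like() -> FluorophoreModel:
    return FluorophoreModel(
        name="CFP-like (synthetic)",
        absorption=gaussian_band(435.0, 60.0, "cfp absorption"),
        emission=skewed_emission(475.0, 15.0, 40.0, "cfp emission"),
        extinction_coefficient=30_000.0,
        quantum_yield=0.93,
    )


def _yfp_like() -> FluorophoreModel:
    return FluorophoreModel(
        name="YFP-like (synthetic)",
        absorption=gaussian_band(515.0, 40.0, "yfp absorption"),
        emission=skewed_emission(530.0, 10.0, 30.0, "yfp emission"),
        extinction_coefficient=104_000.0,
        quantum_yield=0.77,
    )


@lru_cache(maxsize=None)
def reference_rp(step_nm: float = 1.0) -> float:
    """Gain ratio R_P of the synthetic CFP/YFP configuration."""
    white = SpectrumTable(np.arange(380.0, 600.0), np.ones(220), "broadband source")
    cfp_ch = ChannelConfig("CFP", band_filter(436.0, 20.0), band_filter(470.0, 24.0))
    yfp_ch = ChannelConfig("YFP", band_filter(500.0, 20.0), band_filter(535.0, 30.0))
    return compute_rp_from_model(_cfp_like(), _yfp_like(), cfp_ch, yfp_ch, white, step_nm)


# -- donor-only calibration experiment ---------------------------------------


def simulate_donor_only_calibration(
    n_pairs: int = 24,
    rng: np.random.Generator | None = None,
    measurement_cv: float = 0.01,
    tail_error_fraction: float = _TAIL_ERROR_FRACTION,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Donor-only image pairs from a "true" instrument with an emission-tail error.

    Tabulated spectra carry small errors that stack at filter edges; here the
    true donor emission tail is ``tail_error_fraction`` longer than the
    tabulated one, so the directly measured crosstalk ratio comes out
    slightly above the computed value.  Returns ``(i_fret, i_donor,
    true_r_xt)`` with multiplicative lognormal measurement noise of
    coefficient of variation ``measurement_cv`` on each intensity.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    donor_ch, fret_ch = reference_channels()
    true_sensor = SensorOpticalModel(
        donor=_donor_like(_DONOR_TAIL_NM * (1.0 + tail_error_fraction)),
        acceptor=_acceptor_like(),
        light_source=band_filter(635.0, 22.0, "635/22 source band"),
    )
    products = spectral_products(true_sensor, donor_ch, fret_ch, 1.0)
    true_r_xt = compute_ratios(products).r_xt
    i_donor = 1000.0 * rng.lognormal(0.0, 0.2, size=n_pairs)  # expression spread
    i_donor *= rng.lognormal(0.0, measurement_cv, size=n_pairs)
    pt = fret_ch.power_exposure / donor_ch.power_exposure
    i_fret = i_donor * true_r_xt * pt * rng.lognormal(0.0, measurement_cv, size=n_pairs)
    return i_fret, i_donor, true_r_xt


def measured_reference_rxt(n_pairs: int = 24, seed: int = 0) -> float:
    """Run the donor-only calibration on the synthetic instrument end to end."""
    donor_ch, fret_ch = reference_channels()
    i_fret, i_donor, _ = simulate_donor_only_calibration(
        n_pairs, np.random.default_rng(seed)
    )
    return calibrate_rxt(i_fret, i_donor, donor_ch, fret_ch)
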