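"""Imaging-system optical model and spectral calibration ratios.

The sensitized-emission measurement of a red/far-red FRET pair imaged with a
shared excitation band is governed by three dimensionless spectral ratios:

* ``R_XT``   -- crosstalk: donor emission collected in the FRET channel,
  relative to the donor channel;
* ``R_Chan`` -- channel: acceptor directly excited at the donor wavelength and
  collected in the FRET channel, relative to the donor signal;
* ``R_FRET`` -- sensitized acceptor emission in the FRET channel per unit of
  transferred donor excitation, relative to the donor signal.

Each is a ratio of integrals of excitation x emission spectral products

    X_c^f(lambda) = source(lambda) * ex_filter_c(lambda) * eps_f * absorption_f(lambda)
    M_c^f(lambda) = QY_f * emission_f(lambda) * em_filter_c(lambda)

where ``c`` indexes the imaging channel (D = donor channel, F = FRET channel)
and ``f`` the fluorophore (D = donor, A = acceptor).  For the two-filter
CFP/YFP configuration the single gain ratio ``R_P`` (donor-channel gain over
acceptor-channel gain) plays the analogous role.

Because every quantity is a ratio of integrals of products of the same
curves, a common positive rescaling of any spectrum leaves all ratios
unchanged; spectra may therefore be supplied in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .spectra import SpectrumTable, common_grid

__all__ = [
    "CalibrationError",
    "ChannelConfig",
    "FluorophoreModel",
    "SensorOpticalModel",
    "ChannelSpectralProducts",
    "SpectralRatios",
    "spectral_products",
    "compute_ratios",
    "channel_gain",
    "compute_rp",
    "calibrate_rxt",
]

CHANNELS = ("D", "F")
FLUOROPHORES = ("D", "A")


class CalibrationError(ValueError):
    """Raised when a spectral calibration is degenerate (e.g. zero donor gain)."""


@dataclass(frozen=True)
class ChannelConfig:
    """One imaging channel: filter pair plus delivered power and exposure."""

    name: str
    excitation_filter: SpectrumTable
    emission_filter: SpectrumTable
    relative_power: float = 1.0
    exposure_s: float = 1.0

    def __post_init__(self) -> None:
        if self.relative_power <= 0:
            raise CalibrationError(f"channel {self.name!r}: relative_power must be > 0")
        if self.exposure_s <= 0:
            raise CalibrationError(f"channel {self.name!r}: exposure must be > 0")

    @property
    def power_exposure(self) -> float:
        return self.relative_power * self.exposure_s


@dataclass(frozen=True)
class FluorophoreModel:
    """Absorption/emission spectra with molar extinction and quantum yield."""

    name: str
    absorption: SpectrumTable
    emission: SpectrumTable
    extinction_coefficient: float = 1.0
    quantum_yield: float = 1.0

    def __post_init__(self) -> None:
        if self.extinction_coefficient <= 0:
            raise CalibrationError(f"fluorophore {self.name!r}: extinction must be > 0")
        if not (0 < self.quantum_yield <= 1):
            raise CalibrationError(f"fluorophore {self.name!r}: quantum yield must be in (0, 1]")


@dataclass(frozen=True)
class SensorOpticalModel:
    """A FRET pair plus the light source; ``k`` is the acceptor/donor concentration ratio.

    ``k`` defaults to 1: a single-chain sensor carries one donor and one
    acceptor per molecule.  It is exposed for photobleaching or chromophore
    maturation asymmetry studies.
    """

    donor: FluorophoreModel
    acceptor: FluorophoreModel
    light_source: SpectrumTable
    concentration_ratio_k: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration_ratio_k <= 0:
            raise CalibrationError("concentration_ratio_k must be > 0")


@dataclass(frozen=True)
class ChannelSpectralProducts:
    """The eight X/M spectral products on one shared grid.

    Keys are ``(channel, fluorophore)`` with channel in {"D", "F"} and
    fluorophore in {"D", "A"}.  The donor-channel acceptor-emission product
    ``M[("D", "A")]`` is the crosstalk term neglected by the simplified
    measurement model; it is carried here so the full forward model can
    quantify that approximation.
    """

    X: Mapping[tuple[str, str], SpectrumTable]
    M: Mapping[tuple[str, str], SpectrumTable]
    grid_step_nm: float

    def integral_XM(self, channel: str, x_fluor: str, m_fluor: str) -> float:
        """Signal integral for one channel/fluorophore pairing.

        Excitation and emission passbands of a real channel are disjoint
        (split by a dichroic), so the physically measured signal factorizes
        into (trapezoidal integral of X) * (trapezoidal integral of M); a
        pointwise product of the two curves would be identically zero.
        """
        return self.X[(channel, x_fluor)].integral() * self.M[(channel, m_fluor)].integral()


@dataclass(frozen=True)
class SpectralRatios:
    """Calibration constants of the measurement model.

    ``r_p`` is only meaningful for the two-filter CFP/YFP configuration and
    is ``None`` otherwise.  ``source`` records whether the crosstalk ratio
    came from spectral integration ("computed") or from a direct donor-only
    calibration measurement ("measured"); a measured value takes precedence
    because tail-stacking errors in vendor spectra concentrate in R_XT.
    """

    r_xt: float
    r_chan: float
    r_fret: float
    r_p: float | None = None
    source: str = "computed"

    def __post_init__(self) -> None:
        for label, v in (("R_XT", self.r_xt), ("R_Chan", self.r_chan), ("R_FRET", self.r_fret)):
            if not np.isfinite(v) or v < 0:
                raise CalibrationError(f"{label} must be finite and >= 0, got {v!r}")
        if self.r_p is not None and (not np.isfinite(self.r_p) or self.r_p <= 0):
            raise CalibrationError(f"R_P must be finite and > 0, got {self.r_p!r}")

    def with_measured_rxt(self, r_xt: float) -> "SpectralRatios":
        return replace(self, r_xt=float(r_xt), source="measured")


def spectral_products(
    sensor: SensorOpticalModel,
    donor_channel: ChannelConfig,
    fret_channel: ChannelConfig,
    step_nm: float = 1.0,
) -> ChannelSpectralProducts:
    """Compute all eight excitation (X) and emission (M) spectral products.

    All curves are first resampled onto one grid spanning the union of their
    supports (linear interpolation inside each support, zero outside).
    Raises :class:`CalibrationError` if the donor channel would measure
    nothing (identically zero ``X_D^D`` or ``M_D^D``).
    """
    channels = {"D": donor_channel, "F": fret_channel}
    fluors = {"D": sensor.donor, "A": sensor.acceptor}
    curves = [sensor.light_source]
    for ch in channels.values():
        curves += [ch.excitation_filter, ch.emission_filter]
    for fl in fluors.values():
        curves += [fl.absorption, fl.emission]
    grid = common_grid(curves, step_nm)

    source = sensor.light_source.on_grid(grid)
    X: dict[tuple[str, str], SpectrumTable] = {}
    M: dict[tuple[str, str], SpectrumTable] = {}
    for c, ch in channels.items():
        ex = ch.excitation_filter.on_grid(grid)
        em = ch.emission_filter.on_grid(grid)
        for f, fl in fluors.items():
            X[(c, f)] = (source * ex * fl.absorption.on_grid(grid)).scaled(
                fl.extinction_coefficient
            )
            M[(c, f)] = (fl.emission.on_grid(grid) * em).scaled(fl.quantum_yield)
    products = ChannelSpectralProducts(X=X, M=M, grid_step_nm=step_nm)
    if products.integral_XM("D", "D", "D") <= 0:
        raise CalibrationError(
            "donor channel measures nothing: X_D^D * M_D^D integrates to zero "
            "(disjoint spectral supports?)"
        )
    return products


def compute_ratios(products: ChannelSpectralProducts) -> SpectralRatios:
    """Spectral ratios by trapezoidal integration of the X and M products.

    R_XT   = [X_F^D M_F^D] / [X_D^D M_D^D]
    R_Chan = [X_F^A M_F^A] / [X_D^D M_D^D]
    R_FRET = [X_F^D M_F^A] / [X_D^D M_D^D]

    where [X M] denotes the factorized signal integral
    (int X d lambda) * (int M d lambda); see
    :meth:`ChannelSpectralProducts.integral_XM`.
    """
    denom = products.integral_XM("D", "D", "D")
    if denom <= 0:
        raise CalibrationError("zero donor-channel denominator integral")
    return SpectralRatios(
        r_xt=products.integral_XM("F", "D", "D") / denom,
        r_chan=products.integral_XM("F", "A", "A") / denom,
        r_fret=products.integral_XM("F", "D", "A") / denom,
        source="computed",
    )


def channel_gain(
    fluorophore: FluorophoreModel,
    channel: ChannelConfig,
    light_source: SpectrumTable,
    step_nm: float = 1.0,
) -> float:
    """Total gain of one fluorophore imaged in one channel.

    The spectral product of every contributing imaging-system parameter:
    relative excitation power, exposure time, extinction coefficient, quantum
    yield, light-source spectrum, both filter transmissivities, and the
    fluorophore absorption and emission spectra.
    """
    curves = [
        light_source,
        channel.excitation_filter,
        channel.emission_filter,
        fluorophore.absorption,
        fluorophore.emission,
    ]
    grid = common_grid(curves, step_nm)
    x = (
        light_source.on_grid(grid)
        * channel.excitation_filter.on_grid(grid)
        * fluorophore.absorption.on_grid(grid)
    ).scaled(fluorophore.extinction_coefficient)
    m = (fluorophore.emission.on_grid(grid) * channel.emission_filter.on_grid(grid)).scaled(
        fluorophore.quantum_yield
    )
    return channel.power_exposure * x.integral() * m.integral()


def compute_rp(donor_gain: float, acceptor_gain: float) -> float:
    """Gain ratio R_P = donor-channel gain / acceptor-channel gain (CFP/YFP mode)."""
    if donor_gain <= 0 or acceptor_gain <= 0:
        raise CalibrationError("channel gains must be positive to form R_P")
    return donor_gain / acceptor_gain


def compute_rp_from_model(
    donor: FluorophoreModel,
    acceptor: FluorophoreModel,
    donor_channel: ChannelConfig,
    acceptor_channel: ChannelConfig,
    light_source: SpectrumTable,
    step_nm: float = 1.0,
) -> float:
    """R_P from first principles via :func:`channel_gain` for each arm."""
    gd = channel_gain(donor, donor_channel, light_source, step_nm)
    ga = channel_gain(acceptor, acceptor_channel, light_source, step_nm)
    return compute_rp(gd, ga)


def calibrate_rxt(
    i_fret: Sequence[float] | np.ndarray,
    i_donor: Sequence[float] | np.ndarray,
    donor_channel: ChannelConfig,
    fret_channel: ChannelConfig,
) -> float:
    """Directly measured crosstalk ratio from donor-only images.

    With only the donor fluorophore present, the power/exposure-normalized
    FRET-to-donor intensity ratio equals R_XT; the calibration is the mean of
    that ratio over the supplied image pairs.  A measured R_XT should
    override the computed one (see :meth:`SpectralRatios.with_measured_rxt`).
    """
    i_fret = np.asarray(i_fret, dtype=float)
    i_donor = np.asarray(i_donor, dtype=float)
    if i_fret.size == 0 or i_fret.shape != i_donor.shape:
        raise CalibrationError("need at least one paired (I_FRET, I_Donor) measurement")
    if np.any(i_donor <= 0):
        raise CalibrationError("donor-only calibration requires positive donor intensities")
    norm = fret_channel.power_exposure / donor_channel.power_exposure
    return float(np.mean((i_fret / i_donor) / norm))
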