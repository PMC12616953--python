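"""Conversion between measured channel intensities and the FRET response EfA.

EfA is the product of the FRET efficiency E of the associated (phosphorylated,
intramolecularly bound) sensor configuration and the fraction f_A of sensor
molecules in that configuration.  The two factors are not separately
identifiable from an intensity ratio, so only their product is represented.

Red pair (shared excitation, two emission channels), simplified model with
the acceptor-in-donor-channel term neglected:

    NIR = (I_FRET / I_Donor) / (P_F t_F / P_D t_D)
    NIR = (R_XT (1 - EfA) + R_FRET EfA + k R_Chan) / (1 - EfA)          (forward)
    EfA = (NIR - R_XT - k R_Chan) / (NIR - R_XT + R_FRET)               (inverse)

These two maps are exact algebraic inverses of each other.

CFP/YFP pair (two filter sets):  EfA = 1 - (I_CFP / I_YFP) / R_P.

Out-of-[0, 1] EfA values are legitimate noise excursions: they are flagged,
never clipped, because clipping would bias the downstream noise-variance
estimate.  Frames whose denominator is within tolerance of zero become NaN
(missing), never a raised error, so one bad frame cannot abort a track.
"""

from __future__ import annotations

import numpy as np

from .optics import ChannelConfig, ChannelSpectralProducts, SpectralRatios

__all__ = [
    "nir_from_intensities",
    "efa_from_nir",
    "forward_nir",
    "forward_nir_full",
    "efa_cfp_yfp",
    "out_of_range_flags",
    "quantify_tracks",
]

#: Relative tolerance below which the Eq.-4 denominator counts as zero.
DENOM_RTOL = 1e-9


def nir_from_intensities(
    i_fret: np.ndarray | float,
    i_donor: np.ndarray | float,
    donor_channel: ChannelConfig | None = None,
    fret_channel: ChannelConfig | None = None,
    pt_ratio: float | None = None,
) -> np.ndarray | float:
    """Power/exposure-normalized intensity ratio.

    ``pt_ratio`` is (P_F t_F)/(P_D t_D); it may be given directly instead of
    channel configs (default 1).  Nonpositive donor intensities yield NaN.
    """
    if pt_ratio is None:
        if donor_channel is not None and fret_channel is not None:
            pt_ratio = fret_channel.power_exposure / donor_channel.power_exposure
        else:
            pt_ratio = 1.0
    if pt_ratio <= 0:
        raise ValueError("channel power*exposure ratio must be positive")
    i_fret = np.asarray(i_fret, dtype=float)
    i_donor = np.asarray(i_donor, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        nir = np.where(i_donor > 0, (i_fret / i_donor) / pt_ratio, np.nan)
    return nir if nir.ndim else float(nir)


def efa_from_nir(
    nir: np.ndarray | float, ratios: SpectralRatios, k: float = 1.0
) -> np.ndarray | float:
    """Invert the measurement model:  EfA = (NIR - R_XT - k R_Chan) / (NIR - R_XT + R_FRET).

    Frames with |denominator| <= DENOM_RTOL * (1 + |NIR|) become NaN.
    """
    if k <= 0:
        raise ValueError("concentration ratio k must be positive")
    nir = np.asarray(nir, dtype=float)
    denom = nir - ratios.r_xt + ratios.r_fret
    bad = np.abs(denom) <= DENOM_RTOL * (1.0 + np.abs(nir))
    with np.errstate(divide="ignore", invalid="ignore"):
        efa = (nir - ratios.r_xt - k * ratios.r_chan) / denom
    efa = np.where(bad, np.nan, efa)
    return efa if efa.ndim else float(efa)


def forward_nir(
    efa: np.ndarray | float, ratios: SpectralRatios, k: float = 1.0
) -> np.ndarray | float:
    """Simplified forward model:  NIR = (R_XT (1-EfA) + R_FRET EfA + k R_Chan) / (1-EfA)."""
    if k <= 0:
        raise ValueError("concentration ratio k must be positive")
    efa = np.asarray(efa, dtype=float)
    if np.any(efa >= 1.0) or np.any(efa < 0):
        raise ValueError("forward model requires EfA in [0, 1): the donor-channel "
                         "intensity vanishes at EfA = 1")
    nir = (ratios.r_xt * (1.0 - efa) + ratios.r_fret * efa + k * ratios.r_chan) / (1.0 - efa)
    return nir if nir.ndim else float(nir)


def forward_nir_full(
    efa: np.ndarray | float,
    products: ChannelSpectralProducts,
    k: float = 1.0,
) -> np.ndarray | float:
    """Full forward model retaining the acceptor-in-donor-channel emission terms.

    The denominator additionally carries X_D^D M_D^A EfA and k X_D^A M_D^A;
    comparing against :func:`forward_nir` quantifies the error of neglecting
    the donor-channel acceptor-emission crosstalk.
    """
    if k <= 0:
        raise ValueError("concentration ratio k must be positive")
    efa = np.asarray(efa, dtype=float)
    if np.any(efa >= 1.0) or np.any(efa < 0):
        raise ValueError("forward model requires EfA in [0, 1)")
    i = products.integral_XM
    num = (
        i("F", "D", "D") * (1.0 - efa)
        + i("F", "D", "A") * efa
        + k * i("F", "A", "A")
    )
    den = (
        i("D", "D", "D") * (1.0 - efa)
        + i("D", "D", "A") * efa
        + k * i("D", "A", "A")
    )
    nir = num / den
    return nir if nir.ndim else float(nir)


def efa_cfp_yfp(
    i_cfp: np.ndarray | float, i_yfp: np.ndarray | float, r_p: float
) -> np.ndarray | float:
    """Two-filter configuration:  EfA = 1 - (I_CFP / I_YFP) / R_P.

    Nonpositive acceptor (YFP) intensities yield NaN for that frame.
    """
    if r_p <= 0:
        raise ValueError("R_P must be positive")
    i_cfp = np.asarray(i_cfp, dtype=float)
    i_yfp = np.asarray(i_yfp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        efa = np.where(i_yfp > 0, 1.0 - (i_cfp / i_yfp) / r_p, np.nan)
    return efa if efa.ndim else float(efa)


def out_of_range_flags(efa: np.ndarray | float) -> np.ndarray | bool:
    """True where a (finite) EfA value lies outside [0, 1]; such values are kept as-is."""
    efa = np.asarray(efa, dtype=float)
    flags = np.isfinite(efa) & ((efa < 0.0) | (efa > 1.0))
    return flags if flags.ndim else bool(flags)


def quantify_tracks(
    tracks,
    ratios_by_sensor: dict[str, SpectralRatios],
    k: float = 1.0,
    pt_ratio: float = 1.0,
):
    """Convert a long intensity track table into an EfA table.

    Sensors whose rows carry ``donor``/``fret`` channels are quantified with
    the crosstalk-corrected red-pair model; sensors with ``cfp``/``yfp``
    channels with the two-filter gain-ratio model (requires ``r_p`` on that
    sensor's ratios).  Output has one row per cell-frame-sensor with columns
    ``efa``, ``efa_undefined`` (denominator/intensity failure) and
    ``efa_out_of_range``; out-of-[0, 1] values are flagged, never clipped.
    """
    import pandas as pd

    meta_cols = [
        c
        for c in (
            "time_min",
            "technical_replicate",
            "experimental_replicate",
            "egf_time_min",
            "inhibitor_time_min",
            "is_ta",
        )
        if c in tracks.columns
    ]
    out_frames = []
    for sensor, grp in tracks.groupby("sensor", sort=False):
        channels = set(grp["channel"])
        wide = grp.pivot_table(
            index=["cell_id", "frame"] + meta_cols,
            columns="channel",
            values="intensity",
            aggfunc="first",
        ).reset_index()
        if {"donor", "fret"} <= channels:
            ratios = ratios_by_sensor[sensor]
            nir = nir_from_intensities(
                wide["fret"].to_numpy(), wide["donor"].to_numpy(), pt_ratio=pt_ratio
            )
            efa = efa_from_nir(nir, ratios, k)
        elif {"cfp", "yfp"} <= channels:
            ratios = ratios_by_sensor[sensor]
            if ratios.r_p is None:
                raise ValueError(f"sensor {sensor!r} uses CFP/YFP channels but R_P is unset")
            efa = efa_cfp_yfp(wide["cfp"].to_numpy(), wide["yfp"].to_numpy(), ratios.r_p)
        else:
            raise ValueError(
                f"sensor {sensor!r}: expected channels donor/fret or cfp/yfp, got {sorted(channels)}"
            )
        efa = np.asarray(efa, dtype=float)
        res = wide[["cell_id", "frame"] + meta_cols].copy()
        res.insert(2, "sensor", sensor)
        res["efa"] = efa
        res["efa_undefined"] = ~np.isfinite(efa)
        res["efa_out_of_range"] = out_of_range_flags(efa)
        out_frames.append(res)
    out = pd.concat(out_frames, ignore_index=True)
    return out.sort_values(["cell_id", "sensor", "frame"]).reset_index(drop=True)
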