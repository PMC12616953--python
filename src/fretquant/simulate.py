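"""Seeded single-cell ERK-activity simulator and forward optical model.

Emulates live-cell biosensor experiments in MCF-10A-like epithelial cells:
frames every 6 min, an EGF-induced activity peak ~30 min after stimulation,
exponential suppression reaching its minimum within ~20 min of MEK/EGFR
inhibition, an optional sensor-specific undershoot below baseline that
recovers over ~60 min, flat phospho-dead (T/A) control traces, lognormal
per-cell heterogeneity in expression and peak response, and per-frame noise
placed either on the channel intensities (the shared-excitation imaging
configuration makes intensity noise the physical source) or directly on EfA
(simpler for estimator-calibration studies).

Ground-truth activity and EfA accompany every generated population so that
recovery by the quantification/characterization pipeline can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .optics import SpectralRatios
from .quantify import forward_nir

__all__ = [
    "ActivityProfileParams",
    "SensorResponseParams",
    "SensorSpec",
    "PopulationSpec",
    "simulate_activity",
    "activity_to_efa",
    "efa_to_intensities",
    "generate_population",
    "rekar_like_sensor",
    "ekaren4_like_sensor",
    "sensor_for_target_characterization",
]

TRACK_COLUMNS = [
    "cell_id", "frame", "time_min", "sensor", "channel", "intensity",
    "technical_replicate", "experimental_replicate",
    "egf_time_min", "inhibitor_time_min", "is_ta",
]
EFA_COLUMNS = [
    "cell_id", "frame", "time_min", "sensor", "efa",
    "technical_replicate", "experimental_replicate",
    "egf_time_min", "inhibitor_time_min", "is_ta",
]


@dataclass(frozen=True)
class ActivityProfileParams:
    """Piecewise ERK-activity kinetics on a 0-1 activity scale.

    baseline -> logistic rise peaking ``peak_time_offset_min`` after EGF ->
    exponential relaxation toward an elevated plateau -> after the
    inhibitor, exponential decay (time constant ``inhibition_decay_tau_min``,
    clamped to its target after five time constants so the minimum is
    attained within ~20 min) optionally overlaid with a gamma-shaped
    undershoot of depth ``undershoot_depth`` that recovers over
    ``undershoot_recovery_min``.  T/A mutants ignore every treatment.
    """

    frame_interval_min: float = 6.0
    baseline_activity: float = 0.10
    egf_time_min: float = 60.0
    peak_time_offset_min: float = 30.0
    peak_activity: float = 0.95
    plateau_fraction: float = 0.5       # post-peak relaxation target, as fraction of (peak-baseline)
    post_peak_decay_rate: float = 0.02  # per minute
    inhibitor_time_min: float = 240.0
    inhibition_decay_tau_min: float = 3.0
    undershoot_depth: float = 0.0
    undershoot_recovery_min: float = 60.0
    is_ta_mutant: bool = False

    def validate(self, duration_min: float) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if not (0.0 <= self.baseline_activity <= self.peak_activity <= 1.0):
            raise ValueError("need 0 <= baseline_activity <= peak_activity <= 1")
        if min(self.egf_time_min, self.peak_time_offset_min, self.inhibitor_time_min) < 0:
            raise ValueError("treatment times must be nonnegative")
        if self.inhibitor_time_min < self.egf_time_min + self.peak_time_offset_min:
            raise ValueError("inhibitor must come after the EGF-induced peak")
        if duration_min < self.inhibitor_time_min:
            raise ValueError("movie must cover the inhibitor treatment")
        if self.undershoot_depth < 0 or self.undershoot_recovery_min <= 0:
            raise ValueError("invalid undershoot parameters")
        if self.inhibition_decay_tau_min <= 0 or self.post_peak_decay_rate < 0:
            raise ValueError("invalid decay parameters")


@dataclass(frozen=True)
class SensorResponseParams:
    """How a sensor maps activity to EfA and how its readout is corrupted.

    ``noise_mode`` "intensity" adds Gaussian noise of sd ``noise_sd`` (in
    units of the unit-expression donor intensity) to each channel at each
    frame; "efa" adds Gaussian noise of sd ``efa_noise_sd`` directly to the
    EfA trace.  In either mode the effective EfA noise of a cell scales as
    1/expression, the signature of photon-limited shared-excitation imaging.
    """

    efa_min: float = 0.15
    efa_max: float = 0.40
    mode: str = "red"                 # "red" (donor/FRET channels) or "cfp_yfp"
    noise_mode: str = "intensity"
    noise_sd: float = 0.01
    efa_noise_sd: float = 0.012
    expression_lognormal_sigma: float = 0.5
    peak_lognormal_sigma: float = 0.15
    dropout_prob_per_frame: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.efa_min < self.efa_max <= 1.0):
            raise ValueError("need 0 <= efa_min < efa_max <= 1")
        if self.mode not in ("red", "cfp_yfp"):
            raise ValueError(f"unknown sensor mode {self.mode!r}")
        if self.noise_mode not in ("intensity", "efa"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        if min(self.noise_sd, self.efa_noise_sd) < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if not (0.0 <= self.dropout_prob_per_frame < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")


@dataclass(frozen=True)
class SensorSpec:
    """One biosensor: its activity kinetics and its optical response."""

    activity: ActivityProfileParams
    response: SensorResponseParams


@dataclass(frozen=True)
class PopulationSpec:
    """Study design: cells x technical x experimental replicates, per-sensor specs.

    With ``dual_sensor`` every cell co-expresses all sensors reading the same
    underlying stimulus (shared per-cell peak heterogeneity); otherwise each
    sensor gets its own cells.  A fixed seed makes the output byte-identical;
    each cell draws from its own stream keyed by (seed, sensor index, cell
    index), so subsetting cells is reproducible.
    """

    sensors: Mapping[str, SensorSpec]
    n_cells: int = 50
    n_technical_replicates: int = 3
    n_experimental_replicates: int = 3
    seed: int = 0
    dual_sensor: bool = False
    duration_min: float = 540.0

    def __post_init__(self) -> None:
        if not self.sensors:
            raise ValueError("at least one sensor spec required")
        if min(self.n_technical_replicates, self.n_experimental_replicates) < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for label, spec in self.sensors.items():
            spec.activity.validate(self.duration_min)


def simulate_activity(
    params: ActivityProfileParams,
    duration_min: float,
    peak_multiplier: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic activity trace; returns ``(time_min, activity)``.

    ``peak_multiplier`` scales the EGF-induced amplitude above baseline
    (per-cell heterogeneity hook); the result is clipped to [0, 1].
    """
    params.validate(duration_min)
    t = np.arange(0.0, duration_min + 0.5 * params.frame_interval_min, params.frame_interval_min)
    b = params.baseline_activity
    if params.is_ta_mutant:
        return t, np.full_like(t, b)

    amp = (params.peak_activity - b) * peak_multiplier
    peak = b + amp
    t_peak = params.egf_time_min + params.peak_time_offset_min
    a = np.full_like(t, b)

    # logistic rise, renormalized to hit exactly b at EGF and exactly peak at t_peak
    rise = (t >= params.egf_time_min) & (t <= t_peak)
    if np.any(rise):
        mid = params.egf_time_min + params.peak_time_offset_min / 2.0
        scale = params.peak_time_offset_min / 8.0
        g = 1.0 / (1.0 + np.exp(-(t[rise] - mid) / scale))
        g0 = 1.0 / (1.0 + np.exp(-(params.egf_time_min - mid) / scale))
        g1 = 1.0 / (1.0 + np.exp(-(t_peak - mid) / scale))
        a[rise] = b + amp * (g - g0) / (g1 - g0)

    # post-peak relaxation toward an elevated plateau
    plateau = b + params.plateau_fraction * amp
    relax = (t > t_peak) & (t < params.inhibitor_time_min)
    a[relax] = plateau + (peak - plateau) * np.exp(
        -params.post_peak_decay_rate * (t[relax] - t_peak)
    )

    # inhibition: exponential decay to baseline, clamped after 5 tau
    inh = t >= params.inhibitor_time_min
    if np.any(inh):
        dt = t[inh] - params.inhibitor_time_min
        start = plateau + (peak - plateau) * np.exp(
            -params.post_peak_decay_rate * (params.inhibitor_time_min - t_peak)
        )
        tau = params.inhibition_decay_tau_min
        decay = b + (start - b) * np.exp(-dt / tau)
        decay[dt >= 5.0 * tau] = b
        if params.undershoot_depth > 0:
            tau_dip = params.undershoot_recovery_min / 5.0
            dip = params.undershoot_depth * (dt / tau_dip) * np.exp(1.0 - dt / tau_dip)
            decay = decay - dip
        a[inh] = decay

    return t, np.clip(a, 0.0, 1.0)


def activity_to_efa(activity: np.ndarray, sensor: SensorResponseParams) -> np.ndarray:
    """Affine map of 0-1 activity onto the sensor's EfA operating range."""
    activity = np.asarray(activity, dtype=float)
    if np.any((activity < 0) | (activity > 1)):
        raise ValueError("activity must lie in [0, 1]")
    return sensor.efa_min + activity * (sensor.efa_max - sensor.efa_min)


def efa_to_intensities(
    efa: np.ndarray,
    ratios: SpectralRatios,
    sensor: SensorResponseParams,
    rng: np.random.Generator,
    expression: float = 1.0,
    k: float = 1.0,
    pt_ratio: float = 1.0,
) -> dict[str, np.ndarray]:
    """Forward model from a ground-truth EfA trace to noisy channel intensities.

    Red mode: donor intensity proportional to expression * (1 - EfA), FRET
    intensity = donor * NIR * (P_F t_F / P_D t_D).  CFP/YFP mode: the
    acceptor (YFP) channel is proportional to expression and
    I_CFP / I_YFP = R_P (1 - EfA).  Additive Gaussian noise of sd
    ``sensor.noise_sd`` per channel per frame.
    """
    efa = np.asarray(efa, dtype=float)
    if np.any(efa >= 1.0):
        raise ValueError("EfA = 1 leaves no donor-channel intensity to measure")
    n = sensor.noise_sd
    if sensor.mode == "red":
        donor = expression * (1.0 - efa)
        fret = donor * np.asarray(forward_nir(efa, ratios, k)) * pt_ratio
        return {
            "donor": donor + rng.normal(0.0, n, efa.shape),
            "fret": fret + rng.normal(0.0, n, efa.shape),
        }
    if ratios.r_p is None:
        raise ValueError("cfp_yfp mode requires ratios with R_P set")
    yfp = expression * np.ones_like(efa)
    cfp = yfp * ratios.r_p * (1.0 - efa)
    return {
        "cfp": cfp + rng.normal(0.0, n, efa.shape),
        "yfp": yfp + rng.normal(0.0, n, efa.shape),
    }


def _cell_rng(seed: int, sensor_index: int, cell_index: int) -> np.random.Generator:
    # per-cell stream: subsetting or re-ordering cells never changes a cell's draws
    return np.random.default_rng(np.random.SeedSequence((seed, sensor_index, cell_index)))


def generate_population(
    spec: PopulationSpec,
    ratios_by_sensor: Mapping[str, SpectralRatios] | None = None,
    output: str = "intensity",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long track table plus the matching ground-truth table.

    ``output`` "intensity" emits one row per cell-frame-channel with noisy
    intensities (requires spectral ratios per sensor); "efa" skips the
    optical layer and emits noisy EfA directly (one row per cell-frame).
    Returns ``(tracks, truth)``; both are deterministic under a fixed seed.
    """
    if output not in ("intensity", "efa"):
        raise ValueError(f"unknown output {output!r}")
    if output == "intensity":
        if ratios_by_sensor is None:
            from .reference import reference_ratios, reference_rp

            ratios_by_sensor = {}
            for label, sspec in spec.sensors.items():
                base = reference_ratios()
                if sspec.response.mode == "cfp_yfp":
                    base = replace(base, r_p=reference_rp())
                ratios_by_sensor[label] = base
        for label, sspec in spec.sensors.items():
            if label not in ratios_by_sensor:
                raise ValueError(f"no spectral ratios supplied for sensor {label!r}")
            if sspec.response.mode == "cfp_yfp" and ratios_by_sensor[label].r_p is None:
                raise ValueError(f"sensor {label!r} is cfp_yfp but ratios carry no R_P")

    sensor_labels = list(spec.sensors)
    track_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []

    # iterate "cell slots"; in dual mode one slot hosts every sensor
    slot_groups = [sensor_labels] if spec.dual_sensor else [[s] for s in sensor_labels]
    for group_idx, group in enumerate(slot_groups):
        cell_counter = 0
        for exp_rep in range(1, spec.n_experimental_replicates + 1):
            for tech_rep in range(1, spec.n_technical_replicates + 1):
                for _ in range(spec.n_cells):
                    rng = _cell_rng(spec.seed, group_idx, cell_counter)
                    prefix = "cell" if spec.dual_sensor else group[0]
                    cell_id = f"{prefix}_e{exp_rep}t{tech_rep}n{cell_counter}"
                    cell_counter += 1

                    peak_mult = float(
                        rng.lognormal(0.0, spec.sensors[group[0]].response.peak_lognormal_sigma)
                    )
                    expression = float(
                        rng.lognormal(
                            0.0, spec.sensors[group[0]].response.expression_lognormal_sigma
                        )
                    )

                    # dropout: a failed frame (segmentation loss) hits every
                    # sensor and channel of the cell at once
                    p_drop = spec.sensors[group[0]].response.dropout_prob_per_frame
                    n_frames = int(
                        np.floor(
                            spec.duration_min
                            / spec.sensors[group[0]].activity.frame_interval_min
                        )
                    ) + 1
                    keep = rng.random(n_frames) >= p_drop

                    for label in group:
                        sspec = spec.sensors[label]
                        t, act = simulate_activity(
                            sspec.activity, spec.duration_min, peak_mult
                        )
                        efa_true = activity_to_efa(act, sspec.response)
                        frames = np.arange(t.size)
                        meta = dict(
                            cell_id=cell_id,
                            sensor=label,
                            technical_replicate=tech_rep,
                            experimental_replicate=exp_rep,
                            egf_time_min=sspec.activity.egf_time_min,
                            inhibitor_time_min=sspec.activity.inhibitor_time_min,
                            is_ta=sspec.activity.is_ta_mutant,
                        )
                        truth_rows.append(
                            pd.DataFrame(
                                dict(
                                    cell_id=cell_id,
                                    frame=frames,
                                    time_min=t,
                                    sensor=label,
                                    activity=act,
                                    efa_true=efa_true,
                                    expression=expression,
                                    technical_replicate=tech_rep,
                                    experimental_replicate=exp_rep,
                                )
                            )
                        )
                        if output == "efa":
                            noisy = efa_true + rng.normal(
                                0.0, sspec.response.efa_noise_sd / expression, t.shape
                            )
                            df = pd.DataFrame(
                                dict(frame=frames, time_min=t, efa=noisy, **meta)
                            )[EFA_COLUMNS]
                            track_rows.append(df[keep])
                        else:
                            channels = efa_to_intensities(
                                efa_true,
                                ratios_by_sensor[label],
                                sspec.response,
                                rng,
                                expression=expression,
                            )
                            for channel, intensity in channels.items():
                                df = pd.DataFrame(
                                    dict(
                                        frame=frames,
                                        time_min=t,
                                        channel=channel,
                                        intensity=intensity,
                                        **meta,
                                    )
                                )[TRACK_COLUMNS]
                                track_rows.append(df[keep])

    columns = TRACK_COLUMNS if output == "intensity" else EFA_COLUMNS
    if not track_rows:
        empty = pd.DataFrame(columns=columns)
        truth = pd.DataFrame(
            columns=[
                "cell_id", "frame", "time_min", "sensor", "activity", "efa_true",
                "expression", "technical_replicate", "experimental_replicate",
            ]
        )
        return empty, truth
    tracks = pd.concat(track_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return tracks, truth


# -- convenience sensor presets ---------------------------------------------


def rekar_like_sensor(
    undershoot_depth: float = 0.05, ta_mutant: bool = False, **response_overrides
) -> SensorSpec:
    """Red-pair sensor preset: EfA range 0.15-0.40, post-inhibition undershoot."""
    return SensorSpec(
        activity=ActivityProfileParams(
            undershoot_depth=0.0 if ta_mutant else undershoot_depth,
            is_ta_mutant=ta_mutant,
        ),
        response=SensorResponseParams(efa_min=0.15, efa_max=0.40, mode="red", **response_overrides),
    )


def ekaren4_like_sensor(ta_mutant: bool = False, **response_overrides) -> SensorSpec:
    """CFP/YFP sensor preset: EfA range 0.30-0.65, no undershoot."""
    return SensorSpec(
        activity=ActivityProfileParams(undershoot_depth=0.0, is_ta_mutant=ta_mutant),
        response=SensorResponseParams(
            efa_min=0.30, efa_max=0.65, mode="cfp_yfp", **response_overrides
        ),
    )


def sensor_for_target_characterization(
    target_signal: float,
    target_noise_variance: float,
    display_scale: float = 1.0,
    efa_min: float = 0.15,
    undershoot_depth: float = 0.05,
    **response_overrides,
) -> SensorSpec:
    """Sensor whose noise-free dynamic range is ``target_signal`` (raw EfA)
    and whose post-inhibition window variance is ``target_noise_variance`` on
    a display scale ``display_scale`` (raw per-frame sd =
    sqrt(target_noise_variance) / display_scale).

    Used to generate populations at published characterization operating
    points; noise is applied post-ratio ("efa" mode) so the generating values
    are exact.
    """
    activity = ActivityProfileParams(undershoot_depth=undershoot_depth)
    # noise-free activity span: peak down to the sampled post-inhibition minimum
    t, a = simulate_activity(activity, 540.0)
    span = float(a.max() - a.min())
    width = target_signal / span
    response = SensorResponseParams(
        efa_min=efa_min,
        efa_max=efa_min + width,
        mode="red",
        noise_mode="efa",
        efa_noise_sd=float(np.sqrt(target_noise_variance)) / display_scale,
        **response_overrides,
    )
    return SensorSpec(activity=activity, response=response)
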