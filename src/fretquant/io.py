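"""File formats, run configuration and the end-to-end pipeline driver.

Canonical on-disk forms are plain text: long CSV/TSV track tables (one row
per cell-frame-channel for intensities, per cell-frame for EfA), two-column
CSV spectra, a YAML manifest describing the optical system, JSON spectral
ratios, and JSON run metadata embedding the seed and a config hash so every
output is attributable to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .characterize import (
    CharacterizationConfig,
    aggregate_replicates,
    characterize_cells,
    compare_groups,
)
from .optics import (
    ChannelConfig,
    FluorophoreModel,
    SensorOpticalModel,
    SpectralRatios,
    calibrate_rxt,
    compute_ratios,
    spectral_products,
)
from .pipeline import PipelineConfig, filter_tracks, process_tracks
from .quantify import quantify_tracks
from .spectra import SpectrumTable

logger = logging.getLogger("fretquant")

__all__ = [
    "TrackFormatError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_manifest",
    "read_track_table",
    "write_track_table",
    "write_ratios",
    "read_ratios",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("cell_id", "frame", "time_min", "sensor")
NUMERIC_COLUMNS = ("frame", "time_min", "intensity", "efa", "egf_time_min", "inhibitor_time_min")


class TrackFormatError(ValueError):
    """Raised for malformed track tables; the message names the offending column/rows."""


def read_spectrum_csv(path: str | Path, name: str = "") -> SpectrumTable:
    """Two-column CSV (wavelength_nm, value); header optional."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise TrackFormatError(f"{path}: expected two columns (wavelength_nm, value)")
    wl = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    val = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if wl.isna().any() or val.isna().any():
        raise TrackFormatError(f"{path}: non-numeric spectrum entries")
    return SpectrumTable(wl.to_numpy(), val.to_numpy(), name or Path(path).stem)


def write_spectrum_csv(spectrum: SpectrumTable, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength_nm, "value": spectrum.value}
    ).to_csv(path, index=False)


def read_manifest(path: str | Path):
    """Optical-system manifest (YAML): spectra files plus scalar parameters.

    Layout::

        light_source: source.csv
        donor:    {absorption: d_abs.csv, emission: d_em.csv, extinction: 94000, quantum_yield: 0.185}
        acceptor: {absorption: a_abs.csv, emission: a_em.csv, extinction: 98000, quantum_yield: 0.061}
        concentration_ratio_k: 1.0
        channels:
          donor: {excitation_filter: ex.csv, emission_filter: em667.csv, relative_power: 1, exposure_s: 1}
          fret:  {excitation_filter: ex.csv, emission_filter: em730.csv, relative_power: 1, exposure_s: 1}

    Relative paths resolve against the manifest's directory.  Returns
    ``(SensorOpticalModel, donor ChannelConfig, fret ChannelConfig)``.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    root = path.parent

    def spectrum(rel: str, name: str) -> SpectrumTable:
        return read_spectrum_csv(root / rel, name)

    def fluor(section: Mapping, name: str) -> FluorophoreModel:
        return FluorophoreModel(
            name=name,
            absorption=spectrum(section["absorption"], f"{name} absorption"),
            emission=spectrum(section["emission"], f"{name} emission"),
            extinction_coefficient=float(section.get("extinction", 1.0)),
            quantum_yield=float(section.get("quantum_yield", 1.0)),
        )

    def channel(section: Mapping, name: str) -> ChannelConfig:
        return ChannelConfig(
            name=name,
            excitation_filter=spectrum(section["excitation_filter"], f"{name} ex"),
            emission_filter=spectrum(section["emission_filter"], f"{name} em"),
            relative_power=float(section.get("relative_power", 1.0)),
            exposure_s=float(section.get("exposure_s", 1.0)),
        )

    sensor = SensorOpticalModel(
        donor=fluor(cfg["donor"], "donor"),
        acceptor=fluor(cfg["acceptor"], "acceptor"),
        light_source=spectrum(cfg["light_source"], "light source"),
        concentration_ratio_k=float(cfg.get("concentration_ratio_k", 1.0)),
    )
    return sensor, channel(cfg["channels"]["donor"], "donor"), channel(cfg["channels"]["fret"], "fret")


def calibrate_from_manifest(
    manifest_path: str | Path,
    donor_only_csv: str | Path | None = None,
    step_nm: float = 1.0,
) -> SpectralRatios:
    """Compute spectral ratios from a manifest; optionally override R_XT with
    a direct donor-only calibration measurement (CSV with columns
    ``i_fret``, ``i_donor``)."""
    sensor, donor_ch, fret_ch = read_manifest(manifest_path)
    ratios = compute_ratios(spectral_products(sensor, donor_ch, fret_ch, step_nm))
    if donor_only_csv is not None:
        df = pd.read_csv(donor_only_csv)
        for col in ("i_fret", "i_donor"):
            if col not in df.columns:
                raise TrackFormatError(f"{donor_only_csv}: missing required column '{col}'")
        measured = calibrate_rxt(df["i_fret"], df["i_donor"], donor_ch, fret_ch)
        logger.info("measured R_XT %.4f overrides computed %.4f", measured, ratios.r_xt)
        ratios = ratios.with_measured_rxt(measured)
    return ratios


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Validated long track table (CSV or TSV).

    Requires ``cell_id``, ``frame``, ``time_min``, ``sensor`` and either
    ``channel`` + ``intensity`` or ``efa``.  Malformed numeric entries are
    reported with their (1-based, header-inclusive) line numbers.
    """
    df = _read_table(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrackFormatError(f"{path}: missing required column '{col}'")
    has_intensity = {"channel", "intensity"} <= set(df.columns)
    if not has_intensity and "efa" not in df.columns:
        raise TrackFormatError(
            f"{path}: need either 'channel' and 'intensity' columns or an 'efa' column"
        )
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
            raise TrackFormatError(
                f"{path}: non-numeric values in column '{col}' at line(s) {lines}"
            )
        df[col] = coerced
    return df


def write_track_table(df: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def write_ratios(ratios: SpectralRatios, path: str | Path) -> None:
    payload = {k: v for k, v in dataclasses.asdict(ratios).items() if v is not None}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_ratios(path: str | Path) -> SpectralRatios:
    with open(path) as fh:
        payload = json.load(fh)
    return SpectralRatios(**payload)


# -- end-to-end driver -------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Everything an end-to-end run needs; see :func:`run_pipeline`."""

    output_dir: str | Path
    seed: int = 0
    tracks_path: str | Path | None = None      # pre-existing table (intensity or EfA)
    simulate: dict | None = None                # kwargs for the built-in dual-sensor demo
    ratios_path: str | Path | None = None       # JSON ratios; default: synthetic reference
    pipeline: PipelineConfig = dataclasses.field(default_factory=PipelineConfig)
    characterization: CharacterizationConfig = dataclasses.field(
        default_factory=CharacterizationConfig
    )
    movie_frames: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "pipeline" in kwargs:
            kwargs["pipeline"] = PipelineConfig(**kwargs["pipeline"])
        if "characterization" in kwargs:
            kwargs["characterization"] = CharacterizationConfig(**kwargs["characterization"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (where outputs land is excluded)."""

        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return repr(o)

        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineStageError(RuntimeError):
    """Wraps a failure with the stage name so runs fail loudly and identifiably."""


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Quantify -> filter -> process -> characterize -> statistics.

    Writes ``quantified_tracks.csv``, ``processed_tracks.csv``,
    ``rejections.csv``, ``per_cell.csv``, ``replicates.csv``, ``stats.csv``
    (when >= 2 comparable groups exist) and ``run_metadata.json`` into
    ``output_dir``; returns the mapping of output names to paths.
    Deterministic under a fixed seed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # re-raise with stage context
            raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc

    # -- obtain tracks
    if config.tracks_path is not None:
        tracks = stage("read", read_track_table, config.tracks_path)
    elif config.simulate is not None:
        from .simulate import PopulationSpec, ekaren4_like_sensor, generate_population, rekar_like_sensor

        sim = dict(config.simulate)
        sensors = {
            "REKAR67": rekar_like_sensor(**sim.pop("rekar_overrides", {})),
            "EKAREN4": ekaren4_like_sensor(**sim.pop("ekar_overrides", {})),
        }
        spec = PopulationSpec(sensors=sensors, seed=config.seed, dual_sensor=True, **sim)
        tracks, truth = stage("simulate", generate_population, spec)
        truth_path = out_dir / "ground_truth.csv"
        write_track_table(truth, truth_path)
        outputs["ground_truth"] = truth_path
    else:
        raise ValueError("RunConfig needs either tracks_path or simulate settings")

    # -- quantify intensities if needed
    if "efa" not in tracks.columns:
        if config.ratios_path is not None:
            base = read_ratios(config.ratios_path)
            ratios_by_sensor = {s: base for s in tracks["sensor"].unique()}
        else:
            from .reference import reference_ratios, reference_rp

            base = reference_ratios()
            with_rp = dataclasses.replace(base, r_p=reference_rp())
            ratios_by_sensor = {s: with_rp for s in tracks["sensor"].unique()}
        efa_table = stage("quantify", quantify_tracks, tracks, ratios_by_sensor)
    else:
        efa_table = tracks
    outputs["quantified_tracks"] = out_dir / "quantified_tracks.csv"
    write_track_table(efa_table, outputs["quantified_tracks"])

    # -- filter + process
    retained, rejections = stage(
        "filter", filter_tracks, efa_table, config.pipeline, config.movie_frames
    )
    n_tracks = efa_table.groupby(["cell_id", "sensor"]).ngroups
    logger.info(
        "filter audit: %d tracks in, %d removed by length, %d removed by range, %d retained",
        n_tracks,
        int((rejections["rule"] == "track_length").sum()),
        int((rejections["rule"] == "signal_range").sum()),
        retained.groupby(["cell_id", "sensor"]).ngroups,
    )
    outputs["rejections"] = out_dir / "rejections.csv"
    rejections.to_csv(outputs["rejections"], index=False)
    processed = stage("process", process_tracks, retained, config.pipeline)
    outputs["processed_tracks"] = out_dir / "processed_tracks.csv"
    write_track_table(processed, outputs["processed_tracks"])

    # -- characterize
    per_cell = stage("characterize", characterize_cells, processed, config.characterization)
    outputs["per_cell"] = out_dir / "per_cell.csv"
    per_cell.to_csv(outputs["per_cell"], index=False)

    stats_payload = {}
    if {"technical_replicate", "experimental_replicate"} <= set(per_cell.columns):
        replicates = stage("aggregate", aggregate_replicates, per_cell)
        outputs["replicates"] = out_dir / "replicates.csv"
        replicates.to_csv(outputs["replicates"], index=False)
        by_group = replicates.groupby("sensor")["signal"].size()
        if (by_group >= 2).sum() >= 2:
            rows = []
            for metric in ("signal", "noise", "snr"):
                res = stage("compare", compare_groups, replicates, metric,
                            alpha=config.characterization.alpha)
                t = res["tukey"].copy()
                t.insert(0, "metric", metric)
                t["anova_f"] = res["anova_f"]
                t["anova_p"] = res["anova_p"]
                rows.append(t)
            stats = pd.concat(rows, ignore_index=True)
            outputs["stats"] = out_dir / "stats.csv"
            stats.to_csv(outputs["stats"], index=False)
            stats_payload = {"n_comparisons": int(len(stats))}

    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_tracks_in": int(n_tracks),
        "n_tracks_retained": int(retained.groupby(["cell_id", "sensor"]).ngroups),
        "n_rejections_length": int((rejections["rule"] == "track_length").sum()),
        "n_rejections_range": int((rejections["rule"] == "signal_range").sum()),
        **stats_payload,
    }
    outputs["run_metadata"] = out_dir / "run_metadata.json"
    with open(outputs["run_metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outputs
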