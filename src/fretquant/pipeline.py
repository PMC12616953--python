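"""Single-cell track processing: filtering, smoothing, scaling, normalization.

A "track" is one cell's EfA time series for one sensor.  Processing follows
the plotting-normalization recipe used for cross-sensor comparison:

1. drop tracks that are present in <= 85% of the movie's frames or that show
   any EfA value outside the sensor's expected operating range;
2. 3-point centered moving average (window shrinks at edges; missing frames
   are excluded from each window);
3. subtract each track's minimum smoothed value;
4. multiply by the sensor's red-to-CFP/YFP scaling factor (1 for the
   CFP/YFP sensor) and then by a per-sensor normalizing value chosen to map
   signals onto a common 0-1 display scale.

Tracks are never interpolated: fabricating frames would fabricate noise
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PipelineConfig",
    "filter_tracks",
    "smooth",
    "baseline_subtract",
    "process_tracks",
    "compute_scaling_factor",
    "normalize_for_plotting",
]

TRACK_KEY = ["cell_id", "sensor"]


class PipelineConfigError(ValueError):
    """Raised when a track references configuration that does not exist."""


@dataclass(frozen=True)
class PipelineConfig:
    """Constants of the track-processing recipe.

    ``expected_range_by_sensor`` keys are matched to sensor labels first
    exactly, then by prefix, so "REKAR67-T/A" inherits the "REKAR67" range.
    ``range_filter_mode`` "any_frame" (default, strictest reading) rejects a
    track if any single frame leaves the range; "mean" tests the track mean.
    """

    min_track_fraction: float = 0.85
    expected_range_by_sensor: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "EKAREN4": (0.30, 0.65),
            "REKAR67": (0.15, 0.40),
            "REKAR76": (0.15, 0.40),
            "REKAR": (0.15, 0.40),
        }
    )
    smoothing_window: int = 3
    rekar_to_ekar_scale: Mapping[str, float] = field(
        default_factory=lambda: {"REKAR67": 1.5679, "REKAR76": 3.0042, "EKAREN4": 1.0}
    )
    normalizing_value_by_sensor: Mapping[str, float] = field(
        default_factory=lambda: {"REKAR67": 5.0, "REKAR76": 3.0, "EKAREN4": 4.0}
    )
    range_filter_mode: str = "any_frame"
    ratio_floor_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.min_track_fraction <= 1.0):
            raise ValueError("min_track_fraction must be in (0, 1]")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")
        for label, (lo, hi) in self.expected_range_by_sensor.items():
            if not lo < hi:
                raise ValueError(f"range for {label!r} must have lower < upper")
        if self.range_filter_mode not in ("any_frame", "mean"):
            raise ValueError(f"unknown range_filter_mode {self.range_filter_mode!r}")

    def _lookup(self, mapping: Mapping[str, float] | Mapping[str, tuple], label: str, what: str):
        if label in mapping:
            return mapping[label]
        matches = [k for k in mapping if label.startswith(k)]
        if matches:
            return mapping[max(matches, key=len)]
        raise PipelineConfigError(f"no {what} configured for sensor {label!r}")

    def sensor_range(self, label: str) -> tuple[float, float]:
        return self._lookup(self.expected_range_by_sensor, label, "expected range")

    def scale_factor(self, label: str) -> float:
        return self._lookup(self.rekar_to_ekar_scale, label, "scaling factor")

    def normalizing_value(self, label: str) -> float:
        return self._lookup(self.normalizing_value_by_sensor, label, "normalizing value")


def filter_tracks(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    movie_frames: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the track-length and signal-range filters.

    ``movie_frames`` is the total number of frames of the experiment; by
    default it is inferred from the full frame span of the table (not of any
    single track).  Returns ``(retained table, rejection log)``; the log has
    one row per (track, fired rule) with a human-readable detail.
    """
    config = config or PipelineConfig()
    if table.empty:
        return table.copy(), pd.DataFrame(columns=TRACK_KEY + ["rule", "detail"])
    if movie_frames is None:
        movie_frames = int(table["frame"].max() - table["frame"].min()) + 1

    log_rows: list[dict] = []
    keep_keys: list[tuple] = []
    for key, grp in table.groupby(TRACK_KEY, sort=False):
        present = grp.loc[grp["efa"].notna(), "frame"].nunique()
        fraction = present / movie_frames
        lo, hi = config.sensor_range(key[1])
        ok = True
        if not fraction > config.min_track_fraction:
            ok = False
            log_rows.append(
                dict(zip(TRACK_KEY, key))
                | {"rule": "track_length", "detail": f"present fraction {fraction:.3f} <= "
                   f"{config.min_track_fraction}"}
            )
        values = grp["efa"].dropna()
        if config.range_filter_mode == "any_frame":
            bad = values[(values < lo) | (values > hi)]
            if not bad.empty:
                ok = False
                log_rows.append(
                    dict(zip(TRACK_KEY, key))
                    | {"rule": "signal_range",
                       "detail": f"{bad.size} frame(s) outside [{lo}, {hi}], "
                       f"e.g. {bad.iloc[0]:.4f}"}
                )
        else:
            m = values.mean()
            if not (lo <= m <= hi):
                ok = False
                log_rows.append(
                    dict(zip(TRACK_KEY, key))
                    | {"rule": "signal_range", "detail": f"mean {m:.4f} outside [{lo}, {hi}]"}
                )
        if ok:
            keep_keys.append(key)

    idx = pd.MultiIndex.from_tuples(keep_keys, names=TRACK_KEY) if keep_keys else None
    if idx is None:
        retained = table.iloc[0:0].copy()
    else:
        retained = table.set_index(TRACK_KEY).loc[idx.unique()].reset_index()
        retained = retained[table.columns]
    log = pd.DataFrame(log_rows, columns=TRACK_KEY + ["rule", "detail"])
    return retained, log


def smooth(values: np.ndarray | pd.Series, window: int = 3) -> np.ndarray:
    """Centered moving average; edges shrink, missing values are skipped.

    A frame that is itself missing stays missing (no interpolation).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    if s.notna().sum() == 0:
        raise ValueError("cannot smooth an all-missing trace")
    out = s.rolling(window, center=True, min_periods=1).mean()
    out[s.isna()] = np.nan
    return out.to_numpy()


def baseline_subtract(values: np.ndarray | pd.Series) -> np.ndarray:
    """Subtract the minimum so the trace floor is exactly zero."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.all(np.isnan(v)):
        raise ValueError("cannot baseline-subtract an empty trace")
    return v - np.nanmin(v)


def normalize_for_plotting(
    values: np.ndarray | pd.Series, scaling_factor: float, normalizing_value: float
) -> np.ndarray:
    """Scale a smoothed, baseline-subtracted trace onto the display scale (no clipping)."""
    return np.asarray(values, dtype=float) * scaling_factor * normalizing_value


def process_tracks(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Add ``efa_smooth``, ``efa_rezeroed`` and ``efa_norm`` columns per track.

    The input must already be filtered; tracks are processed independently in
    time order.
    """
    config = config or PipelineConfig()
    out = table.sort_values(TRACK_KEY + ["frame"]).reset_index(drop=True).copy()

    def _per_track(grp: pd.DataFrame) -> pd.DataFrame:
        sm = smooth(grp["efa"].to_numpy(), config.smoothing_window)
        rz = sm - np.nanmin(sm)
        label = grp["sensor"].iloc[0]
        grp = grp.copy()
        grp["efa_smooth"] = sm
        grp["efa_rezeroed"] = rz
        grp["efa_norm"] = normalize_for_plotting(
            rz, config.scale_factor(label), config.normalizing_value(label)
        )
        return grp

    return (
        out.groupby(TRACK_KEY, sort=False, group_keys=False)[out.columns]
        .apply(_per_track)
        .reset_index(drop=True)
    )


def compute_scaling_factor(
    processed: pd.DataFrame,
    rekar_label: str,
    ekar_label: str = "EKAREN4",
    config: PipelineConfig | None = None,
) -> float:
    """Red-to-CFP/YFP scaling factor from dual-sensor cells.

    For each cell expressing both sensors, the framewise ratio of the
    smoothed, baseline-subtracted CFP/YFP signal to the red signal is
    averaged over frames where the red signal exceeds a floor (a fraction of
    the cell's CFP/YFP maximum, guarding against 0/0 near the re-zeroed
    baseline); the factor is the mean of the per-cell averages pooled across
    replicates.
    """
    config = config or PipelineConfig()
    need = {"efa_rezeroed"}
    if not need <= set(processed.columns):
        raise ValueError("compute_scaling_factor expects process_tracks output")
    per_cell: list[float] = []
    for cell_id, grp in processed.groupby("cell_id", sort=False):
        sensors = set(grp["sensor"])
        if rekar_label not in sensors or ekar_label not in sensors:
            continue
        r = grp[grp["sensor"] == rekar_label].set_index("frame")["efa_rezeroed"]
        e = grp[grp["sensor"] == ekar_label].set_index("frame")["efa_rezeroed"]
        joined = pd.concat({"r": r, "e": e}, axis=1).dropna()
        floor = config.ratio_floor_fraction * joined["e"].max()
        valid = joined[joined["r"] > floor]
        if not valid.empty:
            per_cell.append(float((valid["e"] / valid["r"]).mean()))
    if not per_cell:
        raise ValueError(
            f"no dual-sensor cell has frames above the ratio floor for "
            f"{rekar_label!r} vs {ekar_label!r}"
        )
    return float(np.mean(per_cell))
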