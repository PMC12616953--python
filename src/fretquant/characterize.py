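"""Per-cell Signal, Noise and SNR, replicate aggregation, and group comparison.

Signal (dynamic range) is a cell's maximum minus minimum EfA over its full
retained, unsmoothed trace.  Noise is the unbiased sample variance of the
signal in the window 2-5 h after inhibitor treatment, when true kinase
activity is fully suppressed, optionally reported on a per-sensor display
scale (variance is offset-invariant, so the display scale enters only as a
squared multiplier).  SNR is each cell's Signal divided by its own Noise.

Statistics operate on technical-replicate means pooled across experimental
replicates: one-way ANOVA followed by a Tukey-Kramer post-hoc test (the
studentized-range procedure for possibly unequal group sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CharacterizationConfig",
    "dynamic_range",
    "noise_variance",
    "snr",
    "characterize_cells",
    "aggregate_replicates",
    "compare_groups",
]

TRACK_KEY = ["cell_id", "sensor"]


@dataclass(frozen=True)
class CharacterizationConfig:
    """Noise-window placement (hours after inhibitor, closed on both ends)."""

    noise_window_start_h: float = 2.0
    noise_window_end_h: float = 5.0
    min_frames_in_window: int = 10
    alpha: float = 0.05
    noise_mode: str = "window_variance"  # or "first_difference"

    def __post_init__(self) -> None:
        if not (0 <= self.noise_window_start_h < self.noise_window_end_h):
            raise ValueError("need 0 <= window start < window end")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_frames_in_window < 2:
            raise ValueError("need at least 2 frames to form a variance")
        if self.noise_mode not in ("window_variance", "first_difference"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")


def dynamic_range(efa: np.ndarray | pd.Series) -> float:
    """max - min over the present frames of a trace; NaN if fewer than 2 frames."""
    v = np.asarray(efa, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    return float(v.max() - v.min())


def noise_variance(
    efa: np.ndarray | pd.Series,
    time_min: np.ndarray | pd.Series,
    inhibitor_time_min: float,
    config: CharacterizationConfig | None = None,
) -> float:
    """Unbiased variance of EfA in the closed post-inhibition window.

    Frames with ``inhibitor + start <= t <= inhibitor + end`` (hours
    converted to minutes) are selected; fewer present frames than
    ``min_frames_in_window`` yields NaN.  In "first_difference" mode the
    variance of successive frame differences divided by two is returned
    instead (equal to the plain variance for uncorrelated noise, insensitive
    to slow drift).
    """
    config = config or CharacterizationConfig()
    v = np.asarray(efa, dtype=float)
    t = np.asarray(time_min, dtype=float)
    lo = inhibitor_time_min + 60.0 * config.noise_window_start_h
    hi = inhibitor_time_min + 60.0 * config.noise_window_end_h
    sel = v[(t >= lo) & (t <= hi)]
    sel = sel[np.isfinite(sel)]
    if sel.size < config.min_frames_in_window:
        return float("nan")
    if config.noise_mode == "first_difference":
        d = np.diff(sel)
        return float(np.var(d, ddof=1) / 2.0)
    return float(np.var(sel, ddof=1))


def snr(signal: float, noise: float) -> float:
    """Signal divided by the cell's own noise variance; NaN (with a warning) at zero noise."""
    if not np.isfinite(signal) or not np.isfinite(noise):
        return float("nan")
    if noise <= 0:
        warnings.warn("cell excluded from SNR: noise variance is zero", stacklevel=2)
        return float("nan")
    return signal / noise


def characterize_cells(
    table: pd.DataFrame,
    config: CharacterizationConfig | None = None,
    value_col: str = "efa",
    noise_display_scale: float | dict[str, float] = 1.0,
) -> pd.DataFrame:
    """Per-track Signal / Noise / SNR with replicate labels carried through.

    ``noise_display_scale`` maps each sensor label to the display scale its
    noise is reported on (Noise is multiplied by the square of the scale);
    Signal always stays on the raw trace scale.
    """
    config = config or CharacterizationConfig()
    rows = []
    for key, grp in table.groupby(TRACK_KEY, sort=False):
        label = key[1]
        k = (
            noise_display_scale.get(label, 1.0)
            if isinstance(noise_display_scale, dict)
            else noise_display_scale
        )
        sig = dynamic_range(grp[value_col])
        noi = noise_variance(
            grp[value_col], grp["time_min"], float(grp["inhibitor_time_min"].iloc[0]), config
        ) * k**2
        row = {
            "cell_id": key[0],
            "sensor": label,
            "signal": sig,
            "noise": noi,
            "snr": snr(sig, noi),
        }
        for col in ("technical_replicate", "experimental_replicate", "is_ta"):
            if col in grp.columns:
                row[col] = grp[col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_replicates(
    per_cell: pd.DataFrame,
    metrics: tuple[str, ...] = ("signal", "noise", "snr"),
    group_col: str = "sensor",
) -> pd.DataFrame:
    """Technical-replicate means, one row per (group, experimental, technical) replicate.

    The pooled rows are the statistical sample for group comparison.  Empty
    replicates (all-NaN metric values) are dropped with a warning.
    """
    need = {group_col, "technical_replicate", "experimental_replicate"}
    missing = need - set(per_cell.columns)
    if missing:
        raise ValueError(f"missing replicate labels: {sorted(missing)}")
    grouped = per_cell.groupby(
        [group_col, "experimental_replicate", "technical_replicate"], sort=False
    )
    agg = grouped[list(metrics)].mean().reset_index()
    n_cells = grouped.size().reset_index(name="n_cells")
    agg = agg.merge(n_cells, on=[group_col, "experimental_replicate", "technical_replicate"])
    empty = agg[list(metrics)].isna().all(axis=1)
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} empty replicate(s)", stacklevel=2)
        agg = agg[~empty]
    return agg.reset_index(drop=True)


def compare_groups(
    replicate_table: pd.DataFrame,
    value_col: str,
    group_col: str = "sensor",
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA plus all pairwise Tukey-Kramer comparisons.

    Groups with fewer than two replicate-level values are excluded with a
    warning.  Returns ``{"anova_f", "anova_p", "tukey"}`` where ``tukey`` is
    a table of pairwise mean differences, adjusted p-values and significance
    flags at ``alpha``.
    """
    df = replicate_table[[group_col, value_col]].dropna()
    sizes = df.groupby(group_col)[value_col].size()
    small = sizes[sizes < 2]
    if not small.empty:
        warnings.warn(
            f"excluding group(s) with < 2 replicate values: {list(small.index)}",
            stacklevel=2,
        )
        df = df[~df[group_col].isin(small.index)]
    groups = [g[value_col].to_numpy() for _, g in df.groupby(group_col)]
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 replicate values")
    f_stat, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(df[value_col].to_numpy(), df[group_col].to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    tukey = tukey.rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    tukey["p_adj"] = tk.pvalues  # full precision, not the rounded summary
    return {"anova_f": float(f_stat), "anova_p": float(p), "tukey": tukey}
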