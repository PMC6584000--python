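"""Raw logger streams to fortnightly pressure metrics.

Daily water-quality records (turbidity in NTU, daily light integral, raw
deposition-sensor output) are converted to the three pressure metrics the
distance-decay models consume: a 14 d trailing running mean of
nephelometrically derived SSC (NTU x 1.8 mg/L per NTU), a 14 d running mean
DLI, and a 60 d running mean of the per-site 0-1 sediment deposition index.
Each series is then summarised as the fortnightly maximum of the running
mean, the fortnight being a 14-day bin counted from the start of dredging.

Running means are trailing (right-aligned): the exposure a site has
experienced up to a given day, never using future data.  A window is only
emitted when at least ``min_window_coverage`` of its days are present,
guarding against fouled or serviced sensors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessConfig",
    "ntu_to_ssc",
    "dli_from_flux",
    "deposition_index",
    "running_mean",
    "fortnight_summary",
    "preprocess_water_quality",
]


@dataclass(frozen=True)
class PreprocessConfig:
    ntu_to_ssc_factor: float = 1.8
    ssc_window_days: int = 14
    dli_window_days: int = 14
    depo_window_days: int = 60
    fortnight_length_days: int = 14
    #: 'max' is the standard pressure summary; 'min' available for DLI where
    #: low light rather than high light is the pressure
    dli_summary_stat: str = "max"
    min_window_coverage: float = 0.5

    def __post_init__(self) -> None:
        for name in ("ssc_window_days", "dli_window_days", "depo_window_days",
                     "fortnight_length_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ntu_to_ssc_factor <= 0:
            raise ValueError("ntu_to_ssc_factor must be positive")
        if not 0 < self.min_window_coverage <= 1:
            raise ValueError("min_window_coverage must be in (0, 1]")
        if self.dli_summary_stat not in ("max", "min"):
            raise ValueError("dli_summary_stat must be 'max' or 'min'")


def ntu_to_ssc(ntu, factor: float = 1.8):
    """Suspended sediment concentration (mg/L) from turbidity (NTU)."""
    ntu_arr = np.asarray(ntu, dtype=float)
    if np.any(ntu_arr < 0):
        raise ValueError("NTU must be non-negative")
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    out = factor * ntu_arr
    return float(out) if np.isscalar(ntu) or out.ndim == 0 else out


def dli_from_flux(flux, interval_s: float = 1.0) -> float:
    """Daily light integral (mol photons m^-2 d^-1) from quantum flux.

    Integrates per-sample quantum flux (umol m^-2 s^-1) over one civil day:
    DLI = sum(flux * interval_s) / 1e6.  Missing samples (NaN) are filled
    with the day's mean available flux, i.e. the integral scales the mean
    flux to the full day; an empty or all-missing day returns NaN.
    """
    f = np.asarray(flux, dtype=float)
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    if f.size == 0 or np.all(np.isnan(f)):
        return float("nan")
    if np.any(f[~np.isnan(f)] < 0):
        raise ValueError("quantum flux must be non-negative")
    mean_flux = np.nanmean(f)
    filled = np.where(np.isnan(f), mean_flux, f)
    return float(np.sum(filled) * interval_s / 1e6)


def deposition_index(depo_raw: pd.Series) -> pd.Series:
    """Per-site min-max scaling of daily-mean deposition output to [0, 1].

    The sensor reports relative backscatter in instrument units; absolute
    accumulation rates are not recoverable, so each site's series is scaled
    so its minimum maps to 0 and its maximum to 1.  A constant series maps
    to all zeros with a warning.
    """
    x = pd.Series(depo_raw, dtype=float)
    if x.dropna().nunique() < 2:
        warnings.warn(
            "constant deposition series: index set to 0 everywhere", stacklevel=2
        )
        return x * 0.0
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo)


def running_mean(
    series: pd.Series, window_days: int, min_coverage: float = 0.5
) -> pd.Series:
    """Trailing running mean over a daily-indexed series.

    The window ends at each day and averages the available (non-missing)
    values; the result is emitted only where available/window >= coverage.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    min_periods = max(1, math.ceil(window_days * min_coverage))
    return series.rolling(window=window_days, min_periods=min_periods).mean()


def fortnight_summary(
    frame: pd.DataFrame,
    value_col: str = "value",
    fortnight_length_days: int = 14,
    stat: str = "max",
) -> pd.DataFrame:
    """Per (site, fortnight) summary of a daily running-mean series.

    ``frame`` needs columns site_id, day and ``value_col``; fortnight =
    floor(day / fortnight_length).  Empty bins yield no row.
    """
    if stat not in ("max", "min"):
        raise ValueError("stat must be 'max' or 'min'")
    work = frame.dropna(subset=[value_col]).copy()
    work["fortnight"] = np.floor_divide(work["day"].to_numpy(), fortnight_length_days)
    grouped = (
        work.groupby(["site_id", "fortnight"], sort=True)[value_col]
        .agg(stat)
        .reset_index()
        .rename(columns={value_col: "value"})
    )
    return grouped


def preprocess_water_quality(
    water: pd.DataFrame,
    config: PreprocessConfig = PreprocessConfig(),
    dredge_phase_only: bool = True,
) -> pd.DataFrame:
    """Daily records to the long fortnightly metric table used by the fits.

    Returns columns (site_id, fortnight, metric, value) with metric in
    {ssc, dli, depo_index}: running means per config windows, summarised as
    the fortnightly maximum (or minimum for DLI when configured).  With
    ``dredge_phase_only`` the summaries are restricted to day >= 0.
    """
    required = {"site_id", "day", "ntu", "dli", "depo_raw"}
    missing = required - set(water.columns)
    if missing:
        raise ValueError(f"water-quality table missing columns {sorted(missing)}")

    pieces = []
    for site_id, grp in water.sort_values("day").groupby("site_id", sort=True):
        grp = grp.set_index("day")
        # reindex to a full daily grid so trailing windows count gaps
        days = np.arange(grp.index.min(), grp.index.max() + 1)
        grp = grp.reindex(days)
        ssc = ntu_to_ssc(grp["ntu"].to_numpy(), config.ntu_to_ssc_factor)
        channels = {
            "ssc": running_mean(
                pd.Series(ssc, index=days),
                config.ssc_window_days,
                config.min_window_coverage,
            ),
            "dli": running_mean(
                grp["dli"], config.dli_window_days, config.min_window_coverage
            ),
            "depo_index": running_mean(
                deposition_index(grp["depo_raw"]),
                config.depo_window_days,
                config.min_window_coverage,
            ),
        }
        for metric, series in channels.items():
            frame = pd.DataFrame(
                {"site_id": site_id, "day": days, "value": series.to_numpy()}
            )
            if dredge_phase_only:
                frame = frame[frame["day"] >= 0]
            stat = config.dli_summary_stat if metric == "dli" else "max"
            summary = fortnight_summary(
                frame, "value", config.fortnight_length_days, stat
            )
            summary.insert(2, "metric", metric)
            pieces.append(summary)
    out = pd.concat(pieces, ignore_index=True)
    return out[["site_id", "fortnight", "metric", "value"]]
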