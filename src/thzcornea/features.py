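"""Per-sample predictors from per-pixel, per-frame spectral slopes.

Each scan frame is reduced to the mean slope of its central 5x5 pixel
block; the per-frame series is then averaged over the last 30 minutes of
the acclimation, elevated-IOP and post-elevation physiological periods,
giving the three predictors S_Start, S_Elev and S_Phys (all in ps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .protocol import ProtocolSpec

__all__ = [
    "PeriodWindows",
    "SlopeSeries",
    "FeatureVector",
    "central_roi_mean",
    "period_windows",
    "extract_features",
    "feature_table",
]

#: Largest tolerated fraction of NaN pixels inside the ROI.
MAX_NAN_ROI_FRACTION = 0.2


class PeriodWindows(NamedTuple):
    """Half-open (lo, hi] averaging windows in minutes, one per period."""

    acclimation: Tuple[float, float]
    elevated: Tuple[float, float]
    recovery: Tuple[float, float]


@dataclass
class SlopeSeries:
    """Per-frame ROI-mean slope with timestamps and IOP annotation."""

    sample_id: str
    t_min: np.ndarray
    slope_ps: np.ndarray
    iop_mmhg: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, float)
        self.slope_ps = np.asarray(self.slope_ps, float)
        self.iop_mmhg = np.asarray(self.iop_mmhg, float)
        if not (len(self.t_min) == len(self.slope_ps) == len(self.iop_mmhg)):
            raise ValueError("series arrays must have equal length")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class FeatureVector:
    """The three spectral-slope predictors of one sample, in ps."""

    sample_id: str
    group_mmhg: float
    s_start: float
    s_elev: float
    s_phys: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.s_start, self.s_elev, self.s_phys])):
            raise ValueError("features must be finite")


def _roi_size(m: int) -> int:
    # smallest odd block covering at least half the grid; 5 for the 9x9 scan
    k = (m + 1) // 2
    return k if k % 2 == 1 else k + 1


def central_roi_mean(frame_slopes) -> float:
    """Mean slope over the central pixel block (central 25 of a 9x9 scan).

    NaN pixels (failed deconvolutions) are excluded if they make up at
    most 20% of the ROI; more than that is an error.  Even-sized grids
    have no unique centre and are rejected.
    """
    grid = np.asarray(frame_slopes, dtype=float)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError(f"expected a square grid, got shape {grid.shape}")
    m = grid.shape[0]
    if m % 2 == 0:
        raise ValueError("even-sized grid has no unique central block")
    k = _roi_size(m)
    lo = (m - k) // 2
    roi = grid[lo : lo + k, lo : lo + k]
    n_nan = int(np.isnan(roi).sum())
    if n_nan > MAX_NAN_ROI_FRACTION * roi.size:
        raise ValueError(
            f"{n_nan}/{roi.size} ROI pixels are NaN (> {MAX_NAN_ROI_FRACTION:.0%})"
        )
    return float(np.nanmean(roi))


def period_windows(protocol: ProtocolSpec, window_min: float = 30.0) -> PeriodWindows:
    """The last ``window_min`` minutes of each pressure period, as (lo, hi].

    For the default protocol: acclimation (30, 60], elevated (270, 300],
    recovery (510, 540].
    """
    ends = np.cumsum(
        [protocol.acclimation_min, protocol.elevated_min, protocol.recovery_min]
    )
    durations = [protocol.acclimation_min, protocol.elevated_min, protocol.recovery_min]
    for name, dur in zip(PeriodWindows._fields, durations):
        if dur < window_min:
            raise ValueError(f"{name} period ({dur} min) is shorter than the {window_min} min window")
    return PeriodWindows(*[(float(e - window_min), float(e)) for e in ends])


def _window_mean(series: SlopeSeries, window: Tuple[float, float]) -> float:
    lo, hi = window
    mask = (series.t_min > lo) & (series.t_min <= hi)
    if not np.any(mask):
        raise ValueError(
            f"sample {series.sample_id}: no frames in window ({lo}, {hi}] min"
        )
    return float(np.mean(series.slope_ps[mask]))


def extract_features(
    series: SlopeSeries,
    protocol: ProtocolSpec,
    group_mmhg: Optional[float] = None,
    window_min: float = 30.0,
) -> FeatureVector:
    """S_Start / S_Elev / S_Phys from a per-frame slope series."""
    windows = period_windows(protocol, window_min)
    return FeatureVector(
        sample_id=series.sample_id,
        group_mmhg=float(group_mmhg) if group_mmhg is not None else float("nan"),
        s_start=_window_mean(series, windows.acclimation),
        s_elev=_window_mean(series, windows.elevated),
        s_phys=_window_mean(series, windows.recovery),
    )


def feature_table(
    slope_table: pd.DataFrame,
    protocol: ProtocolSpec,
    labels: Optional[pd.DataFrame] = None,
    window_min: float = 30.0,
) -> pd.DataFrame:
    """Per-sample feature table from a per-pixel slope table.

    ``slope_table`` is the output of
    :func:`thzcornea.processing.process_archive`.  If ``labels`` is
    given it is joined on ``sample_id``.  Returns columns
    sample_id, group_mmHg, S_Start_ps, S_Elev_ps, S_Phys_ps
    (plus ecd_cells_per_mm2 when labels are provided).
    """
    required = {"sample_id", "frame_index", "t_min", "iop_mmHg", "pixel_row", "pixel_col", "slope_ps"}
    missing = required - set(slope_table.columns)
    if missing:
        raise ValueError(f"slope table missing columns: {sorted(missing)}")

    records = []
    for sid, sdf in slope_table.groupby("sample_id", sort=True):
        frames = []
        for (k, t, iop), fdf in sdf.groupby(["frame_index", "t_min", "iop_mmHg"], sort=True):
            m = int(fdf["pixel_row"].max()) + 1
            grid = np.full((m, m), np.nan)
            grid[fdf["pixel_row"].to_numpy(), fdf["pixel_col"].to_numpy()] = fdf[
                "slope_ps"
            ].to_numpy()
            try:
                frames.append((float(t), float(iop), central_roi_mean(grid)))
            except ValueError as exc:
                raise ValueError(f"sample {sid}, frame {k}: {exc}") from exc
        frames.sort()
        series = SlopeSeries(
            sample_id=str(sid),
            t_min=[f[0] for f in frames],
            iop_mmhg=[f[1] for f in frames],
            slope_ps=[f[2] for f in frames],
        )
        elevated = series.iop_mmhg[series.iop_mmhg != protocol.baseline_iop_mmhg]
        group = float(elevated[0]) if len(elevated) else float("nan")
        fv = extract_features(series, protocol, group_mmhg=group, window_min=window_min)
        records.append(
            {
                "sample_id": fv.sample_id,
                "group_mmHg": fv.group_mmhg,
                "S_Start_ps": fv.s_start,
                "S_Elev_ps": fv.s_elev,
                "S_Phys_ps": fv.s_phys,
            }
        )
    table = pd.DataFrame.from_records(records)
    if labels is not None:
        table = table.drop(columns=["group_mmHg"]).merge(
            labels[["sample_id", "group_mmHg", "ecd_cells_per_mm2"]],
            on="sample_id",
            how="inner",
        )[["sample_id", "group_mmHg", "ecd_cells_per_mm2", "S_Start_ps", "S_Elev_ps", "S_Phys_ps"]]
    return table
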