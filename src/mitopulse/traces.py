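"""Normalized per-mitochondrion time series, morphology, and population labels.

Converts tracked per-frame measurements into area-normalized,
baseline-normalized (F/F0, dF/F) or ratiometric (R/R0) traces, computes
Euclidean distance to the stimulation point, classifies mitochondria into
spot/proximal/distal/other subpopulations relative to the cell's maximum
distance, and aggregates per-frame population summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

POPULATIONS = ("spot", "proximal", "distal", "other", "control")

# distance-fraction presets: HEK 30/70%, MEF 20/50%
_PRESETS = {
    "HEK": (0.30, 0.70),
    "MEF": (0.20, 0.50),
}


@dataclass(frozen=True)
class PopulationConfig:
    """Thresholds of the distance-based subpopulation rule.

    A mitochondrion at distance d from the stimulation point, in a cell
    whose farthest mitochondrion sits at distance M, is *proximal* when
    d/M < `proximal_frac`, *distal* when d/M > `distal_frac`, and *spot*
    when d < `spot_radius` (an absolute radius, reported separately from
    the remaining proximal group). Everything else is *other*.
    """

    proximal_frac: float = 0.30
    distal_frac: float = 0.70
    spot_radius: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.proximal_frac < self.distal_frac < 1:
            raise ValueError(
                "need 0 < proximal_frac < distal_frac < 1, got "
                f"{self.proximal_frac}, {self.distal_frac}"
            )
        if self.spot_radius <= 0:
            raise ValueError(f"spot_radius must be > 0, got {self.spot_radius}")

    @classmethod
    def preset(cls, name: str, spot_radius: float = 1.5) -> "PopulationConfig":
        """Named presets: 'HEK' (30/70%) or 'MEF' (20/50%)."""
        try:
            lo, hi = _PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
        return cls(proximal_frac=lo, distal_frac=hi, spot_radius=spot_radius)


@dataclass
class NormalizedTrace:
    """A dimensionless per-object (or per-cell) time series.

    `kind` is one of 'F/F0', 'dF/F', 'R/R0'. Baseline-mean is 1 for
    F/F0 and R/R0, 0 for dF/F. `time` is in seconds, aligned to the
    acquisition clock (stimulation onset available via metadata).
    """

    track_id: object
    time: np.ndarray
    values: np.ndarray
    kind: str = "F/F0"
    channel_role: str | None = None
    baseline_window: tuple[int, int] | None = None
    population: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must have identical shape")
        if self.population is not None and self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")

    def as_dff(self) -> "NormalizedTrace":
        """Convert an F/F0 or R/R0 trace to dF/F (subtract 1)."""
        if self.kind == "dF/F":
            return self
        return replace(self, values=self.values - 1.0, kind="dF/F")


def area_normalize(track, channel_role: str) -> np.ndarray:
    """Per-frame sum intensity of one channel divided by area (counts/um^2).

    Accepts a MitoTrack (segment module) or any object with
    `sum_intensity(channel_role)` and `areas()` arrays.
    """
    sums = np.asarray(track.sum_intensity(channel_role), dtype=float)
    areas = np.asarray(track.areas(), dtype=float)
    if np.any(areas <= 0):
        raise ValueError(
            f"track {getattr(track, 'track_id', '?')} has non-positive area; "
            "upstream segmentation bug"
        )
    return sums / areas


def baseline_normalize(
    series: np.ndarray,
    baseline_window: tuple[int, int],
    *,
    time: np.ndarray | None = None,
    dff: bool = False,
    track_id: object = None,
    channel_role: str | None = None,
) -> NormalizedTrace:
    """Divide a series by its mean over `baseline_window` (frame slice [a, b)).

    With `dff=True` the result is dF/F = F/F0 - 1.
    """
    series = np.asarray(series, dtype=float)
    a, b = baseline_window
    if b <= a:
        raise ValueError(f"empty baseline window [{a}, {b})")
    base = series[a:b]
    if base.size == 0:
        raise ValueError(f"baseline window [{a}, {b}) selects no samples")
    mean = float(np.mean(base))
    if mean <= 0:
        raise ValueError(f"baseline mean must be > 0, got {mean}")
    values = series / mean
    kind = "F/F0"
    if dff:
        values = values - 1.0
        kind = "dF/F"
    if time is None:
        time = np.arange(series.size, dtype=float)
    return NormalizedTrace(
        track_id=track_id,
        time=time,
        values=values,
        kind=kind,
        channel_role=channel_role,
        baseline_window=(a, b),
    )


def ratiometric_trace(
    series_488: np.ndarray,
    series_405: np.ndarray,
    baseline_window: tuple[int, int],
    *,
    time: np.ndarray | None = None,
    track_id: object = None,
) -> NormalizedTrace:
    """R/R0 trace: 488-excitation emission over 405-excitation emission,
    baseline-normalized. Common multiplicative losses cancel in the ratio."""
    f488 = np.asarray(series_488, dtype=float)
    f405 = np.asarray(series_405, dtype=float)
    if f488.shape != f405.shape:
        raise ValueError("channel series must be frame-aligned")
    if np.any(f405 <= 0):
        raise ValueError("405-excitation series must be strictly positive")
    out = baseline_normalize(f488 / f405, baseline_window, time=time, track_id=track_id)
    out.kind = "R/R0"
    return out


def quench_ratio_trace(
    sensor_series: np.ndarray,
    reference_series: np.ndarray,
    baseline_window: tuple[int, int],
    *,
    time: np.ndarray | None = None,
    track_id: object = None,
) -> NormalizedTrace:
    """Sensor/reference ratio, baseline-normalized.

    Supports the localization-quenching readout where a shared quencher
    bleaches the cytosolic reference faster than a protected sensor; the
    endpoint ratio (e.g. at 1000 s) then reports compartment protection.
    """
    sensor = np.asarray(sensor_series, dtype=float)
    ref = np.asarray(reference_series, dtype=float)
    if sensor.shape != ref.shape:
        raise ValueError("sensor and reference series must be frame-aligned")
    if np.any(ref <= 0):
        raise ValueError("reference series must be strictly positive")
    out = baseline_normalize(sensor / ref, baseline_window, time=time, track_id=track_id)
    out.kind = "R/R0"
    return out


def distance_to_stim(track, stim_point: tuple[float, float] | None) -> np.ndarray:
    """Per-frame Euclidean distance (um) from the track centroid to the
    fixed stimulation point."""
    if stim_point is None:
        raise ValueError("stimulation point not set")
    cx, cy = float(stim_point[0]), float(stim_point[1])
    xy = np.asarray(track.centroids(), dtype=float)  # (n, 2) of (x, y)
    return np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)


def label_distance(d: float, max_distance: float, config: PopulationConfig) -> str:
    """Label a single distance under the subpopulation rule.

    The spot rule (absolute radius) takes precedence; otherwise the
    fractional proximal/distal thresholds apply, with the band between
    them labelled 'other'.
    """
    if max_distance <= 0:
        raise ValueError("maximum distance must be > 0 (single object at stim point?)")
    if d < config.spot_radius:
        return "spot"
    frac = d / max_distance
    if frac < config.proximal_frac:
        return "proximal"
    if frac > config.distal_frac:
        return "distal"
    return "other"


def classify_population(
    distances: Mapping[object, float] | pd.Series,
    config: PopulationConfig = PopulationConfig(),
) -> dict:
    """Assign one population label per track from reference-window distances.

    `distances` maps track_id -> distance to the stimulation point (um)
    evaluated in the reference window (by convention the stimulation
    frame; labels stay fixed for the whole recording). The per-cell
    maximum distance M is taken over the supplied tracks.
    """
    if isinstance(distances, pd.Series):
        distances = distances.to_dict()
    if not distances:
        raise ValueError("need at least one track to classify")
    dvals = {k: float(v) for k, v in distances.items()}
    M = max(dvals.values())
    if M <= 0:
        raise ValueError("maximum distance is 0: every object sits on the stim point")
    return {tid: label_distance(d, M, config) for tid, d in dvals.items()}


def form_factor(perimeter: float | np.ndarray, area: float | np.ndarray) -> float | np.ndarray:
    """Form factor perimeter^2 / (4*pi*area): 1 for a circle, larger for
    elongated or complex shapes. Unit-free (invariant to spatial rescaling)."""
    perimeter = np.asarray(perimeter, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(perimeter <= 0) or np.any(area <= 0):
        raise ValueError("perimeter and area must be > 0")
    ff = perimeter**2 / (4.0 * np.pi * area)
    return float(ff) if ff.ndim == 0 else ff


def moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average for display export only; edges use the
    available samples. Analysis always runs on raw series."""
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def population_summary(
    df: pd.DataFrame,
    *,
    value_col: str = "value",
    include_other_in_proportion: bool = True,
    smooth_window: int | None = None,
) -> pd.DataFrame:
    """Per-frame, per-population n / mean / SEM plus population proportions.

    `df` needs columns frame, population and `value_col`. Proportions are
    n_population / n_total per frame; they sum to 1 when 'other' is
    included, <= 1 otherwise. `smooth_window` adds a display-only
    `mean_smoothed` column (centered moving average); the `mean` column
    stays raw.
    """
    required = {"frame", "population", value_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary input missing columns {sorted(missing)}")
    present = df["population"].unique()
    for pop in POPULATIONS:
        if pop not in present and pop in ("proximal", "distal"):
            warnings.warn(f"population {pop!r} is empty; omitted from summary")

    grouped = df.groupby(["frame", "population"], sort=True)[value_col]
    out = grouped.agg(n="count", mean="mean", sem=lambda v: v.sem(ddof=1)).reset_index()
    out.loc[out["n"] == 1, "sem"] = 0.0
    totals = df.groupby("frame")["population"].count()
    out["proportion"] = out.apply(
        lambda r: r["n"] / totals.loc[r["frame"]], axis=1
    )
    if not include_other_in_proportion:
        out.loc[out["population"] == "other", "proportion"] = np.nan
    if smooth_window:
        out["mean_smoothed"] = np.nan
        for pop, idx in out.groupby("population").groups.items():
            sub = out.loc[idx].sort_values("frame")
            out.loc[sub.index, "mean_smoothed"] = moving_average(
                sub["mean"].to_numpy(), smooth_window
            )
    return out


def kr_expression_normalize(amplitude: float, kr_prestim_mean: float) -> float:
    """Scale a cell's response amplitude by its pre-stimulation
    photosensitizer expression level (simple division)."""
    if kr_prestim_mean <= 0:
        raise ValueError("pre-stimulation photosensitizer mean must be > 0")
    return amplitude / kr_prestim_mean
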