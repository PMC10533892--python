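"""Sigmoid standard curves per mitochondrial microdomain and inverse
interpolation of biosensor responses into exogenous-H2O2-equivalent
concentrations.

The standard curve is a 4-parameter logistic in linear concentration,
S(c) = bottom + (top - bottom) / (1 + (EC50/c)^h), with S(0) = bottom as
the c -> 0 limit so the 0 uM anchor needs no log-dose dialect. Fits run on
per-concentration averages by default; curves with R^2 <= 0.99 raise a
recorded warning and mark downstream equivalents as provisional.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

R2_GATE = 0.99
#: gate: responses above top minus this fraction of span count as saturated
SATURATION_SPAN_FRACTION = 0.01

VALID_REASONS = ("ok", "below_baseline", "above_saturation", "no_response")


class CurveQualityWarning(UserWarning):
    """Raised when a standard curve fails the R^2 > 0.99 quality gate."""


@dataclass
class StandardCurve:
    """Fitted 4-parameter logistic dose-response curve for one microdomain."""

    microdomain: str
    bottom: float
    top: float
    EC50: float
    hill: float
    R2: float = float("nan")
    normalization: str = "raw"  # or "baseline_saturation"

    def __post_init__(self) -> None:
        if not self.bottom < self.top:
            raise ValueError(f"need bottom < top, got {self.bottom} >= {self.top}")
        if self.EC50 <= 0 or self.hill <= 0:
            raise ValueError("EC50 and Hill slope must be > 0")
        if self.normalization not in ("raw", "baseline_saturation"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def passes_gate(self) -> bool:
        return bool(self.R2 > R2_GATE)

    def predict(self, c: float | np.ndarray) -> float | np.ndarray:
        """S(c); strictly increasing in c, S(0) = bottom."""
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be >= 0")
        with np.errstate(divide="ignore"):
            ratio = np.where(c > 0, (self.EC50 / np.where(c > 0, c, 1.0)) ** self.hill, np.inf)
        out = self.bottom + (self.top - self.bottom) / (1.0 + ratio)
        return float(out) if out.ndim == 0 else out

    def saturation_cutoff(self) -> float:
        return self.top - SATURATION_SPAN_FRACTION * (self.top - self.bottom)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StandardCurve":
        return cls(**d)


@dataclass
class InterpolationResult:
    """An exogenous-H2O2-equivalent concentration for one response.

    `equivalent_conc` is the bath concentration that would elicit the
    same biosensor response — explicitly not an in-situ concentration.
    """

    equivalent_conc: float  # uM; NaN when not computable
    valid: bool
    reason: str = "ok"

    def __post_init__(self) -> None:
        if self.reason not in VALID_REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.valid and not self.equivalent_conc >= 0:
            raise ValueError("valid result requires equivalent_conc >= 0")


def _logistic(c: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c > 0, (ec50 / np.where(c > 0, c, 1.0)) ** hill, np.inf)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_standard_curve(
    samples: Sequence | pd.DataFrame,
    microdomain: str,
    *,
    average_per_concentration: bool = True,
    normalization: str = "raw",
) -> StandardCurve:
    """Least-squares 4-parameter logistic fit to dose-response samples.

    `samples` is a list of DoseResponseSample or a frame with columns
    concentration_uM and response (and optionally microdomain to filter
    on). Responses are averaged per concentration before fitting unless
    `average_per_concentration=False`. Needs >= 4 distinct concentrations
    including a 0 or clearly sub-EC50 anchor. A fit with R^2 <= 0.99
    triggers a CurveQualityWarning but is still returned.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
        if "microdomain" in df.columns:
            df = df[df["microdomain"] == microdomain]
    else:
        df = pd.DataFrame(
            {
                "concentration_uM": [s.concentration for s in samples],
                "response": [s.response for s in samples],
                "microdomain": [s.microdomain for s in samples],
            }
        )
        df = df[df["microdomain"] == microdomain]
    if df.empty:
        raise ValueError(f"no samples for microdomain {microdomain!r}")

    if average_per_concentration:
        agg = df.groupby("concentration_uM", sort=True)["response"].mean().reset_index()
    else:
        agg = df[["concentration_uM", "response"]].sort_values("concentration_uM")
    c = agg["concentration_uM"].to_numpy(dtype=float)
    r = agg["response"].to_numpy(dtype=float)

    if np.unique(c).size < 4:
        raise ValueError("need >= 4 distinct concentrations to fit a 4-parameter curve")
    spread = np.ptp(r)
    if spread <= 1e-12 * max(abs(r).max(), 1.0):
        raise ValueError("degenerate dose-response data: responses have no spread")

    pos = c[c > 0]
    p0 = (float(r.min()), float(r.max()), float(np.median(pos)), 1.0)
    lower = (-np.inf, -np.inf, 1e-9, 1e-3)
    upper = (np.inf, np.inf, 1e6, 100.0)
    popt, _ = curve_fit(
        _logistic, c, r, p0=p0, bounds=(lower, upper), maxfev=20000
    )
    bottom, top, ec50, hill = (float(v) for v in popt)
    if top < bottom:  # symmetric parameterization: reorder
        bottom, top = top, bottom
    pred = _logistic(c, bottom, top, ec50, hill)
    rss = float(np.sum((r - pred) ** 2))
    tss = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    curve = StandardCurve(
        microdomain=microdomain, bottom=bottom, top=top, EC50=ec50, hill=hill,
        R2=r2, normalization=normalization,
    )
    if not curve.passes_gate:
        warnings.warn(
            f"standard curve for {microdomain!r} has R^2 = {r2:.4f} <= {R2_GATE}; "
            "downstream equivalents are provisional",
            CurveQualityWarning,
        )
    return curve


def normalize_baseline_saturation(
    responses: np.ndarray | float, baseline_resp: float, saturation_resp: float
) -> np.ndarray | float:
    """Rescale responses to the [baseline, saturation] span: r' =
    (r - baseline)/(saturation - baseline). Noise may push values slightly
    outside [0, 1]; they are not clipped."""
    if saturation_resp <= baseline_resp:
        raise ValueError(
            f"saturation ({saturation_resp}) must exceed baseline ({baseline_resp})"
        )
    responses = np.asarray(responses, dtype=float)
    out = (responses - baseline_resp) / (saturation_resp - baseline_resp)
    return float(out) if out.ndim == 0 else out


def interpolate_equivalents(
    response: float, curve: StandardCurve, *, enforce_gate: bool = False
) -> InterpolationResult:
    """Invert the standard curve: c = EC50 * ((r - bottom)/(top - r))^(1/h).

    Responses at or below the fitted bottom are flagged below_baseline
    (the exclusion rule for cells that decreased below baseline);
    responses at or beyond the saturation cutoff (top minus 1% of span)
    are flagged above_saturation. Flagged results still carry the
    algebraic concentration when it exists.
    """
    if enforce_gate and not curve.passes_gate:
        raise ValueError(
            f"curve for {curve.microdomain!r} fails the R^2 > {R2_GATE} gate"
        )
    r = float(response)
    if r <= curve.bottom:
        return InterpolationResult(float("nan"), valid=False, reason="below_baseline")
    if r >= curve.top:
        return InterpolationResult(float("nan"), valid=False, reason="above_saturation")
    conc = curve.EC50 * ((r - curve.bottom) / (curve.top - r)) ** (1.0 / curve.hill)
    if r >= curve.saturation_cutoff():
        return InterpolationResult(float(conc), valid=False, reason="above_saturation")
    return InterpolationResult(float(conc), valid=True, reason="ok")


def equivalents_table(
    per_cell_responses: pd.DataFrame,
    curves: Mapping[str, StandardCurve],
    *,
    group_cols: Sequence[str] = ("microdomain",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell exogenous-equivalent concentrations plus a summary.

    `per_cell_responses` needs columns microdomain, cell_id, response
    (plus any grouping columns, e.g. condition). Returns (table, summary):
    the table carries equivalent_uM, valid, reason per cell; the summary
    has n, mean and SD of the valid equivalents per group. A microdomain
    without a curve raises.
    """
    required = {"microdomain", "cell_id", "response"}
    missing = required - set(per_cell_responses.columns)
    if missing:
        raise ValueError(f"responses table missing columns {sorted(missing)}")
    rows = []
    for _, rec in per_cell_responses.iterrows():
        md = rec["microdomain"]
        if md not in curves:
            raise ValueError(f"no standard curve for microdomain {md!r}")
        res = interpolate_equivalents(rec["response"], curves[md])
        row = dict(rec)
        row["equivalent_uM"] = res.equivalent_conc
        row["valid"] = res.valid
        row["reason"] = res.reason
        rows.append(row)
    table = pd.DataFrame(rows)

    valid = table[table["valid"]]
    if valid.empty:
        warnings.warn("no valid interpolations: summary is empty")
        summary = pd.DataFrame(columns=[*group_cols, "n", "mean_uM", "sd_uM"])
    else:
        summary = (
            valid.groupby(list(group_cols))["equivalent_uM"]
            .agg(n="count", mean_uM="mean", sd_uM=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
            .reset_index()
        )
    return table, summary


def write_curves(curves: Mapping[str, StandardCurve], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {md: c.to_dict() for md, c in sorted(curves.items())}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_curves(path: str | Path) -> dict[str, StandardCurve]:
    payload = json.loads(Path(path).read_text())
    return {md: StandardCurve.from_dict(d) for md, d in payload.items()}


def sigmoid(c, bottom: float, top: float, ec50: float, hill: float):
    """Standalone 4-parameter logistic S(c); exposed for oracles and plots."""
    c = np.asarray(c, dtype=float)
    out = _logistic(c, bottom, top, ec50, hill)
    return float(out) if out.ndim == 0 else out
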