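"""Synthetic two-channel photostimulation movies, traces, and dose-response
samples with machine-readable ground truth.

The scene model: capsule-shaped mitochondria (rectangle with semicircular
caps) drift with Brownian centroid motion inside the field of view. A fixed
stimulation point pulses at given frames. Each pulse drives the biosensor
channel of a mitochondrion at distance d through an immediate fractional
rise A(d) = A0 * max(0, 1 - d/d_max), a plateau, then a single-phase
exponential decay at rate K (per minute) back toward baseline. The
photosensitizer channel photobleaches by a distance-attenuated fraction at
each pulse. Mitochondria close to the stimulation point transiently
elongate. Shot (Poisson) and Gaussian read noise are applied last; ground
truth records the noiseless per-object quantities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mitopulse.io import AcquisitionMeta, MovieStack, write_csv
from mitopulse.traces import PopulationConfig, classify_population

#: extinction distance of the stimulus response per sensor microdomain (um)
MICRODOMAIN_RANGES = {"matrix": 12.0, "IMS": 6.0, "OMM": 1.0}

_PACKING_LIMIT = 0.40  # max fraction of the field covered by bounding disks


@dataclass
class SimParams:
    """Parameters of the synthetic movie generator.

    Distances/coordinates in um, times in seconds, decay rate in
    per-minute units. `stim_frames` lists (frame_index, duration_s)
    pulses; `decay_rate` may be a scalar or one rate per pulse.
    """

    image_shape: tuple[int, int] = (256, 256)  # (H, W) px
    pixel_size: float = 1.0 / 19.3  # um/px
    frame_interval: float = 5.0  # s
    n_frames: int = 230
    n_mitos: int = 10
    mito_length_range: tuple[float, float] = (0.8, 2.0)  # um, tip to tip
    mito_width_range: tuple[float, float] = (0.4, 0.6)  # um
    motion_sigma: float = 0.02  # um/frame
    stim_point: tuple[float, float] | None = None  # um; None -> image center
    stim_frames: tuple[tuple[int, float], ...] = ((36, 5.0), (150, 5.0))
    response_amplitude: float = 0.65  # A0, fractional rise at d = 0
    response_range: float = 12.0  # d_max, um (matrix sensor default)
    plateau_duration: float = 60.0  # s
    decay_rate: float | tuple[float, ...] = (0.54, 0.085)  # K, per min
    bleach_fraction: float = 0.30  # photosensitizer loss per pulse at d = 0
    elongation_factor: float = 1.3  # max major-axis stretch post-stimulus
    elongation_radius: float = 5.0  # um; mitos closer than this elongate
    elongation_duration: float = 120.0  # s of the transient stretch window
    biosensor_density: float = 300.0  # counts per px at baseline
    photosensitizer_density: float = 300.0  # counts per px at baseline
    background_offset: float = 10.0  # counts, camera floor
    noise_read_sigma: float = 2.0  # counts
    noise_shot: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if self.n_frames < 1 or self.n_mitos < 0:
            raise ValueError("n_frames must be >= 1 and n_mitos >= 0")
        for name, rng in (
            ("mito_length_range", self.mito_length_range),
            ("mito_width_range", self.mito_width_range),
        ):
            lo, hi = rng
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got {rng}")
        if self.response_range <= 0:
            raise ValueError(f"d_max must be > 0, got {self.response_range}")
        if not 0 <= self.bleach_fraction <= 1:
            raise ValueError(f"bleach_fraction must be in [0, 1], got {self.bleach_fraction}")
        if self.response_amplitude < 0:
            raise ValueError(f"A0 must be >= 0, got {self.response_amplitude}")
        if self.plateau_duration < 0:
            raise ValueError("plateau_duration must be >= 0")
        if self.motion_sigma < 0 or self.noise_read_sigma < 0:
            raise ValueError("noise/motion sigmas must be >= 0")
        if self.elongation_factor < 1:
            raise ValueError("elongation_factor must be >= 1")
        for frame, dur in self.stim_frames:
            if not 0 <= frame < self.n_frames:
                raise ValueError(
                    f"stim frame {frame} outside [0, {self.n_frames})"
                )
            if dur <= 0:
                raise ValueError("stim duration must be > 0")
        rates = self.decay_rates()
        if any(k < 0 for k in rates):
            raise ValueError("decay rates must be >= 0")

    def decay_rates(self) -> tuple[float, ...]:
        """One decay rate per stimulation pulse (scalar broadcast)."""
        k = self.decay_rate
        n = len(self.stim_frames)
        if np.isscalar(k):
            return tuple(float(k) for _ in range(n))
        k = tuple(float(v) for v in k)
        if len(k) < n:
            raise ValueError(f"need {n} decay rates, got {len(k)}")
        return k[:n]

    @property
    def field_um(self) -> tuple[float, float]:
        h, w = self.image_shape
        return (h - 1) * self.pixel_size, (w - 1) * self.pixel_size

    def resolved_stim_point(self) -> tuple[float, float]:
        if self.stim_point is not None:
            return (float(self.stim_point[0]), float(self.stim_point[1]))
        fh, fw = self.field_um
        return (fw / 2.0, fh / 2.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["stim_frames"] = [[int(f), float(s)] for f, s in self.stim_frames]
        if not np.isscalar(d["decay_rate"]):
            d["decay_rate"] = list(self.decay_rates())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        d["image_shape"] = tuple(d["image_shape"])
        d["stim_frames"] = tuple((int(f), float(s)) for f, s in d["stim_frames"])
        for key in ("mito_length_range", "mito_width_range"):
            d[key] = tuple(d[key])
        if d.get("stim_point") is not None:
            d["stim_point"] = tuple(d["stim_point"])
        if isinstance(d.get("decay_rate"), list):
            d["decay_rate"] = tuple(d["decay_rate"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True per-frame, per-mitochondrion records plus the generating params.

    `records` columns: frame, time_s, true_id, x_um, y_um, area_um2,
    perimeter_um, major_um, minor_um, dist_um, population,
    biosensor_multiplier, photosensitizer_multiplier,
    biosensor_intensity, photosensitizer_intensity (total counts,
    noiseless, background excluded).
    """

    records: pd.DataFrame
    params: SimParams

    def n_objects(self) -> int:
        return 0 if self.records.empty else self.records["true_id"].nunique()

    def frame_counts(self) -> pd.Series:
        """Number of true objects per frame."""
        if self.records.empty:
            return pd.Series(dtype=int)
        return self.records.groupby("frame")["true_id"].count()

    def distances_at(self, frame: int) -> dict:
        sub = self.records[self.records["frame"] == frame]
        return dict(zip(sub["true_id"], sub["dist_um"]))

    def write(self, directory: str | Path, stem: str = "ground_truth") -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = write_csv(self.records, directory / f"{stem}.csv")
        json_path = directory / f"{stem}_params.json"
        json_path.write_text(json.dumps(self.params.to_dict(), indent=2, sort_keys=True))
        return csv_path, json_path

    @classmethod
    def read(cls, directory: str | Path, stem: str = "ground_truth") -> "GroundTruth":
        directory = Path(directory)
        records = pd.read_csv(directory / f"{stem}.csv")
        params = SimParams.from_dict(
            json.loads((directory / f"{stem}_params.json").read_text())
        )
        return cls(records=records, params=params)


@dataclass(frozen=True)
class DoseResponseSample:
    """One cell's ratiometric response at one exogenous H2O2 concentration."""

    microdomain: str
    concentration: float  # uM
    response: float  # R/R0, dimensionless
    cell_id: int

    def __post_init__(self) -> None:
        if self.microdomain not in ("matrix", "IMS", "IBM", "OMM", "cytosol"):
            raise ValueError(f"unknown microdomain {self.microdomain!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.response <= 0:
            raise ValueError("response must be > 0")


# ---------------------------------------------------------------------------
# trace model
# ---------------------------------------------------------------------------

def simulate_trace(
    baseline: float,
    A: float,
    plateau_duration: float,
    K: float,
    t: np.ndarray,
    stim_time: float = 0.0,
) -> np.ndarray:
    """Noiseless plateau-then-single-phase-decay response.

    f(t) = baseline before `stim_time`; baseline*(1+A) on
    [stim_time, stim_time + plateau_duration); afterwards the elevation
    relaxes exponentially at K per minute:
    baseline + baseline*A*exp(-K*(t - stim_time - plateau_duration)/60).
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t must be a strictly ascending 1-D grid")
    if plateau_duration < 0:
        raise ValueError("plateau_duration must be >= 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    out = np.full_like(t, float(baseline))
    risen = t >= stim_time
    t_decay = stim_time + plateau_duration
    plateau_mask = risen & (t < t_decay)
    decay_mask = t >= t_decay
    out[plateau_mask] = baseline * (1.0 + A)
    out[decay_mask] = baseline + baseline * A * np.exp(
        -K * (t[decay_mask] - t_decay) / 60.0
    )
    return out


def _multi_pulse_multiplier(
    t: np.ndarray,
    stim_times: Sequence[float],
    amplitudes: Sequence[float],
    plateau_duration: float,
    decay_rates: Sequence[float],
) -> np.ndarray:
    """Biosensor multiplier under repeated pulses: each pulse resets the
    response to 1 + A_k, which then plateaus and decays until the next."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    for k, (t_k, A_k, K_k) in enumerate(zip(stim_times, amplitudes, decay_rates)):
        t_next = stim_times[k + 1] if k + 1 < len(stim_times) else np.inf
        seg = (t >= t_k) & (t < t_next)
        if not np.any(seg):
            continue
        out[seg] = simulate_trace(1.0, A_k, plateau_duration, K_k, t[seg], stim_time=t_k)
    return out


def distance_attenuation(d: np.ndarray | float, A0: float, d_max: float) -> np.ndarray | float:
    """Linear-with-cutoff stimulus attenuation A(d) = A0*max(0, 1 - d/d_max)."""
    d = np.asarray(d, dtype=float)
    out = A0 * np.maximum(0.0, 1.0 - d / d_max)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# geometry / rendering
# ---------------------------------------------------------------------------

def capsule_area(length: float, width: float) -> float:
    """Area of a capsule (um^2): rectangle plus the two semicircular caps."""
    r = width / 2.0
    return (length - width) * width + np.pi * r * r


def capsule_perimeter(length: float, width: float) -> float:
    return 2.0 * (length - width) + np.pi * width


def render_capsule(
    canvas: np.ndarray,
    center_um: tuple[float, float],
    length_um: float,
    width_um: float,
    angle: float,
    density: float,
    pixel_size: float,
) -> float:
    """Add an anti-aliased capsule of uniform `density` (counts/px) onto
    `canvas` in place; returns the summed rendered counts.

    Pixel coverage uses a 1-px linear ramp on the signed distance to the
    capsule boundary, which approximates area coverage to well under 1%
    for widths of a few pixels.
    """
    h, w = canvas.shape
    cx = center_um[0] / pixel_size
    cy = center_um[1] / pixel_size
    half_seg = max(length_um - width_um, 0.0) / 2.0 / pixel_size
    radius = width_um / 2.0 / pixel_size
    ux, uy = np.cos(angle), np.sin(angle)
    pad = int(np.ceil(half_seg + radius + 2))
    x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, w)
    y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, h)
    if x0 >= x1 or y0 >= y1:
        return 0.0
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - cx
    dy = ys - cy
    # distance from pixel centers to the capsule's central segment
    along = np.clip(dx * ux + dy * uy, -half_seg, half_seg)
    px = dx - along * ux
    py = dy - along * uy
    dist = np.hypot(px, py)
    coverage = np.clip(radius - dist + 0.5, 0.0, 1.0)
    patch = density * coverage
    canvas[y0:y1, x0:x1] += patch
    return float(patch.sum())


def _place_mitos(params: SimParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping capsule geometries.

    Clearance uses bounding disks at maximal (elongated) length plus the
    accumulated Brownian drift budget, so objects stay disjoint for the
    whole movie. Raises when the requested density exceeds the packing
    limit or placement fails.
    """
    fh, fw = params.field_um
    lengths = rng.uniform(*params.mito_length_range, size=params.n_mitos)
    widths = rng.uniform(*params.mito_width_range, size=params.n_mitos)
    widths = np.minimum(widths, lengths)  # capsule requires length >= width
    angles = rng.uniform(0, np.pi, size=params.n_mitos)

    drift_budget = params.motion_sigma * np.sqrt(params.n_frames) * 3.0
    bound_r = lengths * params.elongation_factor / 2.0 + drift_budget
    packing = float(np.sum(np.pi * bound_r**2)) / (fh * fw)
    if packing > _PACKING_LIMIT:
        raise ValueError(
            f"object density too high: bounding-disk packing {packing:.2f} exceeds "
            f"{_PACKING_LIMIT} and would make the segmentation oracle ill-defined"
        )

    margin = 0.3  # um of extra surface-to-surface clearance
    centers = np.zeros((params.n_mitos, 2))
    for i in range(params.n_mitos):
        for _ in range(5000):
            x = rng.uniform(bound_r[i], fw - bound_r[i])
            y = rng.uniform(bound_r[i], fh - bound_r[i])
            if i == 0:
                centers[i] = (x, y)
                break
            sep = np.hypot(centers[:i, 0] - x, centers[:i, 1] - y)
            if np.all(sep > bound_r[:i] + bound_r[i] + margin):
                centers[i] = (x, y)
                break
        else:
            raise ValueError(
                f"could not place mitochondrion {i} without overlap; "
                "reduce n_mitos or object sizes"
            )
    return centers, lengths, widths, angles


def simulate_movie(
    params: SimParams,
    population_config: PopulationConfig | None = None,
) -> tuple[MovieStack, GroundTruth]:
    """Generate a two-channel movie (channels [biosensor, photosensitizer])
    and its ground truth.

    Deterministic for a fixed `params.rng_seed`. Ground-truth population
    labels come from the distance rule applied to true distances at the
    first stimulation frame (frame 0 when there is no stimulation).
    """
    rng = np.random.default_rng(params.rng_seed)
    pop_config = population_config or PopulationConfig()
    h, w = params.image_shape
    n_frames = params.n_frames
    dt = params.frame_interval
    stim_xy = params.resolved_stim_point()
    stim_times = [f * dt for f, _ in params.stim_frames]
    decay_rates = params.decay_rates()
    times = np.arange(n_frames) * dt

    meta = AcquisitionMeta(
        pixel_size=params.pixel_size,
        frame_interval=dt,
        channel_roles={0: "biosensor_488", 1: "photosensitizer_561"},
        stim_point=stim_xy,
        stim_events=[(int(f), float(s)) for f, s in params.stim_frames],
    )

    if params.n_mitos == 0:
        signal = np.zeros((n_frames, 2, h, w), dtype=np.float32)
        movie = MovieStack(data=_apply_noise(signal, params, rng), meta=meta)
        gt = GroundTruth(records=_empty_records(), params=params)
        return movie, gt

    centers0, lengths0, widths, angles = _place_mitos(params, rng)

    # Brownian walk of centroids (um), reflecting at bounding-radius margins
    fh, fw = params.field_um
    bound_r = lengths0 * params.elongation_factor / 2.0
    steps = rng.normal(0.0, params.motion_sigma, size=(n_frames - 1, params.n_mitos, 2))
    positions = np.empty((n_frames, params.n_mitos, 2))
    positions[0] = centers0
    for t_idx in range(1, n_frames):
        pos = positions[t_idx - 1] + steps[t_idx - 1]
        for i in range(params.n_mitos):
            pos[i, 0] = _reflect(pos[i, 0], bound_r[i], fw - bound_r[i])
            pos[i, 1] = _reflect(pos[i, 1], bound_r[i], fh - bound_r[i])
        positions[t_idx] = pos

    # distances and pulse amplitudes per mito
    dists = np.hypot(positions[..., 0] - stim_xy[0], positions[..., 1] - stim_xy[1])
    ref_frame = params.stim_frames[0][0] if params.stim_frames else 0
    d_ref = dists[ref_frame]
    labels = classify_population(
        {i: d_ref[i] for i in range(params.n_mitos)}, pop_config
    )

    bio_mult = np.ones((n_frames, params.n_mitos))
    ps_mult = np.ones((n_frames, params.n_mitos))
    for i in range(params.n_mitos):
        if stim_times:
            amps = [
                distance_attenuation(dists[f, i], params.response_amplitude, params.response_range)
                for f, _ in params.stim_frames
            ]
            bio_mult[:, i] = _multi_pulse_multiplier(
                times, stim_times, amps, params.plateau_duration, decay_rates
            )
            for (f, _dur), A_frac in zip(params.stim_frames, amps):
                atten = A_frac / params.response_amplitude if params.response_amplitude > 0 else (
                    float(max(0.0, 1.0 - dists[f, i] / params.response_range))
                )
                ps_mult[f:, i] *= 1.0 - params.bleach_fraction * atten

    # transient elongation of near-spot mitochondria after the first pulse
    elong = np.ones((n_frames, params.n_mitos))
    if params.stim_frames and params.elongation_factor > 1:
        f0 = params.stim_frames[0][0]
        n_win = max(int(round(params.elongation_duration / dt)), 2)
        win = np.arange(n_win)
        profile = 1.0 + (params.elongation_factor - 1.0) * (
            1.0 - np.abs(win - (n_win - 1) / 2.0) / ((n_win - 1) / 2.0)
        )
        lo = f0 + 2
        hi = min(lo + n_win, n_frames)
        for i in range(params.n_mitos):
            if d_ref[i] < params.elongation_radius:
                elong[lo:hi, i] = profile[: hi - lo]

    # render
    signal = np.zeros((n_frames, 2, h, w), dtype=np.float32)
    rows = []
    px_area = params.pixel_size**2
    for t_idx in range(n_frames):
        for i in range(params.n_mitos):
            L = lengths0[i] * elong[t_idx, i]
            W = widths[i]
            area = capsule_area(L, W)
            perim = capsule_perimeter(L, W)
            area_px = area / px_area
            bio_total = params.biosensor_density * area_px * bio_mult[t_idx, i]
            ps_total = params.photosensitizer_density * area_px * ps_mult[t_idx, i]
            render_capsule(
                signal[t_idx, 0], tuple(positions[t_idx, i]), L, W, angles[i],
                bio_total / area_px, params.pixel_size,
            )
            render_capsule(
                signal[t_idx, 1], tuple(positions[t_idx, i]), L, W, angles[i],
                ps_total / area_px, params.pixel_size,
            )
            rows.append(
                (
                    t_idx, times[t_idx], i,
                    positions[t_idx, i, 0], positions[t_idx, i, 1],
                    area, perim, L, W, dists[t_idx, i], labels[i],
                    bio_mult[t_idx, i], ps_mult[t_idx, i], bio_total, ps_total,
                )
            )

    records = pd.DataFrame(
        rows,
        columns=[
            "frame", "time_s", "true_id", "x_um", "y_um", "area_um2",
            "perimeter_um", "major_um", "minor_um", "dist_um", "population",
            "biosensor_multiplier", "photosensitizer_multiplier",
            "biosensor_intensity", "photosensitizer_intensity",
        ],
    )
    movie = MovieStack(data=_apply_noise(signal, params, rng), meta=meta)
    return movie, GroundTruth(records=records, params=params)


def _reflect(x: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return (lo + hi) / 2.0
    span = hi - lo
    x = (x - lo) % (2.0 * span)
    return lo + (x if x <= span else 2.0 * span - x)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "frame", "time_s", "true_id", "x_um", "y_um", "area_um2",
            "perimeter_um", "major_um", "minor_um", "dist_um", "population",
            "biosensor_multiplier", "photosensitizer_multiplier",
            "biosensor_intensity", "photosensitizer_intensity",
        ]
    )


def _apply_noise(signal: np.ndarray, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Camera model: Poisson shot noise on (signal + offset) plus Gaussian
    read noise; noiseless when both are disabled. Operates in place on the
    rendered signal to keep peak memory down for long movies."""
    if params.background_offset:
        signal += params.background_offset
    if params.noise_shot:
        signal = rng.poisson(signal).astype(np.float32)
    if params.noise_read_sigma > 0:
        signal += rng.normal(0.0, params.noise_read_sigma, size=signal.shape).astype(
            signal.dtype
        )
    np.clip(signal, 0.0, None, out=signal)
    return signal


# ---------------------------------------------------------------------------
# dose-response sampling
# ---------------------------------------------------------------------------

def simulate_dose_response(
    curve,
    concentrations: Sequence[float],
    cv: float,
    n_cells: int,
    seed: int,
) -> list[DoseResponseSample]:
    """Per-cell responses from a standard curve with multiplicative
    lognormal noise of the given coefficient of variation.

    `curve` is a calibration.StandardCurve (anything with `.predict(c)`
    and `.microdomain`). cv=0 reproduces curve values exactly; a fixed
    seed reproduces the sample list exactly.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv * cv))  # lognormal CV -> log-sd, unit mean
    mu = -0.5 * sigma * sigma
    samples = []
    cell_id = 0
    for conc in concentrations:
        expected = float(curve.predict(conc))
        for _ in range(n_cells):
            factor = float(np.exp(rng.normal(mu, sigma))) if cv > 0 else 1.0
            samples.append(
                DoseResponseSample(
                    microdomain=curve.microdomain,
                    concentration=float(conc),
                    response=expected * factor,
                    cell_id=cell_id,
                )
            )
            cell_id += 1
    return samples


def dose_response_frame(samples: Sequence[DoseResponseSample]) -> pd.DataFrame:
    """Tidy frame with columns microdomain, concentration_uM, response, cell_id."""
    return pd.DataFrame(
        [
            {
                "microdomain": s.microdomain,
                "concentration_uM": s.concentration,
                "response": s.response,
                "cell_id": s.cell_id,
            }
            for s in samples
        ]
    )
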