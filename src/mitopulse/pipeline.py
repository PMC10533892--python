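"""End-to-end orchestration: simulate -> segment -> track -> quantify ->
fit -> calibrate -> report, plus self-contained test fixtures.

Every intermediate is written as tidy CSV or JSON with a stable column
order; a run manifest records the config echo, seed, input checksums,
per-stage row counts and machine-readable warnings. Reruns with the same
config and inputs are byte-identical.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mitopulse._version import __version__ as _version
from mitopulse.calibration import (
    StandardCurve,
    equivalents_table,
    fit_standard_curve,
    write_curves,
)
from mitopulse.io import MovieStack, read_movie, sha256_of, write_csv, write_movie
from mitopulse.kinetics import auc, extra_ss_f_test, fit_plateau_decay, t_half_rise
from mitopulse.segment import (
    SegmentationConfig,
    detect_artifact_frames,
    link_tracks,
    segment_movie,
    tracks_to_dataframe,
)
from mitopulse.simulate import (
    GroundTruth,
    SimParams,
    dose_response_frame,
    simulate_dose_response,
    simulate_movie,
)
from mitopulse.traces import (
    PopulationConfig,
    classify_population,
    form_factor,
    population_summary,
)


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    movie_path: str
    output_dir: str
    dose_response_path: str | None = None
    responses_path: str | None = None
    # preprocessing / segmentation
    background_radius: int = 50
    smooth_sigma: float = 2.0
    mask_channel: str = "biosensor_488"
    threshold: str | float = "otsu"
    min_area_um2: float = 0.1
    drop_artifact_frames: bool = False
    # linking
    max_disp: float = 2.0
    max_gap: int = 2
    # populations
    population_preset: str = "HEK"
    spot_radius: float = 1.5
    # normalization
    baseline_skip_frames: int = 4
    # kinetics
    t0_stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_radius < 1 or self.smooth_sigma <= 0:
            raise ValueError("invalid preprocessing parameters")
        if self.max_disp <= 0 or self.max_gap < 0:
            raise ValueError("invalid linking parameters")
        if self.baseline_skip_frames < 0:
            raise ValueError("baseline_skip_frames must be >= 0")

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            mask_channel=self.mask_channel,
            background_radius=self.background_radius,
            smooth_sigma=self.smooth_sigma,
            threshold=self.threshold,
            min_area_um2=self.min_area_um2,
        )

    def populations(self) -> PopulationConfig:
        return PopulationConfig.preset(self.population_preset, spot_radius=self.spot_radius)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def validate_paths(self) -> None:
        if not Path(self.movie_path).exists():
            raise FileNotFoundError(f"movie not found: {self.movie_path}")
        for p in (self.dose_response_path, self.responses_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")


@dataclass
class RunManifest:
    """Record of one pipeline run, written atomically at run end."""

    version: str
    seed: int
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        finally:
            if os.path.exists(tmp):
                os.unlink(tmp)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# quantification helpers (tracks -> tidy tables)
# ---------------------------------------------------------------------------

def quantify_tracks(
    tracks,
    meta,
    population_config: PopulationConfig,
    baseline_skip_frames: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Turn linked tracks into tidy normalized-trace and morphology tables.

    Returns (traces, morph, amplitudes). Traces carry per-frame dF/F of
    the biosensor and F/F0 of the photosensitizer; morphology carries
    area and form factor; amplitudes carry one row per track with its
    reference distance, population and immediate post-pulse dF/F.
    Population labels are frozen at the first stimulation frame. Tracks
    without baseline or reference-frame coverage are skipped (warned).
    """
    if not meta.stim_events:
        raise ValueError("quantification requires at least one stimulation event")
    ref_frame = int(meta.stim_events[0][0])
    base_lo = int(baseline_skip_frames)
    base_hi = ref_frame
    if base_hi <= base_lo:
        raise ValueError("no baseline frames before first stimulation")
    stim_xy = meta.stim_point
    if stim_xy is None:
        raise ValueError("stimulation point missing from metadata")

    usable = []
    ref_dist: dict[int, float] = {}
    skipped = 0
    for tr in tracks:
        frames = tr.frames()
        has_base = np.any((frames >= base_lo) & (frames < base_hi))
        at_ref = np.flatnonzero(frames == ref_frame)
        if not has_base or at_ref.size == 0:
            skipped += 1
            continue
        xy = tr.centroids()[int(at_ref[0])]
        ref_dist[tr.track_id] = float(np.hypot(xy[0] - stim_xy[0], xy[1] - stim_xy[1]))
        usable.append(tr)
    if skipped:
        warnings.warn(f"{skipped} track(s) lack baseline or reference-frame coverage")
    if not usable:
        raise ValueError("no track spans both the baseline window and the stimulation frame")

    labels = classify_population(ref_dist, population_config)

    trace_rows, morph_rows, amp_rows = [], [], []
    for tr in usable:
        frames = tr.frames()
        times = frames * meta.frame_interval
        pop = labels[tr.track_id]
        areas = tr.areas()
        perims = tr.perimeters()
        xy = tr.centroids()
        dists = np.hypot(xy[:, 0] - stim_xy[0], xy[:, 1] - stim_xy[1])
        base_mask = (frames >= base_lo) & (frames < base_hi)

        dens = {}
        for role in ("biosensor_488", "photosensitizer_561"):
            try:
                sums = tr.sum_intensity(role)
            except KeyError:
                continue
            d = sums / areas
            b = float(np.mean(d[base_mask]))
            if b <= 0:
                raise ValueError(f"track {tr.track_id}: non-positive baseline for {role}")
            dens[role] = d / b

        for i, f in enumerate(frames):
            if "biosensor_488" in dens:
                trace_rows.append(
                    (tr.track_id, int(f), float(times[i]), "dff_biosensor",
                     float(dens["biosensor_488"][i] - 1.0), pop, float(dists[i]))
                )
            if "photosensitizer_561" in dens:
                trace_rows.append(
                    (tr.track_id, int(f), float(times[i]), "ff0_photosensitizer",
                     float(dens["photosensitizer_561"][i]), pop, float(dists[i]))
                )
            morph_rows.append(
                (tr.track_id, int(f), float(times[i]), float(areas[i]),
                 float(form_factor(perims[i], areas[i])), pop)
            )

        if "biosensor_488" in dens:
            amp_mask = (frames >= ref_frame) & (frames <= ref_frame + 1)
            amp = float(np.mean(dens["biosensor_488"][amp_mask] - 1.0))
            amp_rows.append((tr.track_id, pop, ref_dist[tr.track_id], amp))

    traces = pd.DataFrame(
        trace_rows,
        columns=["track_id", "frame", "time_s", "metric", "value", "population", "dist_um"],
    ).sort_values(["metric", "track_id", "frame"], kind="stable").reset_index(drop=True)
    morph = pd.DataFrame(
        morph_rows,
        columns=["track_id", "frame", "time_s", "area_um2", "form_factor", "population"],
    ).sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    amplitudes = pd.DataFrame(
        amp_rows, columns=["track_id", "population", "dist_um", "amplitude_dff"]
    ).sort_values("track_id", kind="stable").reset_index(drop=True)
    return traces, morph, amplitudes


def population_mean_traces(traces: pd.DataFrame, metric: str = "dff_biosensor") -> pd.DataFrame:
    """Per-frame mean value per population for one metric."""
    sub = traces[traces["metric"] == metric]
    out = (
        sub.groupby(["population", "frame"], sort=True)
        .agg(time_s=("time_s", "first"), value=("value", "mean"), n=("value", "count"))
        .reset_index()
    )
    return out


def fit_population_kinetics(
    traces: pd.DataFrame, meta, t0_stride: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Plateau-decay fits, T1/2 and AUC of per-population mean dF/F traces,
    one fit window per stimulation pulse; plus an F-test report comparing
    pulse-1 vs pulse-2 decay of the most proximal responding population."""
    dt = meta.frame_interval
    pulses = [(int(f) * dt, None) for f, _ in meta.stim_events]
    ends = [p[0] for p in pulses[1:]] + [np.inf]
    means = population_mean_traces(traces)

    rows = []
    windows: dict[tuple[str, int], tuple[np.ndarray, np.ndarray, float]] = {}
    for pop, grp in means.groupby("population", sort=True):
        t = grp["time_s"].to_numpy()
        v = grp["value"].to_numpy()
        for k, ((t_stim, _), t_end) in enumerate(zip(pulses, ends), start=1):
            sel = (t >= t_stim) & (t < t_end)
            if np.sum(sel) < 8:
                continue
            tw, vw = t[sel], v[sel]
            windows[(pop, k)] = (tw, vw, t_stim)
            fit = fit_plateau_decay((tw, vw), stim_time=t_stim, t0_stride=t0_stride)
            try:
                rise = t_half_rise((np.concatenate([t[t < t_stim], tw]),
                                    np.concatenate([v[t < t_stim], vw])), stim_time=t_stim)
                t_half = rise.T_half
                peak = rise.peak_value
            except ValueError:
                t_half, peak = np.nan, float(np.max(vw))
            area = auc((tw, vw), (float(tw[0]), float(tw[-1])), baseline_ref=0.0)
            rows.append(
                (pop, k, fit.plateau, fit.t0 - t_stim, fit.K, fit.baseline,
                 fit.RSS, fit.n, fit.converged, t_half, peak, area)
            )
    fits = pd.DataFrame(
        rows,
        columns=["population", "pulse", "plateau", "t0_s", "K_per_min", "baseline",
                 "RSS", "n", "converged", "t_half_s", "peak_dff", "auc"],
    )

    report: dict = {}
    for pop in ("spot", "proximal"):
        if (pop, 1) in windows and (pop, 2) in windows:
            tA, vA, sA = windows[(pop, 1)]
            tB, vB, sB = windows[(pop, 2)]
            res = extra_ss_f_test([(tA - sA, vA)], [(tB - sB, vB)], stim_time=0.0)
            report = {
                "population": pop,
                "comparison": "pulse1_vs_pulse2_decay",
                "F": res.F, "df_num": res.df_num, "df_den": res.df_den,
                "p": res.p, "RSS_shared": res.RSS_shared, "RSS_separate": res.RSS_separate,
            }
            break
    return fits, report


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage on the configured inputs; returns the manifest.

    Stage order: load -> (artifact screen) -> segment -> link -> quantify
    -> kinetics -> calibrate. Each stage's output is CSV/JSON in
    `config.output_dir`; any stage failure aborts with the stage named.
    """
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=_version, seed=config.seed, config=config.to_dict())
    for p in (config.movie_path, config.dose_response_path, config.responses_path):
        if p:
            manifest.input_checksums[str(p)] = sha256_of(p)

    stage = "load"
    try:
        movie = read_movie(config.movie_path)
        manifest.row_counts["frames"] = movie.n_frames

        stage = "artifact-screen"
        dropped: list[int] = []
        if config.drop_artifact_frames:
            dropped = detect_artifact_frames(movie)
            if dropped:
                manifest.warnings.append(f"dropped artifact frame {dropped[0]}")
        manifest.row_counts["dropped_frames"] = len(dropped)

        stage = "segment"
        per_frame = segment_movie(movie, config.segmentation(), drop_frames=dropped)
        manifest.row_counts["measurements"] = int(sum(len(f) for f in per_frame))

        stage = "link"
        tracks = link_tracks(per_frame, max_disp=config.max_disp, max_gap=config.max_gap)
        manifest.row_counts["tracks"] = len(tracks)
        tracks_df = tracks_to_dataframe(tracks, movie.meta.frame_interval)
        write_csv(tracks_df, out_dir / "tracks.csv")

        stage = "quantify"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            traces, morph, amplitudes = quantify_tracks(
                tracks, movie.meta, config.populations(), config.baseline_skip_frames
            )
            summary = population_summary(
                traces[traces["metric"] == "dff_biosensor"], smooth_window=3
            )
        manifest.warnings.extend(str(w.message) for w in caught)
        write_csv(traces, out_dir / "traces.csv")
        write_csv(morph, out_dir / "morphology.csv")
        write_csv(amplitudes, out_dir / "amplitudes.csv")
        write_csv(summary, out_dir / "population_summary.csv")
        manifest.row_counts["trace_rows"] = len(traces)
        manifest.row_counts["quantified_tracks"] = int(amplitudes["track_id"].nunique())

        stage = "kinetics"
        fits, ftest = fit_population_kinetics(traces, movie.meta, config.t0_stride)
        write_csv(fits, out_dir / "kinetics.csv")
        (out_dir / "ftest.json").write_text(json.dumps(ftest, indent=2, sort_keys=True))
        manifest.row_counts["kinetic_fits"] = len(fits)

        stage = "calibrate"
        if config.dose_response_path:
            dose = pd.read_csv(config.dose_response_path)
            curves: dict[str, StandardCurve] = {}
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                for md in sorted(dose["microdomain"].unique()):
                    curves[md] = fit_standard_curve(dose, md)
            manifest.warnings.extend(str(w.message) for w in caught)
            write_curves(curves, out_dir / "curves.json")
            manifest.row_counts["curves"] = len(curves)
            if config.responses_path:
                responses = pd.read_csv(config.responses_path)
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    table, summ = equivalents_table(responses, curves)
                manifest.warnings.extend(str(w.message) for w in caught)
                write_csv(table, out_dir / "equivalents.csv")
                write_csv(summ, out_dir / "equivalents_summary.csv")
                manifest.row_counts["equivalents"] = len(table)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: generating curves of the bundled dose-response fixture, one per microdomain
FIXTURE_CURVES = {
    "matrix": dict(bottom=1.0, top=6.0, EC50=1.5, hill=1.2),
    "IMS": dict(bottom=1.0, top=4.5, EC50=1.2, hill=1.1),
    "OMM": dict(bottom=1.0, top=5.0, EC50=1.8, hill=1.3),
}

#: true exogenous-equivalent concentrations (uM) of the fixture response cohort
FIXTURE_EQUIVALENTS = {"matrix": 1.0, "IMS": 0.8, "OMM": 1.0}

FIXTURE_CONCENTRATIONS = (0.0, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0)


def fixture_sim_params(size: str, seed: int) -> SimParams:
    """Noiseless generator settings of the bundled fixtures."""
    if size == "tiny":
        return SimParams(
            image_shape=(192, 192), n_frames=20, n_mitos=6,
            mito_length_range=(0.7, 1.4), mito_width_range=(0.4, 0.5),
            motion_sigma=0.01, stim_frames=((6, 5.0),), decay_rate=0.54,
            plateau_duration=30.0, elongation_duration=30.0,
            noise_shot=False, noise_read_sigma=0.0, rng_seed=seed,
        )
    if size == "standard":
        return SimParams(
            image_shape=(512, 512), n_frames=230, n_mitos=20,
            mito_length_range=(0.7, 1.6), mito_width_range=(0.4, 0.55),
            motion_sigma=0.015, stim_frames=((36, 5.0), (150, 5.0)),
            decay_rate=(0.54, 0.085), plateau_duration=60.0,
            elongation_factor=1.25,
            noise_shot=False, noise_read_sigma=0.0, rng_seed=seed,
        )
    raise ValueError(f"unknown fixture size {size!r}; choose 'tiny' or 'standard'")


def make_fixture(size: str, seed: int, out_dir: str | Path) -> Path:
    """Write a self-contained synthetic dataset: movie + metadata sidecar,
    ground truth, dose-response samples, and a per-cell response cohort
    with known equivalents. Deterministic per (size, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = fixture_sim_params(size, seed)
    movie, gt = simulate_movie(params)
    write_movie(movie, out_dir / "movie.tif")
    gt.write(out_dir)

    all_samples = []
    response_rows = []
    rng = np.random.default_rng(seed + 1)
    for i, (md, pars) in enumerate(sorted(FIXTURE_CURVES.items())):
        curve = StandardCurve(microdomain=md, R2=1.0, **pars)
        all_samples.extend(
            simulate_dose_response(
                curve, FIXTURE_CONCENTRATIONS, cv=0.05, n_cells=6, seed=seed + 10 + i
            )
        )
        c_true = FIXTURE_EQUIVALENTS[md]
        expected = curve.predict(c_true)
        noise = rng.normal(0.0, 0.05 * (expected - curve.bottom), size=8)
        for cell, eps in enumerate(noise):
            response_rows.append(
                {"microdomain": md, "cell_id": cell, "response": expected + eps,
                 "true_equivalent_uM": c_true}
            )
    write_csv(dose_response_frame(all_samples), out_dir / "dose_response.csv")
    write_csv(pd.DataFrame(response_rows), out_dir / "responses.csv")

    info = {
        "size": size,
        "seed": seed,
        "checksums": {
            p.name: sha256_of(p)
            for p in sorted(out_dir.iterdir())
            if p.suffix in (".tif", ".csv", ".json") and p.name != "fixture.json"
        },
    }
    (out_dir / "fixture.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    return out_dir


def fixture_config(fixture_dir: str | Path, output_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """Default pipeline configuration for a directory written by make_fixture."""
    fixture_dir = Path(fixture_dir)
    return PipelineConfig(
        movie_path=str(fixture_dir / "movie.tif"),
        output_dir=str(output_dir),
        dose_response_path=str(fixture_dir / "dose_response.csv"),
        responses_path=str(fixture_dir / "responses.csv"),
        seed=seed,
    )
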