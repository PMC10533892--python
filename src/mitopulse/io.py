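"""Movie container and multi-page TIFF + JSON sidecar I/O.

Movies are stored frame-major with channels interleaved per frame
(page order: frame0/ch0, frame0/ch1, frame1/ch0, ...), 16-bit unsigned.
Acquisition metadata (pixel size, frame interval, channel roles,
stimulation geometry/events) lives in a JSON sidecar next to the TIFF.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

#: recognised channel roles
CHANNEL_ROLES = ("biosensor_488", "biosensor_405", "photosensitizer_561", "dye")


@dataclass
class AcquisitionMeta:
    """Acquisition metadata for a two-channel time-lapse movie.

    Parameters
    ----------
    pixel_size : float
        Physical pixel size in um/px.
    frame_interval : float
        Time between frames in seconds.
    channel_roles : dict[int, str]
        Maps channel index to one of :data:`CHANNEL_ROLES`.
    stim_point : tuple[float, float] or None
        (x, y) of the fixed stimulation point in um (image coordinates,
        origin at the top-left pixel center).
    stim_events : list[tuple[int, float]]
        (frame_index, duration_s) for every stimulation pulse.
    """

    pixel_size: float
    frame_interval: float
    channel_roles: dict[int, str] = field(default_factory=dict)
    stim_point: tuple[float, float] | None = None
    stim_events: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        for role in self.channel_roles.values():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")

    def validate_against(self, n_frames: int) -> None:
        for frame, _dur in self.stim_events:
            if not 0 <= frame < n_frames:
                raise ValueError(
                    f"stimulation frame {frame} outside movie of {n_frames} frames"
                )

    def channel_index(self, role: str) -> int:
        """Return the channel index playing `role`."""
        for idx, r in self.channel_roles.items():
            if r == role:
                return int(idx)
        raise KeyError(f"no channel with role {role!r}")

    def stim_times(self) -> list[float]:
        """Stimulation onset times in seconds."""
        return [frame * self.frame_interval for frame, _ in self.stim_events]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_roles"] = {str(k): v for k, v in self.channel_roles.items()}
        d["stim_point"] = list(self.stim_point) if self.stim_point is not None else None
        d["stim_events"] = [[int(f), float(s)] for f, s in self.stim_events]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(
            pixel_size=float(d["pixel_size"]),
            frame_interval=float(d["frame_interval"]),
            channel_roles={int(k): v for k, v in d.get("channel_roles", {}).items()},
            stim_point=tuple(d["stim_point"]) if d.get("stim_point") else None,
            stim_events=[(int(f), float(s)) for f, s in d.get("stim_events", [])],
        )


@dataclass
class MovieStack:
    """Multi-channel, multi-frame image stack plus acquisition metadata.

    `data` has shape (n_frames, n_channels, height, width).
    """

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(
                f"movie data must be (frames, channels, H, W), got shape {self.data.shape}"
            )
        self.meta.validate_against(self.n_frames)

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.data.shape[2]), int(self.data.shape[3])

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) * self.meta.frame_interval

    def channel(self, role: str) -> np.ndarray:
        """All frames of the channel with the given role, shape (T, H, W)."""
        return self.data[:, self.meta.channel_index(role)]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a movie as multi-page TIFF with a JSON metadata sidecar.

    Data are clipped to [0, 65535] and stored as uint16. Returns the
    TIFF path; the sidecar sits next to it with a .json suffix.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_frames, n_channels, h, w = movie.data.shape

    def pages():
        # page-at-a-time conversion keeps peak memory flat for long movies
        for f in range(n_frames):
            for c in range(n_channels):
                page = movie.data[f, c]
                if page.dtype != np.uint16:
                    page = np.clip(np.rint(page), 0, np.iinfo(np.uint16).max).astype(
                        np.uint16
                    )
                yield page

    tifffile.imwrite(
        path,
        pages(),
        shape=(n_frames * n_channels, h, w),
        dtype=np.uint16,
        photometric="minisblack",
    )
    sidecar = {
        "n_frames": n_frames,
        "n_channels": n_channels,
        "height": h,
        "width": w,
        "meta": movie.meta.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a movie written by :func:`write_movie` (TIFF + JSON sidecar)."""
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    pages = tifffile.imread(path)
    n_frames = int(sidecar["n_frames"])
    n_channels = int(sidecar["n_channels"])
    data = np.asarray(pages).reshape(
        n_frames, n_channels, int(sidecar["height"]), int(sidecar["width"])
    )
    meta = AcquisitionMeta.from_dict(sidecar["meta"])
    # keep the stored dtype; stages cast frame-by-frame as needed
    return MovieStack(data=data, meta=meta)


def sha256_of(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_csv(df, path: str | Path, float_format: str = "%.10g") -> Path:
    """Deterministic CSV writer used for every tabular output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format, lineterminator="\n")
    return path
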