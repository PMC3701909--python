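"""Shared containers for single-molecule tracking and kinetics.

Coordinates follow the convention: pixel origin at the center of the
top-left pixel, frames 0-based, world coordinates in micrometers with
``x_um = x_px * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

# Per-frame mobility / visibility states.
FREE = "FREE"
BOUND = "BOUND"
BLEACHED = "BLEACHED"
UNKNOWN = "UNKNOWN"

# End causes of a bound interval.
UNBIND = "unbind"
BLEACH = "bleach"
MOVIE_END = "movie_end"


class InvalidMetadataError(ValueError):
    """Raised when acquisition metadata violates its invariants."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Camera acquisition settings.

    Parameters
    ----------
    frame_interval:
        Time between frame starts, seconds.
    exposure_time:
        Integration time per frame, seconds; must not exceed the frame
        interval.
    pixel_size:
        Lateral pixel size, micrometers (default 0.105, a typical EM-CCD
        pixel back-projected through a 100x TIRF objective).
    field_size:
        (height, width) of the field in pixels.
    n_frames:
        Number of frames in the movie.
    """

    frame_interval: float
    exposure_time: float
    pixel_size: float = 0.105
    field_size: tuple[int, int] = (64, 64)
    n_frames: int = 100

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise InvalidMetadataError("frame_interval must be positive")
        if self.exposure_time <= 0:
            raise InvalidMetadataError("exposure_time must be positive")
        if self.exposure_time > self.frame_interval + 1e-15:
            raise InvalidMetadataError("exposure_time must be <= frame_interval")
        if self.pixel_size <= 0:
            raise InvalidMetadataError("pixel_size must be positive")
        if min(self.field_size) < 16:
            raise InvalidMetadataError("field_size must be at least 16x16 pixels")
        if self.n_frames < 1:
            raise InvalidMetadataError("n_frames must be >= 1")

    @property
    def field_um(self) -> tuple[float, float]:
        """Field extent (height, width) in micrometers."""
        return (self.field_size[0] * self.pixel_size,
                self.field_size[1] * self.pixel_size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class Track:
    """One particle trajectory: ordered (frame, t, x, y) samples."""

    track_id: int
    frame: np.ndarray          # int frame indices, strictly increasing
    t_s: np.ndarray            # seconds
    x_um: np.ndarray
    y_um: np.ndarray
    intensity: np.ndarray | None = None
    state: np.ndarray | None = None   # per-sample mobility label (object dtype)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if np.any(np.diff(self.frame) <= 0):
            raise ValueError("frames must be strictly increasing within a track")
        n = len(self.frame)
        if not (len(self.t_s) == len(self.x_um) == len(self.y_um) == n):
            raise ValueError("track arrays must have equal length")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TrackSet:
    """A collection of tracks plus the acquisition metadata they share."""

    tracks: list[Track]
    meta: AcquisitionMeta

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            df = pd.DataFrame({
                "track_id": tr.track_id,
                "frame": tr.frame,
                "t_s": tr.t_s,
                "x_um": tr.x_um,
                "y_um": tr.y_um,
            })
            df["state"] = tr.state if tr.state is not None else ""
            rows.append(df)
        if not rows:
            return pd.DataFrame(
                columns=["track_id", "frame", "t_s", "x_um", "y_um", "state"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: AcquisitionMeta) -> "TrackSet":
        tracks = []
        for tid, g in df.groupby("track_id", sort=True):
            g = g.sort_values("frame")
            state = None
            if "state" in g and g["state"].astype(str).str.len().max() > 0:
                state = g["state"].astype(str).to_numpy()
            tracks.append(Track(int(tid), g["frame"].to_numpy(),
                                g["t_s"].to_numpy(), g["x_um"].to_numpy(),
                                g["y_um"].to_numpy(), state=state))
        return cls(tracks, meta)


@dataclass
class BoundInterval:
    """One ground-truth bound episode of a simulated molecule."""

    track_id: int
    start_s: float
    end_s: float
    end_cause: str   # one of UNBIND, BLEACH, MOVIE_END

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class GroundTruth:
    """Per-frame state labels and true intervals/change points.

    The oracle for every downstream stage: the simulators record what
    actually happened so detection, classification and kinetic fits can be
    scored without real data.
    """

    labels: dict[int, np.ndarray] = field(default_factory=dict)
    intervals: list[BoundInterval] = field(default_factory=list)
    change_times: np.ndarray | None = None     # seconds, for traces
    change_levels: np.ndarray | None = None    # counts, len = changes + 1

    def bound_durations(self, causes: Sequence[str] | None = None) -> np.ndarray:
        ivs = self.intervals
        if causes is not None:
            ivs = [iv for iv in ivs if iv.end_cause in causes]
        return np.array([iv.duration for iv in ivs])


@dataclass
class DwellSample:
    """Bound-state durations with right-censoring flags."""

    durations: np.ndarray
    censored: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations and censored must have equal length")
        if np.any(self.durations < 0):
            raise ValueError("durations must be non-negative")

    def __len__(self) -> int:
        return len(self.durations)

    @property
    def uncensored(self) -> np.ndarray:
        return self.durations[~self.censored]


@dataclass
class IntensityTrace:
    """Background-subtracted integrated counts per frame for one feature."""

    times: np.ndarray
    counts: np.ndarray
    background_mean: float = 0.0
    background_sd: float = 0.0
    partial: bool = False    # True when the integration window clipped the field

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        finite_t = self.times[np.isfinite(self.times)]
        if len(finite_t) > 1 and np.any(np.diff(finite_t) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)
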