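"""Readers and writers for the package's text/TIFF artifacts.

CSV files carry a first-line header comment ``# smkin-csv v1 {...}`` whose
JSON payload embeds the seed and parameters that produced the file, so any
artifact can be regenerated. JSON is used for scalar summaries and channel
maps; movies are multi-page 16-bit grayscale TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import AcquisitionMeta, DwellSample, IntensityTrace, TrackSet
from .registration import ChannelMap
from .sim import CameraNoise, FrameStack

__all__ = [
    "SchemaError", "write_tracks_csv", "read_tracks_csv",
    "write_dwells_csv", "read_dwells_csv", "write_trace_csv",
    "read_trace_csv", "write_changepoints_csv", "write_map_json",
    "read_map_json", "write_escape_csv", "read_escape_csv",
    "write_stack_tiff", "read_stack_tiff", "write_json", "read_json",
]

_MAGIC = "# smkin-csv v1 "

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "state"]
DWELL_COLUMNS = ["duration_s", "censored", "condition"]
TRACE_COLUMNS = ["t_s", "counts"]
CHANGEPOINT_COLUMNS = ["index", "t_s", "level_before", "level_after",
                       "log_odds"]
ESCAPE_COLUMNS = ["tau_off", "cluster_n", "k_on", "tau_esc_mean", "ratio",
                  "n_rebinds_mean"]


class SchemaError(ValueError):
    """A CSV artifact is missing required columns."""


def _write_csv(path, df: pd.DataFrame, header: dict) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_MAGIC + json.dumps(header, sort_keys=True) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path, required: list[str]) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    header: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_MAGIC):
            header = json.loads(first[len(_MAGIC):])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df, header


def _meta_dict(meta: AcquisitionMeta) -> dict:
    return {"frame_interval": meta.frame_interval,
            "exposure_time": meta.exposure_time,
            "pixel_size": meta.pixel_size,
            "field_size": list(meta.field_size),
            "n_frames": meta.n_frames}


def _meta_from_dict(d: dict) -> AcquisitionMeta:
    return AcquisitionMeta(d["frame_interval"], d["exposure_time"],
                           d["pixel_size"], tuple(d["field_size"]),
                           d["n_frames"])


def write_tracks_csv(path, tracks: TrackSet, params: dict | None = None
                     ) -> None:
    header = dict(params or {})
    header["meta"] = _meta_dict(tracks.meta)
    _write_csv(path, tracks.to_dataframe(), header)


def read_tracks_csv(path) -> TrackSet:
    df, header = _read_csv(path, [c for c in TRACK_COLUMNS if c != "state"])
    if "meta" not in header:
        raise SchemaError(f"{path}: header lacks acquisition metadata")
    return TrackSet.from_dataframe(df, _meta_from_dict(header["meta"]))


def write_dwells_csv(path, dwells: DwellSample, params: dict | None = None
                     ) -> None:
    df = pd.DataFrame({"duration_s": dwells.durations,
                       "censored": dwells.censored.astype(int),
                       "condition": dwells.source})
    _write_csv(path, df, dict(params or {}))


def read_dwells_csv(path) -> DwellSample:
    df, _ = _read_csv(path, DWELL_COLUMNS)
    cond = str(df["condition"].iloc[0]) if len(df) else ""
    return DwellSample(df["duration_s"].to_numpy(),
                       df["censored"].to_numpy().astype(bool), cond)


def write_trace_csv(path, trace: IntensityTrace, params: dict | None = None
                    ) -> None:
    df = pd.DataFrame({"t_s": trace.times, "counts": trace.counts})
    hdr = dict(params or {})
    hdr["partial"] = bool(trace.partial)
    _write_csv(path, df, hdr)


def read_trace_csv(path) -> IntensityTrace:
    df, hdr = _read_csv(path, TRACE_COLUMNS)
    return IntensityTrace(df["t_s"].to_numpy(), df["counts"].to_numpy(),
                          partial=bool(hdr.get("partial", False)))


def write_changepoints_csv(path, cps, times: np.ndarray,
                           params: dict | None = None) -> None:
    """Change points as CSV; ``times`` maps frame indices to seconds."""
    rows = {"index": cps.indices,
            "t_s": np.asarray(times)[cps.indices] if len(cps.indices) else [],
            "level_before": cps.levels[:-1] if cps.n_changes else [],
            "level_after": cps.levels[1:] if cps.n_changes else [],
            "log_odds": cps.log_odds}
    _write_csv(path, pd.DataFrame(rows), dict(params or {}))


def write_map_json(path, cmap: ChannelMap, params: dict | None = None) -> None:
    d = cmap.to_dict()
    d.update(params or {})
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_map_json(path) -> ChannelMap:
    return ChannelMap.from_dict(json.loads(Path(path).read_text()))


def write_escape_csv(path, table: pd.DataFrame, params: dict | None = None
                     ) -> None:
    _write_csv(path, table, dict(params or {}))


def read_escape_csv(path) -> pd.DataFrame:
    df, _ = _read_csv(path, ESCAPE_COLUMNS)
    return df


def write_stack_tiff(path, stack: FrameStack) -> None:
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    meta = {"smkin": _meta_dict(stack.meta)}
    tifffile.imwrite(path, data, metadata=meta)


def read_stack_tiff(path, meta: AcquisitionMeta | None = None) -> FrameStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        if meta is None:
            md = (tf.shaped_metadata or [{}])[0].get("smkin")
            if md is None:
                raise SchemaError(f"{path}: no embedded acquisition metadata; "
                                  "pass meta explicitly")
            meta = _meta_from_dict(md)
    if data.ndim == 2:
        data = data[None]
    return FrameStack(data, meta, CameraNoise())


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
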