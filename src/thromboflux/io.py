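"""File formats: multi-page TIFF stacks, trace/track/fit CSVs.

Image stacks are stored as 16-bit unsigned multi-page TIFF, one page per
frame, with per-frame timestamps in a sidecar CSV (columns: frame_index,
time_s) named ``<stem>_timestamps.csv`` next to the TIFF.  Kinetic
traces, thrombus tracks and fit results are plain CSV so they diff and
version cleanly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinetics import KineticSummary, KineticTrace
from .quant import ThrombusTrack
from .synth import Geometry, ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "timestamp_path",
    "write_trace_csv",
    "read_trace_csv",
    "write_tracks_csv",
    "write_fit_results_csv",
]


def timestamp_path(tiff_path: str | Path) -> Path:
    p = Path(tiff_path)
    return p.with_name(p.stem + "_timestamps.csv")


def write_stack(stack: ImageStack, tiff_path: str | Path) -> None:
    """Write a stack as multi-page uint16 TIFF plus a timestamp sidecar CSV."""
    tiff_path = Path(tiff_path)
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.rint(frames.astype(float)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(tiff_path, frames, metadata={
        "pixel_size_um": stack.geometry.pixel_size_um,
        "flow_axis": stack.geometry.flow_axis,
    })
    pd.DataFrame({
        "frame_index": np.arange(len(stack)),
        "time_s": stack.time_s,
    }).to_csv(timestamp_path(tiff_path), index=False)


def read_stack(tiff_path: str | Path, pixel_size_um: float | None = None) -> ImageStack:
    """Read a multi-page TIFF and its timestamp sidecar back into a stack."""
    tiff_path = Path(tiff_path)
    with tifffile.TiffFile(tiff_path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    ts_file = timestamp_path(tiff_path)
    if not ts_file.exists():
        raise FileNotFoundError(f"timestamp sidecar not found: {ts_file}")
    ts = pd.read_csv(ts_file).sort_values("frame_index")
    if len(ts) != frames.shape[0]:
        raise ValueError("timestamp sidecar length disagrees with TIFF page count")
    if pixel_size_um is None:
        pixel_size_um = float(meta.get("pixel_size_um", 1.0))
    geometry = Geometry(
        height_px=frames.shape[1],
        width_px=frames.shape[2],
        pixel_size_um=pixel_size_um,
        flow_axis=str(meta.get("flow_axis", "along_columns")),
    )
    return ImageStack(frames=frames, time_s=ts["time_s"].to_numpy(float),
                      geometry=geometry)


def write_trace_csv(trace: KineticTrace, path: str | Path, roi_tag: str = "full") -> None:
    pd.DataFrame({
        "time_s": trace.time_s,
        "value": trace.value,
        "metric": trace.metric,
        "source": trace.source,
        "roi_tag": roi_tag,
    }).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> KineticTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    metric = str(df["metric"].iloc[0]) if "metric" in df.columns else "TFI"
    source = str(df["source"].iloc[0]) if "source" in df.columns else "all_thrombi"
    return KineticTrace(
        time_s=df["time_s"].to_numpy(float),
        value=df["value"].to_numpy(float),
        metric=metric,
        source=source,
    )


def write_tracks_csv(
    tracks: list[ThrombusTrack], time_s: np.ndarray, path: str | Path
) -> None:
    rows = []
    for tr in tracks:
        for k in range(tr.n_frames):
            frame = tr.first_frame + k
            rows.append({
                "track_id": tr.id,
                "frame": frame,
                "time_s": float(time_s[frame]),
                "area_px": tr.area_px[k],
                "area_um2": tr.area_um2[k],
                "intensity": tr.intensity[k],
                "centroid_row": tr.centroid[k][0],
                "centroid_col": tr.centroid[k][1],
                "eligible": tr.eligible_central_third,
            })
    pd.DataFrame(rows, columns=[
        "track_id", "frame", "time_s", "area_px", "area_um2", "intensity",
        "centroid_row", "centroid_col", "eligible",
    ]).to_csv(path, index=False)


def write_fit_results_csv(
    summaries: list[tuple[str, str, str, KineticSummary]], path: str | Path
) -> pd.DataFrame:
    """Write per-channel fit endpoints.

    ``summaries`` holds (channel_label, metric, source, summary) tuples;
    the emitted columns are channel, metric, source, A, B, C,
    discriminant, r2, lag_s, lag_quality, rapid_slope, max_value.
    """
    rows = []
    for channel, metric, source, s in summaries:
        rows.append({
            "channel": channel,
            "metric": metric,
            "source": source,
            "A": s.fit.A,
            "B": s.fit.B,
            "C": s.fit.C,
            "discriminant": s.fit.discriminant,
            "r2": s.fit.r2,
            "lag_s": s.lag_time_s,
            "lag_quality": s.lag_quality.value,
            "rapid_slope": s.rapid_slope,
            "max_value": s.max_value,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
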