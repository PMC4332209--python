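"""Frame quantification: TFI, TAC, thrombus segmentation and tracking.

Two whole-field metrics summarize each frame of a perfusion time-lapse:

* **TFI** (total fluorescent intensity) -- the background-subtracted sum
  of pixel intensities in the region of interest; a proxy for total
  platelet/thrombus mass including growth in the z-plane.
* **TAC** (total area covered) -- the number (and µm² equivalent) of
  pixels at or above a threshold; a proxy for thrombus spread in the
  x,y-plane.

Individual thrombi are segmented per frame as 8-connected components of
the thresholded mask and linked across frames by maximal pixel overlap.
To control for edge effects of shear along the channel walls, only
thrombi whose mean centroid lies within the vertical middle third of the
channel width are selected for kinetic analysis.

Conventions used throughout: 0-based (row, col) pixel coordinates,
half-open regions of interest, flow along columns and channel width
along rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.measure import regionprops

from .kinetics import KineticTrace
from .synth import Geometry, ImageStack

__all__ = [
    "ROI",
    "ThrombusTrack",
    "total_fluorescent_intensity",
    "total_area_covered",
    "central_third_roi",
    "segment_thrombi",
    "track_thrombi",
    "select_analysis_thrombi",
    "stack_to_traces",
    "estimate_background",
    "default_threshold",
]

#: components smaller than this many pixels are discarded (single-pixel
#: noise robustness at 8-connectivity)
DEFAULT_MIN_AREA_PX = 4


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based, half-open."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_stop
                and 0 <= self.col_start < self.col_stop):
            raise ValueError("ROI bounds must satisfy 0 <= start < stop")

    def validate_against(self, frame: np.ndarray) -> None:
        if self.row_stop > frame.shape[0] or self.col_stop > frame.shape[1]:
            raise ValueError(
                f"ROI {self} exceeds frame shape {frame.shape}")

    def crop(self, frame: np.ndarray) -> np.ndarray:
        self.validate_against(frame)
        return frame[self.row_start:self.row_stop, self.col_start:self.col_stop]

    @staticmethod
    def full(frame_or_geometry) -> "ROI":
        if isinstance(frame_or_geometry, Geometry):
            h, w = frame_or_geometry.height_px, frame_or_geometry.width_px
        else:
            h, w = frame_or_geometry.shape[:2]
        return ROI(0, h, 0, w)

    def contains_row(self, row: float) -> bool:
        return self.row_start <= row < self.row_stop


@dataclass
class ThrombusTrack:
    """One segmented thrombus followed over contiguous frames."""

    id: int
    first_frame: int
    area_px: list[int] = field(default_factory=list)
    area_um2: list[float] = field(default_factory=list)
    intensity: list[float] = field(default_factory=list)
    centroid: list[tuple[float, float]] = field(default_factory=list)  # (row, col)
    eligible_central_third: bool = False

    @property
    def last_frame(self) -> int:
        return self.first_frame + len(self.area_px) - 1

    @property
    def n_frames(self) -> int:
        return len(self.area_px)

    @property
    def mean_centroid(self) -> tuple[float, float]:
        arr = np.asarray(self.centroid, dtype=float)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())

    def to_trace(self, time_s: np.ndarray, metric: str = "TFI") -> KineticTrace:
        """Per-thrombus kinetic trace (TFI from intensity, TAC from area)."""
        t = np.asarray(time_s, dtype=float)[self.first_frame:self.last_frame + 1]
        values = self.intensity if metric == "TFI" else self.area_um2
        return KineticTrace(time_s=t, value=np.asarray(values, dtype=float),
                            metric=metric, source="individual_thrombus")


def total_fluorescent_intensity(
    frame: np.ndarray, roi: ROI, background: float = 0.0
) -> float:
    """TFI: sum over ROI pixels of max(pixel - background, 0)."""
    if background < 0:
        raise ValueError("background must be nonnegative")
    sub = roi.crop(np.asarray(frame, dtype=float))
    return float(np.maximum(sub - background, 0.0).sum())


def total_area_covered(
    frame: np.ndarray, roi: ROI, threshold: float, pixel_size_um: float = 1.0
) -> tuple[int, float]:
    """TAC: (pixel count at/above threshold, that area in µm²)."""
    sub = roi.crop(np.asarray(frame, dtype=float))
    area_px = int((sub >= threshold).sum())
    return area_px, area_px * pixel_size_um**2


def central_third_roi(geometry: Geometry) -> ROI:
    """Vertical middle third of the channel width (rows), all columns.

    Rows [floor(H/3), H - floor(H/3)), so the region always contains at
    least H/3 rows; the lower boundary row is included (half-open rule).
    """
    h = geometry.height_px
    if h < 3:
        raise ValueError("channel height must be at least 3 px")
    third = h // 3
    return ROI(third, h - third, 0, geometry.width_px)


def estimate_background(stack: ImageStack, roi: ROI | None = None) -> float:
    """Background estimate: median of the first frame within the ROI."""
    roi = roi or ROI.full(stack.geometry)
    return float(np.median(roi.crop(stack.frames[0].astype(float))))


def default_threshold(stack: ImageStack, roi: ROI | None = None) -> float:
    """Global TAC/segmentation threshold: Otsu on the final frame.

    Computed once on the last frame (where signal is strongest) and
    applied to all frames, keeping TAC comparable across time.  Falls
    back to background + 1 if the final frame is constant.
    """
    roi = roi or ROI.full(stack.geometry)
    sub = roi.crop(stack.frames[-1].astype(float))
    if np.ptp(sub) == 0:
        return float(sub.flat[0]) + 1.0
    return float(threshold_otsu(sub))


def segment_thrombi(
    frame: np.ndarray,
    threshold: float,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> np.ndarray:
    """Label 8-connected components of the thresholded mask.

    Components smaller than ``min_area_px`` are discarded; surviving
    labels are renumbered 1..K.
    """
    mask = np.asarray(frame, dtype=float) >= threshold
    labels = _sk_label(mask, connectivity=2)
    if min_area_px > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area_px)
        if small.size:
            labels[np.isin(labels, small)] = 0
        # renumber 1..K
        kept = np.unique(labels)
        remap = np.zeros(kept.max() + 1, dtype=labels.dtype)
        remap[kept] = np.arange(kept.size)
        labels = remap[labels]
    return labels


def track_thrombi(
    stack: ImageStack,
    threshold: float | None = None,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    background: float | None = None,
    roi: ROI | None = None,
) -> list[ThrombusTrack]:
    """Segment every frame and link components over time by pixel overlap.

    Each component in frame *i* is matched to the track whose frame
    *i - 1* footprint it overlaps the most (ties broken by nearest
    centroid); components with no overlap start new tracks, and a track
    ends the first frame no component overlaps it.  When two components
    both claim the same track (a split) the larger overlap wins; when one
    component overlaps several tracks (a merge) it attaches to the
    larger-overlap predecessor and the others end.

    Per member frame the component's pixel area, background-subtracted
    integrated intensity and intensity-weighted centroid are recorded.
    """
    if threshold is None:
        threshold = default_threshold(stack, roi)
    if background is None:
        background = estimate_background(stack, roi)
    px_um = stack.geometry.pixel_size_um

    tracks: list[ThrombusTrack] = []
    active: dict[int, np.ndarray] = {}  # track id -> previous-frame label mask
    for i in range(len(stack)):
        frame = stack.frames[i].astype(float)
        labels = segment_thrombi(frame, threshold, min_area_px)
        props = regionprops(labels, intensity_image=np.maximum(frame - background, 0.0))
        # overlap counts between current components and active tracks
        assignments: dict[int, int] = {}  # component label -> track id
        claims: dict[int, tuple[int, float]] = {}  # track id -> (label, overlap)
        for p in props:
            comp_mask = labels == p.label
            best_tid, best_ov = -1, 0
            for tid, prev_mask in active.items():
                ov = int(np.count_nonzero(comp_mask & prev_mask))
                if ov > best_ov:
                    best_tid, best_ov = tid, ov
                elif ov == best_ov and ov > 0:
                    # tie: nearest centroid wins
                    prev_c = tracks[best_tid].centroid[-1]
                    cand_c = tracks[tid].centroid[-1]
                    cy, cx = p.centroid_weighted
                    if (np.hypot(cy - cand_c[0], cx - cand_c[1])
                            < np.hypot(cy - prev_c[0], cx - prev_c[1])):
                        best_tid = tid
            if best_tid >= 0:
                prev = claims.get(best_tid)
                if prev is None or best_ov > prev[1]:
                    if prev is not None:
                        assignments.pop(prev[0], None)
                    claims[best_tid] = (p.label, best_ov)
                    assignments[p.label] = best_tid
        new_active: dict[int, np.ndarray] = {}
        for p in props:
            cy, cx = p.centroid_weighted
            tid = assignments.get(p.label)
            if tid is None:
                tid = len(tracks)
                tracks.append(ThrombusTrack(id=tid, first_frame=i))
            tr = tracks[tid]
            tr.area_px.append(int(p.area))
            tr.area_um2.append(float(p.area) * px_um**2)
            tr.intensity.append(float(p.image_intensity.sum()))
            tr.centroid.append((float(cy), float(cx)))
            new_active[tid] = labels == p.label
        active = new_active
    return tracks


def select_analysis_thrombi(
    tracks: list[ThrombusTrack], geometry: Geometry
) -> list[ThrombusTrack]:
    """Keep tracks whose mean centroid lies in the central-third ROI.

    Sets ``eligible_central_third`` on every input track and returns the
    eligible subset.
    """
    roi = central_third_roi(geometry)
    selected = []
    for tr in tracks:
        row, _ = tr.mean_centroid
        tr.eligible_central_third = roi.contains_row(row)
        if tr.eligible_central_third:
            selected.append(tr)
    return selected


def stack_to_traces(
    stack: ImageStack,
    threshold: float | None = None,
    background: float | None = None,
    roi: ROI | None = None,
) -> tuple[KineticTrace, KineticTrace]:
    """All-thrombi TFI and TAC traces over the configured ROI.

    Background defaults to the median of the first frame in the ROI and
    the TAC threshold to Otsu on the final frame; both can be overridden
    with fixed values.
    """
    roi = roi or ROI.full(stack.geometry)
    if background is None:
        background = estimate_background(stack, roi)
    if threshold is None:
        threshold = default_threshold(stack, roi)
    px_um = stack.geometry.pixel_size_um
    tfi = np.empty(len(stack))
    tac = np.empty(len(stack))
    for i in range(len(stack)):
        frame = stack.frames[i]
        tfi[i] = total_fluorescent_intensity(frame, roi, background)
        _, tac[i] = total_area_covered(frame, roi, threshold, px_um)
    return (
        KineticTrace(time_s=stack.time_s, value=tfi, metric="TFI"),
        KineticTrace(time_s=stack.time_s, value=tac, metric="TAC"),
    )
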