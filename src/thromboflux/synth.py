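"""Synthetic microfluidic thrombosis assay data with known ground truth.

Emulates the observable of a whole-blood perfusion assay: DiOC6-labeled
platelets accumulating on immobilized collagen under arterial shear
(15 dyn/cm², 1.67 Hz pulse), imaged every 35 s over a 10-min flow period.
Each simulated thrombus nucleates at a time tau and then grows with

* total fluorescence  ``a * (t - tau)**2``  (quadratic accumulation), and
* blob radius         ``r * (t - tau)``     (linear spread),

rendered as a truncated 2-D Gaussian on the pixel grid, over a flat
background with additive Gaussian camera noise clipped at zero.  The
shear stress and pulse frequency are recorded metadata, not simulated
physics.  Ground truth (nucleation times, growth coefficients) is
returned alongside every generated object so downstream estimators can
be scored exactly.

Time origin: t = 0 is the first acquired frame; nucleation times are
relative to it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import KineticTrace

__all__ = [
    "AssayDesign",
    "ThrombusSpec",
    "GroundTruth",
    "ImageStack",
    "Geometry",
    "generate_kinetic_trace",
    "generate_image_stack",
    "random_thrombus_specs",
    "write_ground_truth",
    "read_ground_truth",
    "GroundTruthError",
]


class GroundTruthError(ValueError):
    """Malformed ground-truth file; the message names the offending field."""


@dataclass(frozen=True)
class AssayDesign:
    """Acquisition and simulation constants for one synthetic assay run.

    Defaults mirror the reference assay conditions: 35-s frame interval
    over a 600-s perfusion at 15 dyn/cm² wall shear with a 1.67-Hz pulse.
    Flow runs along image columns; the channel width spans the rows.
    """

    frame_interval_s: float = 35.0
    duration_s: float = 600.0
    frame_height_px: int = 120
    frame_width_px: int = 160
    pixel_size_um: float = 1.0
    flow_axis: str = "along_columns"
    shear_stress_dyn_cm2: float = 15.0   # metadata only
    pulse_hz: float = 1.67               # metadata only
    noise_sd: float = 2.0
    background_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.duration_s < self.frame_interval_s:
            raise ValueError("duration_s must cover at least one interval")
        if self.frame_height_px < 16 or self.frame_width_px < 16:
            raise ValueError("frame dimensions must be at least 16 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.flow_axis != "along_columns":
            raise ValueError("only flow_axis='along_columns' is supported")

    @property
    def frame_times_s(self) -> np.ndarray:
        """Sample times t = 0, Δ, 2Δ, ... (floor(duration/Δ)+1 frames)."""
        n = int(np.floor(self.duration_s / self.frame_interval_s)) + 1
        return np.arange(n, dtype=float) * self.frame_interval_s


@dataclass(frozen=True)
class Geometry:
    """Channel geometry attached to an image stack."""

    height_px: int
    width_px: int
    pixel_size_um: float = 1.0
    flow_axis: str = "along_columns"


@dataclass(frozen=True)
class ThrombusSpec:
    """Ground-truth parameters of one simulated thrombus.

    ``nucleation_time_s`` (tau) is the lag the estimator must recover;
    ``intensity_coeff`` (a) drives total fluorescence a*(t-tau)²;
    ``radius_coeff`` the linear radial spread; ``peak_amplitude`` caps
    the per-pixel brightness.
    """

    id: int
    nucleation_time_s: float
    center_row_px: float
    center_col_px: float
    intensity_coeff: float
    radius_coeff: float = 0.05
    peak_amplitude: float = 40000.0

    def __post_init__(self) -> None:
        if self.nucleation_time_s < 0:
            raise ValueError("nucleation_time_s must be nonnegative")
        if self.intensity_coeff <= 0:
            raise ValueError("intensity_coeff must be positive")
        if self.radius_coeff < 0:
            raise ValueError("radius_coeff must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score an analysis of a synthetic object."""

    specs: tuple[ThrombusSpec, ...]
    design: AssayDesign
    overlapping: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        if not self.specs:
            raise ValueError("specs must be non-empty")

    @property
    def true_overall_lag_s(self) -> float:
        return min(s.nucleation_time_s for s in self.specs)

    def analytic_tfi(self, t: float | np.ndarray) -> np.ndarray:
        """Closed-form total fluorescence: sum of a_i*(t-tau_i)² over active specs."""
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        for s in self.specs:
            dt = np.maximum(t - s.nucleation_time_s, 0.0)
            total += s.intensity_coeff * dt * dt
        return total


@dataclass(frozen=True)
class ImageStack:
    """Ordered fluorescence frames with timestamps and channel geometry."""

    frames: np.ndarray  # (n_frames, H, W)
    time_s: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        t = np.asarray(self.time_s, dtype=float)
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "time_s", t)
        if f.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if f.shape[0] != t.size:
            raise ValueError("one timestamp per frame required")
        if f.shape[0] < 2:
            raise ValueError("an image stack needs at least 2 frames")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if (f.shape[1], f.shape[2]) != (self.geometry.height_px, self.geometry.width_px):
            raise ValueError("frame shape disagrees with geometry")

    def __len__(self) -> int:
        return int(self.frames.shape[0])


def generate_kinetic_trace(
    design: AssayDesign,
    lag_s: float,
    growth_coeff: float,
    noise_sd: float | None = None,
    metric: str = "TFI",
) -> tuple[KineticTrace, GroundTruth]:
    """Synthesize an accumulation trace y(t) = a*(t-lag)² for t >= lag, else 0.

    Zero-mean Gaussian noise of standard deviation ``noise_sd`` (defaults
    to ``design.noise_sd``) is added to every sample; the seeded generator
    in ``design.seed`` makes identical inputs give identical traces.  The
    noiseless trace is constructed so that the quadratic fit plus
    ascending-branch root recovers ``lag_s`` exactly.
    """
    if not 0 <= lag_s < design.duration_s:
        raise ValueError("lag_s must lie in [0, duration_s)")
    if growth_coeff <= 0:
        raise ValueError("growth_coeff must be positive")
    if noise_sd is None:
        noise_sd = design.noise_sd
    t = design.frame_times_s
    dt = np.maximum(t - lag_s, 0.0)
    y = growth_coeff * dt * dt
    if noise_sd > 0:
        rng = np.random.default_rng(design.seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    trace = KineticTrace(time_s=t, value=y, metric=metric, source="all_thrombi")
    spec = ThrombusSpec(
        id=0,
        nucleation_time_s=lag_s,
        center_row_px=design.frame_height_px / 2,
        center_col_px=design.frame_width_px / 2,
        intensity_coeff=growth_coeff,
        radius_coeff=0.0,
    )
    return trace, GroundTruth(specs=(spec,), design=design)


def _render_blob(frame: np.ndarray, spec: ThrombusSpec, t: float) -> None:
    """Add one truncated-Gaussian blob (in place) for an active spec.

    Blob sigma is max(1 px, radius_coeff*(t-tau)), capped so the 3-sigma
    support stays inside the frame; total blob intensity is
    intensity_coeff*(t-tau)², capped at peak_amplitude * support area.
    """
    H, W = frame.shape
    age = t - spec.nucleation_time_s
    if age < 0:
        return
    r, c = spec.center_row_px, spec.center_col_px
    # Cap sigma so the truncation radius 3*sigma stays inside the frame.
    margin = min(r, H - 1 - r, c, W - 1 - c)
    sigma = max(1.0, spec.radius_coeff * age)
    sigma = min(sigma, max(margin, 1.0) / 3.0) if margin >= 3.0 else 1.0
    rad = 3.0 * sigma
    r0, r1 = max(0, int(np.floor(r - rad))), min(H, int(np.ceil(r + rad)) + 1)
    c0, c1 = max(0, int(np.floor(c - rad))), min(W, int(np.ceil(c + rad)) + 1)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    d2 = (rows - r) ** 2 + (cols - c) ** 2
    kernel = np.exp(-0.5 * d2 / sigma**2)
    kernel[d2 > rad * rad] = 0.0
    ksum = kernel.sum()
    if ksum == 0.0:
        return
    total = spec.intensity_coeff * age * age
    total = min(total, spec.peak_amplitude * float((kernel > 0).sum()))
    frame[r0:r1, c0:c1] += (total / ksum) * kernel


def generate_image_stack(
    design: AssayDesign, specs: list[ThrombusSpec] | tuple[ThrombusSpec, ...]
) -> tuple[ImageStack, GroundTruth]:
    """Render a multi-frame synthetic stack from thrombus specs.

    Each frame is ``background_level`` plus one truncated-Gaussian blob
    per active spec plus seeded Gaussian noise clipped at zero, quantized
    to 16-bit by rounding to nearest.  Overlapping specs (3-sigma final
    supports intersecting) are permitted but flagged in the ground truth.
    """
    specs = tuple(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    H, W = design.frame_height_px, design.frame_width_px
    for s in specs:
        if not (0 <= s.center_row_px < H and 0 <= s.center_col_px < W):
            raise ValueError(f"spec {s.id}: center outside frame")
    times = design.frame_times_s
    rng = np.random.default_rng(design.seed)
    frames = np.empty((times.size, H, W), dtype=np.uint16)
    for i, t in enumerate(times):
        img = np.full((H, W), float(design.background_level))
        for s in specs:
            _render_blob(img, s, t)
        if design.noise_sd > 0:
            img += rng.normal(0.0, design.noise_sd, size=img.shape)
        np.clip(img, 0.0, 65535.0, out=img)
        frames[i] = _quantize_preserving_sum(img)
    geometry = Geometry(height_px=H, width_px=W,
                        pixel_size_um=design.pixel_size_um,
                        flow_axis=design.flow_axis)
    stack = ImageStack(frames=frames, time_s=times, geometry=geometry)
    gt = GroundTruth(specs=specs, design=design,
                     overlapping=_any_overlap(specs, design))
    return stack, gt


def _quantize_preserving_sum(img: np.ndarray) -> np.ndarray:
    """Quantize a float frame to uint16 while preserving its total.

    Plain rounding silently discards the many sub-0.5 tail pixels of a
    dim Gaussian blob, biasing integrated intensities low by several
    percent at early growth frames.  Largest-remainder quantization
    floors every pixel and hands the lost total back to the pixels with
    the largest fractional parts, keeping each frame's sum within one
    count of the float image.
    """
    floor = np.floor(img)
    deficit = int(round(float(img.sum() - floor.sum())))
    if deficit > 0:
        frac = (img - floor).ravel()
        idx = np.argpartition(frac, -deficit)[-deficit:]
        out = floor.ravel()
        out[idx] += 1.0
        floor = out.reshape(img.shape)
    return np.clip(floor, 0, 65535).astype(np.uint16)


def _final_sigma(spec: ThrombusSpec, design: AssayDesign) -> float:
    age = max(design.duration_s - spec.nucleation_time_s, 0.0)
    return max(1.0, spec.radius_coeff * age)


def _any_overlap(specs: tuple[ThrombusSpec, ...], design: AssayDesign) -> bool:
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            d = np.hypot(a.center_row_px - b.center_row_px,
                         a.center_col_px - b.center_col_px)
            if d < 3.0 * (_final_sigma(a, design) + _final_sigma(b, design)):
                return True
    return False


def random_thrombus_specs(
    design: AssayDesign,
    n: int,
    rng: np.random.Generator,
    lag_range_s: tuple[float, float] = (35.0, 300.0),
    intensity_range: tuple[float, float] = (0.5, 3.0),
    radius_coeff: float = 0.01,
    min_separation_px: float = 40.0,
    central_third_only: bool = False,
) -> tuple[ThrombusSpec, ...]:
    """Draw n non-overlapping thrombus specs at random positions.

    Centers are rejection-sampled to keep pairwise distances at least
    ``min_separation_px`` and at least 12 px from every frame edge, so
    that the rendered blobs stay separable for tracking tests.  With
    ``central_third_only`` centers are confined to the middle third of
    the channel width (the rows).
    """
    H, W = design.frame_height_px, design.frame_width_px
    lo_r, hi_r = (H // 3, H - H // 3) if central_third_only else (12, H - 12)
    lo_r, hi_r = max(lo_r, 12), min(hi_r, H - 12)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place non-overlapping specs; "
                               "reduce n or min_separation_px")
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(12, W - 12)
        if all(np.hypot(r - rr, c - cc) >= min_separation_px for rr, cc in centers):
            centers.append((r, c))
    specs = []
    for i, (r, c) in enumerate(centers):
        specs.append(ThrombusSpec(
            id=i,
            nucleation_time_s=float(rng.uniform(*lag_range_s)),
            center_row_px=r,
            center_col_px=c,
            intensity_coeff=float(rng.uniform(*intensity_range)),
            radius_coeff=radius_coeff,
        ))
    return tuple(specs)


# ---------------------------------------------------------------------------
# Ground-truth serialization (JSON)

def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth to JSON; round-trips field-for-field."""
    doc = {
        "design": dataclasses.asdict(gt.design),
        "specs": [dataclasses.asdict(s) for s in gt.specs],
        "overlapping": gt.overlapping,
        "true_overall_lag_s": gt.true_overall_lag_s,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Parse a ground-truth JSON file, validating every field."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise GroundTruthError(f"not valid JSON: {exc}") from exc
    for key in ("design", "specs"):
        if key not in doc:
            raise GroundTruthError(f"missing field {key!r}")
    try:
        design = AssayDesign(**doc["design"])
    except (TypeError, ValueError) as exc:
        raise GroundTruthError(f"field 'design': {exc}") from exc
    specs = []
    for i, raw in enumerate(doc["specs"]):
        try:
            specs.append(ThrombusSpec(**raw))
        except (TypeError, ValueError) as exc:
            raise GroundTruthError(f"field 'specs[{i}]': {exc}") from exc
    if not specs:
        raise GroundTruthError("field 'specs': must be non-empty")
    return GroundTruth(specs=tuple(specs), design=design,
                       overlapping=bool(doc.get("overlapping", False)))
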