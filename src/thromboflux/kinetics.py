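"""Quadratic kinetic model for platelet/thrombus accumulation traces.

Whole-blood perfusion over immobilized collagen produces accumulation
curves (total fluorescent intensity, TFI, or total area covered, TAC,
versus time) with a characteristic shape: a quiescent lag, then a rapid,
approximately linear growth phase.  A quadratic ``y = A t**2 + B t + C``
is fitted to the whole trace by ordinary least squares, and the *lag
time* -- the onset of rapid accumulation -- is defined as the real root
of ``A t**2 + B t + C = 0`` that lies on the ascending branch of the
parabola, i.e. the root where the derivative ``2 A t + B`` is positive.

For the idealised noiseless curve ``y = a (t - tau)**2`` for ``t >= tau``
(zero before), the fitted parabola is exactly ``a (t - tau)**2`` when all
samples lie at or after ``tau``; its double root *is* ``tau``, so the
estimator is exact by construction.  Real traces include the flat
pre-nucleation segment and noise, so the fitted discriminant is generally
positive and the ascending-branch root is a smoothed onset estimate.

Three endpoints are produced per trace: the lag time, the rapid-phase
slope (OLS line slope over the post-lag points) and the maximum
accumulation (largest observed value).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticTrace",
    "QuadraticFit",
    "KineticSummary",
    "LagQuality",
    "growth_window",
    "fit_quadratic",
    "lag_time",
    "rapid_phase_slope",
    "max_accumulation",
    "summarize_kinetics",
]

# Relative threshold below which the discriminant of the fitted parabola
# is treated as zero (double root).  Noiseless synthetic traces sit
# exactly on this boundary and round-off can push B**2 - 4AC a hair to
# either side; the cancellation-free scaled-domain discriminant computed
# in fit_quadratic is ~1e-14 relative for such fits, while genuinely
# separated roots give relative discriminants many orders larger.
_DEGENERATE_REL_TOL = 1e-9


class LagQuality(enum.Enum):
    """Diagnostic attached to a lag-time estimate."""

    OK = "ok"
    VERTEX_DEGENERATE = "vertex_degenerate"
    OUT_OF_RANGE = "out_of_range"
    CONCAVE = "concave"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class KineticTrace:
    """A time series of one accumulation metric.

    Parameters
    ----------
    time_s : array of float
        Sample times in seconds, strictly increasing.
    value : array of float
        Metric values (intensity units for TFI, µm² or px for TAC).
    metric : {"TFI", "TAC"}
        Which accumulation metric the values represent.
    source : {"all_thrombi", "individual_thrombus"}
        Whether the trace aggregates the whole region of interest or
        follows one tracked thrombus.
    """

    time_s: np.ndarray
    value: np.ndarray
    metric: str = "TFI"
    source: str = "all_thrombi"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "value", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("time_s and value must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a kinetic trace needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("trace contains non-finite values")
        if self.metric not in ("TFI", "TAC"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.source not in ("all_thrombi", "individual_thrombus"):
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares parabola ``y = A t**2 + B t + C`` with diagnostics.

    ``discriminant`` is ``B**2 - 4 A C`` evaluated in a cancellation-free
    form; ``t_last`` records the last sample time so that downstream root
    selection can flag roots beyond the observed window.
    """

    A: float
    B: float
    C: float
    discriminant: float
    rmse: float
    r2: float
    t_last: float = field(default=math.nan)
    disc_sd: float = field(default=0.0)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * t * t + self.B * t + self.C


@dataclass(frozen=True)
class KineticSummary:
    """The three per-trace endpoints plus fit diagnostics."""

    lag_time_s: float
    lag_quality: LagQuality
    rapid_slope: float  # NaN when fewer than 2 post-lag points
    max_value: float
    fit: QuadraticFit


def growth_window(trace: KineticTrace, baseline: float = 0.0) -> KineticTrace:
    """Restrict a trace to its growth phase.

    Keeps the samples strictly after the last sample at or below
    ``baseline``.  For a background-subtracted accumulation trace the
    pre-nucleation segment hovers at (noiseless: sits exactly on) zero,
    so this drops the flat baseline that the quadratic model does not
    describe; on a noiseless synthetic trace the surviving samples lie
    exactly on ``a (t - tau)**2`` and the fit recovers ``tau`` exactly.
    Falls back to the full trace when fewer than 4 samples survive.
    """
    below = np.flatnonzero(trace.value <= baseline)
    if below.size == 0:
        return trace
    start = int(below[-1]) + 1
    if len(trace) - start < 4:
        return trace
    return KineticTrace(time_s=trace.time_s[start:], value=trace.value[start:],
                        metric=trace.metric, source=trace.source)


def fit_quadratic(trace: KineticTrace, growth_only: bool = True) -> QuadraticFit:
    """Ordinary-least-squares quadratic fit ``y = A t**2 + B t + C``.

    With ``growth_only`` (the default) the fit is restricted to the
    growth phase via :func:`growth_window`, because the accumulation
    model only describes the curve after nucleation; pass
    ``growth_only=False`` to fit every sample as given.

    The solve is performed on centered and scaled time ``u = (t - m)/s``
    for numerical conditioning, then mapped back to the original time
    axis.  The discriminant is computed from the scaled coefficients
    (``disc_t = disc_u / s**2``), which avoids the catastrophic
    cancellation that ``B**2 - 4AC`` suffers when the parabola has a
    (near-)double root far from ``t = 0``.

    Raises
    ------
    ValueError
        If the trace has fewer than 4 points (3 coefficients plus at
        least one residual degree of freedom).
    """
    if len(trace) < 4:
        raise ValueError("quadratic fit requires at least 4 points")
    if growth_only:
        trace = growth_window(trace)
    t = trace.time_s
    y = trace.value
    m = float(t.mean())
    s = float(t.std())
    if s == 0.0:  # unreachable given strictly-increasing timestamps
        raise ValueError("all timestamps identical")
    u = (t - m) / s
    # Vandermonde solve in the scaled domain.
    X = np.column_stack([u * u, u, np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a2, a1, a0 = (float(c) for c in coef)
    # y = a2 u^2 + a1 u + a0 with u=(t-m)/s  ->  A t^2 + B t + C
    A = a2 / s**2
    B = a1 / s - 2.0 * a2 * m / s**2
    C = a0 - a1 * m / s + a2 * m**2 / s**2
    disc = (a1 * a1 - 4.0 * a2 * a0) / s**2

    resid = y - (X @ coef)
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    # Delta-method SD of the discriminant from the coefficient
    # covariance; lets root selection recognise statistically-degenerate
    # (double-root) fits on noisy data.
    dof = max(t.size - 3, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    grad = np.array([-4.0 * a0, 2.0 * a1, -4.0 * a2])
    disc_sd = float(np.sqrt(max(grad @ cov @ grad, 0.0))) / s**2
    return QuadraticFit(A=A, B=B, C=C, discriminant=disc, rmse=rmse, r2=r2,
                        t_last=float(t[-1]), disc_sd=disc_sd)


def lag_time(fit: QuadraticFit, t_last: float | None = None) -> tuple[float, LagQuality]:
    """Lag time: the ascending-branch root of ``A t**2 + B t + C = 0``.

    Among the real roots, the one where the curve is rising
    (``2 A t + B > 0``) is returned -- for an upward parabola this is the
    larger root ``(-B + sqrt(disc)) / (2A)``.  Degenerate and pathological
    shapes are mapped to explicit quality flags rather than errors:

    * discriminant <= 0 (within a relative tolerance): the vertex
      ``-B / (2A)`` with :attr:`LagQuality.VERTEX_DEGENERATE`.  Noiseless
      synthetic traces land here because their fitted parabola has an
      exact double root at the nucleation time.
    * ``A < 0`` (concave fit): the smaller root, which is the ascending
      one for a downward parabola, with :attr:`LagQuality.CONCAVE`.
    * selected root negative or beyond the last sample time: the value is
      still returned, flagged :attr:`LagQuality.OUT_OF_RANGE`.
    * ``A == 0``: linear fallback ``-C / B`` (rejected if ``B`` is also 0).

    Parameters
    ----------
    fit : QuadraticFit
    t_last : float, optional
        Upper end of the plausible lag range; defaults to ``fit.t_last``.
    """
    A, B, C = fit.A, fit.B, fit.C
    if t_last is None:
        t_last = fit.t_last

    if A == 0.0:
        if B == 0.0:
            raise ValueError("degenerate fit: A = B = 0 has no root")
        root = -C / B
        quality = LagQuality.OK if B > 0 else LagQuality.CONCAVE
        return _range_check(root, t_last, quality)

    disc = fit.discriminant
    scale = B * B + abs(4.0 * A * C)
    # Degenerate when the discriminant is zero to within round-off OR
    # not statistically distinguishable from zero (2 SD): a noisy sample
    # of a pure shifted parabola has true discriminant 0 and the
    # spurious sqrt(disc) excursion would bias the root upward.
    if disc <= max(_DEGENERATE_REL_TOL * scale, 2.0 * fit.disc_sd):
        # Double root (or no real root): the vertex is the natural onset.
        return _range_check(-B / (2.0 * A), t_last, LagQuality.VERTEX_DEGENERATE)

    sqrt_disc = math.sqrt(disc)
    # Numerically stable root pair (avoids -B + sqrt(disc) cancellation).
    q = -0.5 * (B + math.copysign(sqrt_disc, B)) if B != 0.0 else 0.5 * sqrt_disc
    r1 = q / A
    r2 = C / q if q != 0.0 else -B / A  # q == 0 only when B == 0 and disc > 0
    lo, hi = (r1, r2) if r1 <= r2 else (r2, r1)
    if A > 0:
        return _range_check(hi, t_last, LagQuality.OK)
    return _range_check(lo, t_last, LagQuality.CONCAVE)


def _range_check(root: float, t_last: float, quality: LagQuality) -> tuple[float, LagQuality]:
    out = root < 0.0 or (not math.isnan(t_last) and root > t_last)
    if out and quality in (LagQuality.OK, LagQuality.VERTEX_DEGENERATE):
        return root, LagQuality.OUT_OF_RANGE
    return root, quality


def rapid_phase_slope(trace: KineticTrace, lag_s: float) -> float:
    """OLS line slope over the post-lag portion of the trace.

    The rapid phase is anchored at the lag estimate: all samples with
    ``time >= lag_s`` enter an ordinary-least-squares straight-line fit
    and its slope is returned.  Returns ``nan`` (never a silent zero)
    when fewer than 2 samples qualify.
    """
    sel = trace.time_s >= lag_s
    if int(sel.sum()) < 2:
        return math.nan
    t = trace.time_s[sel]
    y = trace.value[sel]
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def estimate_lag(
    trace: KineticTrace, max_iter: int = 50
) -> tuple[float, LagQuality, QuadraticFit]:
    """Lag time by self-consistent windowed quadratic fitting.

    The accumulation model ``y = a (t - tau)**2`` holds for ``t >= tau``
    only, so the fit window should start near the (unknown) nucleation
    time.  Starting from the baseline-restricted fit of
    :func:`fit_quadratic`, the window is iteratively refined: fit on the
    current window, extract the lag from the ascending-branch root, move
    the window start there, repeat until the window stops moving.

    The window is extended *below* the current lag estimate by
    ``sqrt(rmse / A)`` — the distance at which the model's misfit to the
    flat pre-nucleation baseline, ``A (tau - t)**2``, reaches the
    estimated noise level.  Samples in that band carry vertex-anchoring
    information at negligible model error, which roughly halves the
    noise-driven lag error; for noiseless traces the extension vanishes
    and every windowed sample lies exactly on the parabola, so the true
    nucleation time is recovered to round-off.  A window is never shrunk
    below 4 samples.
    """
    fit = fit_quadratic(trace)
    lag, quality = lag_time(fit)
    t = trace.time_s
    seen: set[int] = set()
    for _ in range(max_iter):
        ext = math.sqrt(max(fit.rmse, 0.0) / fit.A) if fit.A > 0 else 0.0
        start = int(np.searchsorted(t, lag - ext))
        start = min(max(start, 0), len(trace) - 4)
        if start in seen:
            break
        seen.add(start)
        sub = KineticTrace(time_s=t[start:], value=trace.value[start:],
                           metric=trace.metric, source=trace.source)
        new_fit = fit_quadratic(sub, growth_only=False)
        try:
            new_lag, new_quality = lag_time(new_fit, t_last=float(t[-1]))
        except ValueError:
            break
        fit, lag, quality = new_fit, new_lag, new_quality
        if not math.isfinite(lag):
            break
    return lag, quality, fit


def max_accumulation(trace: KineticTrace) -> float:
    """Maximum observed value of the trace (peak accumulation)."""
    return float(np.max(trace.value))


def summarize_kinetics(trace: KineticTrace) -> KineticSummary:
    """Fit the quadratic model and extract all three endpoints.

    Uses :func:`estimate_lag` (self-consistent windowed fit) for the lag
    and the post-lag OLS line for the rapid-phase slope.
    """
    lag, quality, fit = estimate_lag(trace)
    slope = rapid_phase_slope(trace, lag)
    return KineticSummary(
        lag_time_s=lag,
        lag_quality=quality,
        rapid_slope=slope,
        max_value=max_accumulation(trace),
        fit=fit,
    )
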