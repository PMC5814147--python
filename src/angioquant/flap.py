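"""Photoconversion (FLAP) trace analysis: immobile fraction and half-time.

In a fluorescence-loss-after-photoconversion experiment a junctional protein
pool inside an ROI is photoconverted and the converted signal followed over
time.  After background subtraction, bleach correction (single-exponential,
fitted on a fixed-cell control where no redistribution occurs), and
normalisation (pre-conversion mean -> 0, first post-conversion frame -> 1),
the post-conversion curve of a well-behaved junction follows

    I(t) = f + (1 - f) * 2**(-t / t_half),

with ``f`` the immobile fraction (molecules that never exchange with the
surrounding pool) and ``t_half`` the redistribution half-time of the mobile
pool.  Both are estimated directly from the plotted curve: the plateau is
the mean of the last stretch of frames, and the half-time is where the
(optionally smoothed) curve first crosses the midpoint ``(1 + f) / 2`` of
the mobile span, with linear interpolation between frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FlapTrace",
    "BleachModel",
    "FlapEstimate",
    "subtract_background",
    "fit_bleach",
    "bleach_correct",
    "normalize_trace",
    "smooth",
    "estimate",
    "analyze",
]


@dataclass
class FlapTrace:
    """A photoconversion ROI time course.

    ``times`` are seconds from acquisition start, strictly increasing
    (default experimental cadence: 10 s frames over 15 min).
    ``conversion_index`` is the index of the first post-conversion frame and
    must leave at least one pre-conversion frame before it.
    ``qc_pass`` carries the upstream manual judgement that the junction did
    not substantially move or remodel during the observation.
    """

    times: np.ndarray
    roi_intensity: np.ndarray
    background_intensity: np.ndarray
    conversion_index: int
    trace_id: str = ""
    qc_pass: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=float)
        self.background_intensity = np.asarray(self.background_intensity,
                                               dtype=float)
        if not (len(self.times) == len(self.roi_intensity)
                == len(self.background_intensity)):
            raise ValueError("times, ROI and background series must have "
                             "equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 1 <= self.conversion_index < len(self.times):
            raise ValueError("conversion_index must leave at least one "
                             "pre-conversion frame")

    @property
    def post_times(self) -> np.ndarray:
        """Times of post-conversion frames, re-zeroed at the first one."""
        t = self.times[self.conversion_index:]
        return t - t[0]


@dataclass
class BleachModel:
    """Single-exponential photobleaching, fitted on a fixed-cell control."""

    rate: float  # k_b, 1/s, >= 0
    amplitude: float
    residual: float  # RMS of the fit


@dataclass
class FlapEstimate:
    """Immobile fraction and redistribution half-time of one trace.

    ``half_time`` is ``None`` when the curve never crosses the midpoint of
    its mobile span (reported as undefined, never silently zero).
    """

    immobile_fraction: float  # clamped to [0, 1]
    half_time: float | None  # s
    plateau_window: int  # frames averaged for the plateau
    smoothing_window: int  # frames
    trace_id: str = ""


def subtract_background(trace: FlapTrace) -> FlapTrace:
    """Per-frame background subtraction; warns if the plateau goes negative."""
    corrected = trace.roi_intensity - trace.background_intensity
    tail = corrected[trace.conversion_index:]
    n_tail = max(1, len(tail) // 10)
    if len(tail) and np.mean(tail[-n_tail:]) < 0:
        warnings.warn("background-subtracted plateau is negative", stacklevel=2)
    return replace(trace, roi_intensity=corrected,
                   background_intensity=np.zeros_like(corrected))


def fit_bleach(control: FlapTrace) -> BleachModel:
    """Fit ``A * exp(-k_b * t)`` to a background-subtracted fixed-cell trace.

    The control is a fixed cell (no redistribution, immobile fraction 1), so
    any decay over the full acquisition is photobleaching.
    """
    t = control.times - control.times[0]
    y = control.roi_intensity
    if np.median(y) <= 0:
        raise ValueError("control intensities are non-positive; cannot fit "
                         "a bleach model")
    # Log-linear start values, refined by nonlinear least squares.
    pos = y > 0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    p0 = (float(np.exp(intercept)), max(-slope, 0.0))
    (amp, rate), _ = curve_fit(
        lambda tt, a, k: a * np.exp(-k * tt), t, y, p0=p0,
        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
    )
    resid = float(np.sqrt(np.mean((amp * np.exp(-rate * t) - y) ** 2)))
    return BleachModel(rate=float(rate), amplitude=float(amp), residual=resid)


def bleach_correct(trace: FlapTrace, model: BleachModel) -> FlapTrace:
    """Divide each frame by ``exp(-k_b * t)``, t from acquisition start."""
    t = trace.times - trace.times[0]
    factor = np.exp(model.rate * t)
    return replace(trace, roi_intensity=trace.roi_intensity * factor,
                   background_intensity=trace.background_intensity * factor)


def normalize_trace(trace: FlapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Affine-map the trace: pre-conversion mean -> 0, first post frame -> 1.

    Returns ``(post_times, normalized_post_values)`` — the post-conversion
    portion used for estimation, with t = 0 at the first post-conversion
    frame.
    """
    ci = trace.conversion_index
    baseline = float(trace.roi_intensity[:ci].mean())
    peak = float(trace.roi_intensity[ci])
    if peak <= baseline:
        raise ValueError("post-conversion peak does not exceed the "
                         "pre-conversion baseline; no conversion detected")
    normalized = (trace.roi_intensity[ci:] - baseline) / (peak - baseline)
    return trace.post_times, normalized


def smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use a shrunken (still centered) window.

    ``window`` must be odd; a window of 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be an odd integer >= 1")
    values = np.asarray(values, dtype=float)
    if window == 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    n = len(values)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = values[i - k:i + k + 1].mean()
    return out


def estimate(
    times: np.ndarray,
    normalized: np.ndarray,
    plateau_fraction: float = 0.1,
    smoothing_window: int = 5,
    *,
    trace_id: str = "",
) -> FlapEstimate:
    """Read immobile fraction and half-time off a normalised curve.

    The immobile fraction is the mean of the last ``plateau_fraction`` of
    frames (at least 5 when available), clamped to [0, 1].  The half-time is
    the first time the smoothed curve crosses ``(1 + f) / 2`` — the midpoint
    of the mobile span — with linear interpolation between frames.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(normalized, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 post-conversion frames")
    n_plateau = min(n, max(5, int(np.ceil(plateau_fraction * n))))
    f_raw = float(y[-n_plateau:].mean())
    f = min(1.0, max(0.0, f_raw))
    span = times[-1] - times[0]
    smoothed = smooth(y, smoothing_window)
    midpoint = (1.0 + f) / 2.0
    half_time: float | None = None
    # Strict crossing: a curve that never drops below the midpoint of its
    # mobile span (e.g. fully immobile, constant at 1) has no half-time.
    below = smoothed < midpoint
    if below.any():
        j = int(np.argmax(below))
        if j == 0:
            half_time = float(times[0])
        else:
            y0, y1 = smoothed[j - 1], smoothed[j]
            t0, t1 = times[j - 1], times[j]
            if y1 == y0:
                half_time = float(t1)
            else:
                half_time = float(t0 + (midpoint - y0) / (y1 - y0) * (t1 - t0))
        if half_time is not None and span < 3.0 * half_time:
            warnings.warn("trace spans fewer than 3 estimated half-times; "
                          "plateau may be unreliable", stacklevel=2)
    return FlapEstimate(
        immobile_fraction=f,
        half_time=half_time,
        plateau_window=n_plateau,
        smoothing_window=smoothing_window,
        trace_id=trace_id,
    )


def analyze(
    trace: FlapTrace,
    control: FlapTrace | None = None,
    plateau_fraction: float = 0.1,
    smoothing_window: int = 5,
) -> FlapEstimate:
    """Full pipeline: background, bleach (from control), normalise, estimate."""
    corrected = subtract_background(trace)
    if control is not None:
        model = fit_bleach(subtract_background(control))
        corrected = bleach_correct(corrected, model)
    t, y = normalize_trace(corrected)
    return estimate(t, y, plateau_fraction, smoothing_window,
                    trace_id=trace.trace_id)
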