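"""Fluorescence-trace normalization and intensity thermometry.

Raw ROI mean-intensity time series from the camera are converted to clean
ΔF/F traces in three steps — constant dark-noise subtraction, exponential
photobleaching correction, and baseline normalization — and, for a
temperature-sensitive dye (DyLight 550, −2.2 %/°C), into a local temperature
change series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize

log = logging.getLogger(__name__)

__all__ = [
    "FluorescenceTrace",
    "NormalizedTrace",
    "ThermoCalibration",
    "subtract_dark_noise",
    "default_baseline_mask",
    "bleach_correct",
    "needs_bleach_correction",
    "delta_f_over_f",
    "intensity_to_temperature",
]


@dataclass(frozen=True)
class FluorescenceTrace:
    """Uniformly sampled ROI intensity series (camera counts).

    ``dark_noise`` is the constant camera offset recorded without
    illumination; default sampling is 10 frames/s (100 ms exposure).
    """

    time: np.ndarray
    intensity: np.ndarray
    dark_noise: float = 0.0
    roi: str = "roi0"

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "intensity", intensity)
        if time.ndim != 1 or time.size < 2:
            raise ValueError("time must be a 1-D grid of >=2 samples")
        if intensity.shape != time.shape:
            raise ValueError("time and intensity must have the same length")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if self.dark_noise < 0:
            raise ValueError("dark_noise must be >= 0")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class NormalizedTrace:
    """ΔF/F trace in percent relative to the baseline intensity F0."""

    time: np.ndarray
    dff: np.ndarray
    baseline_F0: float
    roi: str = "roi0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "dff", np.asarray(self.dff, dtype=float))
        if self.time.shape != self.dff.shape:
            raise ValueError("time and dff must have the same length")
        if self.baseline_F0 <= 0:
            raise ValueError("baseline_F0 must be > 0")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class ThermoCalibration:
    """Linear intensity–temperature calibration of the thermometer dye.

    ``slope`` is the percent intensity change per °C (−2.2 for DyLight 550:
    intensity falls as temperature rises); ``reference_temperature`` is the
    temperature at which ΔF/F = 0.
    """

    slope: float = -2.2
    reference_temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")


def subtract_dark_noise(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Subtract the constant camera dark offset, clipping at zero.

    Clipping only occurs when the stated dark noise exceeds recorded counts,
    which indicates a mis-measured offset; a warning is emitted rather than
    an error so batch processing can proceed.
    """
    corrected = trace.intensity - trace.dark_noise
    if np.any(corrected < 0):
        warnings.warn(
            f"dark noise {trace.dark_noise} exceeds recorded intensity in "
            f"{int(np.sum(corrected < 0))} samples; clipping at 0",
            stacklevel=2,
        )
        corrected = np.clip(corrected, 0.0, None)
    return replace(trace, intensity=corrected, dark_noise=0.0)


def default_baseline_mask(
    trace: FluorescenceTrace, median_window_s: float = 5.0, k: float = 2.0
) -> np.ndarray:
    """Baseline samples for the bleach fit.

    The trace is detrended with a rolling median (window long relative to a
    calcium transient, default 5 s) and samples within ``k`` robust standard
    deviations (1.4826·MAD) of the local median are kept. Unlike a simple
    below-percentile rule this keeps baseline samples at *all* times of a
    strongly bleaching recording, which the exponential fit needs.
    """
    n = max(3, int(round(median_window_s * trace.sample_rate)) | 1)
    rolling = ndimage.median_filter(trace.intensity, size=n, mode="nearest")
    resid = trace.intensity - rolling
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if sigma == 0.0:
        return np.ones(trace.intensity.shape, dtype=bool)
    return resid < k * sigma


def bleach_correct(
    trace: FluorescenceTrace, baseline_mask: np.ndarray | None = None
) -> FluorescenceTrace:
    """Remove exponential photobleaching from a dark-subtracted trace.

    The baseline samples (``baseline_mask``; by default those below the
    median-filtered 50th percentile, so calcium transients stay out of the
    fit) are fitted to F'fit(t) = A·exp(−t/τ) + C, and the corrected signal
    is

        F(t) = F'(t) + (F'(0) − F'fit(t)).

    This flattens the baseline at the initial intensity F'(0) while
    preserving transient excursions additively. Falls back to a linear
    baseline with a logged warning if the exponential fit fails.
    """
    if baseline_mask is None:
        baseline_mask = default_baseline_mask(trace)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if baseline_mask.shape != trace.time.shape:
        raise ValueError("baseline_mask must match the trace length")
    if int(baseline_mask.sum()) < 10:
        raise ValueError("baseline_mask must select at least 10 samples")
    t_masked = trace.time[baseline_mask]
    span = t_masked[-1] - t_masked[0]
    duration = trace.time[-1] - trace.time[0]
    if span < duration / 2.0:
        raise ValueError(
            "baseline samples must span at least half the trace duration"
        )

    fitted_full, _ = _evaluate_baseline_on_grid(trace, baseline_mask)
    f0 = fitted_full[0]
    corrected = trace.intensity + (f0 - fitted_full)
    return replace(trace, intensity=corrected)


def _evaluate_baseline_on_grid(
    trace: FluorescenceTrace, mask: np.ndarray
) -> tuple[np.ndarray, bool]:
    t = trace.time - trace.time[0]
    tm, ym = t[mask], trace.intensity[mask]
    a0 = ym[0] - ym[-1]
    c0 = ym[-1]
    tau0 = max((tm[-1] - tm[0]) / 2.0, np.finfo(float).eps)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model,
                tm,
                ym,
                p0=(a0, tau0, c0),
                bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        return model(t, *popt), True
    except (RuntimeError, ValueError):
        log.warning("exponential baseline fit failed; falling back to linear")
        coeffs = np.polyfit(tm, ym, 1)
        return np.polyval(coeffs, t), False


def needs_bleach_correction(
    trace: FluorescenceTrace,
    baseline_mask: np.ndarray | None = None,
    decay_threshold: float = 0.02,
) -> bool:
    """Whether the fitted baseline decays by more than ``decay_threshold``
    (fractional) over the recording — the criterion for applying
    :func:`bleach_correct` at all."""
    if baseline_mask is None:
        baseline_mask = default_baseline_mask(trace)
    fitted, _ = _evaluate_baseline_on_grid(trace, np.asarray(baseline_mask, bool))
    if fitted[0] <= 0:
        return False
    return (fitted[0] - fitted[-1]) / fitted[0] > decay_threshold


def delta_f_over_f(
    trace: FluorescenceTrace, baseline_window: tuple[float, float] = (0.0, 10.0)
) -> NormalizedTrace:
    """Normalize to percent change about the baseline-window mean.

    F0 is the mean intensity inside ``baseline_window`` (seconds, default the
    first 10 s) of the bleach-corrected trace, and
    dff(t) = (F(t) − F0) / F0 × 100.
    """
    lo, hi = baseline_window
    sel = (trace.time >= lo) & (trace.time <= hi)
    if int(sel.sum()) < 5:
        raise ValueError("baseline window must contain at least 5 samples")
    f0 = float(np.mean(trace.intensity[sel]))
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:.3g} must be > 0")
    dff = (trace.intensity - f0) / f0 * 100.0
    return NormalizedTrace(time=trace.time, dff=dff, baseline_F0=f0, roi=trace.roi)


def intensity_to_temperature(
    norm: NormalizedTrace, cal: ThermoCalibration = ThermoCalibration()
) -> np.ndarray:
    """Convert a normalized dye trace to a temperature-change series (°C).

    ΔT(t) = dff(t) / slope. With the DyLight 550 slope of −2.2 %/°C a −4.4%
    intensity dip maps to a +2.0 °C rise. Linearity holds over the few-degree
    range relevant here.
    """
    return norm.dff / cal.slope
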