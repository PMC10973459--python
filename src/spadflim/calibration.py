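"""TDC bin-width calibration from constant-light data.

Under constant illumination, photon arrival times are uniformly distributed
over the reset period ``dT``, so the photon count ``N_i`` recorded in TDC
bin ``i`` is proportional to the bin's true time width:

    W_i = dT * N_i / sum(N_i over the active range [I_R, I_F])

The relative standard error of each estimated width is ``1 / sqrt(N_i)``
(Poisson counting).  The active range is the plateau of nonzero counts
bounded by the rising and falling edges of the code-density curve; edges
are located by half-crossing of a robust plateau level.

This module also measures per-pixel dark-count rates (sensor covered) and
computes differential-nonlinearity (DNL) diagnostics: the photon
probability density, its normalized standard deviation, and its Fourier
magnitude spectrum, whose period-8 harmonic exposes the TDC's eight-step
ring oscillator.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .datatypes import (
    DarkCountMap,
    DnlDiagnostics,
    FrameStack,
    HistogramCube,
    PixelHistogram,
    TdcCalibration,
)

__all__ = [
    "NoActiveRangeError",
    "NarrowPlateauWarning",
    "find_active_edges",
    "estimate_bin_widths",
    "bin_width_error",
    "measure_dark_counts",
    "dnl_diagnostics",
    "calibrate_tdc",
]

MIN_PLATEAU_BINS = 8


class NoActiveRangeError(ValueError):
    """No bin rises above the detection threshold."""


class NarrowPlateauWarning(UserWarning):
    """The detected active range is suspiciously narrow (< 8 bins)."""


def _as_counts(hist) -> np.ndarray:
    if isinstance(hist, PixelHistogram):
        return np.asarray(hist.counts, dtype=float)
    return np.asarray(hist, dtype=float)


def find_active_edges(hist) -> tuple[int, int]:
    """Locate the rising/falling edge bins (I_R, I_F) of the active range.

    The plateau level is the median of counts over bins above 10% of the
    maximum; I_R (I_F) is the first (last) bin whose count reaches half of
    that level.  Works on a ``PixelHistogram`` or a plain counts array.
    """
    counts = _as_counts(hist)
    cmax = counts.max(initial=0.0)
    if cmax <= 0:
        raise NoActiveRangeError("no active range: histogram is empty")
    plateau = float(np.median(counts[counts > 0.1 * cmax]))
    half = plateau / 2.0
    above = np.nonzero(counts >= half)[0]
    i_rise, i_fall = int(above[0]), int(above[-1])
    if i_fall - i_rise + 1 < MIN_PLATEAU_BINS:
        warnings.warn(
            f"active range [{i_rise}, {i_fall}] is narrower than "
            f"{MIN_PLATEAU_BINS} bins",
            NarrowPlateauWarning,
            stacklevel=2,
        )
    return i_rise, i_fall


def estimate_bin_widths(
    hist,
    reset_period_ns: float,
    edges: tuple[int, int] | None = None,
) -> np.ndarray:
    """Estimate absolute bin widths (ps) from constant-light counts.

    Active bins get ``W_i = dT * N_i / sum(N)``; bins outside
    ``[I_R, I_F]`` get width 0.  The active widths are renormalized so
    their sum equals ``dT`` exactly (to one ulp).
    """
    counts = _as_counts(hist)
    if edges is None:
        edges = find_active_edges(counts)
    i_rise, i_fall = edges
    active = counts[i_rise : i_fall + 1]
    total = active.sum()
    if total <= 0:
        raise ValueError("zero total photons in active range")
    reset_ps = reset_period_ns * 1e3
    widths = np.zeros_like(counts, dtype=float)
    w = reset_ps * active / total
    # renormalize: guards against accumulated float error in the division
    w *= reset_ps / w.sum()
    widths[i_rise : i_fall + 1] = w
    return widths


def bin_width_error(n_photons) -> float | np.ndarray:
    """Relative standard error of a bin-width estimate: 1/sqrt(N)."""
    n = np.asarray(n_photons, dtype=float)
    if (n <= 0).any():
        raise ValueError("photon count must be positive")
    out = 1.0 / np.sqrt(n)
    return float(out) if out.ndim == 0 else out


def measure_dark_counts(dark_stack: FrameStack, quantile: float = 0.20) -> DarkCountMap:
    """Per-pixel dark rate (Hz) from a covered-sensor acquisition.

    rate = detections / (n_frames * exposure_time).  The hot-pixel mask
    marks exactly ``ceil(quantile * n_pixels)`` pixels with the highest
    rate, ties broken by row-major pixel order.
    """
    if dark_stack.n_frames < 1:
        raise ValueError("dark stack has no frames")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    geometry = dark_stack.geometry
    detections = dark_stack.photon_counts().astype(float)
    rate = detections / (dark_stack.n_frames * geometry.exposure_time_s)
    n_hot = math.ceil(quantile * geometry.n_pixels)
    order = np.argsort(-rate.ravel(), kind="stable")  # stable: row-major ties
    hot = np.zeros(geometry.n_pixels, dtype=bool)
    hot[order[:n_hot]] = True
    return DarkCountMap(rate_hz=rate, hot_mask=hot.reshape(rate.shape), quantile=quantile)


def dnl_diagnostics(hist, edges: tuple[int, int] | None = None) -> DnlDiagnostics:
    """DNL diagnostics over the active bins of one pixel.

    density: counts / mean(active counts)  (mean 1 by construction)
    normalized_std: std(active counts) / sqrt(total active photons)
    spectrum: |rfft(density)| over the active bins
    """
    counts = _as_counts(hist)
    if edges is None:
        edges = find_active_edges(counts)
    i_rise, i_fall = edges
    active = counts[i_rise : i_fall + 1]
    n_active = active.size
    if n_active < MIN_PLATEAU_BINS:
        raise ValueError(f"need >= {MIN_PLATEAU_BINS} active bins, got {n_active}")
    mean = active.mean()
    if mean <= 0:
        raise ValueError("active range holds no photons")
    density = active / mean
    normalized_std = float(active.std(ddof=0) / np.sqrt(active.sum()))
    spectrum = np.abs(np.fft.rfft(density))
    return DnlDiagnostics(
        density=density,
        normalized_std=normalized_std,
        spectrum=spectrum,
        n_active=n_active,
    )


def calibrate_tdc(cube: HistogramCube, reset_period_ns: float) -> TdcCalibration:
    """Estimate per-pixel active edges and bin widths for a whole array.

    Pixels where no active range can be found are marked invalid and carry
    zero widths.
    """
    geometry = cube.geometry
    shape = (geometry.n_rows, geometry.n_cols)
    i_rise = np.zeros(shape, dtype=np.int64)
    i_fall = np.zeros(shape, dtype=np.int64)
    widths = np.zeros((*shape, geometry.n_bins), dtype=float)
    totals = np.zeros(shape, dtype=np.int64)
    valid = np.zeros(shape, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NarrowPlateauWarning)
        for r in range(geometry.n_rows):
            for c in range(geometry.n_cols):
                counts = cube.counts[r, c]
                try:
                    edges = find_active_edges(counts)
                    widths[r, c] = estimate_bin_widths(counts, reset_period_ns, edges)
                except (NoActiveRangeError, ValueError):
                    continue
                i_rise[r, c], i_fall[r, c] = edges
                totals[r, c] = counts[edges[0] : edges[1] + 1].sum()
                valid[r, c] = True
    return TdcCalibration(
        i_rise=i_rise,
        i_fall=i_fall,
        widths_ps=widths,
        reset_period_ns=reset_period_ns,
        totals=totals,
        valid=valid,
    )
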