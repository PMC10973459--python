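"""Shared data model for TCSPC SPAD-array processing.

The raw acquisition unit is a *frame*: one 2-D image of integer TDC codes,
one per exposure.  Code 0 is reserved for "no photon detected in this
exposure"; code ``k >= 1`` means a photon was timed in TDC bin ``k``.  A
pixel stores at most one photon per exposure (the detection disables the
pixel for the rest of the exposure), so per-pixel histogram totals can never
exceed the number of frames.

Histogram bin index ``i`` corresponds to TDC code ``i + 1``; bins span
half-open time intervals.  Pixel coordinates are (row, col), 0-based,
row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "CameraGeometry",
    "FrameStack",
    "PixelHistogram",
    "HistogramCube",
    "TdcCalibration",
    "DarkCountMap",
    "DnlDiagnostics",
    "GaussianFit",
    "DelayMap",
    "VirtualBinning",
    "DecayCube",
    "LifetimeImage",
]


class ValidationError(ValueError):
    """Raised when data violates the sensor contract."""


@dataclass(frozen=True)
class CameraGeometry:
    """Static description of the sensor and its clocks.

    Parameters
    ----------
    n_rows, n_cols
        Pixel counts (the reference device is 128 rows x 192 columns).
    n_tdc_codes
        Number of raw TDC codes per pixel, *including* the reserved
        no-photon code 0.  Histograms therefore have ``n_tdc_codes - 1``
        bins.
    reset_period_ns
        Master-reset (synchronization clock) period ``dT`` in ns; the TDC
        active range.  Equals the reciprocal of the sync clock frequency.
    laser_rate_mhz
        Pulsed-laser repetition rate in MHz (metadata; pile-up arguments
        only).
    exposure_time_ms
        Single-frame exposure time in ms.
    """

    n_rows: int
    n_cols: int
    n_tdc_codes: int
    reset_period_ns: float
    laser_rate_mhz: float = 78.0
    exposure_time_ms: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_tdc_codes) < 1:
            raise ValidationError("n_rows, n_cols and n_tdc_codes must be >= 1")
        if self.reset_period_ns <= 0:
            raise ValidationError("reset_period_ns must be > 0")
        if self.exposure_time_ms <= 0:
            raise ValidationError("exposure_time_ms must be > 0")

    @property
    def n_bins(self) -> int:
        """Number of histogram bins (codes 1 .. n_tdc_codes - 1)."""
        return self.n_tdc_codes - 1

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def exposure_time_s(self) -> float:
        return self.exposure_time_ms * 1e-3

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "n_tdc_codes": self.n_tdc_codes,
            "reset_period_ns": self.reset_period_ns,
            "laser_rate_mhz": self.laser_rate_mhz,
            "exposure_time_ms": self.exposure_time_ms,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CameraGeometry":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            n_tdc_codes=int(d["n_tdc_codes"]),
            reset_period_ns=float(d["reset_period_ns"]),
            laser_rate_mhz=float(d.get("laser_rate_mhz", 78.0)),
            exposure_time_ms=float(d.get("exposure_time_ms", 1.0)),
        )


@dataclass
class FrameStack:
    """A stack of single-photon frames (TDC-code images).

    ``frames`` has shape ``(n_frames, n_rows, n_cols)`` and integer dtype;
    every code must lie in ``[0, n_tdc_codes)``.
    """

    frames: np.ndarray
    geometry: CameraGeometry

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a 3-D (n_frames, rows, cols) array")
        if self.frames.shape[1:] != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValidationError(
                f"frame shape {self.frames.shape[1:]} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise ValidationError("TDC codes must be integers")
        self.validate_codes()

    def validate_codes(self) -> None:
        bad = (self.frames < 0) | (self.frames >= self.geometry.n_tdc_codes)
        if bad.any():
            f, r, c = (int(x[0]) for x in np.nonzero(bad))
            raise ValidationError(
                f"TDC code {int(self.frames[f, r, c])} out of range "
                f"[0, {self.geometry.n_tdc_codes}) at frame {f}, pixel ({r}, {c})"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def photon_counts(self) -> np.ndarray:
        """Per-pixel number of detected photons (nonzero codes)."""
        return np.count_nonzero(self.frames, axis=0)


@dataclass
class PixelHistogram:
    """Photon counts per TDC bin for one pixel (code 0 excluded)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValidationError("PixelHistogram.counts must be 1-D")
        if (self.counts < 0).any():
            raise ValidationError("histogram counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class HistogramCube:
    """Per-pixel photon-arrival histograms over the full array.

    ``counts`` has shape ``(n_rows, n_cols, n_bins)`` where bin ``i`` counts
    TDC code ``i + 1``.
    """

    counts: np.ndarray
    geometry: CameraGeometry
    n_frames: int
    exposure_time_ms: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (self.geometry.n_rows, self.geometry.n_cols, self.geometry.n_bins)
        if self.counts.shape != expected:
            raise ValidationError(
                f"histogram cube shape {self.counts.shape} != expected {expected}"
            )
        if self.exposure_time_ms is None:
            self.exposure_time_ms = self.geometry.exposure_time_ms

    @property
    def totals(self) -> np.ndarray:
        """Per-pixel photon totals."""
        return self.counts.sum(axis=2)

    def pixel(self, row: int, col: int) -> PixelHistogram:
        return PixelHistogram(self.counts[row, col])


@dataclass
class TdcCalibration:
    """Per-pixel TDC bin-width calibration.

    ``widths_ps[r, c, i]`` is the absolute width (ps) of histogram bin
    ``i`` for pixel (r, c); zero outside the active range
    ``[i_rise, i_fall]``.  For every valid pixel the active widths sum to
    the reset period ``dT`` (enforced by renormalization).
    """

    i_rise: np.ndarray
    i_fall: np.ndarray
    widths_ps: np.ndarray
    reset_period_ns: float
    totals: np.ndarray
    valid: np.ndarray

    @property
    def reset_period_ps(self) -> float:
        return self.reset_period_ns * 1e3

    def active_slice(self, row: int, col: int) -> slice:
        return slice(int(self.i_rise[row, col]), int(self.i_fall[row, col]) + 1)

    def bin_edges_ps(self, row: int, col: int) -> np.ndarray:
        """Cumulative time edges (ps) of the active bins, starting at 0."""
        w = self.widths_ps[row, col, self.active_slice(row, col)]
        return np.concatenate(([0.0], np.cumsum(w)))

    def bin_centers_ns(self, row: int, col: int) -> np.ndarray:
        e = self.bin_edges_ps(row, col)
        return (e[:-1] + e[1:]) / 2e3

    def to_dict(self) -> dict[str, Any]:
        return {
            "format": "spadflim-tdc-calibration",
            "version": 1,
            "reset_period_ns": self.reset_period_ns,
            "i_rise": self.i_rise.tolist(),
            "i_fall": self.i_fall.tolist(),
            "widths_ps": self.widths_ps.tolist(),
            "totals": self.totals.tolist(),
            "valid": self.valid.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TdcCalibration":
        return cls(
            i_rise=np.asarray(d["i_rise"], dtype=np.int64),
            i_fall=np.asarray(d["i_fall"], dtype=np.int64),
            widths_ps=np.asarray(d["widths_ps"], dtype=float),
            reset_period_ns=float(d["reset_period_ns"]),
            totals=np.asarray(d["totals"], dtype=np.int64),
            valid=np.asarray(d["valid"], dtype=bool),
        )


@dataclass
class DarkCountMap:
    """Per-pixel dark-count rates and the derived hot-pixel mask.

    The mask marks exactly ``ceil(quantile * n_pixels)`` pixels with the
    highest rate; rate ties are broken by row-major pixel order.
    """

    rate_hz: np.ndarray
    hot_mask: np.ndarray
    quantile: float = 0.20

    def to_dict(self) -> dict[str, Any]:
        return {
            "format": "spadflim-dark-map",
            "version": 1,
            "quantile": self.quantile,
            "rate_hz": self.rate_hz.tolist(),
            "hot_mask": self.hot_mask.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DarkCountMap":
        return cls(
            rate_hz=np.asarray(d["rate_hz"], dtype=float),
            hot_mask=np.asarray(d["hot_mask"], dtype=bool),
            quantile=float(d["quantile"]),
        )


@dataclass
class DnlDiagnostics:
    """Differential-nonlinearity diagnostics for one pixel.

    ``density`` is the photon probability density: active-bin counts divided
    by their mean (mean 1 by construction).  ``normalized_std`` is the
    standard deviation of the active-bin counts divided by the square root
    of the pixel's total photons.  ``spectrum`` is the magnitude of the
    discrete Fourier transform of the density over the active bins
    (``numpy.fft.rfft`` layout).
    """

    density: np.ndarray
    normalized_std: float
    spectrum: np.ndarray
    n_active: int


@dataclass
class GaussianFit:
    """Result of fitting a Gaussian + constant background to an IRF."""

    mu_ns: float
    sigma_ns: float
    amplitude: float
    background: float
    valid: bool
    residual_norm: float = float("nan")
    mu_stderr_ns: float = float("nan")


@dataclass
class DelayMap:
    """Per-pixel master-reset timing delays derived from IRF peaks.

    ``delay_ns = mu - reference`` where ``mu`` is the fitted IRF peak
    position and the reference is the median of ``mu`` over valid pixels.
    The correction applied during resampling is ``-delay_ns``, so corrected
    IRFs align at the reference time.
    """

    mu_ns: np.ndarray
    delay_ns: np.ndarray
    valid: np.ndarray
    reference_ns: float
    convention: str = "median-mu"

    def to_dict(self) -> dict[str, Any]:
        return {
            "format": "spadflim-delay-map",
            "version": 1,
            "convention": self.convention,
            "reference_ns": self.reference_ns,
            "mu_ns": np.where(np.isfinite(self.mu_ns), self.mu_ns, None).tolist(),
            "delay_ns": np.where(np.isfinite(self.delay_ns), self.delay_ns, None).tolist(),
            "valid": self.valid.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DelayMap":
        mu = np.asarray(
            [[np.nan if v is None else v for v in row] for row in d["mu_ns"]], dtype=float
        )
        delay = np.asarray(
            [[np.nan if v is None else v for v in row] for row in d["delay_ns"]], dtype=float
        )
        return cls(
            mu_ns=mu,
            delay_ns=delay,
            valid=np.asarray(d["valid"], dtype=bool),
            reference_ns=float(d["reference_ns"]),
            convention=str(d.get("convention", "median-mu")),
        )


@dataclass(frozen=True)
class VirtualBinning:
    """Equidistant "virtual" TDC bins for the corrected histograms.

    Bins are half-open ``[start + j*w, start + (j+1)*w)`` in ps.  Virtual
    bins that only partially overlap a pixel's (shifted) arrival-time range
    are dropped and the photons falling in them discarded (edge policy
    ``drop-partial``).
    """

    width_ps: float
    n_bins: int
    start_ps: float = 0.0

    def __post_init__(self) -> None:
        if self.width_ps <= 0:
            raise ValidationError("virtual bin width must be > 0")
        if self.n_bins < 1:
            raise ValidationError("need at least one virtual bin")

    @property
    def edges_ps(self) -> np.ndarray:
        return self.start_ps + self.width_ps * np.arange(self.n_bins + 1)

    @property
    def centers_ns(self) -> np.ndarray:
        e = self.edges_ps
        return (e[:-1] + e[1:]) / 2e3

    @classmethod
    def covering(cls, reset_period_ns: float, width_ps: float, start_ps: float = 0.0):
        """Bins of the given width covering [start, reset period]."""
        n = int(np.floor((reset_period_ns * 1e3 - start_ps) / width_ps + 1e-9))
        return cls(width_ps=width_ps, n_bins=max(n, 1), start_ps=start_ps)

    def to_dict(self) -> dict[str, Any]:
        return {"width_ps": self.width_ps, "n_bins": self.n_bins, "start_ps": self.start_ps}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "VirtualBinning":
        return cls(
            width_ps=float(d["width_ps"]),
            n_bins=int(d["n_bins"]),
            start_ps=float(d.get("start_ps", 0.0)),
        )


@dataclass
class DecayCube:
    """Corrected per-pixel decay histograms over equidistant virtual bins."""

    counts: np.ndarray
    binning: VirtualBinning
    geometry: CameraGeometry
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValidationError("decay cube counts must be 3-D")
        if self.counts.shape[2] != self.binning.n_bins:
            raise ValidationError("decay cube depth does not match virtual binning")
        if (self.counts < 0).any():
            raise ValidationError("decay cube counts must be non-negative")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    @property
    def times_ns(self) -> np.ndarray:
        return self.binning.centers_ns


@dataclass
class LifetimeImage:
    """Per-pixel single-exponential lifetime estimates (the FLIM product)."""

    tau_ns: np.ndarray
    amplitude: np.ndarray
    background: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    tau_range_ns: tuple[float, float] = (0.5, 1.6)

    def __post_init__(self) -> None:
        if (self.intensity < 0).any():
            raise ValidationError("intensity must be non-negative")
        bad = self.valid & ~(self.tau_ns > 0)
        if bad.any():
            raise ValidationError("valid pixels must carry a positive lifetime")
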