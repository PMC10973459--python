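"""Monte-Carlo linearization of TDC histograms.

The sensor reports photon arrival times quantized into TDC bins of unequal
width (differential nonlinearity) and shifted by a per-pixel reset delay.
The correction replaces each recorded photon with a synthetic arrival time
drawn uniformly within its bin's calibrated time span, shifts it by the
pixel's delay correction, and re-histograms all photons into equidistant
"virtual" bins.  The result is one stochastic realization of the corrected
decay, exactly reproducible from (inputs, seed).

Edge policy: virtual bins that only partially overlap the pixel's shifted
arrival-time range are dropped, and photons landing in them are discarded
(and tallied) — a partially covered bin would otherwise be biased low.

Randomness: every pixel draws from its own substream keyed by
``(seed, row, col)``, so results do not depend on pixel iteration order
and are reproducible under parallel execution.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from .datatypes import (
    DecayCube,
    DelayMap,
    FrameStack,
    HistogramCube,
    TdcCalibration,
    VirtualBinning,
)
from .io import accumulate_histograms

__all__ = [
    "CalibrationCoverageWarning",
    "resample_pixel",
    "default_virtual_binning",
    "correct_cube",
    "correct_framewise",
]

_EDGE_EPS_PS = 1e-6


class CalibrationCoverageWarning(UserWarning):
    """Photons recorded in bins the calibration assigned zero width."""


def _seed_tuple(seed) -> tuple[int, ...]:
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


def resample_pixel(
    counts: np.ndarray,
    widths_ps: np.ndarray,
    delay_ps: float,
    binning: VirtualBinning,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Resample one pixel's recorded photons into virtual bins.

    For each of the ``counts[i]`` photons recorded in active bin ``i``, a
    synthetic arrival time is drawn uniformly over
    ``[left_i, left_i + W_i)`` with ``left_i = sum(W_j, j < i)``, shifted
    by ``delay_ps``, and counted into the virtual bins.  Partial edge bins
    are dropped (zeroed) and their photons counted as discarded.

    Returns ``(virtual_counts, n_discarded)``; ``virtual_counts`` has
    length ``binning.n_bins``.
    """
    counts = np.asarray(counts)
    widths = np.asarray(widths_ps, dtype=float)
    if counts.shape != widths.shape or counts.ndim != 1:
        raise ValueError("counts and widths must be 1-D arrays of equal length")
    if (counts < 0).any():
        raise ValueError("negative photon counts")
    if (widths < 0).any():
        raise ValueError("negative bin widths")
    total = int(counts.sum())
    if total == 0:
        return np.zeros(binning.n_bins, dtype=np.int64), 0
    if widths.sum() <= 0:
        raise ValueError("all-zero bin widths cannot carry photons")

    lefts = np.concatenate(([0.0], np.cumsum(widths)[:-1]))
    spans = widths.copy()
    uncovered = (counts > 0) & (widths == 0)
    if uncovered.any():
        # Calibration saw no photons in these codes: spread their photons
        # over one mean active-bin width from the bin's left edge.
        warnings.warn(
            f"{int(counts[uncovered].sum())} photons in zero-width bins; "
            "spreading over one mean bin width",
            CalibrationCoverageWarning,
            stacklevel=2,
        )
        spans[uncovered] = widths[widths > 0].mean()

    t = np.repeat(lefts, counts) + rng.random(total) * np.repeat(spans, counts)
    t += delay_ps

    edges = binning.edges_ps
    lo = delay_ps  # photon support after the shift
    hi = delay_ps + float(widths.sum())
    full = (edges[:-1] >= lo - _EDGE_EPS_PS) & (edges[1:] <= hi + _EDGE_EPS_PS)

    hist, _ = np.histogram(t, bins=edges)
    hist = hist.astype(np.int64)
    hist[~full] = 0
    return hist, total - int(hist.sum())


def default_virtual_binning(calib: TdcCalibration) -> VirtualBinning:
    """Virtual bins matching the median pixel's mean true bin width.

    width = dT / (number of active bins of the median pixel), i.e. about
    the sensor's mean TDC step; bins cover [0, dT).
    """
    n_active = (calib.i_fall - calib.i_rise + 1)[calib.valid]
    if n_active.size == 0:
        raise ValueError("calibration has no valid pixels")
    n = int(np.median(n_active))
    return VirtualBinning(width_ps=calib.reset_period_ps / n, n_bins=n, start_ps=0.0)


def correct_cube(
    hist_cube: HistogramCube,
    calib: TdcCalibration,
    delays: DelayMap | None = None,
    binning: VirtualBinning | None = None,
    seed: int | Sequence[int] = 0,
    invalid_delay_policy: str = "skip",
) -> DecayCube:
    """Monte-Carlo-correct a whole histogram cube.

    Per pixel: ``resample_pixel`` with that pixel's calibrated widths and
    delay correction ``-delay_ns`` (so corrected IRFs align at the delay
    map's reference time).  Pixels the delay map marks invalid are left
    empty (``invalid_delay_policy='skip'``) or corrected with zero delay
    (``'zero-delay'``).  Photons recorded outside the calibrated active
    range are discarded and tallied in the provenance.
    """
    geometry = hist_cube.geometry
    if calib.widths_ps.shape != hist_cube.counts.shape:
        raise ValueError(
            f"calibration shape {calib.widths_ps.shape} does not match "
            f"cube shape {hist_cube.counts.shape}"
        )
    if invalid_delay_policy not in ("skip", "zero-delay"):
        raise ValueError(f"unknown invalid_delay_policy {invalid_delay_policy!r}")
    if binning is None:
        binning = default_virtual_binning(calib)
    base = _seed_tuple(seed)

    out = np.zeros((geometry.n_rows, geometry.n_cols, binning.n_bins), dtype=np.int64)
    discarded_edges = 0
    discarded_inactive = 0
    skipped_pixels = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationCoverageWarning)
        for r in range(geometry.n_rows):
            for c in range(geometry.n_cols):
                counts = hist_cube.counts[r, c]
                if not calib.valid[r, c]:
                    discarded_inactive += int(counts.sum())
                    skipped_pixels += 1
                    continue
                if delays is None:
                    delay_ns = 0.0
                elif delays.valid[r, c]:
                    delay_ns = float(delays.delay_ns[r, c])
                elif invalid_delay_policy == "zero-delay":
                    delay_ns = 0.0
                else:
                    discarded_inactive += int(counts.sum())
                    skipped_pixels += 1
                    continue
                sl = calib.active_slice(r, c)
                discarded_inactive += int(counts.sum() - counts[sl].sum())
                rng = np.random.default_rng(base + (r, c))
                vcounts, n_drop = resample_pixel(
                    counts[sl], calib.widths_ps[r, c, sl], -delay_ns * 1e3, binning, rng
                )
                out[r, c] = vcounts
                discarded_edges += n_drop
    provenance = {
        "seed": list(base),
        "input_photons": int(hist_cube.counts.sum()),
        "output_photons": int(out.sum()),
        "discarded_edge_photons": discarded_edges,
        "discarded_inactive_photons": discarded_inactive,
        "skipped_pixels": skipped_pixels,
        "delay_corrected": delays is not None,
    }
    return DecayCube(counts=out, binning=binning, geometry=geometry, provenance=provenance)


def correct_framewise(
    stack: FrameStack,
    calib: TdcCalibration,
    delays: DelayMap | None = None,
    binning: VirtualBinning | None = None,
    seed: int | Sequence[int] = 0,
    frames_per_output: int | None = None,
) -> Iterable[DecayCube]:
    """Chunk a frame stack and correct each chunk into its own cube.

    Enables FLIM video: e.g. 1000 x 1 ms exposures per video frame.  Chunk
    ``k`` uses the RNG substream ``(seed, k)``, so the single-chunk case
    equals ``correct_cube(..., seed=(seed, 0))``.  A trailing partial
    chunk is kept.
    """
    if frames_per_output is None:
        frames_per_output = stack.n_frames
    if frames_per_output < 1:
        raise ValueError("frames_per_output must be >= 1")
    base = _seed_tuple(seed)
    for k, start in enumerate(range(0, stack.n_frames, frames_per_output)):
        stop = min(start + frames_per_output, stack.n_frames)
        chunk = accumulate_histograms(stack, (start, stop))
        yield correct_cube(chunk, calib, delays, binning, seed=base + (k,))
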