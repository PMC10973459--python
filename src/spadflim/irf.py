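"""Instrument-response-function fitting and the reset-delay map.

The master-reset pulse reaches each pixel's TDC with a different electronic
delay, shifting all its recorded photon times.  The per-pixel delay is
measured by illuminating the sensor with narrow light pulses (an IRF
measurement), fitting each pixel's histogram with a Gaussian plus constant
background

    M(t) = A * exp(-(t - mu)^2 / (2 sigma^2)) + Z0

and taking the fitted peak position ``mu``.  The delay map stores
``mu - reference`` with the reference chosen as the median of ``mu`` over
valid pixels (robust to hot pixels).  Applying ``-delay`` during
resampling aligns all corrected IRFs at the reference time.

Fits run on calibrated time axes (bin centers from cumulative calibrated
widths), since the model is a function of time, not of bin index.  Before
fitting, histograms are smoothed with a discrete Gaussian kernel whose
size is expressed in TDC bins; a kernel of ``k`` bins uses
``sigma = k / 6`` so the stated size spans +-3 sigma.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from .datatypes import DelayMap, GaussianFit, HistogramCube, PixelHistogram, TdcCalibration

__all__ = ["smooth_irf", "fit_irf_gaussian", "build_delay_map"]


def smooth_irf(hist, kernel_bins: int = 9) -> np.ndarray:
    """Gaussian smoothing over bin index with a truncated kernel.

    ``kernel_bins`` must be odd and >= 1; the kernel radius is
    ``(kernel_bins - 1) / 2`` and ``sigma = kernel_bins / 6`` bins.
    Total counts are preserved (zero boundary) for peaks away from the
    edges.  ``kernel_bins = 1`` is the identity.
    """
    counts = np.asarray(
        hist.counts if isinstance(hist, PixelHistogram) else hist, dtype=float
    )
    if kernel_bins < 1 or kernel_bins % 2 == 0:
        raise ValueError("kernel_bins must be odd and >= 1")
    if kernel_bins > counts.size:
        raise ValueError(
            f"kernel of {kernel_bins} bins is wider than the {counts.size}-bin range"
        )
    if kernel_bins == 1:
        return counts.copy()
    radius = (kernel_bins - 1) // 2
    return ndimage.gaussian_filter1d(
        counts, sigma=kernel_bins / 6.0, mode="constant", cval=0.0, radius=radius
    )


def _gaussian(t, a, mu, sigma, z0):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2)) + z0


def fit_irf_gaussian(times_ns: np.ndarray, counts: np.ndarray) -> GaussianFit:
    """Nonlinear least-squares Gaussian + background fit of one IRF.

    Initialization: mu0 at the argmax bin center, A0 = max - min,
    Z0 = min, sigma0 = FWHM / 2.355 from half-maximum crossings.
    Non-convergence or a peak outside the time range yields
    ``valid=False`` (no exception).
    """
    times_ns = np.asarray(times_ns, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times_ns.size != counts.size:
        raise ValueError("times and counts must have equal length")
    if times_ns.size < 5:
        raise ValueError("need at least 5 data points to fit")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")

    cmin, cmax = counts.min(), counts.max()
    if cmax <= cmin:  # degenerate flat input
        return GaussianFit(np.nan, np.nan, np.nan, float(cmin), valid=False)

    i_max = int(np.argmax(counts))
    mu0 = times_ns[i_max]
    a0 = cmax - cmin
    z0 = cmin
    half = cmin + a0 / 2.0
    above = np.nonzero(counts >= half)[0]
    fwhm = times_ns[above[-1]] - times_ns[above[0]]
    spacing = float(np.median(np.diff(times_ns))) if times_ns.size > 1 else 1.0
    sigma0 = max(fwhm / 2.355, spacing / 2.355, 1e-6)

    t_lo, t_hi = float(times_ns.min()), float(times_ns.max())
    weights = np.sqrt(np.clip(counts, 1.0, None))  # Poisson counting noise

    def _residuals(p):
        return (_gaussian(times_ns, *p) - counts) / weights

    try:
        res = optimize.least_squares(
            _residuals,
            x0=(a0, mu0, sigma0, z0),
            bounds=((0.0, t_lo - fwhm - spacing, 1e-9, 0.0),
                    (np.inf, t_hi + fwhm + spacing, t_hi - t_lo + spacing, np.inf)),
            max_nfev=5000,
        )
    except ValueError:
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, valid=False)

    a, mu, sigma, z = (float(p) for p in res.x)
    residual = float(np.linalg.norm(counts - _gaussian(times_ns, *res.x)))
    # covariance of the weighted fit from the Jacobian at the solution
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        mu_stderr = float(np.sqrt(jtj_inv[1, 1]))
    except np.linalg.LinAlgError:
        mu_stderr = np.nan
    converged = res.status > 0
    valid = bool(converged and a > 0 and sigma > 0 and t_lo <= mu <= t_hi)
    return GaussianFit(
        mu_ns=mu,
        sigma_ns=sigma,
        amplitude=a,
        background=z,
        valid=valid,
        residual_norm=residual,
        mu_stderr_ns=mu_stderr,
    )


def build_delay_map(
    irf_cube: HistogramCube,
    calib: TdcCalibration,
    kernel_bins: int = 9,
    min_photons: int = 50,
) -> DelayMap:
    """Fit every pixel's IRF and build the relative reset-delay map.

    Per pixel: convert active-bin indices to times via cumulative
    calibrated widths, smooth, fit a Gaussian, record the peak position
    mu.  The delay is ``mu - median(mu over valid pixels)``.  Raises if
    more than half the calibrated pixels fail to fit (bad acquisition).
    """
    geometry = irf_cube.geometry
    shape = (geometry.n_rows, geometry.n_cols)
    mu = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            if not calib.valid[r, c]:
                continue
            sl = calib.active_slice(r, c)
            counts = irf_cube.counts[r, c, sl].astype(float)
            if counts.sum() < min_photons or counts.size < max(5, kernel_bins):
                continue
            widths = calib.widths_ps[r, c, sl]
            keep = widths > 0  # zero-width bins carry no time information
            times = calib.bin_centers_ns(r, c)[keep]
            smoothed = smooth_irf(counts, kernel_bins)[keep]
            if times.size < 5:
                continue
            fit = fit_irf_gaussian(times, smoothed)
            if fit.valid:
                mu[r, c] = fit.mu_ns
                valid[r, c] = True
    n_calibrated = int(calib.valid.sum())
    if n_calibrated == 0 or valid.sum() <= 0.5 * n_calibrated:
        raise RuntimeError(
            f"IRF fits converged in only {int(valid.sum())}/{n_calibrated} pixels; "
            "the IRF acquisition looks unusable"
        )
    reference = float(np.median(mu[valid]))
    delay = mu - reference
    delay[~valid] = np.nan
    return DelayMap(mu_ns=mu, delay_ns=delay, valid=valid, reference_ns=reference)
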