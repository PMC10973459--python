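import numpy as np
import pytest

import spadflim as sf


@pytest.fixture(scope="session")
def small_camera():
    """Nonlinear 8x12 camera, 10 ns reset, 200 active bins of ~50 ps."""
    return sf.make_camera(
        n_rows=8, n_cols=12, reset_period_ns=10.0, mean_bin_ps=50.0,
        delay_span_ns=2.0, delay_mode="uniform", guard_bins=2, seed=0,
    )


@pytest.fixture(scope="session")
def linear_camera():
    """Ideal 4x6 camera: equal bin widths, no delays, no dark counts."""
    cam = sf.make_camera(
        n_rows=4, n_cols=6, reset_period_ns=10.0, mean_bin_ps=250.0,
        dnl_amplitude=0.0, delay_span_ns=0.0, guard_bins=2, seed=0,
    )
    cam.dark_rate_hz[:] = 0.0
    return cam


@pytest.fixture(scope="session")
def small_calibration(small_camera):
    """Constant-light calibration at ~2e5 photons per TDC bin (the
    acquisition budget a days-long calibration run accumulates)."""
    cube = sf.simulate_histogram_cube(
        small_camera, sf.LightModel("constant", 0.3), photons_per_bin=2e5, seed=5
    )
    return sf.calibrate_tdc(cube, small_camera.geometry.reset_period_ns)


def overlap_expected_counts(counts, widths_ps, delay_ps, binning):
    """Deterministic oracle: expected virtual counts from overlap fractions.

    Each recorded photon is uniform over its bin's span, so the expected
    count in virtual bin j is sum_i N_i * |bin_i ∩ vbin_j| / W_i, with
    partially covered virtual bins zeroed (the drop-partial edge policy).
    """
    counts = np.asarray(counts, dtype=float)
    widths = np.asarray(widths_ps, dtype=float)
    lefts = np.concatenate(([0.0], np.cumsum(widths)[:-1])) + delay_ps
    rights = lefts + widths
    edges = binning.edges_ps
    lo, hi = delay_ps, delay_ps + widths.sum()
    expected = np.zeros(binning.n_bins)
    for j in range(binning.n_bins):
        a, b = edges[j], edges[j + 1]
        if a < lo - 1e-9 or b > hi + 1e-9:
            continue  # partial edge bin: dropped
        ov = np.clip(np.minimum(rights, b) - np.maximum(lefts, a), 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(widths > 0, ov / widths, 0.0)
        expected[j] = float(np.sum(counts * frac))
    return expected
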