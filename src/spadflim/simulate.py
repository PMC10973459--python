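"""Synthetic SPAD-array camera with a fully known ground truth.

The simulator emulates the acquisition model of a TCSPC SPAD array with
in-pixel TDCs: repeated short exposures; in each exposure a pixel detects
at most one photon (the detection disables the pixel until the next
exposure); the photon's arrival time relative to the master reset is
shifted by a per-pixel electronic delay and quantized by that pixel's
nonlinear TDC into an integer code; code 0 means no photon.

Ground truth the estimators are tested against:

* per-pixel TDC bin widths — an 8-periodic multiplicative pattern around a
  38 ps mean step (the eight-step ring-oscillator signature), drawn
  independently per pixel;
* per-pixel reset delays — a smooth gradient across the array or uniform
  draws, spanning ~3.5 ns by default;
* per-pixel dark-count rates — log-normal, median 8.3 Hz by default.

Light models: ``constant`` (uniform arrival times over the reset period),
``irf_pulse`` (a ~100 ps Gaussian pulse), and ``decay`` (single-exponential
fluorescence decay convolved with a Gaussian IRF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .datatypes import CameraGeometry, FrameStack, HistogramCube
from .io import write_frame_stack

def _seed_tuple(seed) -> tuple[int, ...]:
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


__all__ = [
    "GroundTruthCamera",
    "LightModel",
    "make_camera",
    "simulate_stack",
    "simulate_histogram_cube",
    "make_fixture_suite",
    "FIXTURE_PROFILES",
]


@dataclass
class GroundTruthCamera:
    """A camera whose every imperfection is known exactly.

    ``widths_ps`` holds the true width of each histogram bin (zero outside
    the active range ``[i_rise, i_fall]``, shared by all pixels); active
    widths sum to the reset period for every pixel.  ``delays_ns`` and
    ``dark_rate_hz`` are per-pixel.
    """

    geometry: CameraGeometry
    widths_ps: np.ndarray
    delays_ns: np.ndarray
    dark_rate_hz: np.ndarray
    i_rise: int
    i_fall: int

    def __post_init__(self) -> None:
        reset_ps = self.geometry.reset_period_ns * 1e3
        sums = self.widths_ps[..., self.i_rise : self.i_fall + 1].sum(axis=-1)
        if not np.allclose(sums, reset_ps, rtol=1e-9):
            raise ValueError("active widths must sum to the reset period in every pixel")
        if not np.isfinite(self.delays_ns).all():
            raise ValueError("delays must be finite")
        if (self.dark_rate_hz < 0).any():
            raise ValueError("dark rates must be non-negative")

    @property
    def n_active(self) -> int:
        return self.i_fall - self.i_rise + 1

    def quantize(self, row: int, col: int, t_ns: np.ndarray) -> np.ndarray:
        """Map shifted arrival times (ns, already mod reset period) to codes."""
        w = self.widths_ps[row, col, self.i_rise : self.i_fall + 1]
        inner_edges_ns = np.cumsum(w)[:-1] / 1e3
        bins = self.i_rise + np.searchsorted(inner_edges_ns, t_ns, side="right")
        return bins + 1  # histogram bin i holds TDC code i + 1

    def to_dict(self) -> dict[str, Any]:
        return {
            "format": "spadflim-ground-truth",
            "version": 1,
            "geometry": self.geometry.to_dict(),
            "widths_ps": self.widths_ps.tolist(),
            "delays_ns": self.delays_ns.tolist(),
            "dark_rate_hz": self.dark_rate_hz.tolist(),
            "i_rise": self.i_rise,
            "i_fall": self.i_fall,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GroundTruthCamera":
        return cls(
            geometry=CameraGeometry.from_dict(d["geometry"]),
            widths_ps=np.asarray(d["widths_ps"], dtype=float),
            delays_ns=np.asarray(d["delays_ns"], dtype=float),
            dark_rate_hz=np.asarray(d["dark_rate_hz"], dtype=float),
            i_rise=int(d["i_rise"]),
            i_fall=int(d["i_fall"]),
        )


@dataclass
class LightModel:
    """Illumination reaching the sensor.

    ``mean_photons_per_exposure`` is the per-pixel mean number of detected
    signal photons per exposure (must stay well below 1: single-photon
    regime, count rate far under the laser rate, so pile-up is
    negligible).
    """

    mode: str = "constant"  # constant | irf_pulse | decay
    mean_photons_per_exposure: float = 0.1
    pulse_center_ns: float | None = None
    pulse_sigma_ns: float = 0.1
    tau_ns: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "irf_pulse", "decay"):
            raise ValueError(f"unknown light mode {self.mode!r}")
        if not 0 < self.mean_photons_per_exposure < 1:
            raise ValueError(
                "mean_photons_per_exposure must be in (0, 1): single-photon regime"
            )
        if self.pulse_sigma_ns <= 0 or self.tau_ns <= 0:
            raise ValueError("pulse_sigma_ns and tau_ns must be > 0")

    def center(self, reset_period_ns: float) -> float:
        return (
            self.pulse_center_ns
            if self.pulse_center_ns is not None
            else reset_period_ns / 4.0
        )

    def sample_times(
        self, n: int, reset_period_ns: float, rng: np.random.Generator
    ) -> np.ndarray:
        """True arrival times (ns) within one reset period."""
        if self.mode == "constant":
            return rng.uniform(0.0, reset_period_ns, n)
        t0 = self.center(reset_period_ns)
        if self.mode == "irf_pulse":
            t = rng.normal(t0, self.pulse_sigma_ns, n)
        else:  # decay: exponential convolved with the Gaussian IRF
            t = t0 + rng.exponential(self.tau_ns, n) + rng.normal(0.0, self.pulse_sigma_ns, n)
        return np.mod(t, reset_period_ns)


def make_camera(
    n_rows: int = 16,
    n_cols: int = 24,
    reset_period_ns: float = 50.0,
    mean_bin_ps: float = 38.0,
    dnl_amplitude: float = 0.3,
    dnl_period: int = 8,
    delay_span_ns: float = 3.5,
    delay_mode: str = "gradient",
    dark_rate_median_hz: float = 8.3,
    dark_rate_sigma: float = 1.0,
    guard_bins: int = 4,
    exposure_time_ms: float = 1.0,
    laser_rate_mhz: float = 78.0,
    seed: int = 0,
) -> GroundTruthCamera:
    """Build a ground-truth camera with the default artefact structure.

    Bin widths follow ``W_i ∝ 1 + a * p[i mod 8]`` with a zero-mean
    pattern vector ``p`` (max |p| = 1) drawn independently per pixel and
    ``a = dnl_amplitude``; widths are renormalized to sum to the reset
    period.  Delays form a smooth column gradient (``delay_mode
    'gradient'``) or uniform draws over ``[0, delay_span_ns]``
    (``'uniform'``).  ``guard_bins`` empty codes pad each side of the
    active range.
    """
    rng = np.random.default_rng(seed)
    reset_ps = reset_period_ns * 1e3
    n_active = max(int(round(reset_ps / mean_bin_ps)), dnl_period)
    n_bins = n_active + 2 * guard_bins
    geometry = CameraGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        n_tdc_codes=n_bins + 1,
        reset_period_ns=reset_period_ns,
        laser_rate_mhz=laser_rate_mhz,
        exposure_time_ms=exposure_time_ms,
    )
    i_rise = guard_bins
    i_fall = guard_bins + n_active - 1

    # per-pixel zero-mean pattern vectors, max-normalized
    p = rng.standard_normal((n_rows, n_cols, dnl_period))
    p -= p.mean(axis=-1, keepdims=True)
    p /= np.abs(p).max(axis=-1, keepdims=True)
    pattern = p[..., np.arange(n_active) % dnl_period]
    base = reset_ps / n_active
    active = base * (1.0 + dnl_amplitude * pattern)
    active = np.clip(active, 0.02 * base, None)
    active *= reset_ps / active.sum(axis=-1, keepdims=True)
    widths = np.zeros((n_rows, n_cols, n_bins))
    widths[..., i_rise : i_fall + 1] = active

    if delay_mode == "gradient":
        cols = np.linspace(0.0, 1.0, n_cols)
        rows = np.sin(np.linspace(0.0, np.pi, n_rows)) * 0.1
        delays = delay_span_ns * np.clip(cols[None, :] * 0.9 + rows[:, None], 0.0, 1.0)
    elif delay_mode == "uniform":
        delays = rng.uniform(0.0, delay_span_ns, (n_rows, n_cols))
    else:
        raise ValueError(f"unknown delay_mode {delay_mode!r}")

    dark = rng.lognormal(np.log(dark_rate_median_hz), dark_rate_sigma, (n_rows, n_cols))
    return GroundTruthCamera(
        geometry=geometry,
        widths_ps=widths,
        delays_ns=delays,
        dark_rate_hz=dark,
        i_rise=i_rise,
        i_fall=i_fall,
    )


def simulate_stack(
    camera: GroundTruthCamera,
    light: LightModel,
    n_frames: int,
    seed: int = 0,
    store: str = "first",
    log_photons: bool = False,
):
    """Simulate a stack of single-photon frames.

    Per pixel per frame, the number of candidate photons is
    ``Poisson(lambda_signal + lambda_dark)``; if at least one arrives,
    exactly one is stored.  Candidates within an exposure are i.i.d., so
    the stored photon's TCSPC time has the same distribution whether the
    first or the last candidate is kept; the ``store`` switch ('first' or
    'last') is accepted for the record and documented as
    distribution-equivalent.  The stored photon's true arrival time comes
    from the light model (dark counts: uniform), is shifted by the pixel's
    true delay modulo the reset period, and quantized by that pixel's true
    bin widths.

    With ``log_photons=True`` also returns a dict of arrays
    (row, col, t_shifted_ns, code) for quantization audits.
    """
    if store not in ("first", "last"):
        raise ValueError("store must be 'first' or 'last'")
    geometry = camera.geometry
    reset = geometry.reset_period_ns
    base = _seed_tuple(seed)
    lam_sig = light.mean_photons_per_exposure
    frames = np.zeros((n_frames, geometry.n_rows, geometry.n_cols), dtype=np.uint16)
    log: dict[str, list] = {"row": [], "col": [], "t_shifted_ns": [], "code": []}
    for r in range(geometry.n_rows):
        for c in range(geometry.n_cols):
            rng = np.random.default_rng(base + (r, c))
            lam_dark = camera.dark_rate_hz[r, c] * geometry.exposure_time_s
            lam = lam_sig + lam_dark
            if lam >= 1:
                raise ValueError(
                    f"mean photons per exposure {lam:.3f} >= 1 at pixel ({r}, {c}); "
                    "violates the single-photon regime"
                )
            k = rng.poisson(lam, n_frames)
            det = np.nonzero(k > 0)[0]
            n_det = det.size
            if n_det == 0:
                continue
            is_signal = rng.random(n_det) < lam_sig / lam
            t = np.empty(n_det)
            n_sig = int(is_signal.sum())
            t[is_signal] = light.sample_times(n_sig, reset, rng)
            t[~is_signal] = rng.uniform(0.0, reset, n_det - n_sig)
            t_shift = np.mod(t + camera.delays_ns[r, c], reset)
            codes = camera.quantize(r, c, t_shift)
            frames[det, r, c] = codes
            if log_photons:
                log["row"].append(np.full(n_det, r))
                log["col"].append(np.full(n_det, c))
                log["t_shifted_ns"].append(t_shift)
                log["code"].append(codes)
    stack = FrameStack(frames=frames, geometry=geometry)
    if log_photons:
        out = {k: np.concatenate(v) if v else np.empty(0) for k, v in log.items()}
        return stack, out
    return stack


def simulate_histogram_cube(
    camera: GroundTruthCamera,
    light: LightModel,
    photons_per_pixel: float | None = None,
    photons_per_bin: float | None = None,
    seed: int = 0,
) -> HistogramCube:
    """Simulate aggregated photon histograms directly (no frame stream).

    This is the exact aggregate of the frame path at low occupancy:
    per-bin counts are independent Poisson with means proportional to the
    photon flux falling in each bin.  For ``constant`` light with
    ``photons_per_bin`` the counts are drawn per bin (mean scaled by the
    bin's true relative width); otherwise ``Poisson(photons_per_pixel)``
    arrival times are drawn from the light model and quantized.  Dark
    counts are not added (they are negligible at calibration photon
    budgets and carry their own acquisition in practice).
    """
    geometry = camera.geometry
    reset = geometry.reset_period_ns
    base = _seed_tuple(seed)
    counts = np.zeros((geometry.n_rows, geometry.n_cols, geometry.n_bins), dtype=np.int64)
    sl = slice(camera.i_rise, camera.i_fall + 1)
    if photons_per_bin is not None:
        if light.mode != "constant":
            raise ValueError("photons_per_bin applies to constant light only")
        mean_w = camera.widths_ps[..., sl].mean(axis=-1, keepdims=True)
        lam = photons_per_bin * camera.widths_ps[..., sl] / mean_w
        rng = np.random.default_rng(base + (0,))
        counts[..., sl] = rng.poisson(lam)
    elif photons_per_pixel is not None:
        for r in range(geometry.n_rows):
            for c in range(geometry.n_cols):
                rng = np.random.default_rng(base + (r, c))
                n = rng.poisson(photons_per_pixel)
                if n == 0:
                    continue
                t = light.sample_times(n, reset, rng)
                t_shift = np.mod(t + camera.delays_ns[r, c], reset)
                codes = camera.quantize(r, c, t_shift)
                counts[r, c] = np.bincount(codes - 1, minlength=geometry.n_bins)
    else:
        raise ValueError("give photons_per_pixel or photons_per_bin")
    total_max = int(counts.sum(axis=2).max())
    lam = light.mean_photons_per_exposure
    n_frames = max(int(np.ceil(total_max / lam)), 1)
    return HistogramCube(
        counts=counts,
        geometry=geometry,
        n_frames=n_frames,
        exposure_time_ms=geometry.exposure_time_ms,
    )


FIXTURE_PROFILES = (
    "dnl-calibration",
    "irf-calibration",
    "dark",
    "decay-single-tau",
    "decay-two-populations",
)


def make_fixture_suite(profile: str, outdir, seed: int = 0) -> dict[str, Any]:
    """Write a small synthetic acquisition plus its ground-truth document.

    Profiles (all on small arrays so tests stay fast):

    * ``dnl-calibration`` — constant light, >= 10^3 photons per active bin
      (8x12 pixels, 16 wide active bins so the frame path reaches the
      budget);
    * ``irf-calibration`` — ~100 ps pulsed light;
    * ``dark`` — covered sensor, dark counts only;
    * ``decay-single-tau`` — tau = 1.0 ns everywhere;
    * ``decay-two-populations`` — tau = 1.0 ns and 1.7 ns in left/right
      halves (the structure of a treated-vs-control experiment).

    Returns a manifest dict naming the files written.
    """
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {FIXTURE_PROFILES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"profile": profile, "seed": seed}

    if profile == "dnl-calibration":
        camera = make_camera(
            n_rows=8, n_cols=12, reset_period_ns=10.0, mean_bin_ps=625.0,
            guard_bins=2, seed=seed,
        )
        light = LightModel(mode="constant", mean_photons_per_exposure=0.45)
        # detection prob 1 - exp(-0.45) ~= 0.36/frame over 16 active bins
        n_frames = 48_000  # ~= 1.1e3 photons per active bin
        stack = simulate_stack(camera, light, n_frames, seed=seed + 1)
    elif profile == "irf-calibration":
        camera = make_camera(
            n_rows=16, n_cols=24, reset_period_ns=10.0, mean_bin_ps=100.0,
            delay_span_ns=2.0, guard_bins=2, seed=seed,
        )
        light = LightModel(mode="irf_pulse", mean_photons_per_exposure=0.3,
                           pulse_center_ns=3.0)
        n_frames = 10_000
        stack = simulate_stack(camera, light, n_frames, seed=seed + 1)
    elif profile == "dark":
        camera = make_camera(n_rows=16, n_cols=24, reset_period_ns=10.0,
                             mean_bin_ps=100.0, guard_bins=2, seed=seed)
        frames = np.zeros((5000, 16, 24), dtype=np.uint16)
        rng = np.random.default_rng((seed, 99))
        lam = camera.dark_rate_hz * camera.geometry.exposure_time_s
        det = rng.poisson(lam[None, :, :], (5000, 16, 24)) > 0
        t = rng.uniform(0.0, camera.geometry.reset_period_ns, int(det.sum()))
        idx = np.nonzero(det)
        codes = np.empty(t.size, dtype=np.uint16)
        for r in range(16):
            for c in range(24):
                sel = (idx[1] == r) & (idx[2] == c)
                if sel.any():
                    codes[sel] = camera.quantize(r, c, t[sel])
        frames[idx] = codes
        stack = FrameStack(frames=frames, geometry=camera.geometry)
    else:
        tau_map = {"decay-single-tau": (1.0, 1.0), "decay-two-populations": (1.0, 1.7)}
        tau_left, tau_right = tau_map[profile]
        camera = make_camera(
            n_rows=16, n_cols=24, reset_period_ns=12.5, mean_bin_ps=100.0,
            delay_span_ns=1.5, guard_bins=2, seed=seed,
        )
        half = camera.geometry.n_cols // 2
        lights = [
            (slice(0, half), LightModel("decay", 0.3, pulse_center_ns=2.0, tau_ns=tau_left)),
            (slice(half, None), LightModel("decay", 0.3, pulse_center_ns=2.0, tau_ns=tau_right)),
        ]
        n_frames = 20_000
        parts = []
        for col_slice, light in lights:
            sub = simulate_stack(camera, light, n_frames, seed=seed + 1)
            parts.append((col_slice, sub.frames))
        frames = np.zeros_like(parts[0][1])
        for col_slice, fr in parts:
            frames[:, :, col_slice] = fr[:, :, col_slice]
        stack = FrameStack(frames=frames, geometry=camera.geometry)
        manifest["tau_ns"] = {"left": tau_left, "right": tau_right}

    stack_path = outdir / f"{profile}.frames.h5"
    truth_path = outdir / f"{profile}.truth.json"
    write_frame_stack(stack, stack_path)
    with open(truth_path, "w") as f:
        json.dump(camera.to_dict(), f)
    manifest["frames"] = str(stack_path)
    manifest["truth"] = str(truth_path)
    manifest["n_frames"] = stack.n_frames
    with open(outdir / f"{profile}.manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
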