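# Methods

This note records the models, estimators, numerical choices and known
limitations of spadflim, in the spirit of a package methods appendix.

## Acquisition model and data contract

A frame is one 2-D image of integer TDC codes from a single exposure
(default 1 ms).  Code 0 is reserved for "no photon"; code `k ≥ 1` means a
photon was timed into TDC bin `k`.  The sensor stores at most one photon
per pixel per exposure (the detection disables the pixel until the next
reset of the exposure), so per-pixel histogram totals never exceed the
frame count.  Histogram bin `i` corresponds to code `i + 1`; bins span
half-open time intervals.  Whether the stored photon is the first or
last of an exposure is immaterial in the package's model: candidate
photons within one exposure are i.i.d., so either choice has the same
marginal distribution.  The simulator exposes a `store` switch for the
record and draws the stored photon directly.

Count rates are assumed far below the laser repetition rate, so photon
pile-up is neglected throughout (at the ~100 Hz per-pixel rates of a
typical acquisition against a 78 MHz laser this is a ~10⁻⁶ effect).

## Bin-width estimation (code-density calibration)

Under constant light the arrival-time density is uniform over the reset
period ΔT, so bin counts are proportional to bin widths:
`W_i = ΔT · N_i / ΣN_i` over the active range.  Estimated widths are
renormalized so their sum equals ΔT to one ulp; the relative standard
error per bin is `1/√N_i`.

**Active-range detection.**  The rising/falling edge bins `I_R, I_F` are
found by half-crossing of a robust plateau level: the plateau is the
median of counts over bins above 10% of the maximum, and `I_R` (`I_F`)
is the first (last) bin at or above half of it.  The half-crossing rule
is stable under Poisson noise; a plateau narrower than 8 bins raises a
warning-grade signal rather than an error, since downstream diagnostics
need at least 8 bins.

**Zero-count bins.**  Bins inside the active range with zero calibration
counts get width 0 but stay in the range.  If experiment data later puts
photons into such a bin (possible under a different light level), the
resampler spreads them over one mean active-bin width from the bin's
left edge and emits a calibration-coverage warning — a degenerate case
with no principled width assignment, made visible rather than silent.

**Dark counts.**  The per-pixel dark rate is
detections / (frames × exposure).  The hot-pixel mask marks exactly
`ceil(quantile · n_pixels)` pixels (default quantile 0.20), with rate
ties broken by row-major order so the mask is deterministic.  Absolute
rate thresholds are camera-specific and deliberately not hard-coded.

## Delay map (IRF peak alignment)

The per-pixel IRF histogram is smoothed over bin index with a truncated
discrete Gaussian kernel — size expressed in TDC bins, default 9, with
`σ = size/6` so the stated size spans ±3σ — then fitted with
`M(t) = A·exp(−(t−μ)²/(2σ²)) + Z₀` on the *calibrated* time axis (bin
centers from cumulative widths), since the model is a function of time,
not of code index.  Initialization: μ at the argmax bin center,
A = max−min, Z₀ = min, σ from the FWHM of the half-maximum crossings.
The fit is weighted by `√counts` (Poisson noise), run as bounded
least-squares; non-convergence flags the pixel invalid instead of
raising.  Smoothing before fitting measurably lowers the variance of μ
on Poisson-noised pulses (a paired-seed test in the suite verifies
this).

The delay is `μ − median(μ over valid pixels)`.  The median reference is
robust to hot pixels; any global shift of all IRFs leaves the map
unchanged.  If more than half the calibrated pixels fail to fit, the
acquisition is rejected outright.  Delays are applied at full float
resolution (no rounding to whole bins).

## Monte-Carlo correction

For each recorded photon in active bin `i`, a synthetic time is drawn
uniformly over the bin's calibrated span, shifted by the pixel's delay
correction `−delay`, and counted into global equidistant virtual bins.
Uniform within-bin resampling is an approximation for decaying signals;
at ~38 ps bins the induced lifetime bias is second order
(~w²/12τ² ≈ 10⁻⁴ at τ = 1 ns) and a density-gradient refinement is left
as an extension point.

* **Virtual binning default:** ΔT divided by the median pixel's number
  of active bins — i.e. the sensor's mean TDC step — starting at 0.
  Width, count and origin are configurable.
* **Edge policy:** virtual bins only partially overlapping the pixel's
  shifted arrival-time support are zeroed and their photons tallied as
  discarded; a partially covered bin would otherwise be biased low.
  With zero delay and bins exactly covering the active range, the photon
  total is conserved for every seed.
* **Out-of-range photons:** codes outside the calibrated active range
  are discarded and counted in the cube's provenance.
* **Reproducibility:** every pixel uses an RNG substream seeded by
  (seed, row, col), so results are independent of iteration order.  The
  frame-chunked variant keys chunk `k` by (seed, k, row, col); its
  single-chunk output equals a whole-stack correction run with seed
  (seed, 0).

## Synthetic camera

The simulator is the package's ground truth, emulating the study
conditions of a 192×128-pixel sensor with ~38 ps mean steps over a 50 ns
active range (tests run geometrically scaled-down arrays; the physics is
size-independent):

* **DNL:** widths ∝ `1 + a·p[i mod 8]`, with a zero-mean, max-normalized
  8-vector `p` drawn independently per pixel and amplitude `a = 0.3` by
  default.  Per-pixel patterns reflect that each pixel carries its own
  ring oscillator; they give the raw Fourier spectrum power at the four
  harmonics of the 8-bin period and produce realistic pixel-to-pixel
  variability.
* **Delays:** a smooth column gradient or uniform draws spanning 3.5 ns
  by default, applied modulo ΔT (wrap-around, matching a TDC that times
  to the next reset edge).
* **Dark counts:** log-normal rates, median 8.3 Hz.
* **Light models:** constant (uniform times), Gaussian IRF pulse
  (σ = 100 ps default), and single-exponential decay convolved with the
  Gaussian IRF.
* **Aggregated path:** for calibration-scale photon budgets the
  simulator can draw per-bin Poisson counts directly — the exact
  aggregate of the frame path at low occupancy — while the frame path is
  exercised at small n (detection probability `1 − e^{−λ}`, quantization
  audits on logged photons).

What the simulator does *not* emulate: optical blur/lightsheet
geometry, SPAD afterpulsing or dead time beyond one photon per exposure,
TDC cross-talk, temperature drift, and clock-source nonlinearity.
Passing tests therefore demonstrate correctness of the estimators and
the corrector against the stated artefact model, not robustness to
every physical effect of real hardware.

## Lifetime fitting

Decay cubes are binned (3×3 sliding spatial window and 2× temporal by
default; block mode available) and fitted per pixel by Poisson maximum
likelihood with `m(t) = A·exp(−(t−t₀)/τ) + Z` over a window from the
virtual bin after the aligned IRF peak to the end of range.  A
least-squares pass seeds the likelihood optimization.  Fits are flagged
invalid when the window holds fewer than 10 counts, the optimizer fails,
τ reaches the configurable cap (20 ns — flat data), or the fitted decay
component itself contains fewer than 10 photons (`A·τ/Δt`), which
prevents background-only traces from reporting an arbitrary finite τ.
At reference photon budgets of a few thousand counts the estimator's
dispersion sits within a factor ~2 of the Poisson Cramér–Rao bound (the
extra spread is the price of co-estimating amplitude and background).

Display processing: hot pixels (top dark-rate quantile) and dim columns
are replaced by the nearest valid neighbor (Euclidean metric, ties to
the smallest row-major index — fully deterministic); segmentation is an
Otsu threshold followed by 3×3 binary erosion then dilation; rendering
maps τ linearly onto a colormap over the display range, scales color
value linearly with normalized intensity (no gamma), and finishes with a
2× horizontal cubic upscale for the rectangular pixel pitch.

## Problem sizes and numerical conventions

* Test and acceptance runs use scaled-down arrays (8×12 to 32×48) at the
  full 50 ns / 38 ps timing geometry where the quantity under test
  depends on it; calibration budgets mirror an acquisition of ~2×10⁵
  photons per bin, IRF acquisitions ~10⁴ photons per pixel.
* Statistical assertions use seeded RNG streams and tolerance bands of
  3–5 standard errors; chi-square flatness is judged by uniformity of
  per-pixel p-values, not by single-pixel pass/fail.
* Edge comparisons in the resampler carry a 10⁻⁶ ps tolerance so exact
  bin-boundary alignment is classified as full coverage.
* On-disk formats: HDF5 for frame stacks and cubes (self-describing
  attributes), JSON for calibration documents, TIFF/CSV for images.
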