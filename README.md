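# spadflim

Calibration, Monte-Carlo artefact correction and fluorescence-lifetime
(FLIM) analysis for time-correlated single-photon counting (TCSPC) SPAD
array cameras — plus a fully specified synthetic camera so every stage is
testable against known ground truth, without hardware.

## The problem

A TCSPC SPAD array camera times each detected photon with an in-pixel
time-to-digital converter (TDC): the interval between the photon and the
next master-reset pulse is quantized into integer codes.  Two systematic
artefacts corrupt the recorded arrival times:

* **Differential nonlinearity (DNL).**  The TDC's ring oscillator steps
  are unequal, so bin *i* has its own true width `W_i` rather than the
  nominal ~38 ps — with a characteristic 8-bin periodicity from the
  eight oscillator elements.
* **Master-reset timing delay.**  The reset pulse reaches each pixel at
  a slightly different moment, shifting all of that pixel's times by up
  to a few nanoseconds.

Downstream lifetime-analysis software assumes equal bins and no
inter-pixel shifts, so both artefacts must be removed first.

## The method

**Calibration.**  Under constant light, arrival times are uniform over
the reset period ΔT, so the photon count `N_i` in bin *i* measures its
width (over the active range `[I_R, I_F]` between the rising and falling
edges of the code-density curve):

    W_i = ΔT · N_i / Σ_{i=I_R}^{I_F} N_i ,

with relative standard error `1/√N_i` — 1% at 10⁴ photons per bin.
Per-pixel delays come from a pulsed-light instrument-response-function
(IRF) acquisition: each pixel's histogram is smoothed (9-bin Gaussian
kernel) and fitted with `M(t) = A·exp(−(t−μ)²/2σ²) + Z₀`; the delay is
`μ` minus the median `μ` over the array.

**Monte-Carlo correction.**  Every recorded photon is replaced by a
synthetic arrival time drawn uniformly within its bin's calibrated span
`[Σ_{j<i} W_j, Σ_{j≤i} W_j)`, shifted by the pixel's delay correction,
and re-histogrammed into equidistant "virtual" bins.  Virtual bins only
partially covered by the shifted time range are dropped.  This keeps
photon counts integer and Poisson-distributed — unlike per-bin scaling
corrections.  Per-pixel counter-based RNG substreams keyed by
(seed, row, col) make every cube bit-reproducible.

**FLIM.**  Corrected decay cubes are spatially/temporally binned and
fitted per pixel with a Poisson maximum-likelihood single-exponential
tail model `A·exp(−(t−t₀)/τ) + Z`, yielding lifetime images, unit-area
lifetime histograms, and intensity-weighted renderings (with hot-pixel /
dim-column nearest-neighbor clean-up, Otsu segmentation, and the 2×
horizontal cubic upscale that corrects the rectangular pixel pitch).

## Worked example

`examples/02_resample_worked_example.py` runs the five-bin rebinning
illustration — bins of widths 40/60/30/70/50 ps holding 2/6/3/7/7
photons, resampled into 50 ps virtual bins:

```
single realization: [4, 4, 6, 4, 7]  (total 25)
mean over 5000 seeds: [2.99, 5.01, 5.03, 4.97, 7.0]
overlap expectation:      [3.0, 5.0, 5.0, 5.0, 7.0]
shifted by 130 ps: [0, 0, 0, 3, 5, 6, 6, 0]  (5 photons in edge bins dropped)
```

Each run conserves the 25 photons; individual realizations fluctuate but
their seed-average converges to the deterministic overlap expectation.
With a fractional shift, the partially covered first/last virtual bins
are dropped and their photons discarded.

`examples/03_delay_map_correction.py` closes the delay-correction loop
on a synthetic 16×24 array with delays spanning 3.5 ns:

```
raw IRF peak spread: 1.033 ns (true delays span 3.47 ns)
corrected IRF peak spread: 3.8 ps over 384 pixels
```

and `examples/04_flim_two_populations.py` runs the full pipeline on a
two-lifetime scene:

```
left region:  tau = 1.025 +/- 0.016 ns (truth 1.0)
right region: tau = 1.719 +/- 0.027 ns (truth 1.7)
histogram modes at 1.04 ns and 1.72 ns
```

## Command line

The same pipeline is scriptable from a shell:

```sh
spadflim simulate --profile dnl-calibration --output work --seed 1
spadflim calibrate-dnl --input work/dnl-calibration.frames.h5 --output work/calib.json
spadflim correct --input data.frames.h5 --calibration work/calib.json \
                 --seed 1 --output work/corrected.h5
spadflim fit --input work/corrected.h5 --bin-xy 3 --bin-t 2 --output work/flim
spadflim run --seed 1 --output work   # the whole chain from one config
```

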