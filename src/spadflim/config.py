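"""Declarative pipeline configuration and the stage runner.

A single config (YAML on disk, dataclass in memory) names the input
acquisitions, clock settings and processing parameters; ``run_pipeline``
executes an ordered subset of stages (simulate, calibrate-dnl,
calibrate-dark, calibrate-irf, correct, fit), writing versioned outputs
and an append-only JSON-lines provenance log.  All randomness funnels
through the single root ``seed``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import calibration as cal
from . import correction, flim, io, simulate
from .datatypes import VirtualBinning

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("spadflim")

STAGES = ("simulate", "calibrate-dnl", "calibrate-dark", "calibrate-irf", "correct", "fit")


class DependencyError(RuntimeError):
    """A stage was requested before the calibration it needs exists."""


@dataclass
class PipelineConfig:
    output_dir: str = "spadflim-out"
    seed: int = 0
    reset_period_ns: float = 50.0
    # input acquisitions (frame-stack files); the simulate stage fills
    # any that are unset
    dnl_frames: str | None = None
    irf_frames: str | None = None
    dark_frames: str | None = None
    data_frames: str | None = None
    # simulate stage
    simulate_profiles: tuple[str, ...] = (
        "dnl-calibration", "irf-calibration", "dark", "decay-two-populations",
    )
    # processing parameters
    vbin_ps: float | None = None  # None: median-pixel mean bin width
    irf_kernel_bins: int = 9
    hot_pixel_quantile: float = 0.20
    bin_xy: int = 3
    bin_t: int = 2
    tau_range_ns: tuple[float, float] = (0.5, 1.6)
    chunk_frames: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.tau_range_ns, list):
            cfg.tau_range_ns = tuple(cfg.tau_range_ns)
        if isinstance(cfg.simulate_profiles, list):
            cfg.simulate_profiles = tuple(cfg.simulate_profiles)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)


def _log_provenance(outdir: Path, record: dict) -> None:
    record = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), **record}
    with open(outdir / "provenance.jsonl", "a") as f:
        f.write(json.dumps(record) + "\n")


def _need(path: str | None, what: str, stage: str) -> Path:
    if path is None or not Path(path).exists():
        raise DependencyError(
            f"stage {stage!r} needs {what} ({path!r}); run the producing stage first"
        )
    return Path(path)


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | list[str] = STAGES) -> dict:
    """Execute pipeline stages in canonical order; returns output paths.

    Stage products land in ``config.output_dir``: ``calibration.json``
    (bin widths + dark map + delay map as they are produced),
    ``corrected.h5`` (decay cube), ``tau.tiff`` / ``intensity.tiff`` /
    ``lifetime_histogram.csv``.  Every stage appends a provenance record
    (inputs, seed, photon totals, discards, timing).
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    calib_path = outdir / "calibration.json"
    outputs: dict[str, str] = {}

    for stage in stages:
        t_start = time.time()
        record: dict = {"stage": stage, "seed": config.seed}
        if stage == "simulate":
            fixdir = outdir / "fixtures"
            for profile in config.simulate_profiles:
                manifest = simulate.make_fixture_suite(profile, fixdir, seed=config.seed)
                key = {
                    "dnl-calibration": "dnl_frames",
                    "irf-calibration": "irf_frames",
                    "dark": "dark_frames",
                }.get(profile, "data_frames")
                if getattr(config, key) is None:
                    setattr(config, key, manifest["frames"])
                outputs[profile] = manifest["frames"]
            record["profiles"] = list(config.simulate_profiles)

        elif stage == "calibrate-dnl":
            stack = io.read_frame_stack(_need(config.dnl_frames, "constant-light frames", stage))
            cube = io.accumulate_histograms(stack)
            tdc = cal.calibrate_tdc(cube, stack.geometry.reset_period_ns)
            existing = io.load_calibration(calib_path) if calib_path.exists() else {}
            io.save_calibration(calib_path, tdc=tdc, delays=existing.get("delays"),
                                dark=existing.get("dark"))
            outputs["calibration"] = str(calib_path)
            record.update(photons=int(cube.counts.sum()), valid_pixels=int(tdc.valid.sum()))

        elif stage == "calibrate-dark":
            stack = io.read_frame_stack(_need(config.dark_frames, "dark frames", stage))
            dark = cal.measure_dark_counts(stack, quantile=config.hot_pixel_quantile)
            existing = io.load_calibration(calib_path) if calib_path.exists() else {}
            io.save_calibration(calib_path, tdc=existing.get("tdc"),
                                delays=existing.get("delays"), dark=dark)
            io.write_image(dark.rate_hz, outdir / "dark_rate_hz.tiff")
            outputs["calibration"] = str(calib_path)
            record["median_rate_hz"] = float(np.median(dark.rate_hz))

        elif stage == "calibrate-irf":
            from .irf import build_delay_map

            existing = io.load_calibration(_need(str(calib_path), "TDC calibration", stage))
            if "tdc" not in existing:
                raise DependencyError("calibrate-irf needs the TDC (bin width) calibration")
            stack = io.read_frame_stack(_need(config.irf_frames, "pulsed-light frames", stage))
            cube = io.accumulate_histograms(stack)
            delays = build_delay_map(cube, existing["tdc"], kernel_bins=config.irf_kernel_bins)
            io.save_calibration(calib_path, tdc=existing["tdc"], delays=delays,
                                dark=existing.get("dark"))
            io.write_image(np.nan_to_num(delays.mu_ns), outdir / "irf_peak_ns.tiff")
            outputs["calibration"] = str(calib_path)
            record["valid_fits"] = int(delays.valid.sum())

        elif stage == "correct":
            existing = io.load_calibration(_need(str(calib_path), "calibration", stage))
            if "tdc" not in existing:
                raise DependencyError("correct needs the TDC (bin width) calibration")
            stack = io.read_frame_stack(_need(config.data_frames, "experiment frames", stage))
            hist = io.accumulate_histograms(stack)
            binning = (
                VirtualBinning.covering(stack.geometry.reset_period_ns, config.vbin_ps)
                if config.vbin_ps
                else None
            )
            cube = correction.correct_cube(
                hist, existing["tdc"], existing.get("delays"), binning, seed=config.seed
            )
            io.write_decay_cube(cube, outdir / "corrected.h5")
            outputs["corrected"] = str(outdir / "corrected.h5")
            record.update(cube.provenance)

        elif stage == "fit":
            cube = io.read_decay_cube(_need(str(outdir / "corrected.h5"),
                                            "corrected decay cube", stage))
            binned = flim.bin_cube(cube, sxy=config.bin_xy, st=config.bin_t)
            existing = io.load_calibration(calib_path) if calib_path.exists() else {}
            peak = (
                existing["delays"].reference_ns if "delays" in existing else None
            )
            image = flim.fit_cube(binned, irf_peak_time_ns=peak,
                                  tau_range_ns=config.tau_range_ns)
            io.write_image(np.nan_to_num(image.tau_ns), outdir / "tau.tiff")
            io.write_image(image.intensity, outdir / "intensity.tiff")
            hist, edges = flim.lifetime_histogram(image)
            np.savetxt(
                outdir / "lifetime_histogram.csv",
                np.column_stack([edges[:-1], edges[1:], hist]),
                delimiter=",",
                header="tau_lo_ns,tau_hi_ns,density",
                comments="",
            )
            outputs["tau"] = str(outdir / "tau.tiff")
            record["valid_pixels"] = int(image.valid.sum())

        record["elapsed_s"] = round(time.time() - t_start, 3)
        _log_provenance(outdir, record)
        log.info("stage %s done in %.2fs", stage, record["elapsed_s"])

    return outputs
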