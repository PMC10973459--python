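"""On-disk formats.

Frame stacks and histogram/decay cubes go into HDF5 containers with the
geometry and acquisition metadata stored as attributes (the camera-native
format is proprietary, so the container here is self-describing and
documented below).  Calibration products (bin widths, delay map, dark map)
are JSON documents.  2-D images are written as TIFF, or as CSV when the
path ends in ``.csv``.

HDF5 layout
-----------
Frame stack (``format = "spadflim-frames"``):
    /frames        uint16, shape (n_frames, n_rows, n_cols), chunked
    root attrs     format, version, geometry fields
Histogram cube (``format = "spadflim-histcube"``):
    /counts        int64, shape (n_rows, n_cols, n_bins)
    root attrs     format, version, geometry fields, n_frames, exposure_time_ms
Decay cube (``format = "spadflim-decaycube"``):
    /counts        int64, shape (n_rows, n_cols, n_virtual_bins)
    root attrs     format, version, geometry fields, virtual binning,
                   provenance JSON
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import tifffile

from .datatypes import (
    CameraGeometry,
    DarkCountMap,
    DecayCube,
    DelayMap,
    FrameStack,
    HistogramCube,
    TdcCalibration,
    ValidationError,
    VirtualBinning,
)

__all__ = [
    "FormatError",
    "read_frame_stack",
    "write_frame_stack",
    "read_histogram_cube",
    "write_histogram_cube",
    "read_decay_cube",
    "write_decay_cube",
    "write_image",
    "read_image",
    "save_calibration",
    "load_calibration",
    "accumulate_histograms",
]

FRAMES_FORMAT = "spadflim-frames"
HISTCUBE_FORMAT = "spadflim-histcube"
DECAYCUBE_FORMAT = "spadflim-decaycube"


class FormatError(IOError):
    """Raised for malformed or mislabelled containers."""


_GEOM_KEYS = (
    "n_rows",
    "n_cols",
    "n_tdc_codes",
    "reset_period_ns",
    "laser_rate_mhz",
    "exposure_time_ms",
)


def _write_geometry(attrs: h5py.AttributeManager, geometry: CameraGeometry) -> None:
    for key, value in geometry.to_dict().items():
        attrs[key] = value


def _read_geometry(attrs: h5py.AttributeManager) -> CameraGeometry:
    try:
        return CameraGeometry.from_dict({k: attrs[k] for k in _GEOM_KEYS})
    except KeyError as exc:
        raise FormatError(f"missing geometry attribute: {exc}") from exc


def _check_format(attrs: h5py.AttributeManager, expected: str, path) -> None:
    found = attrs.get("format")
    if found != expected:
        raise FormatError(f"{path}: expected format {expected!r}, found {found!r}")


def write_frame_stack(stack: FrameStack, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FRAMES_FORMAT
        f.attrs["version"] = 1
        _write_geometry(f.attrs, stack.geometry)
        f.create_dataset(
            "frames",
            data=stack.frames.astype(np.uint16),
            chunks=(min(stack.n_frames, 256), stack.geometry.n_rows, stack.geometry.n_cols),
            compression="gzip",
            compression_opts=1,
        )


def read_frame_stack(path) -> FrameStack:
    """Read a frame stack, validating every code against the geometry."""
    with h5py.File(path, "r") as f:
        _check_format(f.attrs, FRAMES_FORMAT, path)
        geometry = _read_geometry(f.attrs)
        frames = f["frames"][()]
    return FrameStack(frames=frames, geometry=geometry)


def write_histogram_cube(cube: HistogramCube, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = HISTCUBE_FORMAT
        f.attrs["version"] = 1
        _write_geometry(f.attrs, cube.geometry)
        f.attrs["n_frames"] = cube.n_frames
        f.attrs["cube_exposure_time_ms"] = cube.exposure_time_ms
        f.create_dataset("counts", data=cube.counts.astype(np.int64), compression="gzip",
                         compression_opts=1)


def read_histogram_cube(path) -> HistogramCube:
    with h5py.File(path, "r") as f:
        _check_format(f.attrs, HISTCUBE_FORMAT, path)
        geometry = _read_geometry(f.attrs)
        return HistogramCube(
            counts=f["counts"][()],
            geometry=geometry,
            n_frames=int(f.attrs["n_frames"]),
            exposure_time_ms=float(f.attrs["cube_exposure_time_ms"]),
        )


def write_decay_cube(cube: DecayCube, path) -> None:
    if not np.isfinite(cube.counts).all():
        raise ValidationError("decay cube contains non-finite values")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = DECAYCUBE_FORMAT
        f.attrs["version"] = 1
        _write_geometry(f.attrs, cube.geometry)
        for key, value in cube.binning.to_dict().items():
            f.attrs[f"vbin_{key}"] = value
        f.attrs["provenance"] = json.dumps(cube.provenance)
        f.create_dataset("counts", data=cube.counts.astype(np.int64), compression="gzip",
                         compression_opts=1)


def read_decay_cube(path) -> DecayCube:
    with h5py.File(path, "r") as f:
        _check_format(f.attrs, DECAYCUBE_FORMAT, path)
        geometry = _read_geometry(f.attrs)
        binning = VirtualBinning(
            width_ps=float(f.attrs["vbin_width_ps"]),
            n_bins=int(f.attrs["vbin_n_bins"]),
            start_ps=float(f.attrs["vbin_start_ps"]),
        )
        provenance = json.loads(f.attrs.get("provenance", "{}"))
        return DecayCube(
            counts=f["counts"][()], binning=binning, geometry=geometry, provenance=provenance
        )


def write_image(image: np.ndarray, path) -> None:
    """Write a 2-D image as TIFF (or CSV if the suffix is .csv)."""
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValidationError("write_image expects a 2-D (or RGB 3-D) array")
    if not np.isfinite(image).all():
        raise ValidationError("image contains non-finite values")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if image.ndim != 2:
            raise ValidationError("CSV output supports 2-D images only")
        np.savetxt(path, image, delimiter=",")
    else:
        tifffile.imwrite(path, np.ascontiguousarray(image))


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return np.atleast_2d(np.loadtxt(path, delimiter=","))
    return tifffile.imread(path)


def save_calibration(
    path,
    *,
    tdc: TdcCalibration | None = None,
    delays: DelayMap | None = None,
    dark: DarkCountMap | None = None,
) -> None:
    """Write a versioned JSON calibration document (any subset of parts)."""
    doc: dict[str, Any] = {"format": "spadflim-calibration", "version": 1}
    if tdc is not None:
        doc["tdc"] = tdc.to_dict()
    if delays is not None:
        doc["delays"] = delays.to_dict()
    if dark is not None:
        doc["dark"] = dark.to_dict()
    with open(path, "w") as f:
        json.dump(doc, f)


def load_calibration(path) -> dict[str, Any]:
    """Load a calibration document; returns dict with 'tdc'/'delays'/'dark'."""
    with open(path) as f:
        doc = json.load(f)
    if doc.get("format") != "spadflim-calibration":
        raise FormatError(f"{path}: not a spadflim calibration document")
    out: dict[str, Any] = {}
    if "tdc" in doc:
        out["tdc"] = TdcCalibration.from_dict(doc["tdc"])
    if "delays" in doc:
        out["delays"] = DelayMap.from_dict(doc["delays"])
    if "dark" in doc:
        out["dark"] = DarkCountMap.from_dict(doc["dark"])
    return out


def accumulate_histograms(
    stack: FrameStack, frame_range: tuple[int, int] | None = None
) -> HistogramCube:
    """Histogram TDC codes per pixel over a half-open frame range.

    ``counts[r, c, k - 1]`` is the number of frames in the range in which
    pixel (r, c) recorded code ``k``; code 0 (no photon) is never counted.
    """
    if frame_range is None:
        frame_range = (0, stack.n_frames)
    lo, hi = frame_range
    if not (0 <= lo < hi <= stack.n_frames):
        raise ValueError(f"empty or out-of-range frame range {frame_range}")
    geometry = stack.geometry
    codes = stack.frames[lo:hi]
    n_codes = geometry.n_tdc_codes
    flat = codes.reshape(hi - lo, -1)
    counts = np.zeros((geometry.n_pixels, n_codes), dtype=np.int64)
    # bincount per pixel: offset trick keeps this a single vectorized pass
    offsets = np.arange(geometry.n_pixels, dtype=np.int64) * n_codes
    combined = (flat.astype(np.int64) + offsets[None, :]).ravel()
    binned = np.bincount(combined, minlength=geometry.n_pixels * n_codes)
    counts[:, :] = binned.reshape(geometry.n_pixels, n_codes)
    cube = counts[:, 1:].reshape(geometry.n_rows, geometry.n_cols, geometry.n_bins)
    return HistogramCube(
        counts=cube,
        geometry=geometry,
        n_frames=hi - lo,
        exposure_time_ms=geometry.exposure_time_ms,
    )
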