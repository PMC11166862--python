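"""Image container and file I/O.

Everything downstream works on :class:`ImageGrid`: a 2-D array of CT numbers
in Hounsfield units (HU) with a pixel spacing. Coordinates are 0-based
(row, col) with pixel centers at integer coordinates.

Supported formats:

``csv``
    Plain comma-separated HU grid, lossless (written at full float64
    precision).
``png``
    16-bit grayscale PNG. Raw PNG samples are unsigned, so HU values are
    stored as ``raw * scale + offset`` with the affine recorded in a JSON
    sidecar (``<path>.json``); reading requires the sidecar.
``tiff``
    64-bit float TIFF carrying HU directly (lossless); a JSON sidecar records pixel
    spacing.
``dicom``
    Single-frame CT DICOM; pixel data are converted to HU via the
    RescaleSlope/RescaleIntercept tags, which must be present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ImageGrid", "read_image", "write_image"]

_RASTER_FORMATS = {"csv", "png16", "png", "tiff", "tif", "dicom", "dcm"}


@dataclass
class ImageGrid:
    """A 2-D grid of CT numbers (HU) with pixel spacing in mm."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        sp = tuple(float(s) for s in self.pixel_spacing)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError(f"pixel spacing must be two positive numbers, got {self.pixel_spacing}")
        self.pixel_spacing = sp

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in _RASTER_FORMATS:
            raise ValueError(f"unknown image format {fmt!r}")
        return {"png16": "png", "tif": "tiff", "dcm": "dicom"}.get(f, f)
    ext = path.suffix.lower().lstrip(".")
    if ext in ("csv", "txt"):
        return "csv"
    if ext == "png":
        return "png"
    if ext in ("tif", "tiff"):
        return "tiff"
    if ext in ("dcm", "dicom", "ima"):
        return "dicom"
    raise ValueError(f"cannot infer image format from {path.name!r}; pass format= explicitly")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _read_sidecar(path: Path, required: bool) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        if required:
            raise FileNotFoundError(
                f"raster {path.name} has no JSON sidecar {sc.name}; "
                "cannot recover the HU offset/scale"
            )
        return {}
    with open(sc) as fh:
        return json.load(fh)


def read_image(path: str | Path, format: str | None = None) -> ImageGrid:
    """Read a CT image as an HU grid.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``csv``, ``png16``, ``tiff``, ``dicom``; inferred from the
        extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, format)

    if fmt == "csv":
        try:
            pixels = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path.name}: not a rectangular numeric CSV grid ({exc})") from exc
        meta = _read_sidecar(path, required=False)
        spacing = tuple(meta.get("pixel_spacing", (1.0, 1.0)))
        return ImageGrid(pixels, spacing, source_id=path.name)

    if fmt == "png":
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path))
        if raw.ndim != 2:
            raise ValueError(f"{path.name}: expected a single-channel grayscale PNG")
        meta = _read_sidecar(path, required=True)
        try:
            offset, scale = float(meta["hu_offset"]), float(meta["hu_scale"])
        except KeyError as exc:
            raise KeyError(f"{path.name} sidecar is missing {exc} (need hu_offset, hu_scale)") from exc
        spacing = tuple(meta.get("pixel_spacing", (1.0, 1.0)))
        return ImageGrid(raw.astype(float) * scale + offset, spacing, source_id=path.name)

    if fmt == "tiff":
        import tifffile

        pixels = np.asarray(tifffile.imread(path), dtype=float)
        if pixels.ndim != 2:
            raise ValueError(f"{path.name}: expected a single 2-D TIFF page")
        meta = _read_sidecar(path, required=False)
        spacing = tuple(meta.get("pixel_spacing", (1.0, 1.0)))
        return ImageGrid(pixels, spacing, source_id=path.name)

    # DICOM
    import pydicom

    ds = pydicom.dcmread(path)
    missing = [tag for tag in ("RescaleSlope", "RescaleIntercept") if tag not in ds]
    if missing:
        raise KeyError(f"{path.name}: DICOM is missing rescale tags {missing}; cannot convert to HU")
    pixels = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
    if pixels.ndim != 2:
        raise ValueError(f"{path.name}: multi-frame DICOM is not supported")
    spacing = tuple(float(s) for s in ds.PixelSpacing) if "PixelSpacing" in ds else (1.0, 1.0)
    return ImageGrid(pixels, spacing, source_id=path.name)


def write_image(grid: ImageGrid, path: str | Path, format: str | None = None) -> Path:
    """Write an HU grid; see the module docstring for formats. Returns the path."""
    path = Path(path)
    fmt = _infer_format(path, format)
    meta = {"pixel_spacing": list(grid.pixel_spacing), "units": "HU"}

    if fmt == "csv":
        np.savetxt(path, grid.pixels, delimiter=",", fmt="%.17g")
        return path

    if fmt == "png":
        import imageio.v3 as iio

        lo = float(grid.pixels.min())
        hi = float(grid.pixels.max())
        integral = bool(np.all(grid.pixels == np.round(grid.pixels)))
        if integral and hi - lo <= 65535:
            scale = 1.0
        else:
            scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        raw = np.round((grid.pixels - lo) / scale).astype(np.uint16)
        iio.imwrite(path, raw)
        meta.update({"hu_offset": lo, "hu_scale": scale})
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
        return path

    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, grid.pixels.astype(np.float64))
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
        return path

    raise ValueError(f"writing format {fmt!r} is not supported")
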