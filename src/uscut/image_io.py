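"""Grayscale image and mask I/O with pixel-spacing metadata.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column index, ``y`` the row index, origin at the top-left; pixel centers sit
at integer coordinates. Spacing is isotropic in mm/px so diameters can be
reported in millimeters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "UltrasoundImage",
    "BinaryMask",
    "PointPx",
    "read_image",
    "write_mask",
    "write_contour_csv",
]

# ITU-R BT.601 luma coefficients for color -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PointPx:
    """Pixel coordinate: ``x`` = column, ``y`` = row, both 0-based."""

    x: float
    y: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class UltrasoundImage:
    """2-D grayscale B-mode raster with isotropic pixel spacing.

    Parameters
    ----------
    pixels
        2-D integer array, values in ``[0, max_gray]``.
    spacing
        Isotropic pixel size in mm/px (default 1.0).
    source_id
        Free-text provenance tag (file name, phantom id, ...).
    """

    pixels: np.ndarray
    spacing: float = 1.0
    source_id: str = ""
    max_gray: int = field(init=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"image too small: {px.shape} (minimum 16x16)")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0 mm/px")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be an integer array")
        self.pixels = px
        self.max_gray = 65535 if px.dtype.itemsize > 1 else 255
        if px.min() < 0 or px.max() > self.max_gray:
            raise ValueError("gray values out of range")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def contains(self, p: PointPx) -> bool:
        return 0 <= p.x <= self.width - 1 and 0 <= p.y <= self.height - 1


@dataclass
class BinaryMask:
    """Binary raster (values 0/1) sharing shape and spacing with its image."""

    pixels: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        uniq = np.unique(px)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_px(self) -> int:
        return int(self.pixels.sum())


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
        arr = np.rint(arr)
    return arr


def read_image(path: str | Path, spacing_override: float | None = None) -> UltrasoundImage:
    """Load a PNG, TIFF or single-frame grayscale DICOM image.

    Color rasters are converted by BT.601 luminance. DICOM ``PixelSpacing``
    is honored when present (anisotropic spacing is averaged with a warning)
    unless ``spacing_override`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spacing = 1.0
    if path.suffix.lower() in {".dcm", ".dicom"} or _looks_like_dicom(path):
        import pydicom

        ds = pydicom.dcmread(path)
        n_frames = int(getattr(ds, "NumberOfFrames", 1))
        if n_frames > 1:
            raise ValueError(f"multi-frame DICOM not supported ({n_frames} frames)")
        arr = ds.pixel_array
        if "PixelSpacing" in ds:
            sr, sc = (float(v) for v in ds.PixelSpacing)
            if abs(sr - sc) > 1e-9:
                warnings.warn(
                    f"anisotropic PixelSpacing {sr}\\{sc} mm; using the mean",
                    stacklevel=2,
                )
            spacing = (sr + sc) / 2.0
    else:
        try:
            arr = iio.imread(path)
        except Exception as exc:  # noqa: BLE001 - normalize reader errors
            raise ValueError(f"unreadable image file: {path}") from exc
    arr = _to_gray(np.asarray(arr))
    if arr.ndim != 2:
        raise ValueError(f"expected a single 2-D frame, got shape {arr.shape}")
    dtype = np.uint16 if arr.max(initial=0) > 255 else np.uint8
    if spacing_override is not None:
        spacing = float(spacing_override)
    return UltrasoundImage(arr.astype(dtype), spacing=spacing, source_id=path.name)


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (0 -> 0, 1 -> 255)."""
    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8), extension=".png")


def write_contour_csv(contour: np.ndarray, path: str | Path) -> None:
    """Write contour vertices as CSV with columns ray_index,x,y."""
    with open(path, "w") as fh:
        fh.write("ray_index,x,y\n")
        for k, (x, y) in enumerate(np.asarray(contour)):
            fh.write(f"{k},{x:.4f},{y:.4f}\n")
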