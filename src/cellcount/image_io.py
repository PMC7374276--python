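"""Raster image and point-annotation I/O.

Images are 8-bit TIFF or PNG files, grayscale or RGB, held in memory as
``uint8`` arrays with shape ``(H, W)`` or ``(H, W, 3)`` (channel order
red-green-blue).  Cell annotations are one-pixel marks stored as CSV point
lists with header ``row,col`` and 0-based integer coordinates, row
increasing downward.

Other bit depths are rejected rather than rescaled: the red-fluorescence
threshold is defined on the 0-255 scale, so silently rescaling a 16-bit
frame would change its meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image


class ImageFormatError(ValueError):
    """Unreadable file or unsupported layout."""


class UnsupportedDepthError(ImageFormatError):
    """Bit depth other than 8 bits per sample."""


class AnnotationError(ValueError):
    """Point annotation outside its frame or malformed CSV."""


@dataclass
class RasterImage:
    """An 8-bit raster, grayscale ``(H, W)`` or RGB ``(H, W, 3)``.

    The red channel of an RGB image is always index 0 of the last axis.
    """

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ImageFormatError(
                    f"pixels must be 8-bit (0-255) integers, got dtype {px.dtype}"
                )
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if px.ndim not in (2, 3):
            raise ImageFormatError(f"expected 2-D or 3-D pixel grid, got shape {px.shape}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ImageFormatError(f"color images must have 3 channels, got {px.shape[2]}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("image must be at least 1x1")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial extent (H, W), regardless of channel count."""
        return self.pixels.shape[0], self.pixels.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RasterImage):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )


@dataclass
class PointAnnotations:
    """One-pixel cell marks on a frame of known extent.

    ``points`` is a list of 0-based ``(row, col)`` integer pairs, one per
    cell.  Duplicates are permitted (two overlapping cells may share a
    mark) but trigger a warning, since they usually indicate a labelling
    slip.
    """

    points: list[tuple[int, int]]
    frame_height: int
    frame_width: int

    def __post_init__(self) -> None:
        pts = [(int(r), int(c)) for r, c in self.points]
        for i, (r, c) in enumerate(pts):
            if not (0 <= r < self.frame_height and 0 <= c < self.frame_width):
                raise AnnotationError(
                    f"point #{i} ({r}, {c}) outside frame "
                    f"{self.frame_height}x{self.frame_width}"
                )
        if len(set(pts)) < len(pts):
            warnings.warn("duplicate annotation marks present", stacklevel=3)
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        """Points as an ``(N, 2)`` integer array (empty -> shape (0, 2))."""
        if not self.points:
            return np.zeros((0, 2), dtype=np.int64)
        return np.asarray(self.points, dtype=np.int64)


_LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R BT.601


def luma_grayscale(img: RasterImage) -> RasterImage:
    """RGB -> single-channel via BT.601 luma, rounded to nearest integer.

    Grayscale input is returned unchanged (same object).
    """
    if img.channels == 1:
        return img
    wr, wg, wb = _LUMA_WEIGHTS
    px = img.pixels.astype(np.float64)
    y = wr * px[:, :, 0] + wg * px[:, :, 1] + wb * px[:, :, 2]
    return RasterImage(
        pixels=np.rint(y).clip(0, 255).astype(np.uint8), source_path=img.source_path
    )


def read_image(path: str | Path) -> RasterImage:
    """Read an 8-bit TIFF or PNG into a :class:`RasterImage`.

    Color files are returned with RGB channel order.  16-bit (or any
    non-8-bit) input raises :class:`UnsupportedDepthError` instead of being
    rescaled.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.mode not in ("L", "RGB", "RGBA", "P", "I", "I;16", "F"):
                    im = im.convert("RGB")
                if im.mode == "P":
                    im = im.convert("RGB")
                arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise UnsupportedDepthError(
            f"{path}: only 8-bit images are supported, got dtype {arr.dtype}"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return RasterImage(pixels=arr, source_path=str(path))


def read_image_bytes(data: bytes) -> RasterImage:
    """Decode in-memory TIFF or PNG bytes (same rules as :func:`read_image`)."""
    import io as _io

    try:
        if data[:2] in (b"II", b"MM"):
            arr = tifffile.imread(_io.BytesIO(data))
        else:
            with Image.open(_io.BytesIO(data)) as im:
                if im.mode == "P":
                    im = im.convert("RGB")
                arr = np.asarray(im)
    except Exception as exc:
        raise ImageFormatError(f"cannot decode image bytes: {exc}") from exc
    if arr.dtype != np.uint8:
        raise UnsupportedDepthError(
            f"only 8-bit images are supported, got dtype {arr.dtype}"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RasterImage(pixels=arr)


def write_image(img: RasterImage, path: str | Path) -> None:
    """Write losslessly as TIFF or PNG so that a re-read is bit-identical."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory {path.parent} does not exist")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    elif suffix == ".png":
        Image.fromarray(img.pixels).save(path, format="PNG")
    else:
        raise ImageFormatError(f"unsupported output format {suffix!r} (use .tif/.tiff/.png)")


def read_annotations(path: str | Path, frame_height: int, frame_width: int) -> PointAnnotations:
    """Read a ``row,col`` CSV of one-pixel marks, validated against the frame."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["row", "col"]:
        raise AnnotationError(f"{path}: expected CSV header 'row,col', got {list(df.columns)}")
    df.columns = cols
    points = list(zip(df["row"].astype(int), df["col"].astype(int)))
    try:
        return PointAnnotations(points, frame_height, frame_width)
    except AnnotationError as exc:
        raise AnnotationError(f"{path}: {exc}") from exc


def write_annotations(ann: PointAnnotations, path: str | Path) -> None:
    """Write marks back to a ``row,col`` CSV, preserving order."""
    arr = ann.as_array()
    pd.DataFrame({"row": arr[:, 0], "col": arr[:, 1]}).to_csv(path, index=False)
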