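"""Redundant count-map targets and count inference.

The counting method regresses, for every output pixel, the number of
annotated cell marks inside that pixel's k x k receptive field (k odd, 65
by default).  Each cell therefore contributes to exactly k^2 output pixels
-- the map is "redundant" -- and the cell count of a frame is recovered by
summing the map and dividing by k^2.  Per-pixel prediction errors partially
cancel in that sum, which is where the method's accuracy comes from.

Target maps use full-convolution extent: for an H x W frame and pad
p = (k-1)/2 the map has shape (H+2p) x (W+2p), matching the zero-padded
image fed to the network.  Only at this extent does a cell sitting on the
frame border still cover exactly k^2 map pixels, which the sum / k^2 rule
requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .image_io import PointAnnotations, RasterImage

DEFAULT_KERNEL_SIZE = 65


@dataclass(frozen=True)
class CountMapSpec:
    """Geometry of a redundant count map: odd kernel size k, pad p=(k-1)/2."""

    kernel_size: int = DEFAULT_KERNEL_SIZE

    def __post_init__(self) -> None:
        k = self.kernel_size
        if k < 1 or k % 2 == 0:
            raise ValueError(f"kernel_size must be an odd positive integer, got {k}")

    @property
    def pad(self) -> int:
        return (self.kernel_size - 1) // 2

    @property
    def kernel_area(self) -> int:
        return self.kernel_size * self.kernel_size

    def map_shape(self, frame_height: int, frame_width: int) -> tuple[int, int]:
        return frame_height + 2 * self.pad, frame_width + 2 * self.pad


@dataclass
class CountMap:
    """A redundant count map over the padded extent of one frame.

    ``kind`` is ``"target"`` (integer-valued, built from annotations) or
    ``"prediction"`` (real-valued network output, clipped at zero).
    """

    values: np.ndarray
    spec: CountMapSpec
    kind: str = "target"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"count map must be 2-D, got shape {v.shape}")
        if v.min() < 0:
            raise ValueError("count map values must be non-negative")
        if self.kind not in ("target", "prediction"):
            raise ValueError(f"kind must be 'target' or 'prediction', got {self.kind!r}")
        if self.kind == "target" and not np.array_equal(v, np.rint(v)):
            raise ValueError("target count maps must be integer-valued")
        self.values = v

    @property
    def frame_shape(self) -> tuple[int, int]:
        """Shape of the unpadded source frame this map belongs to."""
        p = self.spec.pad
        return self.values.shape[0] - 2 * p, self.values.shape[1] - 2 * p


def pad_image(img: RasterImage, p: int) -> RasterImage:
    """Zero-pad an image by ``p`` pixels on every side (every channel)."""
    if p < 0:
        raise ValueError(f"pad must be non-negative, got {p}")
    if p == 0:
        return RasterImage(pixels=img.pixels.copy(), source_path=img.source_path)
    if img.channels == 1:
        width = ((p, p), (p, p))
    else:
        width = ((p, p), (p, p), (0, 0))
    return RasterImage(
        pixels=np.pad(img.pixels, width, mode="constant", constant_values=0),
        source_path=img.source_path,
    )


def make_count_target(ann: PointAnnotations, spec: CountMapSpec) -> CountMap:
    """Build the integer target map for a set of one-pixel marks.

    Output pixel ``(i, j)`` of the padded ``(H+2p, W+2p)`` grid counts the
    marks ``(r, c)`` with ``|r+p-i| <= p`` and ``|c+p-j| <= p``.  The map
    sum is exactly ``k^2 * len(ann)``.
    """
    p = spec.pad
    H, W = ann.frame_height, ann.frame_width
    Hp, Wp = spec.map_shape(H, W)
    # impulse grid over the padded extent, then exact k x k box sums via
    # an integral image (all-integer arithmetic)
    impulses = np.zeros((Hp, Wp), dtype=np.int64)
    for r, c in ann.points:
        impulses[r + p, c + p] += 1
    padded = np.pad(impulses, ((p + 1, p), (p + 1, p)))
    sat = padded.cumsum(axis=0).cumsum(axis=1)
    k = spec.kernel_size
    values = (
        sat[k:, k:] - sat[:-k, k:] - sat[k:, :-k] + sat[:-k, :-k]
    )
    return CountMap(values=values, spec=spec, kind="target")


def infer_count(cm: CountMap) -> float:
    """Cell count of a frame: map sum divided by the kernel area k^2.

    Returned unrounded; rounding to whole cells is presentation-only.
    """
    return float(np.asarray(cm.values, dtype=np.float64).sum() / cm.spec.kernel_area)


def rotate_with_annotations(
    img: RasterImage, ann: PointAnnotations, angle: int
) -> tuple[RasterImage, PointAnnotations]:
    """Rotate an image and its marks counter-clockwise by 90, 180 or 270 degrees.

    Point mapping (H x W frame): 90 deg (r,c) -> (W-1-c, r); 180 deg
    (r,c) -> (H-1-r, W-1-c); 270 deg (r,c) -> (c, H-1-r).  Frame extents
    swap for 90/270.
    """
    if angle not in (90, 180, 270):
        raise ValueError(f"angle must be 90, 180 or 270, got {angle}")
    H, W = ann.frame_height, ann.frame_width
    if (H, W) != img.shape:
        raise ValueError(
            f"annotation frame {H}x{W} does not match image {img.shape[0]}x{img.shape[1]}"
        )
    turns = angle // 90
    rot = np.rot90(img.pixels, k=turns, axes=(0, 1)).copy()
    if angle == 90:
        pts = [(W - 1 - c, r) for r, c in ann.points]
        new_h, new_w = W, H
    elif angle == 180:
        pts = [(H - 1 - r, W - 1 - c) for r, c in ann.points]
        new_h, new_w = H, W
    else:
        pts = [(c, H - 1 - r) for r, c in ann.points]
        new_h, new_w = W, H
    return (
        RasterImage(pixels=rot, source_path=img.source_path),
        PointAnnotations(pts, new_h, new_w),
    )


def write_count_map(cm: CountMap, path: str | Path) -> None:
    """Export a count map as a 32-bit float TIFF for visual inspection."""
    tifffile.imwrite(Path(path), np.asarray(cm.values, dtype=np.float32))


def read_count_map(path: str | Path, spec: CountMapSpec, kind: str = "prediction") -> CountMap:
    """Read a count map previously written by :func:`write_count_map`."""
    return CountMap(values=tifffile.imread(Path(path)), spec=spec, kind=kind)
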