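"""Red-fluorescent cell counting via red-channel masking.

A fluorescent reporter shows up in the red channel of an RGB frame.  Cells
expressing it are counted by binarizing the red channel at a user-chosen
intensity threshold (0-255, inclusive comparison), zeroing every grayscale
pixel outside the mask, and running the masked image through the ordinary
counting pipeline.  The count of the masked image is the red-positive cell
count; together with the total count it yields the percentage of
reporter-positive cells, the readout used in stress time-course analysis.

The counting model is trained on single-channel grayscale quadrants, so a
masked grayscale image is a valid model input; RGB frames are converted
with BT.601 luma weights before counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .count_targets import CountMapSpec
from .image_io import RasterImage, luma_grayscale

DEFAULT_RED_THRESHOLD = 100


@dataclass(frozen=True)
class RedThreshold:
    """Red-channel intensity cutoff on the 0-255 scale (inclusive)."""

    value: int = DEFAULT_RED_THRESHOLD

    def __post_init__(self) -> None:
        if not (0 <= self.value <= 255):
            raise ValueError(f"red threshold must be in [0, 255], got {self.value}")


def to_grayscale(img: RasterImage) -> RasterImage:
    """Single-channel version of an image (BT.601 luma for RGB input)."""
    return luma_grayscale(img)


def red_mask(img: RasterImage, t: RedThreshold) -> np.ndarray:
    """Boolean grid: red channel >= threshold.  Grayscale input is an error
    (there is no red channel to binarize)."""
    if img.channels != 3:
        raise ValueError("red_mask needs an RGB image; grayscale has no red channel")
    return img.pixels[:, :, 0] >= t.value


def apply_mask(gray: RasterImage, mask: np.ndarray) -> RasterImage:
    """Zero out grayscale pixels outside the mask (background value 0)."""
    if mask.shape != gray.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image {gray.shape}")
    return RasterImage(pixels=np.where(mask, gray.pixels, 0).astype(np.uint8))


def count_red(model, img: RasterImage, t: RedThreshold, spec: CountMapSpec) -> float:
    """Count red-fluorescence-positive cells in one RGB frame.

    The masked grayscale image is quartered, padded and counted exactly
    like a plain frame.  Note the result is not guaranteed to be <= the
    unmasked count: both are model outputs with independent errors.
    """
    from .tiling import count_frame

    mask = red_mask(img, t)
    masked = apply_mask(to_grayscale(img), mask)
    return count_frame(model, masked, spec)


def masked_training_pairs(img: RasterImage, ann, t: RedThreshold):
    """Quadrant training pairs of the red-masked image.

    The grayscale frame is masked exactly as in :func:`count_red`, and the
    annotations kept are those whose pixel passes the red mask — i.e. the
    reporter-positive cells.  Mixing such pairs into training calibrates
    the model for the masked images the red-counting path feeds it.
    Works on any annotated RGB frame; no per-cell fluorescence labels are
    needed beyond the ordinary one-pixel marks.  Caveat: in dense clusters
    a non-expressing cell's mark can fall inside an expressing neighbour's
    footprint and be included, so this slightly over-labels crowded
    fields.
    """
    from .image_io import PointAnnotations
    from .tiling import quadrant_pairs

    mask = red_mask(img, t)
    masked = apply_mask(to_grayscale(img), mask)
    kept = [(r, c) for r, c in ann.points if mask[r, c]]
    return quadrant_pairs(masked, PointAnnotations(kept, ann.frame_height, ann.frame_width))


def percent_red(total: float, red: float) -> float:
    """Percentage of red-positive cells, ``100 * red / total``."""
    if total <= 0:
        raise ValueError(f"percentage undefined for non-positive total count {total}")
    return 100.0 * red / total
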