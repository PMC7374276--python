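"""Quadrant tiling of full microscope frames.

Full frames (1040 x 1392 in the reference acquisition setup) are too large
to push through the network in one piece on modest hardware, so each frame
is split into four quadrants along floor(H/2) / floor(W/2), and the four
quadrant counts are summed.  Every annotation pixel falls in exactly one
quadrant, so with an exact predictor the quadrant sum equals the
whole-frame count; a real model may count a cell whose body straddles a
quadrant border fractionally in both quadrants, which is an accepted error
source of the method rather than something the tiling corrects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .count_targets import CountMapSpec, infer_count, pad_image
from .fcnn_model import FCNN, predict_count_map
from .image_io import PointAnnotations, RasterImage

Box = tuple[int, int, int, int]  # row0, row1, col0, col1 (half-open)


@dataclass(frozen=True)
class TilingPlan:
    """The four half-open quadrant boxes of one frame."""

    frame_height: int
    frame_width: int
    boxes: tuple[Box, Box, Box, Box]

    @classmethod
    def for_frame(cls, height: int, width: int) -> "TilingPlan":
        if height < 2 or width < 2:
            raise ValueError(
                f"frame must be at least 2x2 to quarter, got {height}x{width}"
            )
        rs, cs = height // 2, width // 2
        boxes = (
            (0, rs, 0, cs),
            (0, rs, cs, width),
            (rs, height, 0, cs),
            (rs, height, cs, width),
        )
        return cls(frame_height=height, frame_width=width, boxes=boxes)


def split_quadrants(img: RasterImage) -> tuple[list[RasterImage], TilingPlan]:
    """Split a frame into its four quadrants (top-left, top-right,
    bottom-left, bottom-right)."""
    plan = TilingPlan.for_frame(img.height, img.width)
    quads = [
        RasterImage(pixels=img.pixels[r0:r1, c0:c1].copy(), source_path=img.source_path)
        for r0, r1, c0, c1 in plan.boxes
    ]
    return quads, plan


def reassemble(quadrants: list[RasterImage], plan: TilingPlan) -> RasterImage:
    """Inverse of :func:`split_quadrants` (bit-exact)."""
    first = quadrants[0].pixels
    shape = (
        (plan.frame_height, plan.frame_width)
        if first.ndim == 2
        else (plan.frame_height, plan.frame_width, first.shape[2])
    )
    out = np.zeros(shape, dtype=np.uint8)
    for quad, (r0, r1, c0, c1) in zip(quadrants, plan.boxes):
        out[r0:r1, c0:c1] = quad.pixels
    return RasterImage(pixels=out)


def split_annotations(ann: PointAnnotations, plan: TilingPlan) -> list[PointAnnotations]:
    """Per-quadrant annotations in quadrant-local coordinates.

    Each mark lands in exactly one quadrant, so the four lists partition
    the original point set.
    """
    if (ann.frame_height, ann.frame_width) != (plan.frame_height, plan.frame_width):
        raise ValueError("annotation frame does not match tiling plan")
    out = []
    for r0, r1, c0, c1 in plan.boxes:
        pts = [(r - r0, c - c0) for r, c in ann.points if r0 <= r < r1 and c0 <= c < c1]
        out.append(PointAnnotations(pts, r1 - r0, c1 - c0))
    return out


def quadrant_pairs(
    img: RasterImage, ann: PointAnnotations
) -> list[tuple[RasterImage, PointAnnotations]]:
    """Quarter an annotated frame into four (quadrant, local annotations)
    training pairs."""
    quads, plan = split_quadrants(img)
    return list(zip(quads, split_annotations(ann, plan)))


def count_frame(model: FCNN, img: RasterImage, spec: CountMapSpec) -> float:
    """Count the cells of one full frame: pad and predict each quadrant,
    sum the four inferred counts."""
    quads, _ = split_quadrants(img)
    total = 0.0
    for quad in quads:
        padded = pad_image(quad, spec.pad)
        total += infer_count(predict_count_map(model, padded, spec))
    return total


def count_directory(
    model: FCNN,
    directory: str | Path,
    spec: CountMapSpec,
    red_threshold: int | None = None,
) -> pd.DataFrame:
    """Batch mode: count every TIFF/PNG in a directory.

    Returns a frame with columns ``path, cell_count, red_count, threshold``
    (``red_count`` is NaN for grayscale inputs or when no threshold is
    given), sorted by file name for reproducibility.
    """
    from .fluorescence import RedThreshold, count_red
    from .image_io import luma_grayscale, read_image

    directory = Path(directory)
    rows = []
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    for path in paths:
        img = read_image(path)
        total = count_frame(model, luma_grayscale(img), spec)
        red = np.nan
        if red_threshold is not None and img.channels == 3:
            red = count_red(model, img, RedThreshold(red_threshold), spec)
        rows.append(
            {
                "path": str(path),
                "cell_count": total,
                "red_count": red,
                "threshold": red_threshold if red_threshold is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["path", "cell_count", "red_count", "threshold"])
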