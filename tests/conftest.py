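"""Shared fixtures: small synthetic scenes and exact-oracle predictors."""

from __future__ import annotations

import numpy as np
import pytest

from cellcount.count_targets import CountMapSpec, make_count_target, pad_image
from cellcount.image_io import PointAnnotations, RasterImage, luma_grayscale
from cellcount.synthetic_data import SyntheticConfig, generate_scene
from cellcount.tiling import quadrant_pairs


class ExactPredictor:
    """Oracle 'model': returns the precomputed exact target map for every
    padded quadrant it has been taught (keyed by pixel content).

    Duck-types the trained network for the tiling/fluorescence pipeline:
    exposes ``spec.kernel_size`` and ``predict_map``.
    """

    def __init__(self, spec: CountMapSpec) -> None:
        self.spec = spec
        self._table: dict[bytes, np.ndarray] = {}

    def teach_frame(self, frame: RasterImage, ann: PointAnnotations) -> None:
        """Register the exact targets of a frame's four padded quadrants."""
        gray = luma_grayscale(frame)
        for quad, qann in quadrant_pairs(gray, ann):
            padded = pad_image(quad, self.spec.pad)
            self._table[padded.pixels.tobytes()] = make_count_target(
                qann, self.spec
            ).values.astype(np.float64)

    def predict_map(self, padded: RasterImage) -> np.ndarray:
        try:
            return self._table[padded.pixels.tobytes()]
        except KeyError:  # pragma: no cover - indicates a broken test setup
            raise AssertionError("ExactPredictor saw an image it was not taught")


class ZeroPredictor:
    """Oracle 'model' that predicts an all-zero count map."""

    def __init__(self, spec: CountMapSpec) -> None:
        self.spec = spec

    def predict_map(self, padded: RasterImage) -> np.ndarray:
        p = self.spec.pad
        return np.zeros((padded.height, padded.width), dtype=np.float64)


@pytest.fixture
def spec33() -> CountMapSpec:
    return CountMapSpec(kernel_size=33)


@pytest.fixture
def rgb_scene():
    """A reproducible 128x128 scene with 40 cells, 8 of them red."""
    return generate_scene(SyntheticConfig(seed=11, red_fraction=0.2))


@pytest.fixture
def random_annotations():
    """Factory for seeded random point sets on a given frame."""

    def make(n: int, height: int, width: int, seed: int = 0) -> PointAnnotations:
        rng = np.random.default_rng(seed)
        pts = {(int(r), int(c)) for r, c in zip(
            rng.integers(0, height, 4 * n), rng.integers(0, width, 4 * n)
        )}
        pts = sorted(pts)[:n]
        return PointAnnotations(list(pts), height, width)

    return make
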