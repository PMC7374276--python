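"""Seeded generator of phase-contrast-like test scenes.

Cultured epithelial-like cells (the kind the counting model targets) are
polymorphic, non-convex, variably sized, and grow in dense clusters.  The
generator emulates those properties well enough to exercise every part of
the counting pipeline: cells are radially perturbed ellipses with a dark
interior and a bright halo rim on a noisy mid-gray background; a subset is
additionally painted into the red channel to mimic a red-fluorescent
reporter.  Every cell carries a one-pixel centroid annotation, so a
generated scene is its own counting ground truth.

Placement mixes a Thomas cluster process (uniform cluster centres,
Gaussian-scattered offspring) with uniform background placement; the
``cluster_fraction`` knob sets the mix.  All randomness flows from a single
seed, and scenes are bit-reproducible.

This is a geometric stand-in, not an optics simulation: shading is flat,
halos are uniform rings, and there are no illumination gradients or focus
drift.  Tests passing on these scenes demonstrate the counting machinery,
not robustness to real microscope artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

from .image_io import PointAnnotations, RasterImage, write_annotations, write_image

_N_VERTICES = 48  # outline sampling resolution
_HALO_WIDTH = 2.0  # px, bright rim thickness
_MAX_ATTEMPTS = 500


class PlacementError(RuntimeError):
    """Could not place the requested number of cells in the frame."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one scene (intensities on the 0-255 scale).

    Defaults describe a dense 128 x 128 field of ~40 cells, the scale used
    throughout the test suite.
    """

    height: int = 128
    width: int = 128
    n_cells: int = 40
    cluster_fraction: float = 0.6
    cluster_sd: float = 9.0
    mean_cluster_size: float = 5.0
    cell_radius_range: tuple[float, float] = (3.5, 6.5)
    shape_irregularity: float = 0.25
    halo_strength: float = 60.0
    interior_depth: float = 55.0
    background_level: float = 120.0
    background_noise_sd: float = 8.0
    red_fraction: float = 0.0
    red_intensity_range: tuple[float, float] = (150.0, 230.0)
    red_background_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must be in [0, 1]")
        if not (0.0 <= self.red_fraction <= 1.0):
            raise ValueError("red_fraction must be in [0, 1]")
        if self.cell_radius_range[0] > self.cell_radius_range[1]:
            raise ValueError("cell_radius_range must be (min, max) with min <= max")
        if self.shape_irregularity < 0:
            raise ValueError("shape_irregularity must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class SyntheticScene:
    """A generated RGB frame plus its ground truth."""

    image: RasterImage
    annotations: PointAnnotations
    red_flags: np.ndarray  # bool per cell, aligned with annotations
    config: SyntheticConfig

    @property
    def n_cells(self) -> int:
        return len(self.annotations)

    @property
    def n_red(self) -> int:
        return int(self.red_flags.sum())


def _cell_outline(rng: np.random.Generator, cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Radial outline r(theta) of one cell: perturbed ellipse, frame-free coords."""
    rmin, rmax = cfg.cell_radius_range
    a = rng.uniform(rmin, rmax)
    b = rng.uniform(rmin, rmax)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    theta = np.linspace(0.0, 2.0 * np.pi, _N_VERTICES, endpoint=False)
    # ellipse radius at angle theta (orientation phi)
    ct, st = np.cos(theta - phi), np.sin(theta - phi)
    r_ell = (a * b) / np.sqrt((b * ct) ** 2 + (a * st) ** 2)
    # low-order harmonics make the outline lobed / non-convex
    perturb = np.zeros_like(theta)
    for m in (2, 3, 4):
        amp = rng.uniform(0.3, 1.0) / m
        phase = rng.uniform(0.0, 2.0 * np.pi)
        perturb += amp * np.cos(m * theta + phase)
    factor = np.clip(1.0 + cfg.shape_irregularity * perturb, 0.3, None)
    return theta, r_ell * factor


def _place_centres(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Candidate cell centres: Thomas-process clusters plus uniform remainder."""
    H, W, n = cfg.height, cfg.width, cfg.n_cells
    margin = cfg.cell_radius_range[1]
    lo_r, hi_r = margin, max(margin + 1.0, H - margin)
    lo_c, hi_c = margin, max(margin + 1.0, W - margin)
    n_clustered = int(round(cfg.cluster_fraction * n))
    centres: list[tuple[float, float]] = []
    if n_clustered > 0:
        n_parents = max(1, int(round(n_clustered / cfg.mean_cluster_size)))
        parents = np.column_stack(
            [rng.uniform(lo_r, hi_r, n_parents), rng.uniform(lo_c, hi_c, n_parents)]
        )
        assignment = rng.integers(0, n_parents, n_clustered)
        for idx in assignment:
            offs = rng.normal(0.0, cfg.cluster_sd, 2)
            centres.append(
                (
                    float(np.clip(parents[idx, 0] + offs[0], lo_r, hi_r)),
                    float(np.clip(parents[idx, 1] + offs[1], lo_c, hi_c)),
                )
            )
    for _ in range(n - n_clustered):
        centres.append((float(rng.uniform(lo_r, hi_r)), float(rng.uniform(lo_c, hi_c))))
    out = np.asarray(centres, dtype=np.float64).reshape(-1, 2)
    return out[rng.permutation(len(out))] if len(out) else out


def generate_scene(cfg: SyntheticConfig) -> SyntheticScene:
    """Render one scene deterministically from ``cfg.seed``.

    Exactly ``cfg.n_cells`` cells are drawn and annotated at their integer
    body centroids (minimum 2 px apart); ``round(red_fraction * n_cells)``
    of them are painted into the red channel at an intensity drawn from
    ``red_intensity_range``.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.height, cfg.width
    gray = np.full((H, W), cfg.background_level, dtype=np.float64)
    red_overlay = np.full((H, W), -1.0)  # -1 = no fluorescence painted

    n_red = int(round(cfg.red_fraction * cfg.n_cells))
    red_flags = np.zeros(cfg.n_cells, dtype=bool)
    if cfg.n_cells:
        red_flags[rng.choice(cfg.n_cells, size=n_red, replace=False)] = True

    centres = _place_centres(rng, cfg)
    annotations: list[tuple[int, int]] = []
    halo_level = min(255.0, cfg.background_level + cfg.halo_strength)

    for i in range(cfg.n_cells):
        placed = False
        centre = centres[i]
        for attempt in range(_MAX_ATTEMPTS):
            if attempt > 0:  # re-draw position after a failed attempt
                margin = cfg.cell_radius_range[1]
                centre = np.array(
                    [
                        rng.uniform(margin, max(margin + 1.0, H - margin)),
                        rng.uniform(margin, max(margin + 1.0, W - margin)),
                    ]
                )
            theta, radius = _cell_outline(rng, cfg)
            body_r = centre[0] + radius * np.sin(theta)
            body_c = centre[1] + radius * np.cos(theta)
            rr, cc = draw_polygon(body_r, body_c, shape=(H, W))
            if rr.size == 0:
                continue
            centroid = (int(round(rr.mean())), int(round(cc.mean())))
            if annotations:
                d = np.hypot(
                    np.asarray(annotations)[:, 0] - centroid[0],
                    np.asarray(annotations)[:, 1] - centroid[1],
                )
                if d.min() < 2.0:
                    continue
            # bright halo rim, then dark interior on top
            halo_rr, halo_cc = draw_polygon(
                centre[0] + (radius + _HALO_WIDTH) * np.sin(theta),
                centre[1] + (radius + _HALO_WIDTH) * np.cos(theta),
                shape=(H, W),
            )
            gray[halo_rr, halo_cc] = halo_level
            interior = cfg.background_level - cfg.interior_depth + rng.normal(0.0, 4.0)
            gray[rr, cc] = np.clip(interior, 0.0, 255.0)
            if red_flags[i]:
                # the reporter fills the whole cell, so the red footprint
                # covers body and rim alike
                red_overlay[halo_rr, halo_cc] = rng.uniform(*cfg.red_intensity_range)
            annotations.append(centroid)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{cfg.n_cells} in a "
                f"{H}x{W} frame after {_MAX_ATTEMPTS} attempts"
            )

    noise = rng.normal(0.0, cfg.background_noise_sd, (H, W))
    gray_final = np.clip(gray + noise, 0.0, 255.0)
    # the green/blue channels carry the phase-contrast image; the red
    # channel is the fluorescence overlay -- dark everywhere except where
    # the reporter is expressed, which is what makes intensity
    # thresholding meaningful
    rgb = np.repeat(gray_final[:, :, None], 3, axis=2)
    red_channel = np.clip(
        rng.normal(cfg.red_background_level, cfg.background_noise_sd / 2.0, (H, W)),
        0.0,
        255.0,
    )
    red_mask = red_overlay >= 0.0
    if red_mask.any():
        red_noise = rng.normal(0.0, cfg.background_noise_sd / 2.0, (H, W))
        red_vals = np.clip(
            red_overlay + red_noise, cfg.red_intensity_range[0], 255.0
        )
        red_channel = np.where(red_mask, red_vals, red_channel)
    rgb[:, :, 0] = red_channel
    img = RasterImage(pixels=np.rint(rgb).astype(np.uint8))
    return SyntheticScene(
        image=img,
        annotations=PointAnnotations(annotations, H, W),
        red_flags=red_flags,
        config=cfg,
    )


def generate_fixture_suite(
    base_cfg: SyntheticConfig,
    n_train: int = 16,
    n_val: int = 4,
    n_test: int = 8,
    seed: int = 0,
) -> tuple[list[SyntheticScene], list[SyntheticScene], list[SyntheticScene]]:
    """Generate disjoint train/validation/test scene lists from one master seed.

    The default 16/4 train/validation split keeps the 8:2 bookkeeping of a
    20-image labelled series.  Per-scene cell counts are drawn from a
    Poisson law around ``base_cfg.n_cells`` (at least 1), mimicking the
    well-to-well variation in seeding density of a real culture series, and
    per-scene seeds are spawned deterministically from ``seed``.
    """
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("scene counts must be non-negative")
    total = n_train + n_val + n_test
    ss = np.random.SeedSequence(seed)
    scene_seeds = ss.generate_state(total + 1) % (2**31)
    count_rng = np.random.default_rng(int(scene_seeds[-1]))
    scenes = []
    for i in range(total):
        n = max(1, int(count_rng.poisson(base_cfg.n_cells)))
        scenes.append(generate_scene(replace(base_cfg, seed=int(scene_seeds[i]), n_cells=n)))
    return scenes[:n_train], scenes[n_train : n_train + n_val], scenes[n_train + n_val :]


def red_masked_pairs(
    scene: SyntheticScene, threshold: int = 100
) -> list[tuple[RasterImage, PointAnnotations]]:
    """Quadrant training pairs of the red-masked scene.

    The red-counting path feeds the model grayscale images whose pixels
    outside the red-channel mask are zeroed.  Training on such pairs (in
    addition to the plain ones) keeps masked images inside the model's
    input distribution, so the same network calibrates for both total and
    red-positive counting.  Targets use the scene's planted red flags —
    exact ground truth; in dense clusters a non-expressing cell's mark may
    sit inside an expressing neighbour's footprint, so selecting marks by
    the mask instead would over-label (that approximation is what
    :func:`cellcount.fluorescence.masked_training_pairs` offers for real,
    flag-less data).
    """
    from .fluorescence import RedThreshold, apply_mask, red_mask
    from .image_io import luma_grayscale
    from .tiling import quadrant_pairs

    mask = red_mask(scene.image, RedThreshold(threshold))
    masked = apply_mask(luma_grayscale(scene.image), mask)
    red_pts = [
        p for p, flag in zip(scene.annotations.points, scene.red_flags) if flag
    ]
    ann = PointAnnotations(red_pts, scene.config.height, scene.config.width)
    return quadrant_pairs(masked, ann)


def export_scene(scene: SyntheticScene, directory: str | Path, stem: str) -> dict[str, Path]:
    """Write TIFF + annotation CSV + red-flag CSV for one scene."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / f"{stem}.tif",
        "annotations": directory / f"{stem}_annotations.csv",
        "red_flags": directory / f"{stem}_red.csv",
    }
    write_image(scene.image, paths["image"])
    write_annotations(scene.annotations, paths["annotations"])
    paths["red_flags"].write_text(
        "red\n" + "\n".join(str(int(f)) for f in scene.red_flags) + "\n"
    )
    return paths
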