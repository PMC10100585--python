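"""Random ellipse phantoms and block-mean ground truth.

Each phantom is a sum of a few ellipses with random centers, semi-axes,
orientations and intensities, lightly smoothed with a Gaussian (sigma = one
fine pixel) and min-max normalised to [0, 1].  Overlapping ellipses add.
Phantoms are rasterised on the fine measurement grid (default 384 x 384);
the ground truth at reconstruction scale is the block mean over
``factor`` x ``factor`` tiles (default 3, giving 128 x 128).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import ImageGrid

__all__ = [
    "Ellipse",
    "Phantom",
    "EllipseRanges",
    "generate_phantom",
    "downsample_truth",
    "save_phantom",
]


@dataclass(frozen=True)
class Ellipse:
    """One ellipse: center (cx, cy) in physical coordinates, semi-axes a, b,
    rotation theta in degrees, additive intensity."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float
    intensity: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if self.intensity <= 0:
            raise ValueError("ellipse intensity must be positive")


@dataclass(frozen=True)
class EllipseRanges:
    """Uniform sampling ranges for random ellipses, expressed relative to the
    grid's physical side length so the same ranges work at any scale.

    Defaults: centers inside the central 70% of the grid, semi-axes between
    ~4% and ~23% of the side (15..90 fine pixels on a 384 grid), any
    orientation, intensities in [0.2, 1.0].
    """

    center_frac: float = 0.70
    axis_frac_min: float = 15.0 / 384.0
    axis_frac_max: float = 90.0 / 384.0
    intensity_min: float = 0.2
    intensity_max: float = 1.0


@dataclass(frozen=True)
class Phantom:
    """A rasterised random phantom with its generating parameters."""

    image: np.ndarray
    ellipses: tuple[Ellipse, ...]
    seed: int
    grid: ImageGrid


def _rasterize(ellipses, grid: ImageGrid) -> np.ndarray:
    x, y = grid.pixel_centers()
    img = np.zeros((grid.n_rows, grid.n_cols))
    for e in ellipses:
        th = np.deg2rad(e.theta)
        dx = x - e.cx
        dy = y - e.cy
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        img += e.intensity * (((u / e.a) ** 2 + (v / e.b) ** 2) <= 1.0)
    return img


def generate_phantom(
    seed: int,
    grid: ImageGrid,
    n_ellipses: int = 4,
    ranges: EllipseRanges = EllipseRanges(),
    max_retries: int = 10,
) -> Phantom:
    """Draw a random phantom: ``n_ellipses`` ellipses summed, Gaussian smoothed
    (sigma = 1 pixel, reflective boundaries), then min-max normalised to [0, 1].

    Deterministic for a given seed.  If a draw yields a constant image before
    normalisation (nothing to normalise), it is redrawn up to ``max_retries``
    times from the same stream.
    """
    if n_ellipses < 1:
        raise ValueError("need at least one ellipse")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    side = min(grid.n_rows, grid.n_cols) * grid.pixel_size
    half = ranges.center_frac * side / 2.0
    for _ in range(max_retries):
        ellipses = tuple(
            Ellipse(
                cx=rng.uniform(-half, half),
                cy=rng.uniform(-half, half),
                a=rng.uniform(ranges.axis_frac_min * side, ranges.axis_frac_max * side),
                b=rng.uniform(ranges.axis_frac_min * side, ranges.axis_frac_max * side),
                theta=rng.uniform(0.0, 180.0),
                intensity=rng.uniform(ranges.intensity_min, ranges.intensity_max),
            )
            for _ in range(n_ellipses)
        )
        img = _rasterize(ellipses, grid)
        img = gaussian_filter(img, sigma=1.0, mode="reflect")
        lo, hi = img.min(), img.max()
        if hi - lo > 1e-12:
            img = (img - lo) / (hi - lo)
            return Phantom(image=img, ellipses=ellipses, seed=seed, grid=grid)
    raise RuntimeError(
        f"could not draw a non-constant phantom in {max_retries} attempts; "
        "check the ellipse parameter ranges"
    )


def downsample_truth(p: Phantom | np.ndarray, factor: int = 3) -> np.ndarray:
    """Block-mean the fine phantom to reconstruction resolution.

    Each output pixel is the arithmetic mean of its ``factor`` x ``factor``
    block, so the image mean is preserved exactly.
    """
    img = p.image if isinstance(p, Phantom) else np.asarray(p)
    nr, nc = img.shape
    if nr % factor or nc % factor:
        raise ValueError(f"image shape {img.shape} not divisible by factor {factor}")
    return img.reshape(nr // factor, factor, nc // factor, factor).mean(axis=(1, 3))


def save_phantom(p: Phantom, path: str | Path) -> None:
    """Write the phantom as 32-bit float TIFF plus a JSON sidecar with the
    ellipse parameters and seed."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, p.image.astype(np.float32))
    sidecar = {
        "seed": p.seed,
        "grid": {"rows": p.grid.n_rows, "cols": p.grid.n_cols,
                 "pixel_size": p.grid.pixel_size},
        "ellipses": [asdict(e) for e in p.ellipses],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
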