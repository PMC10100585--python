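"""Matched forward/back-projection pair, detector bin-down, Poisson noise.

The projector discretises the Radon transform with Siddon-style exact
intersection lengths between each bin's central ray and the pixel grid, so
entry a_ij of the (sparse) system matrix is the chord length of ray j inside
pixel i.  Back-projection is the literal matrix transpose, which makes the
pair an exact adjoint: <A x, y> = <x, A^T y> to machine precision.

Sinograms always live on the *extended* virtual detector (see geometry); the
``measured`` mask flags the bins the physical detector actually records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from ._siddon import trace_all
from .geometry import Detector, Geometry, ImageGrid, ViewSet, make_geometry

__all__ = [
    "Sinogram",
    "ProjectionOperator",
    "forward_project",
    "back_project",
    "bin_down",
    "add_poisson_noise",
]


@dataclass
class Sinogram:
    """Line-integral data: values (n_views, n_bins_extended) and the per-bin
    measured mask (identical at every view)."""

    values: np.ndarray
    measured: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.measured = np.asarray(self.measured, dtype=bool)
        g = self.geometry
        if self.values.shape != (g.views.n_views, g.n_bins_extended):
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"({g.views.n_views} views x {g.n_bins_extended} extended bins)"
            )
        if self.measured.shape != (g.n_bins_extended,):
            raise ValueError("measured mask must have one entry per extended bin")

    def zero_unmeasured(self) -> "Sinogram":
        """Return a copy with unmeasured bins set to zero (the naive
        measurement vector fed to reconstruction)."""
        v = self.values.copy()
        v[:, ~self.measured] = 0.0
        return replace(self, values=v)


class ProjectionOperator:
    """Parallel-beam projector for one geometry.

    The sparse system matrix (rows = view-major extended bins, columns =
    row-major pixels) is built lazily on first use and cached.
    """

    def __init__(self, geometry: Geometry):
        self.geometry = geometry
        self._matrix: sp.csr_matrix | None = None

    @property
    def n_rays(self) -> int:
        g = self.geometry
        return g.views.n_views * g.n_bins_extended

    @property
    def matrix(self) -> sp.csr_matrix:
        if self._matrix is None:
            self._matrix = self._build()
        return self._matrix

    def _build(self) -> sp.csr_matrix:
        g = self.geometry
        grid = g.grid
        counts, cols, lens = trace_all(
            g.views.angles_rad(),
            g.extended_detector.bin_centers(),
            grid.n_rows, grid.n_cols, grid.pixel_size,
        )
        max_per_ray = grid.n_rows + grid.n_cols + 3
        valid = np.arange(max_per_ray)[None, :] < counts[:, None]
        valid = valid.ravel()
        indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        return sp.csr_matrix(
            (lens[valid], cols[valid], indptr),
            shape=(self.n_rays, grid.n_pixels),
        )

    def measured_ray_mask(self) -> np.ndarray:
        """Boolean mask over rays (view-major) marking measured bins."""
        return np.tile(self.geometry.measured_mask(), self.geometry.views.n_views)

    def forward(self, image: np.ndarray) -> Sinogram:
        g = self.geometry
        image = np.asarray(image, dtype=float)
        if image.shape != (g.grid.n_rows, g.grid.n_cols):
            raise ValueError(
                f"image shape {image.shape} does not match grid "
                f"({g.grid.n_rows}, {g.grid.n_cols})"
            )
        p = self.matrix @ image.ravel()
        return Sinogram(
            values=p.reshape(g.views.n_views, g.n_bins_extended),
            measured=g.measured_mask(),
            geometry=g,
        )

    def back(self, sino: Sinogram | np.ndarray) -> np.ndarray:
        g = self.geometry
        values = sino.values if isinstance(sino, Sinogram) else np.asarray(sino, float)
        if values.shape != (g.views.n_views, g.n_bins_extended):
            raise ValueError(
                f"sinogram shape {values.shape} does not match geometry "
                f"({g.views.n_views}, {g.n_bins_extended})"
            )
        x = self.matrix.T @ values.ravel()
        return x.reshape(g.grid.n_rows, g.grid.n_cols)


def forward_project(op: ProjectionOperator, x: np.ndarray) -> Sinogram:
    """Line integrals of image ``x``: bin j gets sum_i a_ij x_i."""
    return op.forward(x)


def back_project(op: ProjectionOperator, s: Sinogram | np.ndarray) -> np.ndarray:
    """Transpose application: pixel i gets sum_j a_ij p_j."""
    return op.back(s)


def bin_down(s: Sinogram, factor: int = 3) -> Sinogram:
    """Combine ``factor`` adjacent fine detector bins into one coarse bin.

    Combined bins are *averaged*, which keeps coarse values on the
    line-integral scale of the coarse system matrix (coarse bin width equals
    the reconstruction pixel size).  A coarse bin is measured only when all
    its fine bins are.
    """
    g = s.geometry
    if g.detector.n_bins % factor or g.n_bins_extended % factor:
        raise ValueError(
            f"bin counts ({g.detector.n_bins} physical, {g.n_bins_extended} "
            f"extended) not divisible by factor {factor}"
        )
    if g.grid.n_rows % factor or g.grid.n_cols % factor:
        raise ValueError("grid not divisible by bin-down factor")
    coarse = make_geometry(
        ImageGrid(g.grid.n_rows // factor, g.grid.n_cols // factor,
                  g.grid.pixel_size * factor),
        Detector(g.detector.n_bins // factor, g.detector.bin_width * factor,
                 g.detector.center_offset),
        g.views,
    )
    if coarse.n_bins_extended * factor != g.n_bins_extended:
        raise ValueError("fine and coarse extended detectors do not align")
    n_views = g.views.n_views
    vals = s.values.reshape(n_views, coarse.n_bins_extended, factor).mean(axis=2)
    meas = s.measured.reshape(coarse.n_bins_extended, factor).all(axis=1)
    if not np.array_equal(meas, coarse.measured_mask()):
        raise ValueError("binned measured mask inconsistent with coarse geometry")
    return Sinogram(values=vals, measured=meas, geometry=coarse)


def add_poisson_noise(s: Sinogram, counts_per_unit: float = 500.0,
                      seed: int = 0) -> Sinogram:
    """Poisson noise on the measured line integrals.

    Each measured bin value v is replaced by Poisson(counts_per_unit * v) /
    counts_per_unit, so the expectation is preserved and the relative noise
    shrinks as counts_per_unit grows.  Unmeasured bins are untouched.
    Deterministic per seed (independent of the phantom stream).
    """
    if counts_per_unit <= 0:
        raise ValueError("counts_per_unit must be positive")
    meas_vals = s.values[:, s.measured]
    if (meas_vals < 0).any():
        raise ValueError("cannot apply Poisson noise to negative line integrals")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    noisy = rng.poisson(counts_per_unit * meas_vals) / counts_per_unit
    out = s.values.copy()
    out[:, s.measured] = noisy
    return replace(s, values=out)
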