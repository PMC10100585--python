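"""Parallel-beam acquisition geometry and angular-coverage ROI prediction.

The geometry model is 2D parallel-beam: a flat 1D detector rotates about a
fixed axis (the origin), taking line-integral measurements at a set of view
angles.  The physical detector may be narrower than the object and displaced
sideways (``center_offset``), which produces truncated, asymmetric
projections — the "interior problem".  To let iterative solvers reason about
the bins they *cannot* see, every geometry also carries an *extended* virtual
detector wide enough to cover the whole image grid; the physical detector's
bins form a contiguous measured subset of the extended bins.

A pixel belongs to the region of interest (ROI) when every line through it,
over the full 180° view span, hits a measured bin; such pixels are fully
measured in the classical 2D data-sufficiency sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "Detector",
    "ViewSet",
    "Geometry",
    "GeometryError",
    "make_geometry",
    "refine_geometry",
    "angular_coverage_map",
    "roi_mask",
]


class GeometryError(ValueError):
    """Raised when a geometry description is inconsistent."""


@dataclass(frozen=True)
class ImageGrid:
    """Square-pixel image grid centered on the rotation axis.

    Pixel (r, c) has its center at physical coordinates
    ``x = (c - (n_cols-1)/2) * pixel_size`` and
    ``y = ((n_rows-1)/2 - r) * pixel_size``; the rotation axis is the origin.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def diagonal(self) -> float:
        """Physical length of the grid diagonal."""
        return float(np.hypot(self.n_rows, self.n_cols) * self.pixel_size)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) physical coordinates of all pixel centers, shape (n_rows, n_cols)."""
        c = np.arange(self.n_cols)
        r = np.arange(self.n_rows)
        x = (c - (self.n_cols - 1) / 2.0) * self.pixel_size
        y = ((self.n_rows - 1) / 2.0 - r) * self.pixel_size
        return np.meshgrid(x, y)[0], np.meshgrid(x, y)[1]


@dataclass(frozen=True)
class Detector:
    """Flat 1D detector: ``n_bins`` bins of ``bin_width``, midpoint displaced
    ``center_offset`` from the projection of the rotation axis (nonzero offset
    means the detector is asymmetric about the axis)."""

    n_bins: int
    bin_width: float = 1.0
    center_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise GeometryError("detector must have at least one bin")
        if self.bin_width <= 0:
            raise GeometryError("bin_width must be positive")

    def bin_centers(self) -> np.ndarray:
        """Signed distances of bin centers from the rotation axis."""
        b = np.arange(self.n_bins)
        return (b - (self.n_bins - 1) / 2.0) * self.bin_width + self.center_offset

    @property
    def span(self) -> tuple[float, float]:
        """Physical extent [low edge of first bin, high edge of last bin]."""
        centers = self.bin_centers()
        return (float(centers[0]) - self.bin_width / 2.0,
                float(centers[-1]) + self.bin_width / 2.0)


@dataclass(frozen=True)
class ViewSet:
    """Uniform angular sampling: ``n_views`` stops starting at ``start_angle``
    degrees with ``angular_increment`` degree steps (default 180 × 1° over 180°)."""

    n_views: int = 180
    start_angle: float = 0.0
    angular_increment: float = 1.0

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise GeometryError("need at least one view")

    def angles_deg(self) -> np.ndarray:
        return self.start_angle + np.arange(self.n_views) * self.angular_increment

    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg())


@dataclass(frozen=True)
class Geometry:
    """Complete acquisition description.

    ``extended_detector`` is the symmetric virtual detector covering the grid;
    ``measured_start`` is the index of the first extended bin that coincides
    with a physical bin (physical bin b == extended bin measured_start + b).
    """

    grid: ImageGrid
    detector: Detector
    views: ViewSet
    extended_detector: Detector
    measured_start: int = field(default=0)

    @property
    def n_bins_extended(self) -> int:
        return self.extended_detector.n_bins

    def measured_mask(self) -> np.ndarray:
        """Boolean mask over extended bins; identical at every view."""
        mask = np.zeros(self.extended_detector.n_bins, dtype=bool)
        mask[self.measured_start : self.measured_start + self.detector.n_bins] = True
        return mask

    def measured_span(self) -> tuple[float, float]:
        """Physical extent of the measured bins (edge to edge)."""
        return self.detector.span

    def to_dict(self) -> dict:
        return {
            "grid": {
                "rows": self.grid.n_rows,
                "cols": self.grid.n_cols,
                "pixel_size": self.grid.pixel_size,
            },
            "detector": {
                "bins": self.detector.n_bins,
                "bin_width": self.detector.bin_width,
                "offset": self.detector.center_offset,
            },
            "views": {
                "count": self.views.n_views,
                "start_deg": self.views.start_angle,
                "step_deg": self.views.angular_increment,
            },
        }

    @staticmethod
    def from_dict(d: dict) -> "Geometry":
        g = d["grid"]
        det = d["detector"]
        v = d["views"]
        return make_geometry(
            ImageGrid(g["rows"], g["cols"], g.get("pixel_size", 1.0)),
            Detector(det["bins"], det.get("bin_width", 1.0), det.get("offset", 0.0)),
            ViewSet(v.get("count", 180), v.get("start_deg", 0.0), v.get("step_deg", 1.0)),
        )


def _lattice_parity(detector: Detector) -> int:
    """Parity (0 even, 1 odd) an extended bin count must have so the physical
    bins land exactly on the extended bin lattice."""
    q = detector.center_offset / detector.bin_width
    two_q = 2.0 * q
    if abs(two_q - round(two_q)) > 1e-9:
        raise GeometryError(
            "detector center_offset must be a multiple of half the bin width "
            "so the physical bins align with the extended detector lattice"
        )
    q_is_int = abs(q - round(q)) < 1e-9
    n_parity = detector.n_bins % 2
    # centers align when (N - n)/2 + q is an integer
    return n_parity if q_is_int else 1 - n_parity


def make_geometry(grid: ImageGrid, detector: Detector, views: ViewSet) -> Geometry:
    """Assemble a :class:`Geometry`, constructing the extended virtual detector.

    The extended detector is symmetric about the rotation axis, uses the same
    bin width as the physical detector, and has the smallest bin count that
    (a) spans at least the grid diagonal and (b) contains all physical bins as
    a contiguous aligned subset.
    """
    w = detector.bin_width
    parity = _lattice_parity(detector)
    n_ext = int(np.ceil(grid.diagonal / w))
    if n_ext % 2 != parity:
        n_ext += 1
    n_ext = max(n_ext, 1 if parity else 2)
    q = detector.center_offset / w
    while True:
        start = (n_ext - detector.n_bins) / 2.0 + q
        start_i = int(round(start))
        if abs(start - start_i) > 1e-9:  # lattice misalignment; should not occur
            raise GeometryError("physical bins do not align with extended lattice")
        if start_i >= 0 and start_i + detector.n_bins <= n_ext:
            break
        n_ext += 2
    extended = Detector(n_bins=n_ext, bin_width=w, center_offset=0.0)
    return Geometry(grid=grid, detector=detector, views=views,
                    extended_detector=extended, measured_start=start_i)


def _pad_extended(g: Geometry, n_ext: int) -> Geometry:
    """Widen the extended detector to ``n_ext`` bins (same parity, symmetric)."""
    cur = g.extended_detector.n_bins
    if n_ext == cur:
        return g
    if n_ext < cur or (n_ext - cur) % 2:
        raise GeometryError(f"cannot pad extended detector from {cur} to {n_ext} bins")
    extended = Detector(n_bins=n_ext, bin_width=g.extended_detector.bin_width,
                        center_offset=0.0)
    return Geometry(grid=g.grid, detector=g.detector, views=g.views,
                    extended_detector=extended,
                    measured_start=g.measured_start + (n_ext - cur) // 2)


def refine_geometry(g: Geometry, factor: int = 3) -> Geometry:
    """Return the fine-scale geometry used for measurement generation.

    The grid is subdivided ``factor``× in each direction (same physical extent)
    and each detector bin is split into ``factor`` fine bins, so a fine
    sinogram bins down exactly onto the coarse one.  Generating data on this
    finer model and reconstructing on the coarse one avoids the inverse crime
    of inverting the very operator that made the data.
    """
    if factor < 1:
        raise GeometryError("refinement factor must be >= 1")
    fine_grid = ImageGrid(g.grid.n_rows * factor, g.grid.n_cols * factor,
                          g.grid.pixel_size / factor)
    fine_det = Detector(g.detector.n_bins * factor, g.detector.bin_width / factor,
                        g.detector.center_offset)
    fine = make_geometry(fine_grid, fine_det, g.views)
    # the coarse extended detector may carry extra symmetric padding (needed to
    # fit an offset physical detector); mirror it so bins align factor:1
    if fine.n_bins_extended < g.n_bins_extended * factor:
        fine = _pad_extended(fine, g.n_bins_extended * factor)
    if fine.n_bins_extended != g.n_bins_extended * factor:
        raise GeometryError(
            "fine extended detector does not align with the coarse one; "
            f"got {fine.n_bins_extended} vs {g.n_bins_extended}x{factor}"
        )
    return fine


def _signed_distances(g: Geometry) -> np.ndarray:
    """Signed distance of every pixel center to the central ray, per view.

    Returns array of shape (n_views, n_rows, n_cols): the detector coordinate
    at which the ray through each pixel lands, for each view angle.
    """
    x, y = g.grid.pixel_centers()
    th = g.views.angles_rad()
    # detector coordinate of point (x, y) at view angle th is x cos + y sin
    return (np.cos(th)[:, None, None] * x[None] +
            np.sin(th)[:, None, None] * y[None])


def angular_coverage_map(g: Geometry) -> np.ndarray:
    """Fraction of views (in [0, 1]) at which the ray through each pixel hits a
    measured detector bin.  Computed by enumerating every view."""
    mask = g.measured_mask()
    if not mask.any():
        return np.zeros((g.grid.n_rows, g.grid.n_cols))
    lo, hi = g.measured_span()
    s = _signed_distances(g)
    covered = (s >= lo) & (s <= hi)
    return covered.mean(axis=0)


def roi_mask(g: Geometry) -> np.ndarray:
    """Binary mask of fully measured pixels: coverage exactly 1 at all views."""
    mask = g.measured_mask()
    if not mask.any():
        return np.zeros((g.grid.n_rows, g.grid.n_cols), dtype=bool)
    lo, hi = g.measured_span()
    s = _signed_distances(g)
    return ((s >= lo) & (s <= hi)).all(axis=0)
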