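"""Dense small-system diagnostics: explicit system matrix, SVD condition
number, and the pseudo-inverse pixel-solvability map diag(A+ A).

These are the classical linear-algebra answers to "which pixels are
recoverable": the condition number sigma_max/sigma_min grades the whole
system, and the diagonal of A+ A (A+ the Moore-Penrose pseudo-inverse,
restricted to the measured rows) equals 1 exactly at pixels the generalized
solution recovers.  Both require the full matrix in memory, so they are only
feasible on small grids; here they serve as an independent cross-check of the
Monte Carlo map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projector import ProjectionOperator

__all__ = [
    "DenseSystem",
    "ConditionNumber",
    "build_dense_matrix",
    "condition_number",
    "pinv_solvability_map",
]

MAX_DENSE_PIXELS = 64 * 64
RANK_RTOL = 1e-10


@dataclass
class DenseSystem:
    """Explicit system matrix over the *measured* bins.

    matrix: (n_views * n_measured_bins, n_pixels); row r corresponds to
    (view, bin) = row_index[r]; column i is pixel (i // n_cols, i % n_cols).
    """

    matrix: np.ndarray
    geometry: object
    row_index: np.ndarray  # (n_rows, 2) of (view, extended-bin) pairs


@dataclass
class ConditionNumber:
    """sigma_max / sigma_min over singular values above the numerical-rank
    tolerance; ``effectively_infinite`` flags a rank-deficient system."""

    value: float
    effectively_infinite: bool
    rank: int


def build_dense_matrix(op: ProjectionOperator) -> DenseSystem:
    """Materialise the measured rows of the system matrix (small grids only)."""
    g = op.geometry
    if g.grid.n_pixels > MAX_DENSE_PIXELS:
        raise ValueError(
            f"grid has {g.grid.n_pixels} pixels; dense diagnostics are limited "
            f"to {MAX_DENSE_PIXELS} (64x64) to keep the SVD in memory"
        )
    meas = op.measured_ray_mask()
    A = op.matrix.toarray()[meas]
    n_bins = g.n_bins_extended
    rays = np.flatnonzero(meas)
    row_index = np.stack([rays // n_bins, rays % n_bins], axis=1)
    return DenseSystem(matrix=A, geometry=g, row_index=row_index)


def _svd_vals(sys: DenseSystem):
    return np.linalg.svd(sys.matrix, compute_uv=False)


def condition_number(sys: DenseSystem, rtol: float = RANK_RTOL) -> ConditionNumber:
    """Ratio of largest to smallest singular value above ``rtol * sigma_max``."""
    s = _svd_vals(sys)
    smax = s[0]
    if smax == 0:
        return ConditionNumber(value=np.inf, effectively_infinite=True, rank=0)
    kept = s[s > rtol * smax]
    rank = int(kept.size)
    # A^T A is singular — the condition number is effectively infinite —
    # whenever the numerical rank falls short of the number of unknowns
    deficient = rank < sys.matrix.shape[1]
    return ConditionNumber(
        value=float(smax / kept[-1]),
        effectively_infinite=bool(deficient),
        rank=rank,
    )


def pinv_solvability_map(sys: DenseSystem, rtol: float = RANK_RTOL) -> np.ndarray:
    """diag(A+ A) reshaped to the image grid.

    With A = U S V^T and r the numerical rank (singular values above
    rtol * sigma_max), A+ A = V_r V_r^T, so the diagonal is the squared row
    norm of V_r — always in [0, 1], and exactly 1 for every pixel when A has
    full column rank.
    """
    A = sys.matrix
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        r = 0
    else:
        r = int(np.sum(s > rtol * s[0]))
    diag = np.sum(vt[:r] ** 2, axis=0)
    g = sys.geometry
    return diag.reshape(g.grid.n_rows, g.grid.n_cols)
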