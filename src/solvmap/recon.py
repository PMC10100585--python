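"""Iterative reconstruction: gradient descent and ML-EM, with optional finite
support enforcement and the truncation modification for interior problems.

Both solvers operate on the extended-detector sinogram.  In *naive* mode the
unmeasured bins simply carry the value zero and participate in the update —
the (incorrect but common) default that the solvability map exposes.  With the
*truncation modification*, each unmeasured bin is overwritten with the current
iterate's own forward projection before every update, so those bins exert no
data-fit force:

    GD:     x^{k+1}_i = x^k_i - alpha * sum_j a_ij (sum_n a_nj x^k_n - p_j)
    ML-EM:  x^{k+1}_i = x^k_i / (sum_j a_ij) * sum_j a_ij p_j / (sum_n a_nj x^k_n)

Finite support: GD zeroes pixels outside the support mask after every update;
ML-EM only needs the support imposed on the initial image, because a pixel
that is zero stays zero under the multiplicative update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation

from .projector import ProjectionOperator, Sinogram

__all__ = [
    "ReconConfig",
    "ReconResult",
    "run_gd",
    "run_mlem",
    "reconstruct",
    "apply_truncation_modification",
    "estimate_lambda_max",
    "default_step_size",
    "support_from_truth",
]


@dataclass
class ReconConfig:
    """Algorithm variant selector.

    algorithm: "gd" or "mlem".
    step_size_alpha: GD step size; None means 1.9 / lambda_max(A^T A) with
    lambda_max estimated by power iteration.
    """

    algorithm: str = "gd"
    n_iterations: int = 200
    step_size_alpha: float | None = None
    use_support: bool = False
    use_truncation_modification: bool = False
    support_mask: np.ndarray | None = None
    epsilon_guard: float = 1e-12

    def __post_init__(self) -> None:
        if self.algorithm not in ("gd", "mlem"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if self.step_size_alpha is not None and self.step_size_alpha <= 0:
            raise ValueError("step size alpha must be positive")
        if self.use_support and self.support_mask is None:
            raise ValueError("use_support requires a support_mask")


@dataclass
class ReconResult:
    """Reconstructed image plus per-iteration data-fit diagnostics
    (0.5 * ||residual||^2 for GD, Poisson log-likelihood for ML-EM)."""

    image: np.ndarray
    data_fit: list = field(default_factory=list)


def apply_truncation_modification(s: Sinogram, current_forward: Sinogram) -> Sinogram:
    """Overwrite unmeasured bins with the current forward projection; measured
    bins are kept from the data."""
    if s.values.shape != current_forward.values.shape:
        raise ValueError("sinogram shapes do not match")
    vals = np.where(s.measured[None, :], s.values, current_forward.values)
    return replace(s, values=vals)


def estimate_lambda_max(op: ProjectionOperator, n_iter: int = 50,
                        seed: int = 0) -> float:
    """Largest eigenvalue of A^T A by power iteration."""
    A = op.matrix
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(A.shape[1])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = A.T @ (A @ v)
        lam = float(np.linalg.norm(w))
        if lam == 0.0:
            return 0.0
        v = w / lam
    return lam


def default_step_size(op: ProjectionOperator, safety: float = 1.9) -> float:
    """Stable GD step: safety / lambda_max(A^T A), safety < 2."""
    lam = estimate_lambda_max(op)
    if lam <= 0:
        raise ValueError("operator has zero spectral norm; cannot pick a step size")
    return safety / lam


def support_from_truth(truth: np.ndarray, dilate: int = 1) -> np.ndarray:
    """Object support from the reconstruction-scale ground truth: nonzero
    pixels, dilated to avoid fragile one-pixel boundaries."""
    mask = np.asarray(truth) > 0
    if dilate:
        mask = binary_dilation(mask, iterations=dilate)
    return mask


def _check_geometry(s: Sinogram, op: ProjectionOperator) -> None:
    g = op.geometry
    if s.values.shape != (g.views.n_views, g.n_bins_extended):
        raise ValueError("sinogram does not match the operator geometry")


def run_gd(s: Sinogram, op: ProjectionOperator, cfg: ReconConfig) -> ReconResult:
    """Gradient descent on the least-squares data fit, from the zero image."""
    if cfg.algorithm != "gd":
        raise ValueError("config is not a GD config")
    _check_geometry(s, op)
    A = op.matrix
    meas = op.measured_ray_mask()
    p = s.values.ravel().copy()
    p[~meas] = 0.0  # unmeasured bins carry zeros (naive); modified mode zeroes their residual below
    alpha = cfg.step_size_alpha
    if alpha is None:
        alpha = default_step_size(op)
    support = None
    if cfg.use_support:
        support = np.asarray(cfg.support_mask, dtype=bool).ravel()
    x = np.zeros(A.shape[1])
    fits = []
    for k in range(cfg.n_iterations):
        r = A @ x - p
        if cfg.use_truncation_modification:
            # unmeasured bins track the iterate exactly, so their residual is 0
            r[~meas] = 0.0
        x = x - alpha * (A.T @ r)
        if support is not None:
            x[~support] = 0.0
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"GD diverged at iteration {k} with step size alpha={alpha:g}"
            )
        with np.errstate(over="ignore"):  # a diverging run may overflow here
            fits.append(0.5 * float(r @ r))
    g = op.geometry
    return ReconResult(image=x.reshape(g.grid.n_rows, g.grid.n_cols), data_fit=fits)


def run_mlem(s: Sinogram, op: ProjectionOperator, cfg: ReconConfig) -> ReconResult:
    """ML-EM from the all-ones image (or the support mask cast to {0,1}).

    Unmeasured bins hold zeros in naive mode; with the truncation modification
    their data/model ratio is forced to one, the multiplicative analogue of
    removing them from the update.  Pixels with zero sensitivity are held at 0.
    """
    if cfg.algorithm != "mlem":
        raise ValueError("config is not an ML-EM config")
    _check_geometry(s, op)
    A = op.matrix
    meas = op.measured_ray_mask()
    p = s.values.ravel().copy()
    if (p[meas] < 0).any():
        raise ValueError("ML-EM requires nonnegative measured data")
    if not cfg.use_truncation_modification:
        p[~meas] = 0.0
    eps = cfg.epsilon_guard
    sens = A.T @ np.ones(A.shape[0])
    if not (sens > 0).any():
        raise ValueError("all pixels have zero sensitivity; geometry sees nothing")
    alive = sens > 0
    x = np.ones(A.shape[1])
    if cfg.use_support:
        x = np.asarray(cfg.support_mask, dtype=float).ravel().copy()
    x[~alive] = 0.0
    fits = []
    for _ in range(cfg.n_iterations):
        q = A @ x
        ratio = p / (q + eps)
        if cfg.use_truncation_modification:
            ratio[~meas] = 1.0
        x = np.where(alive, x * (A.T @ ratio) / np.where(alive, sens, 1.0), 0.0)
        # Poisson log-likelihood over measured bins (constant terms dropped)
        qm = q[meas]
        pm = p[meas]
        pos = pm > 0
        ll = float(np.sum(pm[pos] * np.log(qm[pos] + eps)) - np.sum(qm))
        fits.append(ll)
    g = op.geometry
    return ReconResult(image=x.reshape(g.grid.n_rows, g.grid.n_cols), data_fit=fits)


def reconstruct(s: Sinogram, op: ProjectionOperator, cfg: ReconConfig) -> ReconResult:
    """Dispatch on cfg.algorithm."""
    return run_gd(s, op, cfg) if cfg.algorithm == "gd" else run_mlem(s, op, cfg)
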