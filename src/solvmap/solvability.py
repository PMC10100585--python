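"""Squared-error images, the Monte Carlo solvability map, and its display
transform.

For each random phantom, the squared-error image is e_i = (x_i - x_i^true)^2
at reconstruction resolution; averaging these over n phantoms yields the image
solvability map.  Low map values mark pixels the acquisition geometry and
algorithm reconstruct stably; because of measurement noise and the deliberate
fine-grid/coarse-grid model mismatch, the minimum is never exactly zero.

For display, v -> 1 - exp(-20 v) maps [0, inf) to [0, 1) while expanding the
small values that carry the interesting structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SolvabilityMap",
    "MapAccumulator",
    "squared_error_image",
    "accumulate_map",
    "display_transform",
    "inverse_display_transform",
    "map_summary",
]

DISPLAY_RATE = 20.0


@dataclass
class SolvabilityMap:
    """Per-pixel mean squared reconstruction error over ``n_phantoms``."""

    values: np.ndarray
    n_phantoms: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_phantoms < 1:
            raise ValueError("a map needs at least one phantom")
        if (self.values < 0).any():
            raise ValueError("map values must be nonnegative")

    @property
    def summary(self) -> dict:
        return map_summary(self)


def squared_error_image(recon: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pixel-wise squared error (x_i - x_i^true)^2."""
    recon = np.asarray(recon, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if recon.shape != truth.shape:
        raise ValueError(f"shape mismatch: {recon.shape} vs {truth.shape}")
    return (recon - truth) ** 2


class MapAccumulator:
    """Streaming (running-sum) accumulation of squared-error images; the
    result is bit-identical to the batch mean."""

    def __init__(self, shape: tuple[int, int]):
        self.total = np.zeros(shape)
        self.count = 0

    def add(self, error_image: np.ndarray) -> None:
        err = np.asarray(error_image, dtype=float)
        if err.shape != self.total.shape:
            raise ValueError("error image shape mismatch")
        self.total += err
        self.count += 1

    def result(self) -> SolvabilityMap:
        if self.count == 0:
            raise ValueError("no error images accumulated")
        return SolvabilityMap(values=self.total / self.count, n_phantoms=self.count)


def accumulate_map(errors) -> SolvabilityMap:
    """Average a sequence of squared-error images into a solvability map."""
    errors = list(errors)
    if not errors:
        raise ValueError("cannot average an empty sequence of error images")
    acc = MapAccumulator(np.asarray(errors[0]).shape)
    for e in errors:
        acc.add(e)
    return acc.result()


def display_transform(v):
    """Monotone map v -> 1 - exp(-20 v) from [0, inf) to [0, 1)."""
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("display transform is defined for nonnegative values")
    out = 1.0 - np.exp(-DISPLAY_RATE * v)
    return float(out) if out.ndim == 0 else out


def inverse_display_transform(v_o):
    """Inverse of :func:`display_transform`: -ln(1 - v_o) / 20."""
    v_o = np.asarray(v_o, dtype=float)
    if (v_o < 0).any() or (v_o >= 1).any():
        raise ValueError("inverse display transform is defined on [0, 1)")
    out = -np.log1p(-v_o) / DISPLAY_RATE
    return float(out) if out.ndim == 0 else out


def map_summary(m: SolvabilityMap) -> dict:
    """Min/max report row, as in the solvability-map tables."""
    return {"min": float(m.values.min()), "max": float(m.values.max())}
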