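"""Numba kernel: exact ray/pixel-grid intersection lengths (Siddon-style).

Each detector bin is represented by its central ray.  For a ray at view angle
theta hitting detector coordinate s, the origin is (s cos, s sin) and the
direction (-sin, cos).  The kernel walks the pixel grid (Amanatides-Woo
traversal) and records, per ray, the indices of crossed pixels and the chord
length inside each.  Rays lying exactly on a pixel boundary are attributed to
the pixel on the positive-index side (floor convention), which keeps the
operator deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=False)
def _trace_ray(ox, oy, dx, dy, nr, nc, px, cols, lens):  # pragma: no cover - jit
    """Trace one ray; fill cols/lens; return number of crossed pixels."""
    xmin = -nc * px / 2.0
    ymax = nr * px / 2.0
    count = 0

    if abs(dx) < _EPS:  # vertical ray: one pixel column, full traversal
        c = int(np.floor((ox - xmin) / px))
        if 0 <= c < nc:
            for r in range(nr):
                cols[count] = r * nc + c
                lens[count] = px
                count += 1
        return count
    if abs(dy) < _EPS:  # horizontal ray: one pixel row
        r = int(np.floor((ymax - oy) / px))
        if 0 <= r < nr:
            for c in range(nc):
                cols[count] = r * nc + c
                lens[count] = px
                count += 1
        return count

    # slab entry/exit parameters
    tx0 = (xmin - ox) / dx
    tx1 = (xmin + nc * px - ox) / dx
    if tx0 > tx1:
        tx0, tx1 = tx1, tx0
    ty0 = (ymax - nr * px - oy) / dy
    ty1 = (ymax - oy) / dy
    if ty0 > ty1:
        ty0, ty1 = ty1, ty0
    t0 = max(tx0, ty0)
    t1 = min(tx1, ty1)
    if t1 <= t0 + _EPS:
        return 0

    # entry voxel, nudged just inside
    tin = t0 + 1e-9 * px
    x = ox + tin * dx
    y = oy + tin * dy
    c = int(np.floor((x - xmin) / px))
    r = int(np.floor((ymax - y) / px))
    if c < 0:
        c = 0
    if c >= nc:
        c = nc - 1
    if r < 0:
        r = 0
    if r >= nr:
        r = nr - 1

    step_c = 1 if dx > 0 else -1
    # y decreases as r increases
    step_r = 1 if dy < 0 else -1
    t_dx = px / abs(dx)
    t_dy = px / abs(dy)
    if dx > 0:
        t_max_x = (xmin + (c + 1) * px - ox) / dx
    else:
        t_max_x = (xmin + c * px - ox) / dx
    if dy > 0:
        t_max_y = (ymax - r * px - oy) / dy
    else:
        t_max_y = (ymax - (r + 1) * px - oy) / dy

    t = t0
    while t < t1 - _EPS:
        if t_max_x < t_max_y:
            t_next = t_max_x
        else:
            t_next = t_max_y
        if t_next > t1:
            t_next = t1
        seg = t_next - t
        if seg > _EPS:
            cols[count] = r * nc + c
            lens[count] = seg
            count += 1
        if t_max_x < t_max_y:
            c += step_c
            t_max_x += t_dx
        else:
            r += step_r
            t_max_y += t_dy
        t = t_next
        if c < 0 or c >= nc or r < 0 or r >= nr:
            break
    return count


@njit(cache=False)
def trace_all(angles, s_centers, nr, nc, px):  # pragma: no cover - jit
    """Trace every (view, bin) ray.

    Returns (counts, cols, lens): per-ray entry counts plus flattened column
    indices and lengths, ``max_per_ray`` slots per ray.
    """
    n_views = angles.shape[0]
    n_bins = s_centers.shape[0]
    n_rays = n_views * n_bins
    max_per_ray = nr + nc + 3
    counts = np.zeros(n_rays, dtype=np.int64)
    cols = np.zeros(n_rays * max_per_ray, dtype=np.int32)
    lens = np.zeros(n_rays * max_per_ray, dtype=np.float64)
    for v in range(n_views):
        ct = np.cos(angles[v])
        st = np.sin(angles[v])
        for b in range(n_bins):
            s = s_centers[b]
            ray = v * n_bins + b
            off = ray * max_per_ray
            counts[ray] = _trace_ray(
                s * ct, s * st, -st, ct, nr, nc, px,
                cols[off : off + max_per_ray], lens[off : off + max_per_ray],
            )
    return counts, cols, lens
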