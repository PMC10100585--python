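import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from solvmap import (
    Detector,
    ImageGrid,
    ProjectionOperator,
    Sinogram,
    ViewSet,
    add_poisson_noise,
    back_project,
    bin_down,
    forward_project,
    make_geometry,
    refine_geometry,
)


def test_zero_image_projects_to_zero(toy16):
    _, op = toy16
    s = forward_project(op, np.zeros((16, 16)))
    np.testing.assert_array_equal(s.values, 0.0)


def test_forward_projection_is_linear(toy16, rng):
    _, op = toy16
    x1 = rng.normal(size=(16, 16))
    x2 = rng.normal(size=(16, 16))
    lhs = forward_project(op, 2.5 * x1 - 0.7 * x2).values
    rhs = 2.5 * forward_project(op, x1).values - 0.7 * forward_project(op, x2).values
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_disk_central_bin_equals_chord_length():
    """A centered uniform disk of radius 10 has central line integral 2r = 20
    at every view (up to pixelisation of the disk boundary)."""
    g = make_geometry(ImageGrid(64, 64, 1.0), Detector(93, 1.0, 0.0),
                      ViewSet(180, 0.0, 1.0))
    op = ProjectionOperator(g)
    x, y = g.grid.pixel_centers()
    disk = (np.hypot(x, y) <= 10.0).astype(float)
    s = forward_project(op, disk)
    central = s.values[:, g.n_bins_extended // 2]
    assert np.all(np.abs(central - 20.0) < 2.0)
    assert abs(central.mean() - 20.0) < 0.3
    # rotational symmetry: whole sinogram rows agree across views
    row_spread = s.values[:, op.geometry.measured_mask()].std(axis=0)
    assert row_spread.max() < 1.0


def test_zero_sinogram_backprojects_to_zero(toy16):
    g, op = toy16
    s = Sinogram(np.zeros((g.views.n_views, g.n_bins_extended)),
                 g.measured_mask(), g)
    np.testing.assert_array_equal(back_project(op, s), 0.0)


def test_adjoint_identity(toy16, rng):
    g, op = toy16
    x = rng.normal(size=(16, 16))
    y = rng.normal(size=(g.views.n_views, g.n_bins_extended))
    lhs = np.vdot(forward_project(op, x).values, y)
    rhs = np.vdot(x, back_project(op, y))
    assert abs(lhs - rhs) <= 1e-12 * abs(lhs)


def test_backprojection_of_ones_equals_column_sums(toy16):
    g, op = toy16
    ones = Sinogram(np.ones((g.views.n_views, g.n_bins_extended)),
                    g.measured_mask(), g)
    colsums = np.asarray(op.matrix.todense()).sum(axis=0).reshape(16, 16)
    np.testing.assert_allclose(back_project(op, ones), colsums, atol=1e-12)


def test_shape_mismatches_rejected(toy16):
    _, op = toy16
    with pytest.raises(ValueError):
        forward_project(op, np.zeros((8, 8)))
    with pytest.raises(ValueError):
        back_project(op, np.zeros((3, 3)))


def _fine_sinogram(values_row):
    """Build a fine sinogram whose every view holds ``values_row``."""
    coarse = make_geometry(ImageGrid(6, 6, 1.0), Detector(3, 1.0, 0.0),
                           ViewSet(2, 0.0, 90.0))
    fine = refine_geometry(coarse, 3)
    assert fine.n_bins_extended == len(values_row)
    vals = np.tile(np.asarray(values_row, float), (2, 1))
    return Sinogram(vals, fine.measured_mask(), fine), coarse


def test_bin_down_averages_groups_of_three():
    fine_ext = refine_geometry(
        make_geometry(ImageGrid(6, 6, 1.0), Detector(3, 1.0, 0.0),
                      ViewSet(2, 0.0, 90.0)), 3).n_bins_extended
    row = np.arange(fine_ext, dtype=float)
    s, coarse = _fine_sinogram(row)
    down = bin_down(s, 3)
    expected = row.reshape(-1, 3).mean(axis=1)
    np.testing.assert_allclose(down.values, np.tile(expected, (2, 1)))
    assert down.geometry.detector.n_bins == 3
    assert down.geometry.detector.bin_width == pytest.approx(3.0 * (1.0 / 3.0))


@pytest.mark.parametrize("n_coarse,offset", [(107, 39.0), (185, 0.0)])
def test_bin_down_study_detectors(n_coarse, offset):
    coarse = make_geometry(ImageGrid(128, 128, 1.0), Detector(n_coarse, 1.0, offset),
                           ViewSet(2, 0.0, 90.0))
    fine = refine_geometry(coarse, 3)
    assert fine.detector.n_bins == 3 * n_coarse
    s = Sinogram(np.ones((2, fine.n_bins_extended)), fine.measured_mask(), fine)
    down = bin_down(s, 3)
    assert down.geometry.detector.n_bins == n_coarse
    assert down.measured.sum() == n_coarse


def test_bin_down_rejects_bad_factor():
    s, _ = _fine_sinogram(np.zeros(
        refine_geometry(make_geometry(ImageGrid(6, 6, 1.0), Detector(3, 1.0, 0.0),
                                      ViewSet(2, 0.0, 90.0)), 3).n_bins_extended))
    with pytest.raises(ValueError):
        bin_down(s, 2)


@settings(derandomize=True, max_examples=25)
@given(scale=st.floats(0.1, 10.0))
def test_bin_down_commutes_with_scaling(scale):
    fine_ext = refine_geometry(
        make_geometry(ImageGrid(6, 6, 1.0), Detector(3, 1.0, 0.0),
                      ViewSet(2, 0.0, 90.0)), 3).n_bins_extended
    row = np.linspace(0.0, 5.0, fine_ext)
    s, _ = _fine_sinogram(row)
    s_scaled, _ = _fine_sinogram(scale * row)
    np.testing.assert_allclose(bin_down(s_scaled, 3).values,
                               scale * bin_down(s, 3).values, rtol=1e-12)


def test_poisson_noise_mean_variance_and_determinism():
    value = 4.0
    counts = 50.0
    # one wide sinogram supplies > 1e4 iid draws of Poisson(counts*value)/counts
    g = make_geometry(ImageGrid(16, 16, 1.0), Detector(23, 1.0, 0.0),
                      ViewSet(500, 0.0, 0.36))
    base = Sinogram(np.full((500, g.n_bins_extended), value), g.measured_mask(), g)
    draws = add_poisson_noise(base, counts, seed=0).values.ravel()
    assert draws.size >= 10_000
    assert draws.mean() == pytest.approx(value, rel=0.01)
    assert draws.var() == pytest.approx(value / counts, rel=0.05)
    a = add_poisson_noise(base, counts, seed=1).values
    b = add_poisson_noise(base, counts, seed=1).values
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, add_poisson_noise(base, counts, seed=2).values)


def test_poisson_noise_vanishes_at_high_counts(toy16, rng):
    g, op = toy16
    x = rng.random((16, 16))
    s = forward_project(op, x)
    noisy = add_poisson_noise(s, counts_per_unit=1e12, seed=0)
    np.testing.assert_allclose(noisy.values, s.values, atol=1e-4)


def test_poisson_noise_preserves_unmeasured_and_rejects_negative(toy24_truncated):
    g, op = toy24_truncated
    vals = np.ones((g.views.n_views, g.n_bins_extended))
    s = Sinogram(vals, g.measured_mask(), g)
    noisy = add_poisson_noise(s, 10.0, seed=0)
    np.testing.assert_array_equal(noisy.values[:, ~s.measured],
                                  vals[:, ~s.measured])
    bad = Sinogram(-vals, g.measured_mask(), g)
    with pytest.raises(ValueError):
        add_poisson_noise(bad, 10.0, seed=0)
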