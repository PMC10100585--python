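import numpy as np
import pytest

from solvmap import (
    Detector,
    ImageGrid,
    ProjectionOperator,
    ReconConfig,
    Sinogram,
    ViewSet,
    apply_truncation_modification,
    default_step_size,
    estimate_lambda_max,
    forward_project,
    make_geometry,
    run_gd,
    run_mlem,
    support_from_truth,
)


def test_config_validation():
    with pytest.raises(ValueError):
        ReconConfig(algorithm="fbp")
    with pytest.raises(ValueError):
        ReconConfig(algorithm="gd", n_iterations=0)
    with pytest.raises(ValueError):
        ReconConfig(algorithm="gd", step_size_alpha=0.0)
    with pytest.raises(ValueError):
        ReconConfig(algorithm="gd", use_support=True)  # no mask


def test_truncation_modification_selection(toy24_truncated, rng):
    g, op = toy24_truncated
    shape = (g.views.n_views, g.n_bins_extended)
    data = Sinogram(rng.random(shape), g.measured_mask(), g)
    fwd = Sinogram(rng.random(shape), g.measured_mask(), g)
    out = apply_truncation_modification(data, fwd)
    np.testing.assert_array_equal(out.values[:, g.measured_mask()],
                                  data.values[:, g.measured_mask()])
    np.testing.assert_array_equal(out.values[:, ~g.measured_mask()],
                                  fwd.values[:, ~g.measured_mask()])
    # all measured -> identity on the data
    all_meas = Sinogram(data.values, np.ones(g.n_bins_extended, bool), g)
    fwd_all = Sinogram(fwd.values, np.ones(g.n_bins_extended, bool), g)
    np.testing.assert_array_equal(
        apply_truncation_modification(all_meas, fwd_all).values, data.values)
    # none measured -> the forward projection
    no_meas = Sinogram(data.values, np.zeros(g.n_bins_extended, bool), g)
    fwd_none = Sinogram(fwd.values, np.zeros(g.n_bins_extended, bool), g)
    np.testing.assert_array_equal(
        apply_truncation_modification(no_meas, fwd_none).values, fwd.values)


def test_power_iteration_matches_dense_spectrum(toy16):
    _, op = toy16
    A = op.matrix.toarray()
    lam_dense = np.linalg.eigvalsh(A.T @ A)[-1]
    assert estimate_lambda_max(op) == pytest.approx(lam_dense, rel=1e-6)
    assert default_step_size(op) == pytest.approx(1.9 / lam_dense, rel=1e-6)


def test_gd_zero_data_keeps_zero_image(toy16):
    g, op = toy16
    s = Sinogram(np.zeros((g.views.n_views, g.n_bins_extended)),
                 g.measured_mask(), g)
    res = run_gd(s, op, ReconConfig("gd", n_iterations=3, step_size_alpha=1e-3))
    np.testing.assert_array_equal(res.image, 0.0)


def test_gd_converges_to_dense_least_squares(toy16, toy16_truth):
    """Noiseless consistent data on a full-rank system: GD approaches the
    normal-equations solution computed on the explicit dense matrix."""
    _, op = toy16
    sino = forward_project(op, toy16_truth)
    ls = np.linalg.lstsq(op.matrix.toarray(), sino.values.ravel(), rcond=None)[0]
    res = run_gd(sino, op, ReconConfig("gd", n_iterations=80_000))
    err = np.linalg.norm(res.image.ravel() - ls) / np.linalg.norm(ls)
    assert err < 1e-6


def test_gd_residual_nonincreasing_below_stability_bound(toy16, toy16_truth, rng):
    g, op = toy16
    sino = forward_project(op, toy16_truth)
    noisy = sino.values + 0.1 * rng.normal(size=sino.values.shape)
    s = Sinogram(noisy, g.measured_mask(), g)
    res = run_gd(s, op, ReconConfig("gd", n_iterations=200))
    fits = np.array(res.data_fit)
    assert np.all(np.diff(fits) <= 1e-9 * fits[0])


def test_gd_support_equals_restricted_dense_gd(toy16, toy16_truth):
    """Zeroing outside the support each iteration is identical to running GD
    on the dense matrix restricted to the support columns."""
    g, op = toy16
    truth = toy16_truth.copy()
    truth[:4, :] = 0.0  # carve a known zero region
    support = truth > 0
    sino = forward_project(op, truth)
    alpha = 1e-3
    n_iter = 40
    res = run_gd(sino, op, ReconConfig("gd", n_iterations=n_iter,
                                       step_size_alpha=alpha,
                                       use_support=True, support_mask=support))
    A = op.matrix.toarray()[:, support.ravel()]
    p = sino.values.ravel()
    xs = np.zeros(A.shape[1])
    for _ in range(n_iter):
        xs = xs - alpha * (A.T @ (A @ xs - p))
    full = np.zeros(truth.size)
    full[support.ravel()] = xs
    np.testing.assert_allclose(res.image.ravel(), full, atol=1e-12)


def test_gd_modified_form_equals_residual_zeroing(toy24_truncated, rng):
    """Overwriting unmeasured bins with the current forward projection (the
    explicit form) gives bit-identical GD iterates to zeroing their residual."""
    g, op = toy24_truncated
    meas = g.measured_mask()
    data = Sinogram(np.abs(rng.random((g.views.n_views, g.n_bins_extended))),
                    meas, g).zero_unmeasured()
    alpha = 1e-3
    res = run_gd(data, op, ReconConfig("gd", n_iterations=25, step_size_alpha=alpha,
                                       use_truncation_modification=True))
    A = op.matrix
    x = np.zeros(A.shape[1])
    p0 = data.values.ravel()
    ray_meas = op.measured_ray_mask()
    for _ in range(25):
        p = np.where(ray_meas, p0, A @ x)  # Eq-style explicit overwrite
        x = x - alpha * (A.T @ (A @ x - p))
    np.testing.assert_array_equal(res.image.ravel(), x)


def test_gd_divergence_reports_step_size(toy16, toy16_truth):
    _, op = toy16
    sino = forward_project(op, toy16_truth)
    with pytest.raises(FloatingPointError, match="alpha"):
        run_gd(sino, op, ReconConfig("gd", n_iterations=500, step_size_alpha=100.0))


def test_mlem_fixed_point(toy16):
    g, op = toy16
    x0 = np.ones((16, 16))
    sino = forward_project(op, x0)
    res = run_mlem(sino, op, ReconConfig("mlem", n_iterations=1))
    np.testing.assert_allclose(res.image, x0, atol=1e-9)


def test_mlem_zero_pixels_stay_zero(toy16, toy16_truth):
    g, op = toy16
    support = np.ones((16, 16), bool)
    support[5:8, 5:8] = False
    sino = forward_project(op, toy16_truth)
    res = run_mlem(sino, op, ReconConfig("mlem", n_iterations=50,
                                         use_support=True, support_mask=support))
    np.testing.assert_array_equal(res.image[~support], 0.0)
    assert (res.image >= 0).all()


def test_mlem_converges_to_truth(toy16, toy16_truth):
    _, op = toy16
    sino = forward_project(op, toy16_truth)
    res = run_mlem(sino, op, ReconConfig("mlem", n_iterations=20_000))
    err = np.linalg.norm(res.image - toy16_truth) / np.linalg.norm(toy16_truth)
    assert err < 1e-3


def test_mlem_likelihood_nondecreasing_and_nonnegative(toy16, toy16_truth):
    g, op = toy16
    sino = forward_project(op, toy16_truth)
    from solvmap import add_poisson_noise

    noisy = add_poisson_noise(sino, counts_per_unit=200.0, seed=4)
    res = run_mlem(noisy, op, ReconConfig("mlem", n_iterations=300))
    ll = np.array(res.data_fit)
    assert np.all(np.diff(ll) >= -1e-9 * abs(ll[0]))
    assert (res.image >= 0).all()


def test_mlem_rejects_negative_data(toy16):
    g, op = toy16
    s = Sinogram(-np.ones((g.views.n_views, g.n_bins_extended)),
                 g.measured_mask(), g)
    with pytest.raises(ValueError):
        run_mlem(s, op, ReconConfig("mlem", n_iterations=1))


def test_support_mask_from_truth_dilates():
    truth = np.zeros((8, 8))
    truth[4, 4] = 1.0
    mask = support_from_truth(truth, dilate=1)
    assert mask[4, 4] and mask[3, 4] and mask[4, 5]
    assert not mask[1, 1]
    assert mask.sum() == 5
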