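"""GNCC metric, synthetic reference, NLCG optimizer, per-frame estimation."""

import numpy as np
import pytest

from kccmoco.kspace import (
    KGrid,
    RigidParams,
    forward_transform,
    inverse_transform,
    invert_rigid,
    translate_array,
)
from kccmoco.registration import (
    GaussianWeight,
    OptimizerOptions,
    build_reference,
    estimate_frame,
    gncc,
    nlcg_minimize,
    objective,
    rotation_objective_magnitude,
)
from kccmoco.sampling import SamplingSpec, make_masks

from conftest import make_smooth_image


class TestGaussianWeight:
    def test_peak_one_at_center_and_symmetry(self):
        g = GaussianWeight(20.0, (64, 64))
        assert g.w[32, 32] == 1.0 and g.w.max() == 1.0
        assert np.allclose(g.w, g.w.T)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            GaussianWeight(0.0, (64, 64))


class TestBuildReference:
    def test_identical_full_frames(self):
        s = forward_transform(make_smooth_image(64, 0))
        g1 = GaussianWeight(20.0, (64, 64))
        ref = build_reference(np.stack([s, s, s]), g1)
        assert np.abs(ref - g1.w * s).max() < 1e-12

    def test_center_is_mean_of_center_samples(self):
        frames = np.stack([forward_transform(make_smooth_image(64, s)) for s in range(4)])
        g1 = GaussianWeight(20.0, (64, 64))
        ref = build_reference(frames, g1)
        assert ref[32, 32] == pytest.approx(frames[:, 32, 32].mean())

    def test_support_matches_union_mask(self):
        """Zero-filled radial frames: reference support == union of spokes."""
        grid = KGrid(200, 200)
        spec = SamplingSpec("golden_radial_cartesian", 4, 32, grid)
        masks = make_masks(spec)
        rng = np.random.default_rng(0)
        base = rng.standard_normal((200, 200)) + 1j * rng.standard_normal((200, 200))
        frames = np.stack([base * m for m in masks])
        g1 = GaussianWeight(20.0, (200, 200))
        ref = build_reference(frames, g1)
        union = masks.any(axis=0)
        assert np.all((np.abs(ref) > 0) <= union)
        # inside the union and where G1 is materially nonzero, support is kept
        strong = union & (g1.w > 1e-12)
        assert np.count_nonzero(np.abs(ref)[strong] > 0) == np.count_nonzero(strong)

    def test_single_frame_rejected(self):
        g1 = GaussianWeight(20.0, (64, 64))
        with pytest.raises(ValueError):
            build_reference(np.zeros((1, 64, 64), complex), g1)


class TestGncc:
    g = GaussianWeight(20.0, (64, 64))

    def test_self_correlation_is_one(self):
        s = forward_transform(make_smooth_image(64, 1))
        v = gncc(s, s, self.g)
        assert abs(v - 1.0) < 1e-12

    def test_positive_scale_invariance(self):
        s = forward_transform(make_smooth_image(64, 2))
        for alpha in [0.1, 3.7]:
            assert abs(gncc(s, alpha * s, self.g) - 1.0) < 1e-12

    def test_white_noise_decorrelation(self):
        """|V| of independent complex white noise stays small (Monte Carlo)."""
        g = GaussianWeight(20.0, (200, 200))
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(100):
            a = rng.standard_normal((200, 200)) + 1j * rng.standard_normal((200, 200))
            b = rng.standard_normal((200, 200)) + 1j * rng.standard_normal((200, 200))
            vals.append(abs(gncc(a, b, g)))
        assert max(vals) < 0.05

    def test_parseval_identity_with_image_domain_ncc(self):
        """Plain k-space NCC equals image-domain NCC on fully-sampled pairs."""
        sa = forward_transform(make_smooth_image(64, 4))
        sb = forward_transform(make_smooth_image(64, 5))
        v_k = gncc(sa, sb, self.g, centering="none")
        ia, ib = inverse_transform(sa), inverse_transform(sb)
        v_img = np.sum(ia * np.conj(ib)) / np.sqrt(
            np.sum(np.abs(ia) ** 2) * np.sum(np.abs(ib) ** 2)
        )
        assert abs(v_k - v_img) < 1e-10

    def test_zero_inputs_named(self):
        s = forward_transform(make_smooth_image(64, 6))
        z = np.zeros_like(s)
        with pytest.raises(ValueError, match="moving"):
            gncc(s, z, self.g, centering="none")
        with pytest.raises(ValueError, match="reference"):
            gncc(z, s, self.g, centering="none")

    def test_unknown_centering_rejected(self):
        s = forward_transform(make_smooth_image(64, 6))
        with pytest.raises(ValueError):
            gncc(s, s, self.g, centering="median")


class TestObjective:
    g = GaussianWeight(20.0, (64, 64))

    def test_global_minimum_minus_one_for_identical_frames(self):
        s = forward_transform(make_smooth_image(64, 7))
        f = objective(np.zeros(2), s, s, self.g, "translation", centering="none")
        assert f == pytest.approx(-1.0, abs=1e-12)

    def test_even_in_translation_for_symmetrized_input(self):
        """Average of a +-dx pair gives a symmetric objective in dx.

        Exact for the plain (uncentered) correlation of real images; the
        G-weighted mean removal breaks strict evenness because the weighted
        mean of a shifted image depends on the shift direction.
        """
        s = forward_transform(make_smooth_image(64, 8).real)
        sym = 0.5 * (translate_array(s, 1.5, 0.0) + translate_array(s, -1.5, 0.0))
        g = self.g
        for dx in [0.5, 1.0, 2.0]:
            fp = objective(np.array([dx, 0.0]), sym, s, g, "translation", centering="none")
            fm = objective(np.array([-dx, 0.0]), sym, s, g, "translation", centering="none")
            assert fp == pytest.approx(fm, abs=1e-10)

    def test_translation_grid_scan_attains_true_shift(self):
        """Exhaustive 0.25-px scan of the objective peaks at the true shift."""
        s = forward_transform(make_smooth_image(64, 9))
        moved = translate_array(s, 2.0, -1.5)
        grid = np.arange(-3.0, 3.01, 0.25)
        best = min(
            ((a, b, objective(np.array([a, b]), moved, s, self.g, "translation"))
             for a in grid for b in grid),
            key=lambda v: v[2],
        )
        assert (best[0], best[1]) == (-2.0, 1.5)

    def test_rotation_out_of_range_is_inf(self):
        s = forward_transform(make_smooth_image(64, 9))
        assert objective(np.array([1.0]), s, s, self.g, "rotation") == np.inf
        assert rotation_objective_magnitude(1.0, s, s) == np.inf

    def test_unknown_stage_rejected(self):
        s = forward_transform(make_smooth_image(64, 9))
        with pytest.raises(ValueError):
            objective(np.zeros(2), s, s, self.g, "affine")


class TestNlcg:
    opts = OptimizerOptions()

    def test_convex_quadratic(self):
        a = np.array([1.3, -2.1, 0.4])
        opts = OptimizerOptions(max_iter=200, tol_px=1e-9, fd_step_px=1e-6)
        x, fx, _ = nlcg_minimize(lambda v: float(np.sum((v - a) ** 2)), np.zeros(3), opts)
        assert np.abs(x - a).max() < 1e-6

    def test_rosenbrock(self):
        def rosen(v):
            return float(100.0 * (v[1] - v[0] ** 2) ** 2 + (1 - v[0]) ** 2)

        opts = OptimizerOptions(max_iter=500, tol_px=1e-9, initial_step_px=0.5)
        x, fx, _ = nlcg_minimize(rosen, np.array([-1.2, 1.0]), opts)
        assert fx < 1e-6

    def test_monotone_contract_never_worse_than_start(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = rng.standard_normal(2)

            def bumpy(v):
                return float(np.sum((v - a) ** 2) + 0.3 * np.sin(5 * v).sum())

            x0 = rng.standard_normal(2)
            _, fx, _ = nlcg_minimize(bumpy, x0, self.opts)
            assert fx <= bumpy(x0) + 1e-15

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError):
            nlcg_minimize(lambda v: float("nan"), np.zeros(2), self.opts)


class TestEstimateFrame:
    def test_null_motion_recovers_zero(self):
        s = forward_transform(make_smooth_image(64, 12))
        g = GaussianWeight(20.0, (64, 64))
        params, diag = estimate_frame(s, GaussianWeight(20.0, (64, 64)).w * s, g)
        assert abs(params.theta2) < 0.05 and abs(params.theta3) < 0.05
        assert abs(params.theta1) < 0.005
        assert diag["abs_V"] > 0.99

    def test_known_rigid_motion_recovered_on_smooth_image(self):
        from kccmoco.kspace import ComplexKFrame, apply_rigid

        s = forward_transform(make_smooth_image(128, 13, sigma=4.0))
        g1 = GaussianWeight(20.0, (128, 128))
        p = RigidParams(0.03, 2.5, -3.0)
        moved = apply_rigid(
            ComplexKFrame(s, np.ones((128, 128), np.uint8)), p
        ).data
        est, _ = estimate_frame(moved, g1.w * s, g1)
        inv = invert_rigid(p)
        assert abs(est.theta1 - inv.theta1) < 0.005
        assert abs(est.theta2 - inv.theta2) < 0.1
        assert abs(est.theta3 - inv.theta3) < 0.1

    def test_deterministic(self):
        s = forward_transform(make_smooth_image(64, 14))
        g = GaussianWeight(20.0, (64, 64))
        ref = g.w * translate_array(s, 0.7, -0.3)
        a, _ = estimate_frame(s, ref, g)
        b, _ = estimate_frame(s, ref, g)
        assert a == b

    def test_shape_mismatch_rejected(self):
        g = GaussianWeight(20.0, (64, 64))
        with pytest.raises(ValueError):
            estimate_frame(np.zeros((64, 64), complex), np.zeros((32, 32), complex), g)
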