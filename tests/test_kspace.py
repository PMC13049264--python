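"""Fourier conventions and exact rigid transforms on the Cartesian k-space grid."""

import numpy as np
import pytest
import scipy.ndimage
from hypothesis import given, settings
from hypothesis import strategies as st

from kccmoco.kspace import (
    ComplexKFrame,
    KGrid,
    RigidParams,
    apply_rigid,
    apply_translation,
    forward_transform,
    inverse_transform,
    invert_rigid,
    rotate_3shear,
    rotate_array_3shear,
    translate_array,
)

from conftest import make_smooth_image


def full_frame(data):
    return ComplexKFrame(data=data, mask=np.ones(data.shape, dtype=np.uint8))


def spatial_rotate(img, theta, order=5):
    """Independent spatial-domain rotation oracle (spline resampling)."""
    n = img.shape[0]
    c, s = np.cos(theta), np.sin(theta)
    rot_inv = np.array([[c, -s], [s, c]])  # R(-theta) in (row, col)
    center = np.array([n // 2, n // 2], dtype=float)
    return scipy.ndimage.affine_transform(
        img, rot_inv, offset=center - rot_inv @ center, order=order
    )


class TestGridAndTypes:
    def test_kzero_sits_at_half_index(self):
        g = KGrid(8, 12)
        assert g.k_y[4] == 0.0 and g.k_x[6] == 0.0
        assert np.all(np.diff(g.k_y) > 0) and np.all(np.diff(g.k_x) > 0)

    @pytest.mark.parametrize("shape", [(7, 8), (8, 7)])
    def test_odd_sizes_rejected_naming_axis(self, shape):
        with pytest.raises(ValueError, match="odd"):
            KGrid(*shape)

    def test_rigid_params_reject_nonfinite_and_large_rotation(self):
        with pytest.raises(ValueError):
            RigidParams(theta1=np.nan)
        with pytest.raises(ValueError, match="3-shear"):
            RigidParams(theta1=np.pi / 3)

    def test_frame_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ComplexKFrame(data=np.zeros((8, 8)), mask=np.ones((8, 10)))


class TestForwardTransform:
    def test_dc_image_concentrates_at_center(self):
        s = forward_transform(np.ones((256, 256)))
        assert abs(s[128, 128]) > 1e-6
        s[128, 128] = 0.0
        assert np.abs(s).max() < 1e-10

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_roundtrip_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        back = inverse_transform(forward_transform(img))
        assert np.abs(back - img).max() < 1e-12

    def test_parseval(self):
        img = make_smooth_image(64, 0)
        s = forward_transform(img)
        e_img = np.sum(np.abs(img) ** 2)
        e_k = np.sum(np.abs(s) ** 2)
        assert abs(e_img - e_k) / e_img < 1e-10

    def test_odd_input_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            forward_transform(np.ones((63, 64)))


class TestTranslation:
    def test_zero_translation_is_identity(self, smooth_image):
        fr = full_frame(forward_transform(smooth_image))
        out = apply_translation(fr, 0.0, 0.0)
        assert np.array_equal(out.data, fr.data)

    @pytest.mark.parametrize("shift", [(3, 0), (0, -2), (5, 7), (-4, -11)])
    def test_integer_shift_matches_circular_roll(self, shift, smooth_image):
        """Shift theorem: integer translations == np.roll in image domain."""
        dx, dy = shift
        fr = full_frame(forward_transform(smooth_image))
        out = apply_translation(fr, dx, dy)
        img = inverse_transform(out.data)
        expected = np.roll(smooth_image, (dy, dx), axis=(0, 1))
        assert np.abs(img - expected).max() < 1e-10

    def test_delta_image_peak_moves_three_pixels(self):
        img = np.zeros((64, 64), complex)
        img[32, 32] = 1.0
        out = apply_translation(full_frame(forward_transform(img)), 3.0, 0.0)
        peak = np.unravel_index(np.argmax(np.abs(inverse_transform(out.data))), (64, 64))
        assert peak == (32, 35)

    def test_half_pixel_group_property(self, smooth_image):
        fr = full_frame(forward_transform(smooth_image))
        twice = apply_translation(apply_translation(fr, 0.5, 0.0), 0.5, 0.0)
        once = apply_translation(fr, 1.0, 0.0)
        assert np.abs(twice.data - once.data).max() < 1e-12

    def test_energy_preserved_exactly(self, smooth_image):
        fr = full_frame(forward_transform(smooth_image))
        out = apply_translation(fr, 1.37, -2.61)
        assert np.isclose(np.sum(np.abs(out.data) ** 2), np.sum(np.abs(fr.data) ** 2))

    def test_nonfinite_rejected(self, smooth_image):
        fr = full_frame(forward_transform(smooth_image))
        with pytest.raises(ValueError):
            apply_translation(fr, np.inf, 0.0)
        with pytest.raises(ValueError):
            translate_array(fr.data, 0.0, np.nan)


class TestRotation3Shear:
    def test_zero_angle_identity(self, smooth_image):
        fr = full_frame(forward_transform(smooth_image))
        out = rotate_3shear(fr, 0.0)
        assert np.array_equal(out.data, fr.data)

    def test_inverse_pair_recovers_center(self, smooth_image):
        fr = full_frame(forward_transform(smooth_image))
        back = rotate_3shear(rotate_3shear(fr, 0.05), -0.05)
        img0 = inverse_transform(fr.data)
        img1 = inverse_transform(back.data)
        q = slice(16, 48)
        assert np.abs((img1 - img0)[q, q]).max() < 1e-6

    def test_matches_spatial_spline_oracle(self):
        """k-space 3-shear rotation vs independent image-domain spline rotation."""
        n = 128
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        img = np.exp(-((yy - 74) ** 2 + (xx - 84) ** 2) / (2 * 8.0**2))
        rot_k = inverse_transform(
            rotate_array_3shear(forward_transform(img), 0.1)
        ).real
        oracle = spatial_rotate(img, 0.1)
        q = slice(n // 4, 3 * n // 4)
        err = np.linalg.norm((rot_k - oracle)[q, q]) / np.linalg.norm(oracle[q, q])
        assert err < 1e-2

    @pytest.mark.parametrize("theta", [0.01, -0.05, 0.1])
    def test_energy_conservation(self, theta, smooth_image):
        s = forward_transform(smooth_image)
        r = rotate_array_3shear(s, theta)
        e0, e1 = np.sum(np.abs(s) ** 2), np.sum(np.abs(r) ** 2)
        assert abs(e1 - e0) / e0 < 1e-9

    def test_large_angle_rejected(self, smooth_image):
        with pytest.raises(ValueError, match="pi/4"):
            rotate_array_3shear(forward_transform(smooth_image), 0.9)

    def test_mask_transport_stays_binary(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[::4, :] = 1
        fr = ComplexKFrame(data=mask.astype(complex), mask=mask)
        out = rotate_3shear(fr, 0.08)
        assert set(np.unique(out.mask)) <= {0, 1}
        # roughly area-preserving for a small rotation
        assert 0.7 * mask.sum() < out.mask.sum() < 1.3 * mask.sum()


class TestApplyRigid:
    def test_identity_params(self, smooth_image):
        fr = full_frame(forward_transform(smooth_image))
        out = apply_rigid(fr, RigidParams())
        assert np.array_equal(out.data, fr.data)

    def test_pure_translation_reduces_to_phase_ramp(self, smooth_image):
        fr = full_frame(forward_transform(smooth_image))
        a = apply_rigid(fr, RigidParams(0.0, 1.5, -2.5))
        b = apply_translation(fr, 1.5, -2.5)
        assert np.abs(a.data - b.data).max() < 1e-12

    def test_matches_spatial_rigid_oracle(self):
        """Rotation + shift in image domain vs apply_rigid in k-space."""
        n = 128
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        img = np.exp(-((yy - 74) ** 2 + (xx - 84) ** 2) / (2 * 8.0**2))
        p = RigidParams(0.1, 5.0, -3.0)
        moved = inverse_transform(
            apply_rigid(full_frame(forward_transform(img)), p).data
        ).real
        oracle = scipy.ndimage.shift(spatial_rotate(img, p.theta1), (p.theta3, p.theta2), order=5)
        q = slice(n // 4, 3 * n // 4)
        err = np.linalg.norm((moved - oracle)[q, q]) / np.linalg.norm(oracle[q, q])
        assert err < 1e-2

    def test_inverse_composition_recovers_input(self, smooth_image):
        fr = full_frame(forward_transform(smooth_image))
        p = RigidParams(0.07, 2.0, -1.0)
        back = apply_rigid(apply_rigid(fr, p), invert_rigid(p))
        img0 = inverse_transform(fr.data)
        img1 = inverse_transform(back.data)
        q = slice(16, 48)
        assert np.abs((img1 - img0)[q, q]).max() < 1e-6

    def test_invert_rigid_is_involution(self):
        p = RigidParams(0.1, 3.0, -2.0)
        q = invert_rigid(invert_rigid(p))
        assert np.allclose(p.as_array(), q.as_array(), atol=1e-12)
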