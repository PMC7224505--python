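"""Alignment metrics, resampling, and parameter recovery on phantoms."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from fasc3d.core import AffineTransform2D
from fasc3d.phantom import PhantomSpec, generate_phantom
from fasc3d.registration import (
    RegistrationSchedule,
    apply_transform,
    default_schedule,
    estimate_background,
    mse,
    register_pair,
    register_stack,
    ssim,
)


class TestMetrics:
    def test_identical_images(self, rng):
        a = rng.random((32, 32))
        assert mse(a, a) == 0.0
        assert ssim(a, a) == pytest.approx(1.0)

    def test_constant_offset_one_level(self, rng):
        a = rng.random((32, 32)) * 0.9
        b = a + 1.0 / 255.0
        assert mse(a, b) == pytest.approx(1.0)

    def test_mse_matches_loop_oracle(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        total = 0.0
        for i in range(16):
            for j in range(16):
                total += ((a[i, j] - b[i, j]) * 255.0) ** 2
        assert mse(a, b) == pytest.approx(total / 256)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.zeros((4, 4)), np.zeros((5, 4)))


class TestEstimateBackground:
    def test_uniform(self):
        assert estimate_background(np.full((50, 50), 0.37)) == pytest.approx(0.37)

    def test_centered_object_ignored(self):
        img = np.full((100, 100), 0.9)
        img[30:70, 30:70] = 0.1
        assert estimate_background(img) == pytest.approx(0.9)

    def test_checkerboard_border_median(self):
        img = np.indices((60, 60)).sum(axis=0) % 2 * 0.5 + 0.25
        width = max(1, int(round(0.02 * 60)))
        ring = np.concatenate([
            img[:width].ravel(), img[-width:].ravel(),
            img[width:-width, :width].ravel(), img[width:-width, -width:].ravel(),
        ])
        assert estimate_background(img) == pytest.approx(np.median(ring))


class TestApplyTransform:
    def test_identity_bitwise(self, rng):
        img = rng.random((30, 30))
        out = apply_transform(img, AffineTransform2D.identity(), fill=0.0)
        assert np.array_equal(out, img)

    def test_integer_translation_exact(self, rng):
        img = rng.random((40, 40))
        t = AffineTransform2D.from_params((10, -5))
        out = apply_transform(img, t, fill=0.5)
        assert np.allclose(out[0:35, 10:], img[5:, 0:30])
        assert np.all(out[:, :10] == 0.5)  # vacated band gets the fill
        assert np.all(out[35:, :] == 0.5)

    def test_round_trip_on_smooth_image(self, rng):
        img = ndi.gaussian_filter(rng.random((64, 64)), 3.0)
        t = AffineTransform2D.from_params((3.7, -2.2), 8, 1.03, center=(31.5, 31.5))
        back = apply_transform(
            apply_transform(img, t, fill=img.mean()), t.inverse(), fill=img.mean()
        )
        interior = np.abs(back - img)[8:-8, 8:-8]
        assert interior.mean() < 0.02


class TestSchedule:
    def test_default_steps_are_nested_and_coarse_to_fine(self):
        for stain, step3 in (("HE", 0.75), ("IHC", 1.0)):
            sched = default_schedule(stain)
            families = [f for f, _ in sched.steps]
            scales = [s for _, s in sched.steps]
            assert families == ["translation", "rigid", "similarity", "affine"]
            assert scales == [0.25, 0.5, step3, 1.0]

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            RegistrationSchedule([("affine", 0.5), ("translation", 1.0)])

    def test_decreasing_scales_rejected(self):
        with pytest.raises(ValueError):
            RegistrationSchedule([("translation", 0.5), ("rigid", 0.25)])


@pytest.fixture(scope="module")
def phantom_slice():
    spec = PhantomSpec(
        n_slices=2, image_size=320, n_fascicles=4,
        fascicle_radii=(9, 20), noise_sd=0.02, seed=5,
    )
    stack, _ = generate_phantom(spec)
    return stack.slices[0].gray()


class TestRegisterPair:
    def test_self_registration_near_identity(self, phantom_slice):
        t, q = register_pair(phantom_slice, phantom_slice, "IHC")
        assert np.linalg.norm(t.translation) < 0.5
        assert abs(t.rotation_deg) < 0.2
        assert q.mse_after <= q.mse_before + 1e-6

    def test_known_shift_recovered(self, phantom_slice):
        true = AffineTransform2D.from_params((12, -7))
        fill = estimate_background(phantom_slice)
        moving = apply_transform(phantom_slice, true.inverse(), fill=fill)
        t, q = register_pair(moving, phantom_slice, "IHC")
        assert np.allclose(t.translation, (12, -7), atol=1.0)
        assert q.mse_after < q.mse_before
        assert q.ssim_after > q.ssim_before

    def test_known_rotation_and_scale_recovered(self, phantom_slice):
        h, w = phantom_slice.shape
        center = ((w - 1) / 2, (h - 1) / 2)
        true = AffineTransform2D.from_params((0, 0), 5.0, 1.05, center=center)
        fill = estimate_background(phantom_slice)
        moving = apply_transform(phantom_slice, true.inverse(), fill=fill)
        t, _ = register_pair(moving, phantom_slice, "IHC")
        assert t.rotation_deg == pytest.approx(5.0, abs=1.0)
        assert t.scale == pytest.approx(1.05, abs=0.01)


class TestRegisterStack:
    def test_identical_slices_near_identity(self):
        spec = PhantomSpec(
            n_slices=4, image_size=256, n_fascicles=3,
            fascicle_radii=(9, 18), centerline_wander=0.0,
            noise_sd=0.0, seed=3,
        )
        stack, _ = generate_phantom(spec)
        _, transforms, quality = register_stack(stack)
        assert len(quality) == len(stack) - 1  # one record per pair
        # pairwise jitter from stochastic metric sampling accumulates
        # through chaining; composed transforms stay within ~1.5 px
        for t in transforms:
            assert np.linalg.norm(t.translation) < 1.5
            assert abs(t.rotation_deg) < 0.2

    def test_known_jitter_recovered_through_chaining(self):
        """Composed transforms recover per-slice frame jitter when the
        anatomy itself does not move between slices."""
        spec = PhantomSpec(
            n_slices=5, image_size=320, n_fascicles=4,
            fascicle_radii=(9, 20), centerline_wander=0.0,
            misalignment=(15.0, 8.0, 0.0), noise_sd=0.02, seed=7,
        )
        stack, truth = generate_phantom(spec)
        _, transforms, _ = register_stack(stack)
        probe = np.array([[80, 80], [240, 80], [80, 240], [240, 240], [160, 160]])
        for est, true in zip(transforms, truth.transforms):
            err = np.linalg.norm(
                est.apply_points(probe) - true.apply_points(probe), axis=1
            )
            assert err.max() < 2.0
            assert abs(est.rotation_deg - true.rotation_deg) < 1.0
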