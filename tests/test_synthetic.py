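import numpy as np
import pytest

from hsfocus import (
    OpticsSpec,
    SceneSpec,
    add_poisson_noise,
    apply_illumination_gradient,
    dof,
    make_scene,
    render_stack,
    step_size,
)
from hsfocus.measures import compute, entropy_fm
from hsfocus.synthetic import DetectorSpec, illumination_profile


class TestDepthOfField:
    def test_closed_form_value(self):
        optics = OpticsSpec(wavelength_um=0.55, n=1.0, na=0.5)
        expected = 0.55 / (4 * (1 - np.sqrt(0.75)))
        assert dof(optics) == pytest.approx(expected)
        assert expected == pytest.approx(1.0266, abs=1e-3)

    def test_linear_in_wavelength(self):
        a = dof(OpticsSpec(wavelength_um=0.55, na=0.3))
        b = dof(OpticsSpec(wavelength_um=1.10, na=0.3))
        assert b == pytest.approx(2 * a)

    def test_diverges_as_na_vanishes(self):
        values = [dof(OpticsSpec(na=na)) for na in (0.4, 0.2, 0.1, 0.05)]
        assert values == sorted(values)
        assert values[-1] > 50 * values[0] / 10

    def test_invalid_na(self):
        with pytest.raises(ValueError):
            dof(OpticsSpec(na=1.5, n=1.0))

    def test_step_is_half_dof(self):
        optics = OpticsSpec()
        assert step_size(optics) == pytest.approx(dof(optics) / 2)
        assert step_size(optics) < dof(optics)


class TestScene:
    @pytest.mark.parametrize("texture", ["soil", "edges", "mixed"])
    @pytest.mark.parametrize("axes", ["spatial_spectral", "spatial_spatial"])
    def test_scene_valid_and_reproducible(self, texture, axes):
        spec = SceneSpec(texture=texture, axes=axes, size=(32, 32), seed=9)
        a, b = make_scene(spec), make_scene(spec)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.pixels.min() >= 0
        assert a.pixels.max() <= 2**spec.bit_depth - 1
        assert a.pixels.std() > 0

    def test_unknown_texture(self):
        with pytest.raises(ValueError):
            make_scene(SceneSpec(texture="tartan"))


class TestRenderStack:
    def test_true_focus_frame_is_the_scene(self):
        scene = make_scene(SceneSpec(size=(32, 32), seed=3))
        stack = render_stack(scene, n_frames=11, detector=None)
        center = stack.meta["true_focus_index"]
        assert center == 5
        np.testing.assert_array_equal(stack[center].pixels, scene.pixels)

    def test_blur_symmetric_about_focus(self):
        stack = render_stack(SceneSpec(size=(32, 32), seed=3), n_frames=11,
                             detector=None)
        c = stack.meta["true_focus_index"]
        for k in (1, 3, 5):
            np.testing.assert_allclose(stack[c - k].pixels, stack[c + k].pixels)

    def test_gradient_fms_peak_at_true_focus_noise_free(self):
        stack = render_stack(SceneSpec(size=(48, 48), seed=2), n_frames=21,
                             detector=None)
        c = stack.meta["true_focus_index"]
        for fm_id in ("TEN1", "BRE", "BOD", "EIG", "SAG"):
            values = [compute(fm_id, fr) for fr in stack.frames]
            assert int(np.argmax(values)) == c

    def test_detector_noise_reproducible_from_seed(self):
        spec = SceneSpec(size=(32, 32), seed=1)
        a = render_stack(spec, n_frames=5, seed=11)
        b = render_stack(spec, n_frames=5, seed=11)
        c = render_stack(spec, n_frames=5, seed=12)
        np.testing.assert_array_equal(a.pixel_cube(), b.pixel_cube())
        assert np.any(a.pixel_cube() != c.pixel_cube())

    def test_z_axis_centered_with_nyquist_step(self):
        optics = OpticsSpec()
        stack = render_stack(SceneSpec(size=(32, 32)), optics, n_frames=41)
        assert len(stack) == 41
        np.testing.assert_allclose(np.diff(stack.z_um), step_size(optics))
        assert stack.z_um[20] == pytest.approx(optics.true_focus_z)


class TestPoissonNoise:
    def test_deterministic_given_seed(self, clean_stack):
        a = add_poisson_noise(clean_stack, 25, seed=3)
        b = add_poisson_noise(clean_stack, 25, seed=3)
        np.testing.assert_array_equal(a.pixel_cube(), b.pixel_cube())

    def test_added_noise_mean_matches_level(self, clean_stack):
        level = 50
        noisy = add_poisson_noise(clean_stack, level, seed=7)
        added = noisy.pixel_cube().astype(float) - clean_stack.pixel_cube()
        assert added.size > 4e4
        assert added.mean() == pytest.approx(level, rel=0.01)

    def test_scaled_mode_preserves_mean(self, clean_stack):
        noisy = add_poisson_noise(clean_stack, 10, seed=7, mode="scaled")
        assert noisy.pixel_cube().mean() == pytest.approx(
            clean_stack.pixel_cube().mean(), rel=0.02
        )

    def test_invalid_level(self, clean_stack):
        with pytest.raises(ValueError):
            add_poisson_noise(clean_stack, 0)


class TestIllumination:
    def test_profile_center_orientation(self):
        g = illumination_profile(101, peak=1.0, orientation="center")
        assert g[50] == pytest.approx(1.0)
        assert g[0] == 0.0 and g[-1] == 0.0

    def test_center_pixel_unchanged_at_peak_one(self, clean_stack):
        out = apply_illumination_gradient(clean_stack, peak=1.0)
        mid = clean_stack.frame_shape[1] // 2
        w = clean_stack.frame_shape[1]
        g_mid = 1.0 - (2.0 * mid / (w - 1) - 1.0) ** 2
        np.testing.assert_allclose(
            out[0].pixels[:, mid], clean_stack[0].pixels[:, mid] * g_mid
        )
        assert g_mid == pytest.approx(1.0, abs=1e-3)

    def test_edge_orientation_profile(self):
        g = illumination_profile(11, peak=0.8, orientation="edge")
        assert g[0] == pytest.approx(0.8)
        assert g[-1] == 0.0

    def test_histogram_fm_changes_but_stays_permutation_invariant(self, clean_stack,
                                                                  rng):
        out = apply_illumination_gradient(clean_stack, peak=0.9)
        frame = out[0].pixels
        assert entropy_fm(frame) != entropy_fm(clean_stack[0].pixels)
        perm = rng.permutation(frame.ravel()).reshape(frame.shape)
        assert entropy_fm(perm) == pytest.approx(entropy_fm(frame))

    def test_invalid_peak(self, clean_stack):
        with pytest.raises(ValueError):
            apply_illumination_gradient(clean_stack, peak=1.5)
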