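"""CAS/VD pipeline: orientation estimation, axis, masking, vernier detection."""

import numpy as np
import pytest
from scipy import ndimage

from sarcolattice import (
    ImageStack,
    MorphometryConfig,
    analyze_fiber_stack,
    cosine_angle_sum,
    detect_verniers,
    estimate_fiber_axis,
    generate_striated_fiber,
    local_orientation_field,
    mask_intracellular_shg,
    mean_cos_deviation,
    vernier_density,
)
from sarcolattice.morphometry import OrientationField
from sarcolattice.synth import auto_collagen_streaks

from conftest import (
    SNR5_NOISE_SD,
    match_events,
    scene_with,
    small_fiber_scene,
    vernier_scene,
)


def grating(angle_deg: float, shape=(128, 128), period_px=10.0) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    th = np.deg2rad(angle_deg)
    s = cc * np.cos(th) + rr * np.sin(th)
    return 0.5 * (1 + np.sin(2 * np.pi * s / period_px))


class TestOrientationField:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 117.0])
    def test_grating_angle_recovered(self, angle):
        fld = local_orientation_field(grating(angle), spacing_px=10.0)
        interior = np.zeros((128, 128), bool)
        interior[20:-20, 20:-20] = True
        sel = fld.valid & interior
        assert sel.any()
        dev = (fld.angle_deg[sel] - angle + 90) % 180 - 90
        assert np.max(np.abs(dev)) < 0.5

    def test_flat_image_has_no_valid_pixels(self):
        fld = local_orientation_field(np.full((64, 64), 0.3), spacing_px=10.0)
        assert fld.n_valid == 0

    def test_undersampled_spacing_rejected(self):
        with pytest.raises(ValueError, match="aliased"):
            local_orientation_field(grating(0.0), spacing_px=1.5)


class TestFiberAxis:
    def test_rotated_rectangle_principal_axis(self):
        rr, cc = np.mgrid[0:200, 0:200].astype(float)
        th = np.deg2rad(25.0)
        s = (cc - 100) * np.cos(th) + (rr - 100) * np.sin(th)
        t = -(cc - 100) * np.sin(th) + (rr - 100) * np.cos(th)
        mask = (np.abs(s) < 80) & (np.abs(t) < 20)
        ang, method = estimate_fiber_axis(mask)
        assert method == "mask_moments"
        assert abs((ang - 25.0 + 90) % 180 - 90) < 1.0

    def test_isotropic_mask_falls_back_to_field(self):
        rr, cc = np.mgrid[0:128, 0:128].astype(float)
        mask = (rr - 64) ** 2 + (cc - 64) ** 2 < 50**2
        fld = local_orientation_field(grating(40.0), spacing_px=10.0, mask=mask)
        ang, method = estimate_fiber_axis(mask, field=fld)
        assert method == "field_circular_mean"
        assert abs((ang - 40.0 + 90) % 180 - 90) < 1.0

    def test_axis_invariant_under_180_rotation(self):
        rr, cc = np.mgrid[0:100, 0:100].astype(float)
        mask = (np.abs(cc - 50) < 40) & (np.abs(rr - 50 - 0.3 * (cc - 50)) < 10)
        a1, _ = estimate_fiber_axis(mask)
        a2, _ = estimate_fiber_axis(mask[::-1, ::-1])
        assert abs((a1 - a2 + 90) % 180 - 90) < 1e-6

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_fiber_axis(np.zeros((10, 10), bool))


class TestCosineAngleSum:
    def _field(self, angles, axis_shape=(10, 10)):
        a = np.broadcast_to(np.asarray(angles, float), axis_shape).copy()
        return OrientationField(
            angle_deg=a, energy=np.ones_like(a), valid=np.ones_like(a, bool)
        )

    def test_parallel_field_gives_one(self):
        assert cosine_angle_sum(self._field(37.0), 37.0) == pytest.approx(1.0)

    def test_two_population_60_degrees(self):
        a = np.zeros((10, 10))
        a[:5] = 80.0  # +60 from axis 20
        a[5:] = 140.0  # -60 from axis 20 (mod 180)
        fld = OrientationField(a, np.ones_like(a), np.ones((10, 10), bool))
        assert cosine_angle_sum(fld, 20.0) == pytest.approx(0.5, abs=1e-12)

    def test_ninety_degree_deviation_contributes_zero(self):
        assert cosine_angle_sum(self._field(110.0), 20.0) == pytest.approx(0.0, abs=1e-12)

    def test_no_valid_pixels_rejected(self):
        fld = OrientationField(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4), bool))
        with pytest.raises(ValueError, match="valid"):
            cosine_angle_sum(fld, 0.0)

    def test_matches_bruteforce_on_jittered_scene(self):
        scene = small_fiber_scene(angular_jitter_sd_deg=10.0, shape=(1, 256, 256),
                                  fiber_length_um=40.0, fiber_width_um=22.0)
        stack, truth = generate_striated_fiber(scene, seed=2)
        fm = analyze_fiber_stack(stack)
        oracle = mean_cos_deviation(truth.injected_angle_field_deg, truth.fiber_axis_deg)
        assert abs(fm.cas - oracle) < 0.02


class TestMasking:
    def test_collagen_streaks_excluded_from_analysis(self):
        scene = small_fiber_scene()
        scene = scene_with(scene, collagen_streaks=auto_collagen_streaks(scene, 3, seed=1))
        stack, truth = generate_striated_fiber(scene, seed=0)
        masked, cell = mask_intracellular_shg(stack)
        streaks = truth.collagen_mask[0]
        assert streaks.any()
        assert not np.any(cell[0] & streaks)  # streak pixels never analysed
        assert np.all(masked[0][streaks] == 0.0)

    def test_collagen_free_fiber_identity_on_mask(self, parallel_fiber):
        stack, _ = parallel_fiber
        masked, cell = mask_intracellular_shg(stack)
        assert np.allclose(masked[0][cell[0]], stack.shg_forward[0][cell[0]])

    def test_zero_autofluorescence_rejected(self):
        stack = ImageStack(np.ones((1, 64, 64)), np.zeros((1, 64, 64)), pixel_size_um=0.2)
        with pytest.raises(ValueError, match="all zero"):
            mask_intracellular_shg(stack)


class TestVernierDetection:
    def test_defect_free_lattice_yields_zero(self, parallel_fiber):
        stack, _ = parallel_fiber
        fm = analyze_fiber_stack(stack)
        assert fm.vernier_count == 0
        assert fm.vd_per_100um2 == 0.0

    def test_recall_and_precision_at_snr5(self):
        scene = vernier_scene(12, placement_seed=100, noise_gaussian_sd=SNR5_NOISE_SD)
        stack, truth = generate_striated_fiber(scene, seed=1)
        fm = analyze_fiber_stack(stack)
        detected = list(fm.per_slice[0].vernier_positions_um)
        truth_xy = [(x, y) for _, x, y in truth.vernier_positions]
        tp, fp, fn = match_events(detected, truth_xy, radius_um=2.0)
        assert tp / 12 >= 0.9
        assert tp / max(1, len(detected)) >= 0.9

    def test_events_within_one_spacing_merge(self):
        # two injected events half a spacing apart must count once
        scene = small_fiber_scene()
        base = vernier_scene(1, placement_seed=3)
        (z, x, y) = base.vernier_events[0]
        import math

        th = math.radians(scene.fiber_axis_angle_deg)
        dx, dy = 0.5 * scene.sarcomere_spacing_um * math.cos(th), \
            0.5 * scene.sarcomere_spacing_um * math.sin(th)
        doubled = scene_with(base, vernier_events=((z, x, y), (z, x + dx, y + dy)))
        stack, _ = generate_striated_fiber(doubled, seed=0)
        fm = analyze_fiber_stack(stack)
        assert fm.vernier_count <= 1

    def test_standalone_detection_without_axis(self):
        scene = vernier_scene(6, placement_seed=4)
        stack, truth = generate_striated_fiber(scene, seed=0)
        masked, cell = mask_intracellular_shg(stack)
        events = detect_verniers(masked[0], spacing_px=10.0, mask=cell[0],
                                 pixel_size_um=0.2)
        truth_xy = [(x, y) for _, x, y in truth.vernier_positions]
        tp, _, _ = match_events(events, truth_xy, radius_um=2.0)
        assert tp >= 5


class TestVernierDensity:
    def test_arithmetic(self):
        assert vernier_density(12, 400.0) == pytest.approx(3.0)
        assert vernier_density(0, 400.0) == 0.0

    def test_doubling_area_halves_density(self):
        assert vernier_density(7, 800.0) == pytest.approx(vernier_density(7, 400.0) / 2)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            vernier_density(3, 0.0)


class TestStackAggregation:
    def test_identical_slices_give_slice_cas(self):
        scene = small_fiber_scene(shape=(1, 160, 160), angular_jitter_sd_deg=5.0)
        stack1, _ = generate_striated_fiber(scene, seed=5)
        rep = ImageStack(
            np.repeat(stack1.shg_forward, 5, axis=0),
            np.repeat(stack1.autofluorescence, 5, axis=0),
            pixel_size_um=stack1.pixel_size_um,
        )
        fm1 = analyze_fiber_stack(stack1)
        fm5 = analyze_fiber_stack(rep)
        assert fm5.cas == pytest.approx(fm1.cas, abs=1e-12)
        assert fm5.vernier_count == 5 * fm1.vernier_count
        assert fm5.vd_per_100um2 == pytest.approx(fm1.vd_per_100um2, abs=1e-12)

    def test_pooled_vd_is_ratio_of_sums(self):
        scene = vernier_scene(6, placement_seed=8, noise_gaussian_sd=0.1)
        stack, _ = generate_striated_fiber(scene, seed=2)
        fm = analyze_fiber_stack(stack)
        counts = sum(s.vernier_count for s in fm.per_slice)
        areas = sum(s.analyzed_area_um2 for s in fm.per_slice)
        assert fm.vd_per_100um2 == pytest.approx(100.0 * counts / areas)
        assert fm.vernier_count == counts

    def test_intensity_invariance(self):
        scene = vernier_scene(6, placement_seed=2, angular_jitter_sd_deg=5.0)
        stack, _ = generate_striated_fiber(scene, seed=1)
        fm1 = analyze_fiber_stack(stack)
        scaled = ImageStack(stack.shg_forward * 7.3, stack.autofluorescence * 7.3,
                            pixel_size_um=stack.pixel_size_um)
        fm2 = analyze_fiber_stack(scaled)
        assert fm2.cas == pytest.approx(fm1.cas, rel=1e-6)
        assert fm2.vd_per_100um2 == pytest.approx(fm1.vd_per_100um2, rel=1e-6)

    def test_rotation_changes_axis_not_readouts(self):
        scene = vernier_scene(12, placement_seed=5, shape=(1, 192, 192),
                              fiber_axis_angle_deg=20.0)
        stack, _ = generate_striated_fiber(scene, seed=3)
        fm0 = analyze_fiber_stack(stack)
        for phi in (15.0, 30.0):
            shg = ndimage.rotate(stack.shg_forward[0], phi, reshape=False, order=1)[None]
            af = ndimage.rotate(stack.autofluorescence[0], phi, reshape=False, order=1)[None]
            fm = analyze_fiber_stack(ImageStack(shg, af, pixel_size_um=0.2))
            expected_axis = (20.0 - phi) % 180.0
            assert abs((fm.fiber_axis_deg - expected_axis + 90) % 180 - 90) < 2.0
            assert abs(fm.cas - fm0.cas) <= 0.02
            assert abs(fm.vd_per_100um2 - fm0.vd_per_100um2) <= 0.1 * fm0.vd_per_100um2

    def test_cas_bounded_for_noisy_input(self):
        scene = small_fiber_scene(angular_jitter_sd_deg=25.0, noise_gaussian_sd=0.3)
        stack, _ = generate_striated_fiber(scene, seed=9)
        fm = analyze_fiber_stack(stack)
        assert 0.0 <= fm.cas <= 1.0
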