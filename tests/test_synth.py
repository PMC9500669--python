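"""Generator contracts: determinism, ground-truth consistency, channel scheme."""

import numpy as np
import pytest

from sarcolattice import (
    FiberScene,
    generate_cross_section,
    generate_striated_fiber,
    generate_stress_relaxation,
    generate_twitch_tetanus,
    mean_cos_deviation,
)
from sarcolattice.synth import auto_collagen_streaks, auto_vernier_events

from conftest import scene_with, small_fiber_scene, vernier_scene


class TestStriatedFiber:
    def test_parallel_lattice_truth(self, parallel_fiber):
        _, truth = parallel_fiber
        assert truth.true_cas == 1.0
        assert truth.true_vernier_count == 0

    def test_true_cas_matches_bruteforce_over_angle_field(self):
        scene = small_fiber_scene(angular_jitter_sd_deg=10.0)
        _, truth = generate_striated_fiber(scene, seed=3)
        recomputed = mean_cos_deviation(
            truth.injected_angle_field_deg, truth.fiber_axis_deg
        )
        assert abs(recomputed - truth.true_cas) < 1e-12
        assert 0.0 <= truth.true_cas <= 1.0

    def test_vernier_density_arithmetic(self):
        scene = vernier_scene(12, placement_seed=7)
        _, truth = generate_striated_fiber(scene, seed=0)
        assert truth.true_vernier_count == 12
        vd = 100.0 * truth.true_vernier_count / truth.true_fiber_area_um2
        assert vd == pytest.approx(3.0, abs=0.01)  # 12 events on ~400 um^2

    def test_seed_determinism_bit_identical(self):
        scene = vernier_scene(6, placement_seed=1, angular_jitter_sd_deg=8.0,
                              noise_gaussian_sd=0.2)
        s1, t1 = generate_striated_fiber(scene, seed=11)
        s2, t2 = generate_striated_fiber(scene, seed=11)
        assert np.array_equal(s1.shg_forward, s2.shg_forward)
        assert np.array_equal(s1.autofluorescence, s2.autofluorescence)
        assert t1.true_cas == t2.true_cas
        s3, _ = generate_striated_fiber(scene, seed=12)
        assert not np.array_equal(s1.shg_forward, s3.shg_forward)

    def test_channel_contract_collagen_dark_in_autofluorescence(self):
        scene = small_fiber_scene()
        scene = scene_with(scene, collagen_streaks=auto_collagen_streaks(scene, 3, seed=2))
        stack, truth = generate_striated_fiber(scene, seed=4)
        collagen = truth.collagen_mask[0]
        assert collagen.any()
        assert np.all(stack.autofluorescence[0][collagen] == 0.0)
        # and the streaks do show up in the SHG channel
        assert stack.shg_forward[0][collagen].mean() > 0.5

    def test_bands_confined_to_mask(self, parallel_fiber):
        stack, truth = parallel_fiber
        outside = ~truth.fiber_mask[0]
        assert np.all(stack.shg_forward[0][outside] == 0.0)

    def test_aliased_spacing_rejected(self):
        with pytest.raises(ValueError, match="aliased"):
            FiberScene(sarcomere_spacing_um=0.3, pixel_size_um=0.2)

    def test_degenerate_fiber_mask_rejected(self):
        # sub-pixel fiber width: no pixel center falls inside the region
        scene = small_fiber_scene(fiber_width_um=0.01, fiber_axis_angle_deg=0.0)
        with pytest.raises(ValueError, match="mask"):
            generate_striated_fiber(scene, seed=0)

    def test_vernier_outside_mask_rejected(self):
        scene = small_fiber_scene()
        scene = scene_with(scene, vernier_events=((0, 1.0, 1.0),))
        with pytest.raises(ValueError, match="outside the fiber mask"):
            generate_striated_fiber(scene, seed=0)


class TestCrossSection:
    def test_zero_fraction_is_exactly_zero(self):
        stack, truth = generate_cross_section(0.0, seed=0, shape=(1, 192, 192))
        assert truth.true_collagen_fraction_pct == 0.0
        # every SHG-positive pixel lies inside the muscle mask
        assert np.all(truth.muscle_mask[0][stack.shg_forward[0] > 0.3])

    @pytest.mark.parametrize("requested", [1.0, 5.0, 21.4])
    def test_realized_fraction_within_half_point(self, requested):
        _, truth = generate_cross_section(requested, seed=1, shape=(1, 256, 256))
        assert abs(truth.true_collagen_fraction_pct - requested) <= 0.5

    def test_same_seed_identical_stacks(self):
        s1, _ = generate_cross_section(8.0, seed=5, shape=(1, 192, 192),
                                       noise_gaussian_sd=0.2)
        s2, _ = generate_cross_section(8.0, seed=5, shape=(1, 192, 192),
                                       noise_gaussian_sd=0.2)
        assert np.array_equal(s1.shg_forward, s2.shg_forward)
        assert np.array_equal(s1.autofluorescence, s2.autofluorescence)

    def test_collagen_muscle_disjoint(self):
        _, truth = generate_cross_section(10.0, seed=2, shape=(1, 192, 192))
        assert not np.any(truth.muscle_mask & truth.collagen_mask)

    def test_fraction_at_least_100_rejected(self):
        with pytest.raises(ValueError):
            generate_cross_section(100.0, seed=0)


class TestStressRelaxation:
    def test_noise_free_plateau_closed_form(self):
        trace, truth = generate_stress_relaxation(100.0, 20.0, tau_s=1.0,
                                                  strains=(0.10,), hold_s=10.0, seed=0)
        stress = trace.force_mn / trace.pcsa_cm2 * 0.01
        # sigma_el(0.10) = 100*0.01 + 20*0.10 = 3.0 kPa
        assert stress[-1] == pytest.approx(3.0, abs=3.0 * np.exp(-9.0) + 1e-9)
        assert truth["elastic_stiffness_kpa"] == pytest.approx(40.0)

    def test_noisy_plateau_within_3_se(self):
        trace, truth = generate_stress_relaxation(100.0, 20.0, tau_s=1.0,
                                                  strains=(0.10,), hold_s=10.0,
                                                  noise_sd_kpa=0.05, seed=3)
        stress = trace.force_mn / trace.pcsa_cm2 * 0.01
        hold = trace.time_s >= trace.time_s[-1] - 0.1 * 10.0
        n = int(hold.sum())
        se = 0.05 / np.sqrt(n)
        assert abs(stress[hold].mean() - 3.0) < 3 * se + 3.0 * np.exp(-9.0)

    def test_non_increasing_strains_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            generate_stress_relaxation(100.0, 20.0, 1.0, strains=(0.10, 0.05))

    def test_strains_outside_range_rejected(self):
        with pytest.raises(ValueError):
            generate_stress_relaxation(100.0, 20.0, 1.0, strains=(0.05, 0.30))


class TestTwitchTetanus:
    def test_twitch_peak_exact_at_zero_noise(self):
        twitch, _, _ = generate_twitch_tetanus(5.0, 25.0, seed=0)
        assert twitch.force_mn.max() == pytest.approx(5.0, abs=1e-12)

    def test_tetanus_plateau_with_ripple_bounded(self):
        _, tet, _ = generate_twitch_tetanus(5.0, 25.0, seed=0, ripple_frac=0.01)
        assert 25.0 <= tet.force_mn.max() <= 25.25 + 1e-9

    def test_zero_length_trace_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            generate_twitch_tetanus(5.0, 25.0, twitch_duration_s=0.0)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            generate_twitch_tetanus(-1.0, 25.0)


def test_auto_vernier_events_respect_separation_and_mask():
    scene = small_fiber_scene()
    events = auto_vernier_events(scene, 12, seed=9)
    assert len(events) == 12
    # generating with these events must validate them against the mask
    generate_striated_fiber(scene_with(scene, vernier_events=events), seed=0)
    xy = [(x, y) for _, x, y in events]
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            d = np.hypot(xy[i][0] - xy[j][0], xy[i][1] - xy[j][1])
            assert d >= 2 * scene.sarcomere_spacing_um - 1e-9
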