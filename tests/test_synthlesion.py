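"""Probabilistic lesion formation, simulation determinism, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcet.exposure import build_burst_schedule
from mcet.experiments import DEFAULT_SCHEDULE
from mcet.synthlesion import (
    GeometryError,
    JitterSpec,
    LesionModel,
    MicrolesionSet,
    SectionStack,
    StackSpec,
    TissueSlab,
    lesion_probability,
    render_sections,
    simulate_microlesions,
)


class TestLesionProbability:
    def test_zero_at_or_below_threshold(self):
        model = LesionModel(p_l_mpa=2.0, per_burst_prob_scale=0.5)
        for n in (0, 1, 100):
            assert lesion_probability(2.0, n, model) == 0.0
            assert lesion_probability(0.5, n, model) == 0.0

    def test_cumulative_closed_form(self):
        # chi = 0.2 at 1 MPa above threshold
        model = LesionModel(p_l_mpa=2.0, per_burst_prob_scale=0.2)
        assert lesion_probability(3.0, 1, model) == pytest.approx(0.2)
        assert lesion_probability(3.0, 5, model) == pytest.approx(1.0 - 0.8**5)
        assert lesion_probability(3.0, 5, model) == pytest.approx(0.672, abs=1e-3)

    def test_probability_clamped_to_unity(self):
        model = LesionModel(p_l_mpa=2.0, per_burst_prob_scale=5.0)
        assert lesion_probability(10.0, 3, model) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        p=st.floats(0.0, 6.0),
        dp=st.floats(0.0, 2.0),
        n=st.integers(0, 500),
        dn=st.integers(0, 100),
    )
    def test_monotone_in_pressure_and_bursts(self, p, dp, n, dn):
        model = LesionModel(p_l_mpa=2.0, per_burst_prob_scale=1e-3)
        assert lesion_probability(p + dp, n, model) >= lesion_probability(p, n, model)
        assert lesion_probability(p, n + dn, model) >= lesion_probability(p, n, model)


class TestSimulation:
    def test_zero_bursts_yield_empty_set(self, default_field, default_slab):
        schedule = build_burst_schedule(360.0, 4, 0.0)
        lesions = simulate_microlesions(default_field, schedule, default_slab, LesionModel())
        assert len(lesions) == 0

    def test_seeded_determinism(self, default_field, default_slab):
        model = LesionModel()
        a = simulate_microlesions(default_field, DEFAULT_SCHEDULE, default_slab, model, seed=42)
        b = simulate_microlesions(default_field, DEFAULT_SCHEDULE, default_slab, model, seed=42)
        assert np.array_equal(a.centroids_mm, b.centroids_mm)
        assert np.array_equal(a.volumes_um3, b.volumes_um3)
        assert np.array_equal(a.birth_burst, b.birth_burst)

    def test_focus_outside_slab_is_a_geometry_error(self, default_field):
        slab = TissueSlab(z_min_mm=50.0, z_max_mm=60.0)
        with pytest.raises(GeometryError):
            simulate_microlesions(default_field, DEFAULT_SCHEDULE, slab, LesionModel())

    def test_count_doubles_with_bursts_in_small_chi_regime(self, default_field, default_slab):
        model = LesionModel(per_burst_prob_scale=2e-5)
        short = build_burst_schedule(360.0, 4, 150.0)
        full = build_burst_schedule(360.0, 4, 300.0)
        n1 = len(
            simulate_microlesions(default_field, short, default_slab, model, seed=1)
        )
        n2 = len(
            simulate_microlesions(default_field, full, default_slab, model, seed=2)
        )
        # Poisson counts: doubling bursts doubles the expectation
        sigma = np.sqrt(4 * n1 + n2)
        assert abs(n2 - 2 * n1) < 3 * sigma

    def test_lesion_density_increases_with_pressure(self, pressure_cohorts):
        mean_density = {}
        for peak, animals in pressure_cohorts.items():
            dens = [a.macro.lesion_density_pct for a in animals if a.macro is not None]
            mean_density[peak] = np.mean(dens) if dens else 0.0
        assert mean_density[2.0] < mean_density[2.8] < mean_density[4.0]

    def test_lesions_lie_inside_slab(self, pressure_cohorts, default_slab):
        for animals in pressure_cohorts.values():
            for a in animals:
                if len(a.lesions):
                    assert default_slab.contains(a.lesions.centroids_mm).all()

    def test_infusion_window_limits_accumulation(self, default_field, default_slab):
        model = LesionModel()
        gated = simulate_microlesions(
            default_field,
            DEFAULT_SCHEDULE,
            default_slab,
            model,
            seed=3,
            infusion_window_s=(0.0, 30.0),
        )
        full = simulate_microlesions(
            default_field, DEFAULT_SCHEDULE, default_slab, model, seed=3
        )
        assert len(gated) < len(full)


class TestRendering:
    def test_empty_cloud_renders_blank_images(self, default_slab):
        empty = MicrolesionSet(np.empty((0, 3)), np.empty(0))
        stack = render_sections(empty, default_slab, StackSpec(n_sections=5))
        assert stack.images.sum() == 0

    def test_zero_jitter_offsets_are_identity(self, contiguous_stack):
        for off in contiguous_stack.true_offsets:
            assert off.angle_deg == 0.0
            assert off.row_px == 0.0 and off.col_px == 0.0

    def test_volume_conservation_through_contiguous_sections(
        self, band_lesions, contiguous_stack
    ):
        spec_px = contiguous_stack.pixel_size_um
        rendered = (
            contiguous_stack.images.sum() * spec_px**2 * contiguous_stack.section_thickness_um
        )
        assert rendered == pytest.approx(band_lesions.total_volume_um3, rel=0.10)

    def test_coarse_pixels_warn_and_paint_single_pixels(self, default_slab):
        lesions = MicrolesionSet(np.array([[0.0, 0.0, 30.0]]), np.array([500.0]))
        # first section mid-plane crosses the lesion centre
        spec = StackSpec(
            n_sections=3, pixel_size_um=50.0, image_shape=(64, 64), z_start_mm=29.995
        )
        with pytest.warns(UserWarning, match="single pixels"):
            stack = render_sections(lesions, default_slab, spec)
        assert stack.images.sum() >= 1

    def test_rendered_determinism_with_jitter(self, band_lesions, default_slab):
        spec = StackSpec(n_sections=8, pixel_size_um=10.0, image_shape=(128, 128), z_start_mm=30.0)
        jit = JitterSpec(5.0, 2.0)
        a = render_sections(band_lesions, default_slab, spec, jit, seed=9)
        b = render_sections(band_lesions, default_slab, spec, jit, seed=9)
        assert np.array_equal(a.images, b.images)
        assert a.true_offsets == b.true_offsets

    def test_stack_save_load_round_trip(self, contiguous_stack, tmp_path):
        contiguous_stack.save(tmp_path / "stack")
        loaded = SectionStack.load(tmp_path / "stack")
        assert np.array_equal(loaded.images, contiguous_stack.images)
        assert loaded.pixel_size_um == contiguous_stack.pixel_size_um

    def test_lesion_table_round_trip(self, band_lesions, tmp_path):
        path = tmp_path / "lesions.csv"
        band_lesions.to_csv(path)
        loaded = MicrolesionSet.from_csv(path)
        assert np.allclose(loaded.centroids_mm, band_lesions.centroids_mm)
        assert np.allclose(loaded.volumes_um3, band_lesions.volumes_um3)
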