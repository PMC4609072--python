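"""Scoring pipeline: segmentation, registration, reconstruction, reslicing."""

import numpy as np
import pytest

from mcet.histo import (
    AxisUndefinedError,
    BeamAxisFit,
    Disk,
    DiskStack,
    NoMacrolesionError,
    _containment_radius,
    fit_beam_axis,
    macrolesion_metrics,
    reconstruct_cloud,
    register_stack,
    reslice_disks,
    segment_sections,
)
from mcet.synthlesion import MicrolesionSet, SectionStack


def make_stack(images, px_um=5.0, thickness=10.0, spacing=10.0):
    return SectionStack(np.asarray(images, np.uint8), thickness, spacing, px_um)


def offset_errors(stack, recovered):
    """Angle and translation errors of recovered offsets vs ground truth,
    measured relative to the first section (the registration reference)."""
    shape = stack.image_shape
    ref = stack.true_offsets[0].inverse(shape)
    angle_err, trans_err = [], []
    for truth, rec in zip(stack.true_offsets, recovered):
        rel = truth.compose(ref, shape)
        angle_err.append(abs(rec.angle_deg - rel.angle_deg))
        trans_err.append(np.hypot(rec.row_px - rel.row_px, rec.col_px - rel.col_px))
    return max(angle_err), max(trans_err)


class TestSegmentation:
    def test_blank_section_yields_empty_list(self):
        stack = make_stack(np.zeros((1, 32, 32)))
        assert segment_sections(stack) == [[]]

    def test_square_component_geometry(self):
        img = np.zeros((64, 64), np.uint8)
        img[10:20, 30:40] = 1  # 10 x 10 px at 5 um/px
        stack = make_stack(img[None])
        [[lesion]] = segment_sections(stack)
        assert lesion.area_um2 == pytest.approx(2500.0)
        # square centre at (row 14.5, col 34.5); origin at image centre (31.5, 31.5)
        assert lesion.centroid_um[0] == pytest.approx((34.5 - 31.5) * 5.0)
        assert lesion.centroid_um[1] == pytest.approx((14.5 - 31.5) * 5.0)

    def test_min_area_filter_and_component_count(self):
        rng = np.random.default_rng(0)
        img = np.zeros((128, 128), np.uint8)
        # 9 well-separated 3x3 blobs plus one single pixel
        for i in range(3):
            for j in range(3):
                r, c = 20 + 30 * i, 20 + 30 * j
                img[r : r + 3, c : c + 3] = 1
        img[5, 100] = 1
        stack = make_stack(img[None])
        [components] = segment_sections(stack)
        assert len(components) == 10
        [filtered] = segment_sections(stack, min_area_um2=9 * 25.0)
        assert len(filtered) == 9

    def test_grayscale_requires_threshold(self):
        img = np.full((16, 16), 0.5)
        stack = SectionStack(img[None], 10.0, 10.0, 5.0)
        with pytest.raises(ValueError, match="threshold"):
            segment_sections(stack)


class TestRegistration:
    def test_zero_jitter_recovers_identity(self, contiguous_stack):
        _, recovered = register_stack(contiguous_stack)
        angle_err, trans_err = offset_errors(contiguous_stack, recovered)
        assert angle_err <= 0.5
        assert trans_err <= 1.0

    def test_known_jitter_recovered(self, jittered_stack):
        _, recovered = register_stack(jittered_stack)
        angle_err, trans_err = offset_errors(jittered_stack, recovered)
        assert angle_err <= 1.0
        assert trans_err <= 2.0

    def test_global_shift_equivariance(self, jittered_stack):
        # shifting every section by the same constant leaves the recovered
        # relative offsets unchanged
        shifted = SectionStack(
            np.roll(jittered_stack.images, (4, -6), axis=(1, 2)),
            jittered_stack.section_thickness_um,
            jittered_stack.section_spacing_um,
            jittered_stack.pixel_size_um,
            jittered_stack.z_start_mm,
            jittered_stack.true_offsets,
        )
        _, rec_a = register_stack(jittered_stack)
        _, rec_b = register_stack(shifted)
        for a, b in zip(rec_a, rec_b):
            assert abs(a.angle_deg - b.angle_deg) <= 0.5
            assert np.hypot(a.row_px - b.row_px, a.col_px - b.col_px) <= 1.0

    def test_blank_section_passes_through_with_warning(self):
        rng = np.random.default_rng(1)
        base = (rng.random((32, 32)) > 0.7).astype(np.uint8)
        images = np.stack([base, np.zeros_like(base), base])
        stack = make_stack(images)
        with pytest.warns(UserWarning, match="blank"):
            aligned, recovered = register_stack(stack)
        assert recovered[1].angle_deg == 0.0

    def test_fewer_than_two_content_sections_rejected(self):
        images = np.zeros((3, 16, 16), np.uint8)
        images[0, 8, 8] = 1
        with pytest.raises(ValueError, match="two non-empty"):
            register_stack(make_stack(images))


class TestReconstruction:
    def test_single_blob_single_section(self):
        img = np.zeros((32, 32), np.uint8)
        img[10:14, 10:14] = 1
        cloud = reconstruct_cloud(make_stack(img[None]))
        assert len(cloud) == 1
        assert cloud.volumes_um3[0] == pytest.approx(16 * 25.0 * 10.0)

    def test_blob_spanning_three_sections_merges(self):
        images = np.zeros((4, 32, 32), np.uint8)
        for k in (0, 1, 2):
            images[k, 14 + k : 19 + k, 14:19] = 1  # overlapping in-plane
        cloud = reconstruct_cloud(make_stack(images))
        assert len(cloud) == 1
        assert cloud.volumes_um3[0] == pytest.approx(3 * 25 * 25.0 * 10.0)

    def test_round_trip_volume_conservation(self, band_lesions, jittered_stack):
        aligned, _ = register_stack(jittered_stack)
        cloud = reconstruct_cloud(aligned)
        assert cloud.total_volume_um3 == pytest.approx(
            band_lesions.total_volume_um3, rel=0.10
        )

    def test_missing_spacing_metadata(self):
        stack = SectionStack(np.zeros((2, 8, 8), np.uint8), 10.0, 0.0, 5.0)
        with pytest.raises(ValueError, match="spacing"):
            reconstruct_cloud(stack)


class TestBeamAxis:
    def test_collinear_lesions_recover_exact_line(self):
        t = np.linspace(-3, 3, 20)
        d = np.array([0.2, -0.1, 1.0])
        d = d / np.linalg.norm(d)
        pts = np.array([1.0, 2.0, 30.0]) + t[:, None] * d
        fit = fit_beam_axis(MicrolesionSet(pts, np.full(20, 1e5)))
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)
        assert fit.angle_to(d) == pytest.approx(0.0, abs=1e-6)

    def test_too_few_lesions(self):
        with pytest.raises(AxisUndefinedError):
            fit_beam_axis(MicrolesionSet(np.zeros((2, 3)), np.ones(2)))

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(50, 3)) * np.array([0.3, 0.3, 3.0])
        vols = rng.lognormal(11, 0.4, 50)
        theta = 0.4
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        fit_a = fit_beam_axis(MicrolesionSet(pts, vols))
        fit_b = fit_beam_axis(MicrolesionSet(pts @ rot.T, vols))
        assert fit_b.angle_to(rot @ fit_a.direction) == pytest.approx(0.0, abs=1e-6)
        assert fit_b.rms_residual == pytest.approx(fit_a.rms_residual, rel=1e-9)

    def test_truth_axis_recovery_on_simulated_cohort(self, pressure_cohorts):
        for animal in pressure_cohorts[4.0]:
            fit = fit_beam_axis(animal.lesions)
            assert fit.angle_to(animal.lesions.truth_axis[1]) <= 3.0


class TestResliceDisks:
    def test_uniform_disk_containment_radius(self):
        rng = np.random.default_rng(2)
        n = 40_000
        radius = np.sqrt(rng.uniform(0, 1, n)) * 2.0  # area-uniform in a disk of R=2
        phi = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack(
            [radius * np.cos(phi), radius * np.sin(phi), np.full(n, 30.0)]
        )
        axis = BeamAxisFit(np.array([0.0, 0.0, 30.0]), np.array([0.0, 0.0, 1.0]), 0.0)
        disks = reslice_disks(
            MicrolesionSet(pts, np.ones(n)), axis, disk_thickness_mm=1.0, weighting="count"
        )
        assert len(disks) == 1
        assert disks.disks[0].radius_95_mm == pytest.approx(2.0 * np.sqrt(0.95), rel=0.01)

    def test_containment_matches_brute_force_percentile(self):
        rng = np.random.default_rng(3)
        radii = rng.uniform(0, 3, 101)
        weights = rng.uniform(0.1, 5.0, 101)
        r95 = _containment_radius(radii, weights, 0.95)
        order = np.argsort(radii)
        cum = np.cumsum(weights[order])
        expected = radii[order][np.searchsorted(cum, 0.95 * cum[-1])]
        assert r95 == expected

    def test_sparse_bins_are_omitted(self):
        pts = np.array(
            [[0, 0, 30.1], [0.1, 0, 30.2], [0, 0.1, 30.3], [0, 0, 35.0]]
        )
        axis = BeamAxisFit(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0)
        disks = reslice_disks(
            MicrolesionSet(pts, np.ones(4)), axis, disk_thickness_mm=0.5, min_count=3
        )
        assert len(disks) == 1  # the lone distal lesion's bin is dropped

    def test_empty_cloud_gives_empty_stack(self):
        axis = BeamAxisFit(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0)
        disks = reslice_disks(MicrolesionSet(np.empty((0, 3)), np.empty(0)), axis)
        assert len(disks) == 0
        with pytest.raises(NoMacrolesionError):
            macrolesion_metrics(disks, MicrolesionSet(np.empty((0, 3)), np.empty(0)))


class TestMacrolesion:
    @staticmethod
    def _axis():
        return BeamAxisFit(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0)

    def test_single_disk_cylinder_volume(self):
        disks = DiskStack((Disk(0.5, 1.0, 5, 0.1),), 1.0, self._axis())
        macro = macrolesion_metrics(disks, MicrolesionSet(np.empty((0, 3)), np.empty(0)))
        assert macro.volume_ul == pytest.approx(np.pi)
        assert macro.length_mm == pytest.approx(1.0)

    def test_clinical_target_cylinder_in_ml(self):
        # 4-cm diameter x 21-mm long cylinder assembled from 1-mm disks
        disks = DiskStack(
            tuple(Disk(z + 0.5, 20.0, 10, 0.0) for z in range(21)), 1.0, self._axis()
        )
        macro = macrolesion_metrics(disks, MicrolesionSet(np.empty((0, 3)), np.empty(0)))
        assert macro.volume_ul / 1000.0 == pytest.approx(26.4, abs=0.05)
        assert macro.length_mm == pytest.approx(21.0)

    def test_auto_score_linear_in_lesion_volume(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(60, 3)) * np.array([0.3, 0.3, 2.0]) + np.array([0, 0, 30.0])
        vols = rng.lognormal(12, 0.3, 60)
        axis = fit_beam_axis(MicrolesionSet(pts, vols))
        disks = reslice_disks(MicrolesionSet(pts, vols), axis, 1.0)
        m1 = macrolesion_metrics(disks, MicrolesionSet(pts, vols))
        disks2 = reslice_disks(MicrolesionSet(pts, 2 * vols), axis, 1.0)
        m2 = macrolesion_metrics(disks2, MicrolesionSet(pts, 2 * vols))
        assert m2.microlesion_volume_ul == pytest.approx(2 * m1.microlesion_volume_ul)
        assert m2.auto_score == pytest.approx(2 * m1.auto_score, rel=1e-4)

    def test_metrics_invariant_under_rigid_motion(self, pressure_cohorts):
        animal = pressure_cohorts[4.0][0]
        lesions = animal.lesions
        theta = 0.3
        rot = np.array(
            [
                [1, 0, 0],
                [0, np.cos(theta), -np.sin(theta)],
                [0, np.sin(theta), np.cos(theta)],
            ]
        )
        moved = MicrolesionSet(
            lesions.centroids_mm @ rot.T + np.array([2.0, -1.0, 3.0]), lesions.volumes_um3
        )
        axis_a = fit_beam_axis(lesions)
        axis_b = fit_beam_axis(moved)
        macro_a = macrolesion_metrics(reslice_disks(lesions, axis_a), lesions)
        macro_b = macrolesion_metrics(reslice_disks(moved, axis_b), moved)
        assert macro_b.volume_ul == pytest.approx(macro_a.volume_ul, rel=1e-6)
        assert macro_b.length_mm == pytest.approx(macro_a.length_mm, rel=1e-6)
        assert macro_b.mean_radius_mm == pytest.approx(macro_a.mean_radius_mm, rel=1e-6)
        assert macro_b.lesion_density_pct == pytest.approx(
            macro_a.lesion_density_pct, rel=1e-6
        )

    def test_density_round_trip_at_twenty_percent(
        self, default_field, default_slab
    ):
        from mcet.experiments import DEFAULT_SCHEDULE, score_lesions
        from mcet.synthlesion import calibrate_scale_to_density, simulate_microlesions

        model = calibrate_scale_to_density(default_field, default_slab, target_density_pct=20.0)
        rng = np.random.default_rng(7)
        densities = []
        for _ in range(5):
            lesions = simulate_microlesions(
                default_field, DEFAULT_SCHEDULE, default_slab, model, seed=rng
            )
            _, macro = score_lesions(lesions, model)
            densities.append(macro.lesion_density_pct)
        assert np.mean(densities) == pytest.approx(20.0, abs=3.0)
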