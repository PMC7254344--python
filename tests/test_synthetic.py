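"""Tests of the synthetic-data generator against analytic ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spionquant.synthetic import (
    GrowthSeriesSpec,
    TimePointSpec,
    assemble_tomogram,
    generate_growth_series,
    make_particle_mask,
    rotation_matrix,
    sample_orientations,
    simulate_sphere_saxs,
)
from spionquant.types import ParticleShapeParams

from conftest import SPHERE_VOLUME


class TestMakeParticleMask:
    def test_sphere_volume_within_one_percent(self, sphere_particle):
        assert sphere_particle.voxel_volume_nm3 == pytest.approx(SPHERE_VOLUME, rel=0.01)

    def test_ellipsoid_ground_truth_calipers(self):
        _, truth = make_particle_mask(ParticleShapeParams(semi_axes=(10, 10, 5)), 0.5)
        assert truth["calipers"] == (20, 20, 10)
        assert truth["volume"] == pytest.approx(4 / 3 * np.pi * 10 * 10 * 5)

    def test_perturbed_sphere_regression(self):
        """10% radial perturbation changes the volume by <10%; the exact
        voxel count is pinned by the seed (generator regression)."""
        params = ParticleShapeParams(semi_axes=(10, 10, 10),
                                     perturbation_amplitude=0.1, perturbation_seed=7)
        particle, truth = make_particle_mask(params, 0.5)
        assert particle.voxel_volume_nm3 == pytest.approx(SPHERE_VOLUME, rel=0.10)
        assert particle.voxel_count == 33582  # frozen: same seed must reproduce
        assert truth["volume"] == pytest.approx(particle.voxel_volume_nm3, rel=0.01)

    def test_particle_exceeds_box_rejected_with_hint(self):
        with pytest.raises(ValueError, match="box_edge"):
            make_particle_mask(ParticleShapeParams(semi_axes=(10, 10, 10)), 0.5, box_edge=20)

    def test_voxelization_converges_with_resolution(self):
        """Mask volume converges to 4/3 pi a b c as voxels shrink."""
        params = ParticleShapeParams(semi_axes=(10, 8, 6), euler_angles=(20, 70, 10))
        target = 4 / 3 * np.pi * 10 * 8 * 6
        errors = []
        for vx in (1.0, 0.5, 0.25):
            particle, _ = make_particle_mask(params, vx)
            errors.append(abs(particle.voxel_volume_nm3 - target))
        assert errors[0] > errors[1] > errors[2]

    def test_invalid_semi_axes_rejected(self):
        with pytest.raises(ValueError):
            ParticleShapeParams(semi_axes=(5, 10, 5))
        with pytest.raises(ValueError):
            ParticleShapeParams(semi_axes=(10, 10, 10), perturbation_amplitude=1.0)


class TestRotationMatrix:
    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 179.9), st.floats(0, 179.9), st.floats(0, 359.9))
    def test_orthonormal(self, az, po, ro):
        rot = rotation_matrix(az, po, ro)
        assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_long_axis_polar_angle(self):
        rot = rotation_matrix(90.0, 69.0, 0.0)
        assert np.degrees(np.arccos(rot[2, 0])) == pytest.approx(69.0)


class TestAssembleTomogram:
    def test_noiseless_roundtrip_recovers_mask(self, sphere_particle):
        shape = (50, 50, 50)
        tomo = assemble_tomogram([(sphere_particle, (25, 25, 25))], shape, 0.5)
        recovered = tomo.data < (1.0 - 0.3)  # midpoint of background/particle levels
        m = sphere_particle.mask
        sl = tuple(slice(25 - s // 2, 25 - s // 2 + s) for s in m.shape)
        assert np.array_equal(recovered[sl], m)
        assert recovered.sum() == m.sum()

    def test_elongation_factor_stretches_z(self):
        particle, _ = make_particle_mask(ParticleShapeParams(semi_axes=(8, 8, 8)), 0.5)
        tomo = assemble_tomogram([(particle, (30, 30, 30))], (60, 60, 60), 0.5,
                                 missing_wedge_elongation=1.2)
        mask = tomo.data < 0.7
        zext = np.ptp(np.flatnonzero(mask.any(axis=(1, 2)))) + 1
        xext = np.ptp(np.flatnonzero(mask.any(axis=(0, 1)))) + 1
        assert zext / xext == pytest.approx(1.2, abs=0.06)

    def test_overlapping_particles_reported(self, sphere_particle):
        with pytest.warns(UserWarning, match="overlapping"):
            assemble_tomogram([(sphere_particle, (30, 30, 30)),
                               (sphere_particle, (30, 30, 40))], (60, 60, 70), 0.5)

    def test_out_of_grid_placement_rejected(self, sphere_particle):
        with pytest.raises(ValueError, match="outside"):
            assemble_tomogram([(sphere_particle, (5, 30, 30))], (60, 60, 60), 0.5)


class TestSampleOrientations:
    def test_zero_spread_is_degenerate(self):
        oris = sample_orientations(200, theta_peaks=(69, 111), theta_spread=0.0, seed=0)
        assert set(round(o.theta, 6) for o in oris) == {69.0, 111.0}

    def test_large_sample_modes_near_peaks(self):
        oris = sample_orientations(10_000, theta_peaks=(69, 111), theta_spread=8.0, seed=42)
        thetas = np.array([o.theta for o in oris])
        hist, edges = np.histogram(thetas, bins=np.arange(0, 181, 1.0))
        centers = 0.5 * (edges[:-1] + edges[1:])
        low = centers < 90
        mode_low = centers[low][np.argmax(hist[low])]
        mode_high = centers[~low][np.argmax(hist[~low])]
        assert abs(mode_low - 69) <= 2
        assert abs(mode_high - 111) <= 2

    def test_symmetric_about_ninety(self):
        """With peaks (90-x, 90+x) the theta distribution is symmetric."""
        oris = sample_orientations(20_000, theta_peaks=(70, 110), theta_spread=6.0, seed=3)
        thetas = np.array([o.theta for o in oris])
        assert thetas.mean() == pytest.approx(90.0, abs=0.5)
        assert np.mean(thetas < 90) == pytest.approx(0.5, abs=0.02)

    def test_seeding_contract(self):
        a = sample_orientations(1, seed=7)
        b = sample_orientations(1, seed=7)
        assert a == b

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            sample_orientations(0)


class TestSphereSAXS:
    def test_low_q_limit_is_one(self):
        curve = simulate_sphere_saxs(10.0, np.array([1e-8, 1e-6, 1e-5]))
        assert np.allclose(curve.intensity, 1.0, atol=1e-9)

    def test_noiseless_determinism(self):
        q = np.linspace(0.01, 2, 100)
        a = simulate_sphere_saxs(10.0, q)
        b = simulate_sphere_saxs(10.0, q)
        assert np.array_equal(a.intensity, b.intensity)

    def test_noise_has_unit_mean(self):
        q = np.linspace(0.001, 0.002, 5000)  # flat region: F ~ 1
        curve = simulate_sphere_saxs(10.0, q, noise_sd=0.05, seed=0)
        assert curve.intensity.mean() == pytest.approx(1.0, rel=0.01)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_sphere_saxs(10.0, np.array([]))


def _small_spec(n, cv, mean=500.0, psi=0.95, amp=0.0):
    return GrowthSeriesSpec(time_points=(
        TimePointSpec("t0", mean, cv, psi, n, (69, 111), 8.0, amp),))


class TestGrowthSeries:
    def test_volume_cv_recovered_at_table_sample_size(self):
        """Lognormal draws at n=149 reproduce the 65.2% onset dispersity
        within 10%."""
        data = generate_growth_series(_small_spec(149, 0.652), seed=11)[0]
        v = data.truth["volume"].to_numpy()
        cv = v.std(ddof=1) / v.mean()
        assert cv == pytest.approx(0.652, rel=0.10)

    def test_zero_cv_gives_equal_volumes(self):
        data = generate_growth_series(_small_spec(5, 0.0), seed=1)[0]
        assert data.truth["volume"].nunique() == 1
        assert data.truth["volume"].iloc[0] == pytest.approx(500.0, rel=1e-6)

    def test_seeding_contract(self):
        a = generate_growth_series(_small_spec(6, 0.3), seed=5)[0]
        b = generate_growth_series(_small_spec(6, 0.3), seed=5)[0]
        assert a.truth.equals(b.truth)

    def test_default_sphericity_schedule_decreases(self):
        spec = GrowthSeriesSpec.default()
        targets = [tp.mean_sphericity for tp in spec.time_points]
        assert all(a > b for a, b in zip(targets, targets[1:]))
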