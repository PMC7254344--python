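"""Shape descriptors: closed forms, rotation invariance, brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spionquant.shape_metrics import (
    anisotropy,
    equivalent_radius_2d,
    equivalent_radius_3d,
    max_caliper_search,
    max_pairwise_distance,
    radius_of_gyration_voxels,
    sphericity,
)
from spionquant.synthetic import make_particle_mask, shape_ground_truth
from spionquant.types import BinaryParticle, CaliperTriplet, ParticleShapeParams

from conftest import SPHERE_SURFACE, SPHERE_VOLUME


class TestSphericity:
    def test_sphere_is_exactly_one(self):
        assert sphericity(SPHERE_VOLUME, SPHERE_SURFACE) == pytest.approx(1.0, abs=1e-12)

    def test_cube_closed_form(self):
        a = 7.3
        assert sphericity(a**3, 6 * a**2) == pytest.approx((36 * np.pi) ** (1 / 3) / 6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 1.0)

    def test_decreases_with_flattening(self):
        """Psi falls monotonically as an oblate spheroid departs from a
        sphere (c/a in {1, 0.8, 0.6, 0.4})."""
        psis = [shape_ground_truth(ParticleShapeParams(semi_axes=(10, 10, 10 * r)))["sphericity"]
                for r in (1.0, 0.8, 0.6, 0.4)]
        assert all(a > b for a, b in zip(psis, psis[1:]))
        assert psis[0] == pytest.approx(1.0, abs=1e-3)


class TestAnisotropy:
    def test_equal_calipers_zero(self):
        assert anisotropy(CaliperTriplet(10, 10, 10)) == 0.0

    def test_two_two_one(self):
        assert anisotropy(CaliperTriplet(2, 2, 1)) == pytest.approx(1 / 3)

    def test_needle_limit(self):
        assert anisotropy(CaliperTriplet(1, 1e-9, 1e-9)) == pytest.approx(1.0, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.1, 100),
           st.floats(0.01, 1000))
    def test_scale_invariance(self, lx, ly, lz, k):
        a = anisotropy(CaliperTriplet(lx, ly, lz))
        b = anisotropy(CaliperTriplet(k * lx, k * ly, k * lz))
        assert a == pytest.approx(b, rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            CaliperTriplet(1, 1, 0)


class TestCaliperSearch:
    def test_axis_aligned_ellipsoid(self, oblate_particle):
        triplet, _ = max_caliper_search(oblate_particle, angular_step=2.0)
        vx = oblate_particle.voxel_size
        assert triplet.lambda_x == pytest.approx(20, abs=2 * vx)
        assert triplet.lambda_y == pytest.approx(20, abs=2 * vx)
        assert triplet.lambda_z == pytest.approx(10, abs=2 * vx)

    def test_rotation_invariance(self, oblate_particle):
        rotated, _ = make_particle_mask(
            ParticleShapeParams(semi_axes=(10, 10, 5), euler_angles=(0, 60, 0)), 0.5)
        t0, _ = max_caliper_search(oblate_particle, angular_step=2.0)
        t1, _ = max_caliper_search(rotated, angular_step=2.0)
        assert t1.lambda_x == pytest.approx(t0.lambda_x, rel=0.02)
        assert t1.lambda_y == pytest.approx(t0.lambda_y, rel=0.02)
        assert t1.lambda_z == pytest.approx(t0.lambda_z, rel=0.02)

    def test_ordering_invariant(self):
        particle, _ = make_particle_mask(
            ParticleShapeParams(semi_axes=(12, 8, 5), euler_angles=(30, 75, 50)), 0.5)
        triplet, _ = max_caliper_search(particle, angular_step=2.0)
        assert triplet.lambda_x >= triplet.lambda_y >= triplet.lambda_z

    def test_against_pairwise_distance_oracle(self):
        """lambda_x agrees with the brute-force max pairwise surface-voxel
        distance within 2 voxels on random perturbed particles."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            axes = np.sort(rng.uniform(4, 10, 3))[::-1]
            params = ParticleShapeParams(
                semi_axes=tuple(axes),
                euler_angles=tuple(rng.uniform(0, 180, 3)),
                perturbation_amplitude=rng.uniform(0, 0.2),
                perturbation_seed=int(rng.integers(1000)))
            particle, _ = make_particle_mask(params, 0.5)
            triplet, _ = max_caliper_search(particle, angular_step=2.0)
            oracle = max_pairwise_distance(particle)
            assert abs(triplet.lambda_x - oracle) <= 2 * particle.voxel_size

    def test_recovers_long_axis_tilt(self):
        """A particle whose long axis is placed 21 degrees out of the
        support plane is measured at theta near 69 or 111 degrees."""
        params = ParticleShapeParams(semi_axes=(12, 8, 5), euler_angles=(90, 69, 90))
        particle, _ = make_particle_mask(params, 0.5)
        _, orientation = max_caliper_search(particle, angular_step=1.0)
        assert min(abs(orientation.theta - 69), abs(orientation.theta - 111)) <= 3

    def test_empty_mask_rejected(self):
        empty = BinaryParticle(mask=np.zeros((4, 4, 4), bool), voxel_size=1.0)
        with pytest.raises(ValueError):
            max_caliper_search(empty)


class TestEquivalentRadii:
    def test_sphere_2d_projection(self, sphere_particle):
        r2d, v_model = equivalent_radius_2d(sphere_particle)
        assert r2d == pytest.approx(10.0, rel=0.02)
        assert v_model == pytest.approx(SPHERE_VOLUME, rel=0.05)

    def test_flat_oblate_overestimates(self, oblate_particle):
        """An oblate lying flat projects its full equatorial disc: the
        spherical model then doubles the true volume."""
        r2d, v_model = equivalent_radius_2d(oblate_particle)
        true_volume = 4 / 3 * np.pi * 10 * 10 * 5
        assert r2d == pytest.approx(10.0, rel=0.02)
        assert v_model == pytest.approx(2 * true_volume, rel=0.06)

    def test_3d_closed_forms(self):
        assert equivalent_radius_3d(SPHERE_VOLUME) == pytest.approx(10.0)
        assert equivalent_radius_3d(1.0) == pytest.approx(0.6204, abs=1e-4)
        assert equivalent_radius_3d(33510.3) == pytest.approx(20.0, rel=1e-4)
        with pytest.raises(ValueError):
            equivalent_radius_3d(0.0)

    def test_projection_bias_monotone_in_tilt(self):
        """With the short axis resting in the support plane, the 2D
        model-based volume falls monotonically as the long axis tilts out
        of the plane (the full tilt-sweep bias study lives in the
        end-to-end suite)."""
        ratios = []
        for tilt in (0.0, 10.0, 20.0, 30.0):
            params = ParticleShapeParams(semi_axes=(10, 8, 4),
                                         euler_angles=(0, 90 - tilt, 90))
            particle, truth = make_particle_mask(params, 0.5)
            _, v_model = equivalent_radius_2d(particle)
            ratios.append(v_model / truth["volume"])
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestRadiusOfGyration:
    def test_sphere_closed_form(self):
        particle, _ = make_particle_mask(ParticleShapeParams(semi_axes=(10, 10, 10)), 0.25)
        assert radius_of_gyration_voxels(particle) == pytest.approx(
            np.sqrt(3 / 5) * 10, rel=0.01)

    def test_ellipsoid_closed_form(self):
        particle, _ = make_particle_mask(
            ParticleShapeParams(semi_axes=(10, 8, 6), euler_angles=(15, 80, 40)), 0.25)
        assert radius_of_gyration_voxels(particle) == pytest.approx(
            np.sqrt((100 + 64 + 36) / 5), rel=0.01)

    def test_single_voxel_is_point_mass(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        particle = BinaryParticle(mask=mask, voxel_size=0.5)
        assert radius_of_gyration_voxels(particle) == 0.0
        assert radius_of_gyration_voxels(particle, include_voxel_term=True) == pytest.approx(
            0.25, abs=1e-12)
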