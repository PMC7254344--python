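"""Model-free shape descriptors: sphericity, orthogonal maximum calipers,
anisotropy, equivalent spherical radii and the voxel radius of gyration.

Sphericity: Psi = (36 pi V^2)^(1/3) / A, equal to 1 for a sphere and < 1
otherwise. Anisotropy is the fractional-anisotropy-style spread of the three
orthogonal maximum calipers,

    sqrt( ((lx-ly)^2 + (ly-lz)^2 + (lz-lx)^2) / 2 ) / sqrt(lx^2 + ly^2 + lz^2),

0 for an isotropic body and approaching 1 as two calipers vanish.

The caliper search follows a brute-force rotation scan: the longest caliper
lambda_x is found by scanning rotations about the x axis and measuring the
in-plane Feret of the projected particle at each angle; after aligning
lambda_x, the transverse maximum lambda_y is found by scanning rotations
about the aligned long axis, and lambda_z is the transverse extent a further
90 degrees around it, guaranteeing lambda_x >= lambda_y >= lambda_z for an
exhaustive scan. Rotations act on the foreground voxel coordinate cloud
(its convex hull, which carries all caliper information), not on resampled
images, avoiding interpolation artifacts.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .types import BinaryParticle, CaliperTriplet, ParticleOrientation, ShapeDescriptors

__all__ = [
    "sphericity",
    "anisotropy",
    "max_caliper_search",
    "equivalent_radius_2d",
    "equivalent_radius_3d",
    "radius_of_gyration_voxels",
    "max_pairwise_distance",
    "describe_particle",
]


def sphericity(volume: float, surface_area: float) -> float:
    """Psi = (36 pi V^2)^(1/3) / A. Values slightly above 1 can occur when
    the surface estimate is low; they are returned as-is (flagging is the
    caller's business)."""
    if volume <= 0 or surface_area <= 0:
        raise ValueError("volume and surface area must be positive")
    return float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / surface_area)


def anisotropy(triplet: CaliperTriplet) -> float:
    """Normalised spread of the three orthogonal calipers; 0 iff all equal."""
    lam = triplet.as_array()
    num = ((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2 + (lam[2] - lam[0]) ** 2) / 2.0
    return float(np.sqrt(num) / np.sqrt((lam**2).sum()))


def equivalent_radius_3d(volume: float) -> float:
    """Radius of the sphere with the same volume (model-free route)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def equivalent_radius_2d(particle: BinaryParticle) -> tuple[float, float]:
    """Model-based sizing from the 2D profile: project the mask along z
    (the support normal), take r = sqrt(projected area / pi) and return
    (r, model-based volume 4/3 pi r^3). This is the conventional-TEM route,
    which assumes a spherical particle."""
    if not particle.mask.any():
        raise ValueError("empty mask")
    area = float(particle.mask.any(axis=0).sum()) * particle.voxel_size**2
    r = float(np.sqrt(area / np.pi))
    return r, float(4.0 / 3.0 * np.pi * r**3)


def radius_of_gyration_voxels(particle: BinaryParticle, include_voxel_term: bool = False) -> float:
    """Root-mean-square distance of foreground voxels to their centroid, nm.

    ``include_voxel_term`` adds the intra-voxel second moment
    (voxel_size^2 / 12 per axis), negligible at sub-nanometre voxels.
    """
    mask = particle.mask
    if not mask.any():
        raise ValueError("empty mask")
    coords = np.argwhere(mask) * particle.voxel_size
    centered = coords - coords.mean(axis=0)
    rg2 = float((centered**2).sum(axis=1).mean())
    if include_voxel_term:
        rg2 += particle.voxel_size**2 / 4.0  # 3 axes x t^2/12
    return float(np.sqrt(rg2))


# ---------------------------------------------------------------------------
# caliper search
# ---------------------------------------------------------------------------

def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _hull_points(mask: np.ndarray, voxel_size: float) -> np.ndarray:
    """Convex-hull vertices of the foreground voxel centres, (N, 3) xyz nm."""
    coords = np.argwhere(mask)[:, ::-1].astype(float) * voxel_size  # (x, y, z)
    if len(coords) < 5 or np.linalg.matrix_rank(coords - coords[0]) < 3:
        return coords
    hull = ConvexHull(coords)
    return coords[hull.vertices]


def _feret_2d(xy: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum pairwise distance among projected points and its direction."""
    if len(xy) > 2:
        try:
            hull = ConvexHull(xy)
            xy = xy[hull.vertices]
        except Exception:  # collinear projections fall back to all points
            pass
    d = xy[:, None, :] - xy[None, :, :]
    dist2 = (d**2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(dist2), dist2.shape)
    vec = d[i, j]
    dist = float(np.sqrt(dist2[i, j]))
    return dist, (vec / dist if dist > 0 else np.array([1.0, 0.0]))


def max_caliper_search(particle: BinaryParticle, angular_step: float = 1.0
                       ) -> tuple[CaliperTriplet, ParticleOrientation]:
    """Brute-force search for the three orthogonal maximum calipers.

    Stage 1 scans rotations about the x axis over [0, 180) and measures the
    maximum Feret of the XY projection at each angle; every spatial
    direction enters some projection, so the overall maximum is the 3D
    maximum caliper lambda_x. Stage 2 scans rotations about the aligned
    long axis and measures the transverse (y) extent, giving lambda_y and,
    90 degrees further, lambda_z. Extents are max - min of the projected
    voxel-centre coordinates plus one voxel. Ties break to the smallest
    angle (first maximum in the scan).

    Returns the caliper triplet and the orientation of the long axis:
    theta is its polar angle from the beam (z) axis in [0, 180) (sign fixed
    by requiring a non-negative x, then y, component), phi is the
    x-rotation angle at which the maximum was found.
    """
    if not particle.mask.any():
        raise ValueError("empty mask")
    if not np.isclose((180.0 / angular_step) % 1.0, 0.0):
        raise ValueError("angular_step must divide 180")
    vx = particle.voxel_size
    pts = _hull_points(particle.mask, vx)
    angles = np.arange(0.0, 180.0, angular_step)

    best = (-1.0, 0.0, np.array([1.0, 0.0]))  # (feret, phi, in-plane direction)
    for phi in angles:
        rot = _rot_x(phi)
        feret, direction = _feret_2d((pts @ rot.T)[:, :2])
        if feret > best[0]:
            best = (feret, phi, direction)
    lam_x = best[0] + vx
    phi_star = best[1]
    alpha = np.rad2deg(np.arctan2(best[2][1], best[2][0]))

    # long-axis direction in the lab frame (unit vector, sign-normalised)
    u = _rot_x(phi_star).T @ np.array([np.cos(np.deg2rad(alpha)), np.sin(np.deg2rad(alpha)), 0.0])
    if u[0] < 0 or (abs(u[0]) < 1e-12 and u[1] < 0):
        u = -u
    theta = float(np.rad2deg(np.arccos(np.clip(u[2], -1.0, 1.0)))) % 180.0

    # stage 2: transverse extents around the aligned long axis
    aligned = pts @ (_rot_z(-alpha) @ _rot_x(phi_star)).T
    best_y = (-1.0, 0.0)
    for psi in angles:
        width = float(np.ptp((aligned @ _rot_x(psi).T)[:, 1]))
        if width > best_y[0]:
            best_y = (width, psi)
    lam_y = best_y[0] + vx
    lam_z = float(np.ptp((aligned @ _rot_x(best_y[1] + 90.0).T)[:, 1])) + vx

    triplet = CaliperTriplet(lambda_x=lam_x, lambda_y=lam_y, lambda_z=lam_z)
    orientation = ParticleOrientation(phi=float(phi_star) % 180.0, theta=theta)
    return triplet, orientation


def max_pairwise_distance(particle: BinaryParticle, max_points: int = 10_000,
                          seed: int = 0) -> float:
    """Brute-force maximum pairwise distance between surface voxel centres,
    nm (independent oracle for the caliper search; subsamples the surface
    if it has more than ``max_points`` voxels)."""
    from scipy.ndimage import binary_erosion

    mask = particle.mask
    surface = mask & ~binary_erosion(mask)
    coords = np.argwhere(surface).astype(float) * particle.voxel_size
    if len(coords) > max_points:
        rng = np.random.default_rng(seed)
        coords = coords[rng.choice(len(coords), max_points, replace=False)]
    if len(coords) < 2:
        return 0.0
    return float(pdist(coords).max())


def describe_particle(particle: BinaryParticle, volume: float, surface_area: float,
                      triplet: CaliperTriplet) -> ShapeDescriptors:
    """Assemble the per-particle descriptor row from precomputed estimates."""
    psi = sphericity(volume, surface_area)
    r2d, v_model = equivalent_radius_2d(particle)
    return ShapeDescriptors(
        sphericity=psi,
        anisotropy=anisotropy(triplet),
        equivalent_spherical_radius_3d=equivalent_radius_3d(volume),
        equivalent_spherical_radius_2d=r2d,
        model_based_volume=v_model,
        radius_of_gyration=radius_of_gyration_voxels(particle),
        sphericity_above_one=psi > 1.0,
    )
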