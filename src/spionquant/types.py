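"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* Arrays are indexed ``[z, y, x]`` (slice axis first, as tifffile and
  scikit-image do). The z axis is the optical/beam axis; the support film
  lies in the XY plane.
* All physical lengths are in nanometres; voxels are isotropic.
* Angles are in degrees unless a function explicitly says radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParticleShapeParams",
    "VoxelVolume",
    "Subtomogram",
    "BinaryParticle",
    "ProbeGrid",
    "StereologyEstimate",
    "CaliperTriplet",
    "ParticleOrientation",
    "ShapeDescriptors",
    "SAXSCurve",
    "GuinierFit",
    "RgComparison",
]


@dataclass(frozen=True)
class ParticleShapeParams:
    """Ground-truth description of one synthetic particle.

    The particle is a (possibly rotated) triaxial ellipsoid with semi-axes
    ``a >= b >= c`` whose radial function may be modulated by a band-limited
    random spherical-harmonic field (degrees 2-6) of relative amplitude
    ``perturbation_amplitude`` (normalised so the maximum radial excursion
    equals the amplitude, keeping the body star-shaped for amplitude < 1).

    ``euler_angles = (azimuth, polar, roll)`` in degrees orient the particle
    in the lab frame: the long (a) axis points along the unit vector with
    the given azimuth (about z, from +x) and polar angle (from +z); ``roll``
    rotates the particle about its own long axis, with roll = 0 placing the
    short (c) axis as vertical as possible and roll = 90 placing it in the
    support plane.
    """

    semi_axes: tuple[float, float, float]
    euler_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    perturbation_amplitude: float = 0.0
    perturbation_seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        if not (0 <= self.perturbation_amplitude < 1):
            raise ValueError("perturbation_amplitude must be in [0, 1) to keep the particle star-shaped")


@dataclass
class VoxelVolume:
    """A tomogram: 3D grayscale intensity grid with isotropic voxel size (nm)."""

    data: np.ndarray  # (z, y, x) float array
    voxel_size: float  # nm per voxel edge

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("tomogram must be a 3D grid with at least one voxel per axis")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Subtomogram:
    """A per-particle crop: fixed lateral extent, full original depth."""

    data: np.ndarray  # (z, y, x)
    voxel_size: float
    crop_origin: tuple[int, int, int]  # (z, y, x) voxel offset in the parent tomogram
    source_id: int = 0
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def lateral_extent_nm(self) -> tuple[float, float]:
        return (self.data.shape[1] * self.voxel_size, self.data.shape[2] * self.voxel_size)


@dataclass
class BinaryParticle:
    """Binary mask of a single particle in its subvolume."""

    mask: np.ndarray  # (z, y, x) bool
    voxel_size: float
    source_id: int = 0
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_nm3(self) -> float:
        """Volume by direct voxel counting (not the stereological estimate)."""
        return self.voxel_count * self.voxel_size**3


@dataclass(frozen=True)
class ProbeGrid:
    """Systematic probe grid for stereological estimation.

    ``area_per_point`` multiplies the Cavalieri point count; ``spacing`` is
    the probe lattice pitch in all dimensions. The two are independently
    configurable; a warning is issued when area_per_point != spacing**2
    (the defaults, 0.91 nm^2 and 0.95 nm, differ by ~0.8%).
    """

    area_per_point: float = 0.91  # nm^2
    spacing: float = 0.95  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.area_per_point <= 0:
            raise ValueError("spacing and area_per_point must be positive")
        if abs(self.area_per_point - self.spacing**2) > 1e-9:
            warnings.warn(
                f"area_per_point ({self.area_per_point}) != spacing^2 ({self.spacing ** 2:.4f}); "
                "the Cavalieri estimate is scaled by their ratio",
                stacklevel=2,
            )

    def sample_offsets(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform random per-axis offsets in [0, spacing)."""
        return rng.uniform(0.0, self.spacing, size=3)


@dataclass
class StereologyEstimate:
    """Volume and surface estimates together with the probe metadata."""

    volume: float  # nm^3
    surface_area: float  # nm^2
    point_count: float
    intersection_counts: dict[str, float] = field(default_factory=dict)
    grid: ProbeGrid | None = None
    n_offsets: int = 1


@dataclass(frozen=True)
class CaliperTriplet:
    """Three orthogonal maximum calipers, nm: longest, transverse maximum,
    and the transverse extent 90 degrees further around the longest axis."""

    lambda_x: float
    lambda_y: float
    lambda_z: float

    def __post_init__(self) -> None:
        if min(self.lambda_x, self.lambda_y, self.lambda_z) <= 0:
            raise ValueError("calipers must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda_x, self.lambda_y, self.lambda_z])


@dataclass(frozen=True)
class ParticleOrientation:
    """Orientation of the longest caliper axis, degrees in [0, 180).

    ``theta`` is the polar angle of the longest axis measured from the beam
    (z) axis, so theta = 90 means the axis lies in the support plane.
    ``phi`` is the in-plane azimuth (for sampled orientations) or the
    x-rotation angle at which the longest caliper was located (for measured
    ones).
    """

    phi: float
    theta: float

    def __post_init__(self) -> None:
        if not (0 <= self.phi < 180 and 0 <= self.theta < 180):
            raise ValueError("angles must lie in [0, 180)")


@dataclass
class ShapeDescriptors:
    """Per-particle shape summary row."""

    sphericity: float
    anisotropy: float
    equivalent_spherical_radius_3d: float
    equivalent_spherical_radius_2d: float
    model_based_volume: float
    radius_of_gyration: float
    sphericity_above_one: bool = False


@dataclass
class SAXSCurve:
    """Reduced 1D SAXS curve: momentum transfer q (nm^-1) vs intensity."""

    q: np.ndarray
    intensity: np.ndarray
    wavelength: float = 0.1524  # photon wavelength, nm

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.size == 0:
            raise ValueError("empty q grid")
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have the same shape")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be non-negative and strictly ascending")


@dataclass
class GuinierFit:
    """Result of a Guinier regression of ln I on q^2."""

    rg: float  # nm
    slope: float
    intercept: float
    rg_se: float
    ci95: tuple[float, float]
    q_range: tuple[float, float]
    n_points: int
    n_iterations: int


@dataclass
class RgComparison:
    """Difference-of-means comparison between SAXS and TEM radii of gyration."""

    mean_saxs: float
    mean_tem: float
    diff: float  # mean_saxs - mean_tem
    ci95: tuple[float, float]
    verdict: str  # "no significant difference" | "significant difference"
    n_tem: int
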