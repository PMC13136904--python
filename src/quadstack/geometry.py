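"""Hard-cylinder + patch representation of a G-quadruplex dimer.

Each G4 unit is a hard cylinder (HC).  Two patch families decorate it:

* a *linker* patch of radius ``R0`` on the rim of one base, whose centre
  interacts with the partner's linker patch through an infinite square well of
  width ``2 R0`` — the entire coarse-grained stand-in for the TTA linker;
* *stacking* patches of radius ``R1`` at the centres of the bases, coupled
  across the junction by a finite square well of width ``2 R1`` and depth
  ``u0``.

All energies are expressed in units of ``u0``; the stacking strength is then
controlled solely by the dimensionless effective temperature
``T* = k_B T / u0``.

Convention (one junction per dimer): cylinder A carries its linker patch on
its +axis base and cylinder B on its -axis base; the stacking pair is
(A: +axis base centre, B: -axis base centre).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .overlap import cylinders_intersect

__all__ = [
    "CylinderGeometry",
    "PatchSpec",
    "CylinderPose",
    "DimerState",
    "EffectiveTemperature",
    "axis_frame",
    "patch_centers",
    "cylinders_overlap",
    "pair_energy",
    "is_stacked",
]


@dataclass(frozen=True)
class CylinderGeometry:
    """Hard-cylinder dimensions in nm (defaults: best-fit G4 unit)."""

    radius_RHC: float = 1.26
    height_H: float = 2.64

    def __post_init__(self):
        if self.radius_RHC <= 0 or self.height_H <= 0:
            raise ValueError("cylinder radius and height must be positive")

    @property
    def rg(self) -> float:
        """Gyration radius of the uniform solid cylinder."""
        return math.sqrt(self.radius_RHC**2 / 2.0 + self.height_H**2 / 12.0)

    @property
    def volume(self) -> float:
        return math.pi * self.radius_RHC**2 * self.height_H


@dataclass(frozen=True)
class PatchSpec:
    """Patch radii (nm).  Linker well width 2*R0 (infinite), stacking well
    width 2*R1, depth u0 = 1."""

    linker_radius_R0: float = 0.53
    stacking_radius_R1: float = 0.265

    def __post_init__(self):
        if self.linker_radius_R0 <= 0 or self.stacking_radius_R1 <= 0:
            raise ValueError("patch radii must be positive")
        if self.stacking_radius_R1 >= self.linker_radius_R0:
            raise ValueError("stacking radius must be smaller than linker radius")


@dataclass(frozen=True)
class EffectiveTemperature:
    """Dimensionless T* = k_B T / u0; math.inf encodes the no-stacking limit."""

    T_star: float

    def __post_init__(self):
        if not (self.T_star >= 0):
            raise ValueError("T* must be >= 0")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.T_star)

    @property
    def is_zero(self) -> bool:
        return self.T_star == 0.0


def axis_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal frame (e1, e2) perpendicular to ``axis``.

    The azimuth of a pose is measured from e1 towards e2.  For the z axis
    e1 = x-hat, e2 = y-hat.
    """
    axis = np.asarray(axis, dtype=float)
    t = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = t - np.dot(t, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


@dataclass
class CylinderPose:
    """Position and full orientation of one hard cylinder.

    ``azimuth`` fixes the rotation about the axis (the rim-mounted linker
    patch breaks azimuthal symmetry); it is measured in the deterministic
    frame returned by :func:`axis_frame`.
    """

    center: np.ndarray
    axis: np.ndarray
    azimuth: float = 0.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError("axis must be a unit vector")
        self.axis = self.axis / norm
        self.azimuth = float(self.azimuth) % (2.0 * math.pi)

    @property
    def radial(self) -> np.ndarray:
        """Unit vector from the axis towards the rim linker patch."""
        e1, e2 = axis_frame(self.axis)
        return math.cos(self.azimuth) * e1 + math.sin(self.azimuth) * e2

    @classmethod
    def from_frame(cls, center, axis, radial) -> "CylinderPose":
        """Build a pose from an explicit radial reference vector."""
        axis = np.asarray(axis, dtype=float)
        radial = np.asarray(radial, dtype=float)
        e1, e2 = axis_frame(axis)
        az = math.atan2(float(np.dot(radial, e2)), float(np.dot(radial, e1)))
        return cls(center=center, axis=axis, azimuth=az)


@dataclass
class DimerState:
    """Two tethered hard cylinders; pose_a is the +axis-linker unit."""

    pose_a: CylinderPose
    pose_b: CylinderPose
    geometry: CylinderGeometry = field(default_factory=CylinderGeometry)
    patches: PatchSpec = field(default_factory=PatchSpec)


def patch_centers(pose: CylinderPose, geometry: CylinderGeometry,
                  patches: PatchSpec, linker_base: int = +1):
    """Patch centre positions for one cylinder.

    Returns ``(linker_center, (stack_plus, stack_minus))`` where the stacking
    centres sit at ``center +/- (H/2) axis`` and the linker centre on the rim
    of the base selected by ``linker_base`` (+1 or -1 along the axis).
    """
    if linker_base not in (+1, -1):
        raise ValueError("linker_base must be +1 or -1")
    half = 0.5 * geometry.height_H
    stack_plus = pose.center + half * pose.axis
    stack_minus = pose.center - half * pose.axis
    base = stack_plus if linker_base == +1 else stack_minus
    linker = base + geometry.radius_RHC * pose.radial
    return linker, (stack_plus, stack_minus)


def cylinders_overlap(pose_a: CylinderPose, pose_b: CylinderPose,
                      geometry: CylinderGeometry) -> bool:
    """True iff the two closed finite cylinders intersect."""
    return cylinders_intersect(pose_a.center, pose_a.axis,
                               pose_b.center, pose_b.axis,
                               geometry.radius_RHC, geometry.height_H)


def _junction_distances(d: DimerState) -> tuple[float, float]:
    """(linker patch distance, stacking patch distance) across the junction."""
    link_a, (stack_a, _) = patch_centers(d.pose_a, d.geometry, d.patches, +1)
    link_b, (_, stack_b) = patch_centers(d.pose_b, d.geometry, d.patches, -1)
    return float(np.linalg.norm(link_a - link_b)), float(np.linalg.norm(stack_a - stack_b))


def pair_energy(d: DimerState) -> float:
    """Junction energy in units of u0: +inf on hard violation, -1 stacked, 0 else."""
    if cylinders_overlap(d.pose_a, d.pose_b, d.geometry):
        return math.inf
    d_link, d_stack = _junction_distances(d)
    if d_link > 2.0 * d.patches.linker_radius_R0:
        return math.inf
    if d_stack <= 2.0 * d.patches.stacking_radius_R1:
        return -1.0
    return 0.0


def is_stacked(d: DimerState) -> bool:
    """True iff the junction stacking patches sit inside the square well."""
    _, d_stack = _junction_distances(d)
    return d_stack <= 2.0 * d.patches.stacking_radius_R1
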