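"""Concentric-spherical-shell phantom geometry.

A phantom is a water sphere, optionally containing one concentric shell of
cortical bone spanning radii [d, d + t).  Tally cells are 0.1 cm spherical
shells; the bone layer must be aligned to that lattice so its boundaries
coincide with tally-cell boundaries.  Shell membership uses the half-open
convention [inner, outer), with the outermost shell closed at the phantom
surface.

"Distance of the bone layer from the source" means the bone shell's inner
radius throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomConfig",
    "ShellIndex",
    "build_shell_partition",
    "locate_shell",
    "distance_to_next_boundary",
    "BoundaryAlignmentError",
]

LATTICE_CM = 0.1
_ALIGN_TOL = 1e-9


class BoundaryAlignmentError(ValueError):
    """A bone interval does not sit on the 0.1 cm tally lattice."""


def _aligned(x: float) -> bool:
    return abs(x / LATTICE_CM - round(x / LATTICE_CM)) < 1e-6


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and source description for one simulation.

    ``bone_distance``/``bone_thickness`` are both None for the homogeneous
    water phantom; otherwise the bone shell occupies [d, d + t) cm.
    """

    outer_radius: float = 15.0
    source_energy: float = 0.662
    bone_distance: float | None = None
    bone_thickness: float | None = None
    tally_shell_thickness: float = LATTICE_CM
    tally_range: tuple[float, float] = (0.1, 10.0)
    background_material: str = "water"
    bone_material: str = "cortical_bone"

    def __post_init__(self) -> None:
        if (self.bone_distance is None) != (self.bone_thickness is None):
            raise ValueError("bone_distance and bone_thickness must be given together")
        if self.outer_radius <= 0:
            raise ValueError("outer_radius must be positive")
        if self.tally_shell_thickness <= 0:
            raise ValueError("tally_shell_thickness must be positive")
        if not (0 < self.tally_range[0] < self.tally_range[1]):
            raise ValueError("tally_range must be increasing and positive")
        if self.tally_range[1] > self.outer_radius + _ALIGN_TOL:
            raise ValueError("tally_range upper bound exceeds phantom radius")
        if self.source_energy <= 0:
            raise ValueError("source_energy must be positive")
        if self.bone_distance is not None:
            d, t = self.bone_distance, self.bone_thickness
            if d <= 0 or t <= 0:
                raise ValueError("bone distance and thickness must be positive")
            if d + t > self.outer_radius + _ALIGN_TOL:
                raise ValueError("bone shell extends beyond the phantom surface")

    @property
    def homogeneous(self) -> bool:
        return self.bone_distance is None


@dataclass(frozen=True)
class ShellIndex:
    """One spherical shell of the partition: [inner_radius, outer_radius)."""

    index: int
    inner_radius: float
    outer_radius: float
    material: str


def build_shell_partition(config: PhantomConfig) -> list[ShellIndex]:
    """Partition (0, outer_radius] into lattice shells with materials.

    The whole phantom is meshed at the tally lattice pitch so that bone
    boundaries, tally boundaries and transport boundaries all coincide.
    Raises :class:`BoundaryAlignmentError` if the bone interval or the
    phantom radius is not representable on the lattice.
    """
    h = config.tally_shell_thickness
    n = round(config.outer_radius / h)
    if abs(n * h - config.outer_radius) > 1e-6:
        raise BoundaryAlignmentError(
            f"outer radius {config.outer_radius} not a multiple of the "
            f"{h} cm lattice"
        )
    if not config.homogeneous:
        d, t = config.bone_distance, config.bone_thickness
        if not (_aligned(d) and _aligned(t)):
            raise BoundaryAlignmentError(
                f"bone interval [{d}, {d + t}) must be aligned to the "
                f"{LATTICE_CM} cm tally lattice"
            )
    shells = []
    for i in range(n):
        lo, hi = i * h, (i + 1) * h
        mat = config.background_material
        if not config.homogeneous:
            d, t = config.bone_distance, config.bone_thickness
            # half-open bone extent [d, d+t); compare at shell centers to
            # dodge floating-point edges
            c = 0.5 * (lo + hi)
            if d - _ALIGN_TOL < c < d + t - _ALIGN_TOL:
                mat = config.bone_material
        shells.append(ShellIndex(i, lo, hi, mat))
    return shells


def locate_shell(radius: float, partition: list[ShellIndex]) -> ShellIndex:
    """Return the shell containing ``radius`` (half-open; outermost closed)."""
    outer = partition[-1].outer_radius
    if not (0 < radius <= outer):
        raise ValueError(f"radius {radius} outside phantom (0, {outer}]")
    h = partition[0].outer_radius - partition[0].inner_radius
    i = min(int(radius / h), len(partition) - 1)
    # guard against floating-point landing in the neighbour cell
    if radius < partition[i].inner_radius:
        i -= 1
    elif i + 1 < len(partition) and radius >= partition[i].outer_radius:
        i += 1
    return partition[i]


def distance_to_next_boundary(
    position: np.ndarray,
    direction: np.ndarray,
    partition: list[ShellIndex],
) -> tuple[float, ShellIndex | None]:
    """Distance along a ray to the first shell boundary it crosses.

    Returns ``(distance, next_shell)``; ``next_shell`` is None when the
    ray exits the phantom at that distance.  The ray origin must be inside
    the phantom and ``direction`` must be unit within 1e-9.
    """
    pos = np.asarray(position, float)
    u = np.asarray(direction, float)
    if abs(np.dot(u, u) - 1.0) > 2e-9:
        raise ValueError("direction must be a unit vector")
    r = float(np.linalg.norm(pos))
    outer = partition[-1].outer_radius
    if r > outer * (1 + 1e-12):
        raise ValueError("position outside phantom")
    shell = locate_shell(max(r, 1e-300), partition) if r > 0 else partition[0]
    rmu = float(np.dot(pos, u))  # r * cos(angle to outward radial)
    p2 = r * r - rmu * rmu  # squared impact parameter
    k = shell.index
    # a point numerically on a boundary may yield a degenerate (~0)
    # crossing; in that case it belongs to the neighbour shell instead
    for _ in range(2):
        a = partition[k].inner_radius
        b = partition[k].outer_radius
        if rmu < 0 and a > 0 and p2 < a * a:
            s = -rmu - math.sqrt(a * a - p2)
            k_next = k - 1
        else:
            s = -rmu + math.sqrt(max(b * b - p2, 0.0))
            k_next = k + 1
        if s > 1e-12:
            break
        k = k_next
    s = max(s, 1e-12)
    if k_next < len(partition):
        return s, partition[k_next]
    return s, None
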