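"""Synthetic 2-D planning phantoms.

A phantom is a single transverse slice: a voxel grid with named binary
structure masks (one planning target volume, one or more organs at risk,
a surrounding normal-tissue ring, and a body contour).  Geometries are
described by analytic primitives (disk, annulus, crescent) in millimetres
and rasterized onto the grid.

Coordinate convention: row-major voxel indexing, 0-based; voxel centers at
``(i + 0.5, j + 0.5) * voxel_size``.  In physical coordinates the origin is
the grid center, ``x`` increases with column index (east) and ``y``
decreases with row index (north up).  Gantry angles are measured clockwise
from north.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

Role = Literal["ptv", "oar", "normal_ring", "body"]


class InvalidSpecError(ValueError):
    """Raised when a phantom specification violates its invariants."""


class GeometrySpec(BaseModel):
    """Analytic 2-D primitive, all lengths in mm, centers relative to grid center.

    ``disk``: ``center``, ``radius``.
    ``annulus``: ``center``, ``r_inner``, ``r_outer``.
    ``crescent``: ``center``/``radius`` minus the cutting disk
    ``cut_center``/``cut_radius``.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["disk", "annulus", "crescent"]
    center: Tuple[float, float] = (0.0, 0.0)
    radius: Optional[float] = None
    r_inner: Optional[float] = None
    r_outer: Optional[float] = None
    cut_center: Optional[Tuple[float, float]] = None
    cut_radius: Optional[float] = None

    @model_validator(mode="after")
    def _check_fields(self) -> "GeometrySpec":
        if self.kind == "disk":
            if self.radius is None or self.radius <= 0:
                raise ValueError("disk requires radius > 0")
        elif self.kind == "annulus":
            if self.r_inner is None or self.r_outer is None:
                raise ValueError("annulus requires r_inner and r_outer")
            if not (0 <= self.r_inner < self.r_outer):
                raise ValueError("annulus requires 0 <= r_inner < r_outer")
        elif self.kind == "crescent":
            if self.radius is None or self.radius <= 0:
                raise ValueError("crescent requires radius > 0")
            if self.cut_center is None or self.cut_radius is None or self.cut_radius <= 0:
                raise ValueError("crescent requires cut_center and cut_radius > 0")
        return self


class StructureSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    role: Role
    geometry: GeometrySpec


class PhantomSpec(BaseModel):
    """Declarative phantom description, serializable to YAML/JSON."""

    model_config = ConfigDict(extra="forbid")

    grid_shape: Tuple[int, int] = (64, 64)
    voxel_size: float = 2.5  # mm per voxel side
    structures: List[StructureSpec] = Field(default_factory=list)
    seed: int = 0
    overlap_tolerance: float = 0.0  # allowed ptv/oar overlap, fraction of OAR area

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError("grid_shape must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        roles = [s.role for s in self.structures]
        if self.structures and roles.count("ptv") != 1:
            raise ValueError("exactly one structure must have role 'ptv'")
        return self


class BeamSpec(BaseModel):
    """Coplanar parallel-beam layout.

    ``gantry_angles_deg`` are measured clockwise from north; ``half_aperture``
    sets the lateral extent of each beam's beamlet row about the isocenter.
    """

    model_config = ConfigDict(extra="forbid")

    gantry_angles_deg: List[float] = Field(
        default_factory=lambda: [36.0, 100.0, 180.0, 260.0, 324.0]
    )
    beamlet_width: float = 5.0  # mm
    half_aperture: float = 25.0  # mm
    parallel: bool = True

    @model_validator(mode="after")
    def _check(self) -> "BeamSpec":
        for a in self.gantry_angles_deg:
            if not (0.0 <= a < 360.0):
                raise ValueError("gantry angles must lie in [0, 360)")
        if self.beamlet_width <= 0:
            raise ValueError("beamlet_width must be positive")
        if self.half_aperture <= 0:
            raise ValueError("half_aperture must be positive")
        return self

    def beamlet_offsets(self) -> np.ndarray:
        """Lateral beamlet-center offsets (mm), symmetric about the axis."""
        n = max(1, int(round(2 * self.half_aperture / self.beamlet_width)))
        return (np.arange(n) + 0.5) * self.beamlet_width - self.half_aperture


@dataclass
class Phantom:
    """Rasterized phantom: binary masks over the voxel grid."""

    grid_shape: Tuple[int, int]
    voxel_size: float
    masks: Dict[str, np.ndarray]
    roles: Dict[str, Role]
    spec: Optional[PhantomSpec] = field(default=None, repr=False)

    @property
    def body_mask(self) -> np.ndarray:
        for name, role in self.roles.items():
            if role == "body":
                return self.masks[name]
        # fall back: union of everything
        out = np.zeros(self.grid_shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out

    @property
    def ptv_name(self) -> str:
        for name, role in self.roles.items():
            if role == "ptv":
                return name
        raise KeyError("phantom has no PTV structure")

    def mask_of(self, name: str) -> np.ndarray:
        return self.masks[name]

    def structures_with_role(self, role: Role) -> List[str]:
        return [n for n, r in self.roles.items() if r == role]

    def voxel_centers_mm(self) -> np.ndarray:
        """(n_voxels, 2) physical (x, y) of every voxel center, origin at grid center."""
        rows, cols = self.grid_shape
        i, j = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        x = (j.ravel() + 0.5) * self.voxel_size - cols * self.voxel_size / 2.0
        y = rows * self.voxel_size / 2.0 - (i.ravel() + 0.5) * self.voxel_size
        return np.column_stack([x, y])


def _rasterize(geom: GeometrySpec, centers: np.ndarray) -> np.ndarray:
    cx, cy = geom.center
    d2 = (centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2
    if geom.kind == "disk":
        return d2 <= geom.radius**2
    if geom.kind == "annulus":
        return (d2 >= geom.r_inner**2) & (d2 <= geom.r_outer**2)
    # crescent: disk minus cutting disk
    qx, qy = geom.cut_center
    q2 = (centers[:, 0] - qx) ** 2 + (centers[:, 1] - qy) ** 2
    return (d2 <= geom.radius**2) & (q2 > geom.cut_radius**2)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a :class:`PhantomSpec` onto its voxel grid.

    Deterministic given the spec (the seed is carried through for randomized
    variants built on top).  The normal-tissue ring is carved so that it
    excludes the PTV and the OARs; OAR voxels overlapping the PTV beyond
    ``overlap_tolerance`` raise :class:`InvalidSpecError`.
    """
    rows, cols = spec.grid_shape
    ph = Phantom(grid_shape=(rows, cols), voxel_size=spec.voxel_size, masks={}, roles={}, spec=spec)
    centers = ph.voxel_centers_mm()

    masks: Dict[str, np.ndarray] = {}
    roles: Dict[str, Role] = {}
    for s in spec.structures:
        flat = _rasterize(s.geometry, centers)
        masks[s.name] = flat.reshape(rows, cols)
        roles[s.name] = s.role

    body = None
    for name, role in roles.items():
        if role == "body":
            body = masks[name]
    if body is not None:
        for name in masks:
            if roles[name] != "body":
                inside = masks[name] & body
                if masks[name].sum() and inside.sum() < masks[name].sum():
                    raise InvalidSpecError(f"structure '{name}' extends outside the body contour")
                masks[name] = inside

    ptv_names = [n for n, r in roles.items() if r == "ptv"]
    if not ptv_names:
        raise InvalidSpecError("spec has no PTV structure")
    ptv = masks[ptv_names[0]]
    if not ptv.any():
        raise InvalidSpecError("PTV mask is empty after rasterization")

    for name, role in roles.items():
        if role == "oar":
            overlap = (masks[name] & ptv).sum()
            area = max(int(masks[name].sum()), 1)
            if overlap / area > spec.overlap_tolerance:
                raise InvalidSpecError(
                    f"OAR '{name}' overlaps the PTV by {overlap} voxels "
                    f"({overlap / area:.1%} of its area)"
                )
            masks[name] &= ~ptv

    carve = ptv.copy()
    for name, role in roles.items():
        if role == "oar":
            carve |= masks[name]
    for name, role in roles.items():
        if role == "normal_ring":
            masks[name] &= ~carve

    ph.masks = masks
    ph.roles = roles
    return ph


def default_prostate_spec(
    grid_shape: Tuple[int, int] = (64, 64),
    voxel_size: float = 2.5,
    seed: int = 0,
) -> PhantomSpec:
    """Prostate-like preset: central PTV disk, posterior crescent-shaped
    rectum, anterior bladder disk, 15-mm normal-tissue ring, circular body.

    A geometric stand-in for pelvic anatomy, sized so the standard prostate
    dose-volume prescription is achievable with five coplanar beams.  Two
    calls return identical specs.
    """
    structures = [
        StructureSpec(
            name="body",
            role="body",
            geometry=GeometrySpec(kind="disk", center=(0.0, 0.0), radius=75.0),
        ),
        StructureSpec(
            name="ptv",
            role="ptv",
            geometry=GeometrySpec(kind="disk", center=(0.0, 0.0), radius=12.0),
        ),
        StructureSpec(
            name="rectum",
            role="oar",
            geometry=GeometrySpec(
                kind="crescent",
                center=(0.0, -26.0),
                radius=12.0,
                cut_center=(0.0, -8.0),
                cut_radius=16.0,
            ),
        ),
        StructureSpec(
            name="bladder",
            role="oar",
            geometry=GeometrySpec(kind="disk", center=(0.0, 31.0), radius=17.0),
        ),
        StructureSpec(
            name="ring",
            role="normal_ring",
            geometry=GeometrySpec(kind="annulus", center=(0.0, 0.0), r_inner=12.0, r_outer=27.0),
        ),
    ]
    return PhantomSpec(
        grid_shape=grid_shape, voxel_size=voxel_size, structures=structures, seed=seed
    )


def default_beam_spec() -> BeamSpec:
    """Five coplanar beams at gantry angles 36, 100, 180, 260 and 324 degrees."""
    return BeamSpec()


def export_mask_csv(phantom: Phantom, name: str, path: str) -> None:
    """Write a structure mask as CSV rows of ``row,col`` voxel indices."""
    idx = np.argwhere(phantom.masks[name])
    np.savetxt(path, idx, fmt="%d", delimiter=",", header="row,col", comments="")
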