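"""Voxel flow domains: rasterised scaffold solids with labelled boundaries.

The flow domain is a regular isotropic voxel lattice.  Flow is always
driven along the z axis (through the scaffold thickness, i.e. face-on
inflow perpendicular to the filament layers), with an open entry pad
upstream and an exit pad downstream of the scaffold slab.  Lateral
boundaries can be solid walls, periodic images (for unit cells of the
in-plane-periodic rectangular designs) or symmetry planes (for
quarter-domain solves of mirror-symmetric designs).

Voxels are cubes of edge ``spacing`` (mm); occupancy is decided by a
centre-point inclusion test.  Physical coordinates are voxel-centred,
indices 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .geometry import (
    BoxEnvelope,
    EllipticEnvelope,
    Filament,
    ScaffoldSpec,
    SolidGeometry,
)

__all__ = [
    "VoxelDomain",
    "voxelize",
    "make_channel_fixture",
    "extract_unit_cell",
    "unit_cell_domain",
    "connectivity_filter",
    "write_vtk_image",
]

BC = Literal["wall", "periodic", "symmetry"]


@dataclass
class VoxelDomain:
    """Labelled voxel occupancy grid for a perfusion solve.

    ``solid`` marks no-flow voxels (scaffold material plus any
    enclosure wall voxels); ``scaffold`` marks the subset that is
    scaffold material — wall-shear statistics are taken on the scaffold
    surface only.  ``scaffold_range`` is the half-open voxel slab
    [k0, k1) occupied by the scaffold along the flow axis; the Darcy
    length L is its physical thickness.
    """

    solid: np.ndarray
    spacing: float  # mm per voxel
    scaffold: np.ndarray | None = None
    scaffold_range: tuple[int, int] | None = None
    flow_axis: int = 2
    lateral: dict[str, BC] = field(default_factory=lambda: {"x": "wall", "y": "wall"})
    n_excluded: int = 0
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.solid = np.asarray(self.solid, dtype=bool)
        if self.solid.ndim != 3:
            raise ValueError("solid: occupancy must be a 3-D lattice")
        if self.spacing <= 0:
            raise ValueError("spacing: must be > 0")
        if self.flow_axis != 2:
            raise ValueError("flow_axis: flow is always along axis 2")
        if self.scaffold is None:
            self.scaffold = self.solid.copy()
        if self.scaffold_range is None:
            ks = np.flatnonzero(self.scaffold.any(axis=(0, 1)))
            self.scaffold_range = (int(ks[0]), int(ks[-1]) + 1) if len(ks) else (0, self.shape[2])
        for ax in ("x", "y"):
            if self.lateral.get(ax) not in ("wall", "periodic", "symmetry"):
                raise ValueError(f"lateral[{ax}]: must be wall, periodic or symmetry")

    # -- basic views -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.solid.shape

    @property
    def fluid(self) -> np.ndarray:
        return ~self.solid

    @property
    def L(self) -> float:
        """Scaffold thickness along the flow axis, mm."""
        k0, k1 = self.scaffold_range
        return (k1 - k0) * self.spacing

    @property
    def entry_length(self) -> float:
        return self.scaffold_range[0] * self.spacing

    @property
    def exit_length(self) -> float:
        return (self.shape[2] - self.scaffold_range[1]) * self.spacing

    def porosity(self) -> float:
        """Fluid fraction of the scaffold slab."""
        k0, k1 = self.scaffold_range
        slab = self.fluid[:, :, k0:k1]
        return float(slab.mean())

    def interface_area(self) -> float:
        """Fluid-scaffold interface area, mm^2 (sum of exposed voxel faces)."""
        return _count_interface_faces(self.fluid, self.scaffold) * self.spacing**2

    def cell_centres_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.spacing
        return tuple((np.arange(n) + 0.5) * h for n in self.shape)


def _count_interface_faces(fluid: np.ndarray, solid_sel: np.ndarray) -> int:
    n = 0
    for ax in range(3):
        a = np.swapaxes(fluid, 0, ax)
        b = np.swapaxes(solid_sel, 0, ax)
        n += int((a[:-1] & b[1:]).sum()) + int((b[:-1] & a[1:]).sum())
    return n


# --------------------------------------------------------------------------
# scaffold voxelization
# --------------------------------------------------------------------------


def _validate_resolution(spec: ScaffoldSpec | None, spacing: float) -> None:
    if spec is None:
        return
    if spacing > spec.fibre_diameter / 3 + 1e-12:
        raise ValueError(
            f"spacing {spacing} mm too coarse: must be <= fibre_diameter/3 "
            f"= {spec.fibre_diameter / 3:.4g} mm"
        )
    if spec.min_pore / spacing < 3 - 1e-9:
        raise ValueError(
            f"spacing {spacing} mm too coarse: smallest pore {spec.min_pore} mm "
            "must span at least 3 voxels (solvability floor)"
        )


def _slice_occupancy(geometry: SolidGeometry, X: np.ndarray, Y: np.ndarray, z: float) -> np.ndarray:
    """Occupancy of one z-slice by centre-point test, filament fast path."""
    occ = np.zeros(X.shape, dtype=bool)
    fils = geometry.filaments
    others = [p for p in geometry.primitives if not isinstance(p, Filament)]
    for f in fils:
        dz2 = (z - f.z) ** 2
        if dz2 > f.radius**2:
            continue
        w = math.sqrt(f.radius**2 - dz2)
        t = X if f.axis == 0 else Y
        s = Y if f.axis == 0 else X
        occ |= (
            (np.abs(s - f.transverse) <= w)
            & (t >= f.span[0])
            & (t <= f.span[1])
        )
    if others:
        pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
        sub = SolidGeometry(others, envelope=None)
        occ |= sub.contains(pts).reshape(X.shape)
    return occ


def voxelize(
    geometry: SolidGeometry,
    spacing: float,
    entry_length: float = 1.0,
    exit_length: float = 1.0,
    lateral: BC | dict[str, BC] = "wall",
    quarter: bool = False,
    filter_connectivity: bool = True,
) -> VoxelDomain:
    """Rasterise a scaffold solid into a padded voxel flow domain.

    The duct cross-section is the scaffold's own footprint: for a box
    envelope the lateral boundaries carry the requested boundary
    condition; for an elliptic envelope, voxels outside the footprint
    become enclosure wall.  ``quarter=True`` keeps only the x >= 0,
    y >= 0 quadrant of a centred elliptic design with symmetry planes
    on the cut faces — valid because the 0/90 ring lay-down is mirror
    symmetric in both axes.

    ``entry_length`` / ``exit_length`` are open pads (mm) added before
    and after the scaffold along the flow axis.
    """
    env = geometry.envelope
    if env is None:
        raise ValueError("geometry must carry an envelope to define the flow domain")
    spec = geometry.spec
    _validate_resolution(spec, spacing)
    h = spacing

    if isinstance(env, BoxEnvelope):
        if quarter:
            raise ValueError("quarter domains are only defined for elliptic footprints")
        nx = max(int(round(env.length / h)), 1)
        ny = max(int(round(env.width / h)), 1)
        x0, y0 = 0.0, 0.0
    else:
        if quarter:
            nx = max(int(round(env.semi_x / h)), 1)
            ny = max(int(round(env.semi_y / h)), 1)
            x0, y0 = 0.0, 0.0
        else:
            nx = max(int(round(2 * env.semi_x / h)), 1)
            ny = max(int(round(2 * env.semi_y / h)), 1)
            x0, y0 = -env.semi_x, -env.semi_y
    nz_s = max(int(round(env.height / h)), 1)
    n_in = int(round(entry_length / h))
    n_out = int(round(exit_length / h))
    nz = n_in + nz_s + n_out

    x = x0 + (np.arange(nx) + 0.5) * h
    y = y0 + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(x, y, indexing="ij")

    scaff = np.zeros((nx, ny, nz), dtype=bool)
    for k in range(nz_s):
        z = (k + 0.5) * h
        scaff[:, :, n_in + k] = _slice_occupancy(geometry, X, Y, z)

    solid = scaff.copy()
    if isinstance(env, EllipticEnvelope):
        outside = ~env.footprint_contains(X, Y)
        solid |= outside[:, :, None]

    if isinstance(lateral, str):
        lat = {"x": lateral, "y": lateral}
    else:
        lat = dict(lateral)
    if quarter:
        lat = {"x": "symmetry", "y": "symmetry"}

    dom = VoxelDomain(
        solid=solid,
        spacing=h,
        scaffold=scaff,
        scaffold_range=(n_in, n_in + nz_s),
        lateral=lat,
    )
    if filter_connectivity:
        dom = connectivity_filter(dom)
    return dom


def connectivity_filter(domain: VoxelDomain) -> VoxelDomain:
    """Remove fluid voxels not 6-connected to the inlet face.

    Disconnected pockets carry no flow; they are flagged, excluded from
    the fluid and counted.  The operation is idempotent.
    """
    fluid = domain.fluid
    labels, _ = ndimage.label(fluid, structure=ndimage.generate_binary_structure(3, 1))
    inlet_labels = np.unique(labels[:, :, 0])
    inlet_labels = inlet_labels[inlet_labels != 0]
    connected = np.isin(labels, inlet_labels)
    pockets = fluid & ~connected
    n_new = int(pockets.sum())
    if n_new == 0 and domain.excluded is not None:
        return domain
    solid = domain.solid | pockets
    excluded = pockets if domain.excluded is None else (domain.excluded | pockets)
    return replace(
        domain,
        solid=solid,
        scaffold=domain.scaffold,
        n_excluded=domain.n_excluded + n_new,
        excluded=excluded,
    )


# --------------------------------------------------------------------------
# analytic validation fixtures
# --------------------------------------------------------------------------


def make_channel_fixture(
    kind: Literal["parallel_plate", "circular_tube"],
    gap_or_radius: float,
    length: float,
    spacing: float,
    entry_length: float | None = None,
    exit_length: float | None = None,
) -> VoxelDomain:
    """Straight duct domains with exact laminar solutions.

    ``parallel_plate`` is a slot of gap ``gap_or_radius`` across x,
    periodic in y (planar flow); ``circular_tube`` a cylinder of radius
    ``gap_or_radius``.  The central ``length`` of the duct plays the
    role of the scaffold slab (pressure probes bracket it); by default
    entry/exit pads of 2 x the transverse dimension are added so the
    profile is developed at the first probe.
    """
    h = spacing
    if length <= 0:
        raise ValueError("length: duct length must be > 0")
    if gap_or_radius < 4 * h:
        raise ValueError(
            f"under-resolved duct: gap/radius {gap_or_radius} mm must be >= 4 voxels "
            f"({4 * h} mm)"
        )
    if entry_length is None:
        entry_length = 2.0 * gap_or_radius
    if exit_length is None:
        exit_length = 2.0 * gap_or_radius
    n_len = int(round(length / h))
    n_in = int(round(entry_length / h))
    n_out = int(round(exit_length / h))
    nz = n_in + n_len + n_out

    if kind == "parallel_plate":
        n_gap = int(round(gap_or_radius / h))
        nx = n_gap + 2  # one solid wall layer each side
        ny = 4
        solid = np.zeros((nx, ny, nz), dtype=bool)
        solid[0, :, :] = True
        solid[-1, :, :] = True
        lat = {"x": "wall", "y": "periodic"}
    elif kind == "circular_tube":
        R = gap_or_radius
        n_d = int(round(2 * R / h)) + 2
        nx = ny = n_d
        c = n_d * h / 2.0
        xc = (np.arange(n_d) + 0.5) * h - c
        X, Y = np.meshgrid(xc, xc, indexing="ij")
        outside = X**2 + Y**2 > R**2
        solid = np.repeat(outside[:, :, None], nz, axis=2)
        lat = {"x": "wall", "y": "wall"}
    else:
        raise ValueError(f"kind: unknown fixture kind {kind!r}")

    return VoxelDomain(
        solid=solid,
        spacing=h,
        scaffold=solid.copy(),
        scaffold_range=(n_in, n_in + n_len),
        lateral=lat,
    )


# --------------------------------------------------------------------------
# unit cells
# --------------------------------------------------------------------------


def unit_cell_domain(
    spec: ScaffoldSpec,
    target_spacing: float,
    entry_length: float = 1.0,
    exit_length: float = 1.0,
) -> VoxelDomain:
    """One in-plane period of a rectangular design, periodic laterally.

    The period is ``pore + fibre_diameter``; the voxel spacing is
    snapped to divide the period exactly so the periodic images tile.
    One filament per layer crosses the cell, centred.
    """
    if spec.kind != "rectangular":
        raise ValueError("unit cells are only defined for rectangular (periodic) designs")
    s = spec.spacing()
    n_cell = max(int(round(s / target_spacing)), 1)
    h = s / n_cell
    _validate_resolution(spec, h)
    prims = [
        Filament(axis=i % 2, transverse=s / 2.0, z=float(zc), radius=spec.fibre_diameter / 2.0, span=(0.0, s))
        for i, zc in enumerate(spec.layer_centres())
    ]
    cell = SolidGeometry(prims, envelope=BoxEnvelope(s, s, spec.height), spec=spec)
    return voxelize(
        cell,
        spacing=h,
        entry_length=entry_length,
        exit_length=exit_length,
        lateral="periodic",
    )


def extract_unit_cell(domain: VoxelDomain, spec: ScaffoldSpec) -> VoxelDomain:
    """Crop one in-plane period out of a full rectangular-scaffold domain.

    Requires the period to be an integer number of voxels; the window is
    taken from the domain centre (away from edge margins) and relabelled
    periodic.
    """
    if spec.kind != "rectangular":
        raise ValueError("graded_ring designs have no in-plane period")
    s = spec.spacing()
    h = domain.spacing
    n_cell = s / h
    if abs(n_cell - round(n_cell)) > 1e-6:
        raise ValueError(
            f"period {s} mm is not an integer number of voxels at spacing {h} mm; "
            "re-voxelize with an aligned spacing"
        )
    n_cell = int(round(n_cell))
    nx, ny, _ = domain.shape
    i0 = (nx - n_cell) // 2
    j0 = (ny - n_cell) // 2
    sl = (slice(i0, i0 + n_cell), slice(j0, j0 + n_cell), slice(None))
    return VoxelDomain(
        solid=domain.solid[sl].copy(),
        spacing=h,
        scaffold=domain.scaffold[sl].copy(),
        scaffold_range=domain.scaffold_range,
        lateral={"x": "periodic", "y": "periodic"},
    )


# --------------------------------------------------------------------------
# VTK export (legacy ASCII image data)
# --------------------------------------------------------------------------


def write_vtk_image(path, domain: VoxelDomain, fields: dict[str, np.ndarray] | None = None) -> None:
    """Write occupancy/labels (and optional cell fields) as legacy ASCII
    VTK STRUCTURED_POINTS, one point per voxel centre, mm units."""
    nx, ny, nz = domain.shape
    h = domain.spacing
    data: dict[str, np.ndarray] = {
        "solid": domain.solid.astype(np.int8),
        "scaffold": domain.scaffold.astype(np.int8),
    }
    if fields:
        data.update(fields)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nscaffoldflow voxel domain\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {h / 2} {h / 2} {h / 2}\n")
        fh.write(f"SPACING {h} {h} {h}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 3:
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                vals = arr.transpose(2, 1, 0).ravel()
                np.savetxt(fh, vals[:, None], fmt="%.6g")
            elif arr.ndim == 4 and arr.shape[3] == 3:
                fh.write(f"VECTORS {name} float\n")
                vals = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
                np.savetxt(fh, vals, fmt="%.6g")
            else:
                raise ValueError(f"field {name!r}: expected 3-D scalar or 4-D vector array")
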