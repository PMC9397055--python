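"""Parametric scaffold solids and their geometric characteristics.

Extrusion-printed bone scaffolds are stacks of parallel cylindrical
filaments laid down with a 0/90 pattern: every layer is rotated 90
degrees from the one below, and consecutive layers are printed with a
vertical pitch slightly smaller than the filament diameter so that they
fuse into a single body.  Two families are supported:

* rectangular scaffolds with a single uniform pore size, and
* elliptical scaffolds whose footprint is divided into concentric
  rings, each ring with its own (radially increasing) pore size.

"Pore size" is the clear edge-to-edge spacing between adjacent parallel
filaments within a layer, so the centre-to-centre spacing is
``pore + fibre_diameter``; this is the standard convention for
extrusion scaffolds.

Solids are kept as exact primitive descriptions (capped cylinder
segments, optionally spheres), not meshes: volumes and surface areas
are integrated from the primitives, and meshes are generated only on
STL export.  All geometry-layer lengths are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ScaffoldSpec",
    "Filament",
    "Sphere",
    "BoxEnvelope",
    "EllipticEnvelope",
    "SolidGeometry",
    "GeometryMetrics",
    "build_rectangular_scaffold",
    "build_graded_ring_scaffold",
    "compute_geometry_metrics",
    "export_stl",
]


# --------------------------------------------------------------------------
# design specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaffoldSpec:
    """Parametric description of a 0/90 lay-down scaffold design.

    Parameters
    ----------
    kind:
        ``"rectangular"`` (box footprint, one pore size) or
        ``"graded_ring"`` (elliptical footprint, one pore size per
        concentric ring, strictly increasing outwards).
    length, width, height:
        Bounding dimensions in mm.  For graded-ring designs ``length``
        and ``width`` are the full axes of the elliptical footprint.
    n_layers:
        Number of filament layers.
    fibre_diameter:
        Filament diameter, mm.
    pore_sizes:
        Clear filament-to-filament spacing(s), mm.  One value for
        rectangular designs, one per ring for graded designs.
    layer_pitch:
        Vertical centre-to-centre spacing of consecutive layers, mm.
        Defaults to ``height / n_layers``.  Must not exceed the fibre
        diameter (consecutive layers must touch or fuse).
    lay_down_angle_increment:
        Rotation between consecutive layers, degrees.  Only the 0/90
        pattern (90 degrees) is supported.
    ring_count:
        Number of concentric rings (graded designs only).
    """

    kind: Literal["rectangular", "graded_ring"]
    length: float
    width: float
    height: float
    n_layers: int
    fibre_diameter: float
    pore_sizes: tuple[float, ...]
    layer_pitch: float | None = None
    lay_down_angle_increment: float = 90.0
    ring_count: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pore_sizes", tuple(float(p) for p in np.atleast_1d(self.pore_sizes)))
        if self.kind not in ("rectangular", "graded_ring"):
            raise ValueError(f"kind: unknown scaffold kind {self.kind!r}")
        for name in ("length", "width", "height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be > 0")
        if self.n_layers < 1:
            raise ValueError("n_layers: must be >= 1")
        if self.layer_pitch is None:
            object.__setattr__(self, "layer_pitch", self.height / self.n_layers)
        if self.fibre_diameter <= 0:
            raise ValueError("fibre_diameter: must be > 0")
        if any(p <= 0 for p in self.pore_sizes):
            raise ValueError("pore_sizes: all pore sizes must be > 0")
        if self.layer_pitch > self.fibre_diameter + 1e-12:
            raise ValueError(
                "layer_pitch: must not exceed fibre_diameter "
                "(consecutive layers must touch or fuse)"
            )
        if self.lay_down_angle_increment != 90.0:
            raise ValueError("lay_down_angle_increment: only the 0/90 pattern (90) is supported")
        if self.kind == "rectangular":
            if len(self.pore_sizes) != 1:
                raise ValueError("pore_sizes: rectangular designs take exactly one pore size")
        else:
            if self.ring_count is None:
                object.__setattr__(self, "ring_count", len(self.pore_sizes))
            if self.ring_count != len(self.pore_sizes):
                raise ValueError("ring_count: must equal the number of pore_sizes")
            diffs = np.diff(self.pore_sizes)
            if len(diffs) and not np.all(diffs > 0):
                raise ValueError("pore_sizes: must be strictly increasing from innermost ring outwards")

    # -- catalogue designs -------------------------------------------------

    @classmethod
    def rectangular_case(cls, pore_size: float) -> "ScaffoldSpec":
        """20 x 20 x 3.1 mm, 10 layers, 0.33 mm fibre rectangular design."""
        return cls(
            kind="rectangular",
            length=20.0,
            width=20.0,
            height=3.1,
            n_layers=10,
            fibre_diameter=0.33,
            pore_sizes=(pore_size,),
        )

    @classmethod
    def case_1a(cls) -> "ScaffoldSpec":
        return cls.rectangular_case(0.300)

    @classmethod
    def case_1b(cls) -> "ScaffoldSpec":
        return cls.rectangular_case(0.350)

    @classmethod
    def case_1c(cls) -> "ScaffoldSpec":
        return cls.rectangular_case(0.45)

    @classmethod
    def case_2(cls) -> "ScaffoldSpec":
        """Anatomically inspired six-ring design, 31 x 26.7 mm ellipse."""
        return cls(
            kind="graded_ring",
            length=31.0,
            width=26.7,
            height=3.1,
            n_layers=10,
            fibre_diameter=0.33,
            pore_sizes=(0.476, 0.629, 0.670, 0.730, 0.803, 0.979),
            ring_count=6,
        )

    @classmethod
    def named(cls, name: str) -> "ScaffoldSpec":
        table = {"1A": cls.case_1a, "1B": cls.case_1b, "1C": cls.case_1c, "2": cls.case_2}
        key = name.upper().removeprefix("CASE").strip("_ ")
        if key not in table:
            raise KeyError(f"unknown catalogue design {name!r}; expected one of {sorted(table)}")
        return table[key]()

    @property
    def min_pore(self) -> float:
        return min(self.pore_sizes)

    def spacing(self, ring: int = 0) -> float:
        """Centre-to-centre filament spacing (mm) of ``ring``."""
        return self.pore_sizes[ring] + self.fibre_diameter

    def layer_centres(self) -> np.ndarray:
        """z-coordinates (mm) of the filament-layer axes.

        The bottom layer is tangent to z = 0; with pitch < diameter the
        stack overshoots the nominal height slightly and is trimmed
        flush at z = height.
        """
        r = self.fibre_diameter / 2.0
        return r + self.layer_pitch * np.arange(self.n_layers)


# --------------------------------------------------------------------------
# primitives and envelopes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Filament:
    """A straight cylinder segment with axis along x (axis=0) or y (axis=1).

    ``transverse`` is the in-plane coordinate of the axis (y for an
    x-filament, x for a y-filament); ``z`` the axis height; ``span``
    the (lo, hi) extent along the axis direction.  Ends are cut flush
    (flat caps), mm units.
    """

    axis: int
    transverse: float
    z: float
    radius: float
    span: tuple[float, float]

    @property
    def length(self) -> float:
        return self.span[1] - self.span[0]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        t = pts[:, self.axis]
        s = pts[:, 1 - self.axis]
        inside = (s - self.transverse) ** 2 + (pts[:, 2] - self.z) ** 2 <= self.radius**2
        return inside & (t >= self.span[0]) & (t <= self.span[1])


@dataclass(frozen=True)
class Sphere:
    centre: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2 = ((pts - np.asarray(self.centre)) ** 2).sum(axis=1)
        return d2 <= self.radius**2

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    @property
    def area(self) -> float:
        return 4.0 * math.pi * self.radius**2


@dataclass(frozen=True)
class BoxEnvelope:
    """Axis-aligned bounding box [0, length] x [0, width] x [0, height], mm."""

    length: float
    width: float
    height: float

    @property
    def volume(self) -> float:
        return self.length * self.width * self.height

    def footprint_contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= 0) & (x <= self.length) & (y >= 0) & (y <= self.width)


@dataclass(frozen=True)
class EllipticEnvelope:
    """Elliptic prism centred at the origin in-plane, z in [0, height], mm."""

    semi_x: float
    semi_y: float
    height: float

    @property
    def volume(self) -> float:
        return math.pi * self.semi_x * self.semi_y * self.height

    def footprint_contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x / self.semi_x) ** 2 + (y / self.semi_y) ** 2 <= 1.0


Envelope = BoxEnvelope | EllipticEnvelope


@dataclass
class SolidGeometry:
    """A scaffold solid: union of primitives trimmed to an envelope."""

    primitives: list = field(default_factory=list)
    envelope: Envelope | None = None
    spec: ScaffoldSpec | None = None

    @property
    def filaments(self) -> list[Filament]:
        return [p for p in self.primitives if isinstance(p, Filament)]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Vectorised point-inclusion test (points in mm, shape (n, 3))."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.zeros(len(pts), dtype=bool)
        for prim in self.primitives:
            todo = ~out
            if not todo.any():
                break
            out[todo] = prim.contains(pts[todo])
        if self.envelope is not None and len(self.primitives):
            hmax = self.envelope.height
            out &= (pts[:, 2] >= 0.0) & (pts[:, 2] <= hmax)
        return out

    # -- integrated quantities --------------------------------------------

    def volume(self) -> float:
        """Material volume (mm^3) of the union, exact to quadrature error.

        Computed as the z-integral of the exact slice area.  At any
        height at most one x-layer and one y-layer of filaments are
        active (same-orientation layers are two pitches apart, which
        exceeds the fibre diameter), and within a layer the bands never
        overlap (spacing exceeds the diameter), so the slice is a union
        of axis-aligned bands whose area has a closed form for the
        rectangular family and a rectangle-union form for ring designs.
        """
        if not self.primitives:
            return 0.0
        if all(isinstance(p, Sphere) for p in self.primitives):
            if len(self.primitives) > 1:
                raise NotImplementedError("unions of multiple spheres are not supported")
            return self.primitives[0].volume
        if not all(isinstance(p, Filament) for p in self.primitives):
            raise NotImplementedError("mixed primitive unions are not supported")
        return _filament_union_volume(self.filaments, self.envelope)

    def surface_area(self) -> float:
        """Exposed fluid-solid interface area (mm^2).

        Lateral cylinder surfaces are integrated by quadrature, with
        points buried inside neighbouring filaments or lying outside
        the envelope discarded.  Flat end caps flush with the envelope
        boundary face the enclosure wall, not the fluid, and are
        excluded; interior caps (ring-boundary cuts) are included.
        """
        if not self.primitives:
            return 0.0
        if all(isinstance(p, Sphere) for p in self.primitives):
            return sum(p.area for p in self.primitives)
        return _filament_union_area(self.filaments, self.envelope)


@dataclass(frozen=True)
class GeometryMetrics:
    """Volume, interface-area and derived ratios of a scaffold solid.

    ``porosity`` is the void fraction of the envelope,
    1 - V_material / V_domain; ``specific_surface`` is the interface
    area per envelope volume (mm^-1).
    """

    V_domain: float
    V_material: float
    SA: float
    porosity: float
    specific_surface: float


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------


def _rect_layer_centres(extent: float, spacing: float) -> np.ndarray:
    """Transverse filament-axis positions for a rectangular layer.

    As many filaments as fit at the given spacing — floor(extent /
    spacing) + 1 — centred so the two margins are equal.
    """
    count = int(math.floor(extent / spacing)) + 1
    margin = (extent - (count - 1) * spacing) / 2.0
    return margin + spacing * np.arange(count)


def build_rectangular_scaffold(spec: ScaffoldSpec) -> SolidGeometry:
    """Build the uniform-pore rectangular 0/90 scaffold solid."""
    if spec.kind != "rectangular":
        raise ValueError("kind: build_rectangular_scaffold requires a rectangular spec")
    r = spec.fibre_diameter / 2.0
    s = spec.spacing()
    prims: list[Filament] = []
    for i, zc in enumerate(spec.layer_centres()):
        axis = i % 2  # even layers run along x, odd along y
        extent = spec.width if axis == 0 else spec.length
        run = spec.length if axis == 0 else spec.width
        for c in _rect_layer_centres(extent, s):
            prims.append(Filament(axis=axis, transverse=float(c), z=float(zc), radius=r, span=(0.0, run)))
    env = BoxEnvelope(spec.length, spec.width, spec.height)
    return SolidGeometry(primitives=prims, envelope=env, spec=spec)


def _ring_boundaries(spec: ScaffoldSpec) -> np.ndarray:
    """Normalised elliptical radii of the ring boundaries (0..1].

    Ring radii are not part of the design record; annulus boundaries
    are placed at equal radial increments by default.
    """
    n = spec.ring_count or len(spec.pore_sizes)
    return np.linspace(0.0, 1.0, n + 1)


def _chord_intervals(c: float, a_t: float, a_s: float, rho_in: float, rho_out: float) -> list[tuple[float, float]]:
    """Axial intervals of a line at transverse offset ``c`` inside the
    elliptical annulus rho_in < rho <= rho_out (normalised radii).

    ``a_t`` is the semi-axis along the filament, ``a_s`` across it.
    """
    u = c / a_s
    out2 = rho_out**2 - u**2
    if out2 <= 0:
        return []
    xo = a_t * math.sqrt(out2)
    in2 = rho_in**2 - u**2
    if in2 <= 0:
        return [(-xo, xo)]
    xi = a_t * math.sqrt(in2)
    return [(-xo, -xi), (xi, xo)]


def build_graded_ring_scaffold(spec: ScaffoldSpec) -> SolidGeometry:
    """Build the concentric-ring graded-pore scaffold solid.

    The elliptical footprint is partitioned into ``ring_count``
    concentric annuli; inside annulus k the local 0/90 grid uses
    spacing ``pore_sizes[k] + fibre_diameter``.  Filaments are cut
    flush where their centre-line crosses a ring boundary.
    """
    if spec.kind != "graded_ring":
        raise ValueError("kind: build_graded_ring_scaffold requires a graded_ring spec")
    a, b = spec.length / 2.0, spec.width / 2.0
    r = spec.fibre_diameter / 2.0
    bounds = _ring_boundaries(spec)
    prims: list[Filament] = []
    for i, zc in enumerate(spec.layer_centres()):
        axis = i % 2
        a_t = a if axis == 0 else b  # semi-axis along the filament
        a_s = b if axis == 0 else a  # semi-axis across it
        for k, pore in enumerate(spec.pore_sizes):
            s = pore + spec.fibre_diameter
            rho_in, rho_out = bounds[k], bounds[k + 1]
            # symmetric grid about the centre line
            n_side = int(math.floor(rho_out * a_s / s))
            centres = s * np.arange(-n_side, n_side + 1)
            for c in centres:
                for lo, hi in _chord_intervals(float(c), a_t, a_s, rho_in, rho_out):
                    if hi - lo < 2 * r:  # skip slivers shorter than one diameter
                        continue
                    prims.append(
                        Filament(axis=axis, transverse=float(c), z=float(zc), radius=r, span=(lo, hi))
                    )
    env = EllipticEnvelope(a, b, spec.height)
    return SolidGeometry(primitives=prims, envelope=env, spec=spec)


def build_scaffold(spec: ScaffoldSpec) -> SolidGeometry:
    """Build whichever scaffold family ``spec`` describes."""
    if spec.kind == "rectangular":
        return build_rectangular_scaffold(spec)
    return build_graded_ring_scaffold(spec)


# --------------------------------------------------------------------------
# volume integration
# --------------------------------------------------------------------------


def _clipped_circle_area(zc: float, r: float, zlo: float, zhi: float) -> float:
    """Area of a circle of radius r centred at height zc, clipped to
    zlo <= z <= zhi (circular-segment formula)."""

    def below(h):  # area of the circle with z <= h
        u = np.clip((h - zc) / r, -1.0, 1.0)
        return r * r * (math.acos(-u) + u * math.sqrt(1 - u * u))

    return max(below(zhi) - below(zlo), 0.0)


def _filament_union_volume(fils: Sequence[Filament], env: Envelope | None, nq: int = 400) -> float:
    """Union volume of fused 0/90 filament stacks (mm^3).

    Each filament contributes its z-clipped cross-section area times its
    span length (exact).  Overlap is only possible between perpendicular
    filaments of vertically adjacent layers, and only inside the thin
    height window where both layer circles are active (width
    2r - pitch); those pairwise overlaps are integrated by quadrature
    and subtracted.  Parallel-band overlaps (ring-boundary slivers in
    graded designs) are neglected.
    """
    zlo, zhi = (0.0, env.height) if env is not None else (-math.inf, math.inf)
    total = sum(_clipped_circle_area(f.z, f.radius, zlo, zhi) * f.length for f in fils)

    layers: dict[tuple[int, float], list[Filament]] = {}
    for f in fils:
        layers.setdefault((f.axis, round(f.z, 9)), []).append(f)
    zs = sorted({zc for (_, zc) in layers})

    for z1, z2 in zip(zs, zs[1:]):
        r = layers[[k for k in layers if k[1] == z1][0]][0].radius
        wlo, whi = max(z2 - r, zlo), min(z1 + r, zhi)
        if whi <= wlo:
            continue
        xgrp = layers.get((0, z1), []) + layers.get((0, z2), [])
        ygrp = layers.get((1, z1), []) + layers.get((1, z2), [])
        if not xgrp or not ygrp:
            continue
        xb = np.array([[f.span[0], f.span[1], f.transverse, f.z] for f in xgrp])
        yb = np.array([[f.span[0], f.span[1], f.transverse, f.z] for f in ygrp])
        z = wlo + (np.arange(nq) + 0.5) * ((whi - wlo) / nq)
        wx = np.sqrt(np.clip(r * r - (z[:, None] - xb[None, :, 3]) ** 2, 0.0, None))  # (nq, m)
        wy = np.sqrt(np.clip(r * r - (z[:, None] - yb[None, :, 3]) ** 2, 0.0, None))  # (nq, n)
        # overlap of x-band i and y-band j at height z[k]:
        #   dx = |span_i  ∩  [t_j - wy, t_j + wy]|,  dy symmetric
        dx = np.minimum(xb[None, :, 1, None], yb[None, None, :, 2] + wy[:, None, :]) - np.maximum(
            xb[None, :, 0, None], yb[None, None, :, 2] - wy[:, None, :]
        )
        dy = np.minimum(xb[None, :, 2, None] + wx[:, :, None], yb[None, None, :, 1]) - np.maximum(
            xb[None, :, 2, None] - wx[:, :, None], yb[None, None, :, 0]
        )
        ov = (np.clip(dx, 0.0, None) * np.clip(dy, 0.0, None)).sum(axis=(1, 2))
        total -= float(ov.sum() * (whi - wlo) / nq)
    return float(total)


# --------------------------------------------------------------------------
# surface-area quadrature
# --------------------------------------------------------------------------


def _filament_union_area(
    fils: Sequence[Filament],
    env: Envelope | None,
    n_phi: int = 128,
    per_mm: float = 40.0,
) -> float:
    phi = (np.arange(n_phi) + 0.5) * (2 * math.pi / n_phi)
    cos_phi, sin_phi = np.cos(phi), np.sin(phi)
    ax = np.array([f.axis for f in fils])
    fz = np.array([f.z for f in fils])
    ft = np.array([f.transverse for f in fils])
    flo = np.array([f.span[0] for f in fils])
    fhi = np.array([f.span[1] for f in fils])
    total = 0.0
    for idx, f in enumerate(fils):
        n_t = max(4, int(round(f.length * per_mm)))
        dt = f.length / n_t
        t = f.span[0] + (np.arange(n_t) + 0.5) * dt
        zz = f.z + f.radius * sin_phi
        keep = np.ones((n_t, n_phi), dtype=bool)
        if env is not None:
            keep &= ((zz >= 0.0) & (zz <= env.height))[None, :]
        # only perpendicular filaments from vertically adjacent layers can
        # bury surface points; same-orientation layers are >= 2 pitches away
        cand = np.flatnonzero(
            (ax != f.axis)
            & (np.abs(fz - f.z) < 2 * f.radius)
            & (flo - 1e-12 <= f.transverse)
            & (f.transverse <= fhi + 1e-12)
        )
        for jdx in cand:
            g = fils[jdx]
            lo = np.searchsorted(t, g.transverse - g.radius)
            hi = np.searchsorted(t, g.transverse + g.radius)
            if lo >= hi:
                continue
            d2 = (t[lo:hi, None] - g.transverse) ** 2 + (zz[None, :] - g.z) ** 2
            keep[lo:hi] &= d2 > g.radius**2
        total += dt * (2 * math.pi * f.radius / n_phi) * keep.sum()
        # interior end caps (cuts not flush with the envelope boundary)
        for t_end in f.span:
            if _cap_on_envelope_boundary(f, t_end, env):
                continue
            if f.axis == 0:
                cx, cy = t_end, f.transverse
            else:
                cx, cy = f.transverse, t_end
            p_ax = np.where(ax == 0, cx, cy)  # cap centre along each candidate's axis
            p_tr = np.where(ax == 0, cy, cx)
            near = (
                (np.abs(fz - f.z) < 2 * f.radius)
                & (flo - f.radius <= p_ax)
                & (p_ax <= fhi + f.radius)
                & (np.abs(ft - p_tr) < 2 * f.radius)
            )
            near[idx] = False
            cand_caps = [fils[j] for j in np.flatnonzero(near)]
            total += _cap_area(f, t_end, cand_caps, env)
    return float(total)


def _cap_on_envelope_boundary(f: Filament, t_end: float, env: Envelope | None) -> bool:
    if env is None:
        return False
    if isinstance(env, BoxEnvelope):
        run = env.length if f.axis == 0 else env.width
        return t_end <= 1e-9 or t_end >= run - 1e-9
    # elliptic: cap planes at ring boundaries are interior except the
    # outermost ring's ends, which sit on the lateral enclosure wall
    a_t = env.semi_x if f.axis == 0 else env.semi_y
    a_s = env.semi_y if f.axis == 0 else env.semi_x
    rho = (t_end / a_t) ** 2 + (f.transverse / a_s) ** 2
    return rho >= 1.0 - 1e-6


def _cap_area(f: Filament, t_end: float, candidates: Sequence[Filament], env, n: int = 24) -> float:
    """Disc area at a flat cap, minus parts buried in nearby filaments."""
    u = (np.arange(n) + 0.5) / n * 2 - 1
    U, V = np.meshgrid(u, u, indexing="ij")
    inside = U**2 + V**2 <= 1.0
    s = f.transverse + f.radius * U[inside]
    zz = f.z + f.radius * V[inside]
    tt = np.full(s.shape, t_end)
    pts = np.column_stack([tt, s, zz]) if f.axis == 0 else np.column_stack([s, tt, zz])
    keep = np.ones(len(pts), dtype=bool)
    if env is not None:
        keep &= (pts[:, 2] >= 0.0) & (pts[:, 2] <= env.height)
    for g in candidates:
        if not keep.any():
            break
        keep[keep] &= ~g.contains(pts[keep])
    cell = (2 * f.radius / n) ** 2
    return float(cell * keep.sum())


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def compute_geometry_metrics(geometry, envelope: Envelope | None = None) -> GeometryMetrics:
    """Porosity, interface area and specific surface of a solid.

    ``geometry`` may be a :class:`SolidGeometry` (exact primitive
    integration) or a ``trimesh.Trimesh`` (mesh volume/area; the mesh
    must be watertight).  ``envelope`` defaults to the geometry's own.
    """
    try:  # optional mesh path
        import trimesh

        is_mesh = isinstance(geometry, trimesh.Trimesh)
    except ImportError:  # pragma: no cover
        is_mesh = False

    if is_mesh:
        if not geometry.is_watertight:
            raise ValueError("non-watertight mesh: open boundary edges prevent volume integration")
        v_mat = float(geometry.volume)
        sa = float(geometry.area)
        if envelope is None:
            ext = geometry.bounds[1] - geometry.bounds[0]
            envelope = BoxEnvelope(*ext)
    else:
        if envelope is None:
            envelope = geometry.envelope
        if envelope is None and geometry.primitives:
            raise ValueError("envelope: required when the geometry carries none")
        v_mat = geometry.volume()
        sa = geometry.surface_area()

    v_dom = envelope.volume if envelope is not None else 0.0
    if v_dom <= 0:
        raise ValueError("envelope: domain volume must be > 0")
    if v_mat > v_dom * (1 + 1e-6):
        raise ValueError("geometry does not fit inside the envelope (V_material > V_domain)")
    por = 1.0 - v_mat / v_dom
    return GeometryMetrics(
        V_domain=v_dom,
        V_material=v_mat,
        SA=sa,
        porosity=float(min(max(por, 0.0), 1.0)),
        specific_surface=sa / v_dom,
    )


# --------------------------------------------------------------------------
# STL export
# --------------------------------------------------------------------------


def export_stl(geometry: SolidGeometry, path, sections: int = 48):
    """Write the solid as a binary STL (mm units).

    Each filament/sphere is meshed separately and the meshes are
    concatenated; the export is a visual/CAD artifact and is never used
    for volume or area computation (those come from the primitives).
    """
    import trimesh
    from trimesh.creation import cylinder, icosphere

    meshes = []
    for p in geometry.primitives:
        if isinstance(p, Filament):
            m = cylinder(radius=p.radius, height=p.length, sections=sections)
            # trimesh cylinders are along z, centred at the origin
            mid = 0.5 * (p.span[0] + p.span[1])
            if p.axis == 0:
                m.apply_transform(trimesh.transformations.rotation_matrix(math.pi / 2, [0, 1, 0]))
                m.apply_translation([mid, p.transverse, p.z])
            else:
                m.apply_transform(trimesh.transformations.rotation_matrix(math.pi / 2, [1, 0, 0]))
                m.apply_translation([p.transverse, mid, p.z])
        else:
            m = icosphere(subdivisions=3, radius=p.radius)
            m.apply_translation(list(p.centre))
        meshes.append(m)
    combined = trimesh.util.concatenate(meshes) if meshes else trimesh.Trimesh()
    combined.export(path, file_type="stl")
    return combined
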