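"""Steady incompressible flow through voxel domains.

The solver integrates the laminar incompressible Navier–Stokes
equations (no body force) to steady state on a marker-and-cell (MAC)
staggered grid: velocity components live on voxel faces, pressure at
voxel centres.  Steadiness is reached by artificial-compressibility
pseudo-time marching: pressure obeys dp/dt = -rho c^2 div(u) with an
artificial sound speed c, so at convergence the discrete divergence
vanishes identically and the velocity field satisfies the steady
momentum balance.  The scheme is explicit, matrix-free (pure numpy
stencils), fully deterministic (zero initial field, no random state)
and second-order in the interior, with walls resolved halfway across
voxel faces.

At the perfusion conditions modelled here the interstitial Reynolds
number is well below one, so the flow is laminar and nearly linear; the
advective term is retained by default but is a small correction.

All quantities in this module are SI (m, s, Pa); voxel spacings carried
in mm by the geometry layer are converted once on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .voxel import VoxelDomain

__all__ = [
    "FluidProperties",
    "SolverConfig",
    "FlowSolution",
    "solve_steady_flow",
    "check_convergence",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants; defaults are blood at body temperature."""

    density: float = 1056.0  # kg/m^3
    dynamic_viscosity: float = 0.0045  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density: must be > 0")
        if self.dynamic_viscosity <= 0:
            raise ValueError("dynamic_viscosity: must be > 0")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density

    @classmethod
    def blood(cls) -> "FluidProperties":
        return cls()


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the steady solve.

    ``convergence_tolerance`` bounds the RMS steady-state momentum
    residual (normalised by the viscous scale mu*u_in/h^2);
    ``velocity_change_tolerance`` bounds the relative change of the
    velocity field between successive convergence checks.  Both must
    hold simultaneously.
    """

    inlet_velocity: float  # m/s, uniform plug over the inlet face
    convergence_tolerance: float = 1e-4
    velocity_change_tolerance: float = 1e-6
    max_iterations: int = 400_000
    check_every: int = 200
    include_advection: bool = True
    cfl: float = 0.7
    pseudo_sound_speed: float | None = None  # m/s; derived from grid if None
    backend: str = "auto"  # "auto" | "numba" | "numpy" (reference stencils)
    ramp_steps: int | None = None  # smooth inlet switch-on; None -> ~2 acoustic transits

    def __post_init__(self) -> None:
        if self.inlet_velocity <= 0:
            raise ValueError("inlet_velocity: must be > 0")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance: must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations: must be >= 1")


@dataclass
class FlowSolution:
    """Steady velocity/pressure fields on the staggered voxel grid.

    ``u, v, w`` are face-normal velocities (m/s) with shapes
    (nx+1,ny,nz), (nx,ny+1,nz), (nx,ny,nz+1); ``p`` is cell pressure
    (Pa) with the outlet-plane mean removed (zero-resistance outlet).
    """

    domain: VoxelDomain
    fluid: FluidProperties
    config: SolverConfig
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    residual_history: list
    converged: bool
    iterations: int

    @property
    def h(self) -> float:
        """Grid spacing in metres."""
        return self.domain.spacing * 1e-3

    def cell_velocity(self) -> np.ndarray:
        """Cell-centred velocity vectors, shape (nx, ny, nz, 3)."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        out = np.stack([uc, vc, wc], axis=-1)
        out[self.domain.solid] = 0.0
        return out

    def divergence(self) -> np.ndarray:
        """Discrete divergence per fluid cell, 1/s."""
        div = (
            np.diff(self.u, axis=0) + np.diff(self.v, axis=1) + np.diff(self.w, axis=2)
        ) / self.h
        div[self.domain.solid] = 0.0
        return div

    def flux(self, k: int) -> float:
        """Volumetric flux (m^3/s) through the z-face plane k."""
        return float(self.w[:, :, k].sum()) * self.h**2

    def mass_imbalance(self) -> float:
        """|inlet flux - outlet flux| / inlet flux."""
        qin = self.flux(0)
        qout = self.flux(self.w.shape[2] - 1)
        return abs(qin - qout) / abs(qin)

    def superficial_velocity(self) -> float:
        """Mean axial velocity over the full duct cross-section, m/s."""
        nx, ny, _ = self.domain.shape
        return self.flux(0) / (nx * ny * self.h**2)


def check_convergence(
    residual_history: Sequence,
    tolerance: float = 1e-4,
    change_tolerance: float = 1e-6,
) -> bool:
    """Decide convergence from a residual trace.

    Entries are either scalars (RMS momentum residual) or
    ``(residual, velocity_change)`` pairs.  Converged when the latest
    residual is below ``tolerance`` and, when change data is present,
    the latest relative velocity change is below ``change_tolerance``
    — both criteria must hold simultaneously.
    """
    if len(residual_history) < 2:
        raise ValueError("need at least 2 recorded residuals")
    last = residual_history[-1]
    if np.ndim(last) == 0:
        res, change = float(last), None
    else:
        res, change = float(last[0]), float(last[1])
    ok = res < tolerance
    if change is not None:
        ok = ok and change < change_tolerance
    return bool(ok)


# --------------------------------------------------------------------------
# solver internals
# --------------------------------------------------------------------------


def _face_masks(domain: VoxelDomain):
    """Active-face masks and tangential ghost-correction counts.

    A face is active (an unknown) when both adjacent cells are fluid.
    In the viscous stencil, a missing *normal* neighbour face lies
    exactly on a wall and its stored zero is the correct Dirichlet
    value; a missing *tangential* neighbour lies one voxel past a wall
    running halfway between samples, so its ghost value is -u
    (no-slip) or +u (symmetry/outflow mirror).  The counts returned
    here add those corrections to the zero-filled neighbour sums.
    """
    F = domain.fluid
    nx, ny, nz = F.shape
    lat = domain.lateral
    per_x = lat["x"] == "periodic"
    per_y = lat["y"] == "periodic"

    u_act = np.zeros((nx + 1, ny, nz), dtype=bool)
    u_act[1:nx] = F[:-1] & F[1:]
    if per_x:
        u_act[0] = u_act[nx] = F[-1] & F[0]
    v_act = np.zeros((nx, ny + 1, nz), dtype=bool)
    v_act[:, 1:ny] = F[:, :-1] & F[:, 1:]
    if per_y:
        v_act[:, 0] = v_act[:, ny] = F[:, -1] & F[:, 0]
    w_act = np.zeros((nx, ny, nz + 1), dtype=bool)
    w_act[:, :, 1:nz] = F[:, :, :-1] & F[:, :, 1:]
    # inlet (k=0) is Dirichlet, outlet (k=nz) is zero-gradient: not unknowns

    u_wall, u_sym = _tangential_counts(u_act, (1, 2), lat)
    v_wall, v_sym = _tangential_counts(v_act, (0, 2), lat)
    w_wall, w_sym = _tangential_counts(w_act, (0, 1), lat)
    return (u_act, v_act, w_act), (u_wall, v_wall, w_wall), (u_sym, v_sym, w_sym)


def _shift(a: np.ndarray, ax: int, step: int, periodic: bool) -> np.ndarray:
    """Neighbour values of ``a`` shifted by ``step`` along ``ax``,
    zero-filled (or wrapped when periodic)."""
    if periodic:
        return np.roll(a, -step, axis=ax)
    out = np.zeros_like(a)
    n = a.shape[ax]
    dst = [slice(None)] * a.ndim
    src = [slice(None)] * a.ndim
    if step > 0:
        dst[ax] = slice(0, n - step)
        src[ax] = slice(step, None)
    else:
        dst[ax] = slice(-step, None)
        src[ax] = slice(0, n + step)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _shift_face(a: np.ndarray, ax: int, step: int, periodic: bool) -> np.ndarray:
    """Neighbour values for a *face-normal* component along its own axis.

    The array carries n+1 faces for n cells; under periodicity face n is
    the image of face 0, so wrapped indexing must use period n, not n+1.
    """
    if not periodic:
        return _shift(a, ax, step, False)
    n = a.shape[ax] - 1
    idx = (np.arange(n + 1) + step) % n
    return np.take(a, idx, axis=ax)


def _tangential_counts(act: np.ndarray, tang_axes: tuple[int, int], lat) -> tuple[np.ndarray, np.ndarray]:
    """Per-face counts of tangential neighbours that are wall ghosts (-u)
    or mirror ghosts (+u)."""
    wall = np.zeros(act.shape, dtype=np.int8)
    sym = np.zeros(act.shape, dtype=np.int8)
    for ax in tang_axes:
        if ax == 2:
            bc_lo, bc_hi = "inlet", "outflow"
            periodic = False
        else:
            bc = lat["x" if ax == 0 else "y"]
            periodic = bc == "periodic"
            bc_lo = bc_hi = bc
        for step, bc_side in ((1, bc_hi), (-1, bc_lo)):
            nb = _shift(act, ax, step, periodic)
            missing = act & ~nb
            if periodic:
                wall += missing.astype(np.int8)
                continue
            # split boundary faces from interior misses
            n = act.shape[ax]
            edge = [slice(None)] * 3
            edge[ax] = n - 1 if step > 0 else 0
            edge_mask = np.zeros(act.shape, dtype=bool)
            edge_mask[tuple(edge)] = True
            interior_missing = missing & ~edge_mask
            wall += interior_missing.astype(np.int8)
            at_edge = act & edge_mask
            if bc_side in ("wall", "inlet"):
                wall += at_edge.astype(np.int8)
            else:  # symmetry plane or outflow mirror: ghost = +u
                sym += at_edge.astype(np.int8)
    return wall, sym


def solve_steady_flow(
    domain: VoxelDomain,
    fluid: FluidProperties,
    config: SolverConfig,
    initial: "FlowSolution | None" = None,
) -> FlowSolution:
    """March the flow to steady state and return the converged fields.

    Uniform plug velocity is imposed on the inlet face, zero-gradient
    outflow with zero reference pressure on the outlet, no-slip on all
    solid surfaces, and wall / periodic / symmetry conditions on the
    lateral boundaries as labelled in the domain.

    ``initial`` warm-starts the march from a previous solution on the
    same domain (scaled to the new inlet velocity), which shortens
    velocity sweeps considerably; the converged state is independent of
    the start.

    Raises ``ValueError`` for an impermeable domain.  If the residual
    targets are not met within ``max_iterations`` the best solution is
    returned with ``converged=False`` and a warning.
    """
    F = domain.fluid
    if not F[:, :, 0].any() or not F[:, :, -1].any():
        raise ValueError("impermeable domain: no fluid on the inlet or outlet face")
    # connectivity: any fluid on the outlet face must be reachable
    from scipy import ndimage

    labels, _ = ndimage.label(F, structure=ndimage.generate_binary_structure(3, 1))
    inlet_l = set(np.unique(labels[:, :, 0])) - {0}
    outlet_l = set(np.unique(labels[:, :, -1])) - {0}
    if not (inlet_l & outlet_l):
        raise ValueError("impermeable domain: no fluid path connects inlet to outlet")

    nx, ny, nz = F.shape
    h = domain.spacing * 1e-3
    nu = fluid.kinematic_viscosity
    rho = fluid.density
    u_in = config.inlet_velocity

    (u_act, v_act, w_act), (u_wall, v_wall, w_wall), (u_sym, v_sym, w_sym) = _face_masks(domain)
    per_x = domain.lateral["x"] == "periodic"
    per_y = domain.lateral["y"] == "periodic"

    inlet_mask = F[:, :, 0]
    if initial is not None:
        if initial.u.shape != (nx + 1, ny, nz):
            raise ValueError("initial: field shapes do not match the domain")
        ratio = u_in / initial.config.inlet_velocity
        u = initial.u * ratio
        v = initial.v * ratio
        w = initial.w * ratio
        p = initial.p * ratio
    else:
        u = np.zeros((nx + 1, ny, nz))
        v = np.zeros((nx, ny + 1, nz))
        w = np.zeros((nx, ny, nz + 1))
        p = np.zeros((nx, ny, nz))

    c = config.pseudo_sound_speed
    if c is None:
        c = max(5.0 * nu / h, 15.0 * u_in)
    dt = config.cfl * min(h * h / (6.0 * nu), h / (np.sqrt(3.0) * c), 0.25 * h / (6.0 * u_in))
    c2rho = rho * c * c

    # A sudden plug start excites weakly damped pseudo-acoustic standing
    # waves; switching the inlet on over a couple of wave transits keeps
    # their amplitude negligible.  The steady state is unaffected.
    ramp_steps = config.ramp_steps
    if ramp_steps is None:
        ramp_steps = 0 if initial is not None else int(2.0 * (nz * h) / (c * dt)) + 1

    Ffl = F.astype(float)
    scale = nu * u_in / (h * h)  # viscous momentum scale for residual normalisation
    history: list[tuple[float, float]] = []
    prev_snapshot = None
    converged = False
    it = 0

    use_numba = config.backend != "numpy" and _kernels.HAVE_NUMBA
    if use_numba:
        du = np.zeros_like(u)
        dv = np.zeros_like(v)
        dw = np.zeros_like(w)
        u_act8 = u_act.astype(np.uint8)
        v_act8 = v_act.astype(np.uint8)
        w_act8 = w_act.astype(np.uint8)
        F8 = F.astype(np.uint8)
        uw = u_wall.astype(np.float64)
        vw = v_wall.astype(np.float64)
        ww = w_wall.astype(np.float64)
        us = u_sym.astype(np.float64)
        vs = v_sym.astype(np.float64)
        ws = w_sym.astype(np.float64)

    def lap(a, wall_cnt, sym_cnt, normal_ax):
        s = np.zeros_like(a)
        for ax, per in ((0, per_x), (1, per_y), (2, False)):
            sh = _shift_face if ax == normal_ax else _shift
            s += sh(a, ax, 1, per) + sh(a, ax, -1, per)
        return s - (6.0 + wall_cnt - sym_cnt) * a

    while it < config.max_iterations:
        it += 1
        if it < ramp_steps:
            u_now = u_in * 0.5 * (1.0 - np.cos(np.pi * it / ramp_steps))
        else:
            u_now = u_in
        if use_numba:
            _kernels.momentum_kernel(
                u, v, w, p, du, dv, dw,
                u_act8, v_act8, w_act8,
                uw, vw, ww, us, vs, ws,
                h, nu, rho, per_x, per_y, config.include_advection,
            )
            res_ss, res_n = _kernels.apply_kernel(u, v, w, du, dv, dw, u_act8, v_act8, w_act8, dt)
            w[:, :, nz] = w[:, :, nz - 1]
            w[:, :, 0] = u_now * inlet_mask
            if per_x:
                u[nx] = u[0]
            if per_y:
                v[:, ny] = v[:, 0]
            _kernels.pressure_kernel(u, v, w, p, F8, h, dt * c2rho)
        else:
            # -- pressure gradients on faces -------------------------------
            if per_x:
                gpx = p - np.roll(p, 1, axis=0)  # face i between cells i-1, i
                gpx = np.concatenate([gpx, gpx[:1]], axis=0)
            else:
                gpx = np.zeros_like(u)
                gpx[1:nx] = p[1:] - p[:-1]
            if per_y:
                gpy = p - np.roll(p, 1, axis=1)
                gpy = np.concatenate([gpy, gpy[:, :1]], axis=1)
            else:
                gpy = np.zeros_like(v)
                gpy[:, 1:ny] = p[:, 1:] - p[:, :-1]
            gpz = np.zeros_like(w)
            gpz[:, :, 1:nz] = p[:, :, 1:] - p[:, :, :-1]

            # -- momentum --------------------------------------------------
            du = nu * lap(u, u_wall, u_sym, 0) / (h * h) - gpx / (rho * h)
            dv = nu * lap(v, v_wall, v_sym, 1) / (h * h) - gpy / (rho * h)
            dw = nu * lap(w, w_wall, w_sym, 2) / (h * h) - gpz / (rho * h)
            if config.include_advection:
                au, av, aw = _advection(u, v, w, h, per_x, per_y)
                du -= au
                dv -= av
                dw -= aw

            u += dt * du * u_act
            v += dt * dv * v_act
            w[:, :, 1:nz] += dt * dw[:, :, 1:nz] * w_act[:, :, 1:nz]
            # zero-gradient outflow, fixed plug inflow
            w[:, :, nz] = w[:, :, nz - 1]
            w[:, :, 0] = u_now * inlet_mask
            if per_x:
                u[nx] = u[0]
            if per_y:
                v[:, ny] = v[:, 0]

            # -- artificial compressibility --------------------------------
            div = (np.diff(u, axis=0) + np.diff(v, axis=1) + np.diff(w, axis=2)) / h
            p -= dt * c2rho * div * Ffl
            res_ss, res_n = None, None

        if (it % config.check_every == 0 and it >= ramp_steps) or it == config.max_iterations:
            if res_ss is not None:
                res = np.sqrt(res_ss / max(res_n, 1)) / scale
            else:
                res = _momentum_residual(du, dv, dw, u_act, v_act, w_act, nz) / scale
            snap = np.concatenate([u[u_act], v[v_act], w[w_act]])
            if prev_snapshot is not None and snap.shape == prev_snapshot.shape:
                denom = float(np.linalg.norm(snap)) or 1.0
                change = float(np.linalg.norm(snap - prev_snapshot)) / denom
            else:
                change = np.inf
            prev_snapshot = snap
            history.append((float(res), change))
            if len(history) >= 2 and check_convergence(
                history, config.convergence_tolerance, config.velocity_change_tolerance
            ):
                converged = True
                break

    if not converged:
        import warnings

        warnings.warn(
            f"steady solve not converged after {it} iterations "
            f"(residual {history[-1][0]:.3e}, change {history[-1][1]:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )

    # zero-resistance outlet: report pressures relative to the outlet plane
    out_plane = p[:, :, nz - 1][F[:, :, nz - 1]]
    if out_plane.size:
        p = p - out_plane.mean()
    p = p * Ffl

    return FlowSolution(
        domain=domain,
        fluid=fluid,
        config=config,
        u=u,
        v=v,
        w=w,
        p=p,
        residual_history=history,
        converged=converged,
        iterations=it,
    )


def _momentum_residual(du, dv, dw, u_act, v_act, w_act, nz) -> float:
    parts = [du[u_act], dv[v_act], dw[:, :, 1:nz][w_act[:, :, 1:nz]]]
    n = sum(pp.size for pp in parts)
    ss = sum(float((pp * pp).sum()) for pp in parts)
    return np.sqrt(ss / max(n, 1))


def _to_corner(a: np.ndarray, ax: int, periodic: bool) -> np.ndarray:
    """Interpolate a field with cell-count extent n along ``ax`` to the
    n+1 face/corner positions: c[i] = (a[i-1] + a[i]) / 2.

    Beyond a non-periodic boundary the missing value is taken as zero
    (no-slip / quiescent ghost)."""
    n = a.shape[ax]
    shp = list(a.shape)
    shp[ax] = n + 1
    out = np.zeros(shp)
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[ax] = slice(0, n)
    hi[ax] = slice(1, n + 1)
    out[tuple(lo)] += 0.5 * a
    out[tuple(hi)] += 0.5 * a
    if periodic:
        first = [slice(None)] * 3
        last = [slice(None)] * 3
        first[ax] = 0
        last[ax] = n
        seam = out[tuple(first)] + out[tuple(last)]
        out[tuple(first)] = seam
        out[tuple(last)] = seam
    return out


def _face_diff(f: np.ndarray, ax: int, periodic: bool) -> np.ndarray:
    """Difference of a cell-centred field onto the n+1 faces along ``ax``
    (zero on non-periodic boundary faces, which are never unknowns)."""
    n = f.shape[ax]
    shp = list(f.shape)
    shp[ax] = n + 1
    out = np.zeros(shp)
    mid = [slice(None)] * 3
    mid[ax] = slice(1, n)
    hi = [slice(None)] * 3
    hi[ax] = slice(1, None)
    lo = [slice(None)] * 3
    lo[ax] = slice(0, n - 1)
    out[tuple(mid)] = f[tuple(hi)] - f[tuple(lo)]
    if periodic:
        first = [slice(None)] * 3
        last = [slice(None)] * 3
        first[ax] = 0
        last[ax] = n
        e0 = [slice(None)] * 3
        e0[ax] = 0
        e1 = [slice(None)] * 3
        e1[ax] = n - 1
        seam = f[tuple(e0)] - f[tuple(e1)]
        out[tuple(first)] = seam
        out[tuple(last)] = seam
    return out


def _advection(u, v, w, h, per_x, per_y):
    """Conservative centred advective flux divergence on the staggered
    grid, one array per momentum component.

    Products are formed from linear interpolations of the face fields;
    values beyond walls enter as zeros.  The term is a small correction
    at the creeping-flow conditions of interest.
    """
    # cell-centred squares
    uc = 0.5 * (u[:-1] + u[1:])
    vc = 0.5 * (v[:, :-1] + v[:, 1:])
    wc = 0.5 * (w[:, :, :-1] + w[:, :, 1:])

    # u momentum: d(uu)/dx on u-faces + corner fluxes in y, z
    au = _face_diff(uc**2, 0, per_x) / h
    fy = _to_corner(v, 0, per_x) * _to_corner(u, 1, per_y)  # (nx+1, ny+1, nz)
    au += np.diff(fy, axis=1) / h
    fz = _to_corner(w, 0, per_x) * _to_corner(u, 2, False)  # (nx+1, ny, nz+1)
    au += np.diff(fz, axis=2) / h

    # v momentum
    av = _face_diff(vc**2, 1, per_y) / h
    fx = _to_corner(u, 1, per_y) * _to_corner(v, 0, per_x)
    av += np.diff(fx, axis=0) / h
    fz = _to_corner(w, 1, per_y) * _to_corner(v, 2, False)
    av += np.diff(fz, axis=2) / h

    # w momentum
    aw = _face_diff(wc**2, 2, False) / h
    fx = _to_corner(u, 2, False) * _to_corner(w, 0, per_x)
    aw += np.diff(fx, axis=0) / h
    fy = _to_corner(v, 2, False) * _to_corner(w, 1, per_y)
    aw += np.diff(fy, axis=1) / h

    return au, av, aw
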