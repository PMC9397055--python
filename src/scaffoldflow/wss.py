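"""Wall shear stress on scaffold surfaces and the viability indicator.

The mechanical stimulus a perfused scaffold delivers to attached cells
is the viscous wall shear stress tau_w = mu * du_t/dn, the normal
gradient of the tangential velocity at the wall.  Shear below about
30 mPa is compatible with marrow-derived stromal cell proliferation and
differentiation, while higher values are detrimental, so the fraction
of the scaffold surface below a shear threshold serves as a simple
cell-viability indicator.  Narrower literature bands (0.11-10 mPa
osteogenic stimulation, 0.55-24 mPa mineralisation) can be reported as
additional histogram bands but carry no special logic.

Wall elements are the voxel faces separating fluid from scaffold
material.  The normal derivative is one-sided into the fluid: the
nearest tangential velocity sample sits h/2 off the wall, giving the
first-order estimate tau_w = mu * |u_t| / (h/2); a second-order
two-sample variant is available behind a switch.  All stresses are Pa
(SI); areas are m^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import FlowSolution, FluidProperties
from .voxel import VoxelDomain

__all__ = [
    "WallStressField",
    "ViabilitySummary",
    "compute_wss",
    "viability_fraction",
    "wss_histogram",
    "WSS_VIABILITY_THRESHOLD",
]

#: Default viability cut-off, Pa (30 mPa).
WSS_VIABILITY_THRESHOLD = 0.030


@dataclass
class WallStressField:
    """Per-element wall shear stress on the scaffold surface.

    ``positions`` are face centres (m), ``normals`` outward unit
    normals (pointing into the fluid), ``areas`` element areas (m^2),
    ``tau`` shear magnitudes (Pa).  ``n_orphaned`` counts candidate
    wall faces excluded because their fluid neighbour was removed by
    the connectivity filter.
    """

    positions: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    tau: np.ndarray
    n_orphaned: int = 0

    def __len__(self) -> int:
        return len(self.tau)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def mean_tau(self) -> float:
        """Area-weighted mean shear, Pa."""
        return float((self.tau * self.areas).sum() / self.total_area)

    def max_tau(self) -> float:
        return float(self.tau.max()) if len(self.tau) else 0.0


@dataclass(frozen=True)
class ViabilitySummary:
    """Share of wall surface below a shear threshold, plus a histogram.

    ``viable_fraction`` is the percentage of total wall *surface area*
    with tau_w strictly below ``threshold``.  ``bin_edges`` (Pa) and
    ``percentages`` describe the area-weighted shear histogram.
    """

    threshold: float
    viable_fraction: float
    bin_edges: np.ndarray
    percentages: np.ndarray


def compute_wss(
    solution: FlowSolution,
    domain: VoxelDomain | None = None,
    fluid: FluidProperties | None = None,
    second_order: bool = False,
    include_enclosure: bool = False,
) -> WallStressField:
    """Evaluate tau_w on every fluid-facing scaffold voxel face.

    For a face with normal along axis ``a``, the tangential velocity is
    sampled at the adjacent fluid cell centre (distance h/2), from the
    face-velocity averages of the two tangential components;
    ``second_order=True`` additionally uses the next cell out (3h/2)
    when it is fluid: du/dn|_0 = (9 u1 - u2) / (3 h).

    ``include_enclosure=True`` also returns elements on non-scaffold
    solid (duct walls); scaffold-only is the default used by the
    viability metric.
    """
    domain = domain or solution.domain
    fluid = fluid or solution.fluid
    mu = fluid.dynamic_viscosity
    h = solution.h
    F = domain.fluid
    target = domain.solid if include_enclosure else domain.scaffold
    vel = solution.cell_velocity()  # (nx,ny,nz,3)

    pos, nrm, tau = [], [], []
    n_orphaned = 0
    excluded = domain.excluded
    nx, ny, nz = domain.shape
    tang = {0: (1, 2), 1: (0, 2), 2: (0, 1)}

    for ax in range(3):
        for sign in (+1, -1):
            # fluid cell at index, solid neighbour one step along +-ax
            sol_sl = [slice(None)] * 3
            flu_sl = [slice(None)] * 3
            if sign > 0:
                flu_sl[ax] = slice(0, -1)
                sol_sl[ax] = slice(1, None)
            else:
                flu_sl[ax] = slice(1, None)
                sol_sl[ax] = slice(0, -1)
            pair = F[tuple(flu_sl)] & target[tuple(sol_sl)]
            if excluded is not None:
                # faces whose only adjacent "fluid" was a disconnected pocket
                n_orphaned += int((excluded[tuple(flu_sl)] & target[tuple(sol_sl)]).sum())
            idx = np.argwhere(pair)
            if idx.size == 0:
                continue
            if sign < 0:
                idx[:, ax] += 1  # fluid cell index in full grid
            t1, t2 = tang[ax]
            cells = tuple(idx.T)
            ut1 = vel[cells + (t1,)]
            ut2 = vel[cells + (t2,)]
            if second_order:
                idx2 = idx.copy()
                idx2[:, ax] -= sign  # next cell away from the wall
                valid = (idx2[:, ax] >= 0) & (idx2[:, ax] < F.shape[ax])
                idx2[:, ax] = np.clip(idx2[:, ax], 0, F.shape[ax] - 1)
                far_fluid = F[tuple(idx2.T)] & valid
                f1 = vel[tuple(idx2.T) + (t1,)]
                f2 = vel[tuple(idx2.T) + (t2,)]
                g1 = np.where(far_fluid, (9 * ut1 - f1) / (3 * h), ut1 / (0.5 * h))
                g2 = np.where(far_fluid, (9 * ut2 - f2) / (3 * h), ut2 / (0.5 * h))
            else:
                g1 = ut1 / (0.5 * h)
                g2 = ut2 / (0.5 * h)
            t = mu * np.sqrt(g1**2 + g2**2)
            tau.append(t)
            centre = (idx + 0.5) * h
            centre[:, ax] += sign * 0.5 * h  # face centre
            pos.append(centre)
            n = np.zeros((len(idx), 3))
            n[:, ax] = -sign  # outward from solid = towards the fluid cell
            nrm.append(n)

    if not tau:
        return WallStressField(
            positions=np.zeros((0, 3)),
            normals=np.zeros((0, 3)),
            areas=np.zeros(0),
            tau=np.zeros(0),
        )
    tau_all = np.concatenate(tau)
    return WallStressField(
        positions=np.concatenate(pos),
        normals=np.concatenate(nrm),
        areas=np.full(tau_all.shape, h * h),
        tau=tau_all,
        n_orphaned=n_orphaned,
    )


def viability_fraction(wss: WallStressField, threshold: float = WSS_VIABILITY_THRESHOLD) -> ViabilitySummary:
    """Area-weighted percentage of wall surface with tau_w strictly
    below ``threshold`` (Pa), with a default decade histogram."""
    if threshold <= 0:
        raise ValueError("threshold: must be > 0")
    if len(wss) == 0:
        raise ValueError("empty wall stress field")
    frac = 100.0 * float(wss.areas[wss.tau < threshold].sum()) / wss.total_area
    top = max(wss.max_tau() * 1.0000001, threshold * 2)
    edges = np.array([0.0, threshold / 3, threshold, top])
    hist = wss_histogram(wss, edges)
    return ViabilitySummary(
        threshold=threshold,
        viable_fraction=frac,
        bin_edges=edges,
        percentages=hist,
    )


def wss_histogram(wss: WallStressField, bin_edges) -> np.ndarray:
    """Area-weighted percentage of wall surface per shear bin.

    Bins are half-open [lo, hi); the final bin is closed so the full
    surface is always accounted for when the last edge reaches the
    maximum stress.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges: need >= 2 strictly increasing edges")
    if len(wss) == 0:
        raise ValueError("empty wall stress field")
    nb = len(edges) - 1
    which = np.digitize(wss.tau, edges) - 1
    which[wss.tau == edges[-1]] = nb - 1  # closed final bin
    out = np.zeros(nb)
    ok = (which >= 0) & (which < nb)
    np.add.at(out, which[ok], wss.areas[ok])
    return 100.0 * out / wss.total_area
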