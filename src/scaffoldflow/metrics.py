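"""Perfusion metrics: pressure drop, Darcy permeability, Reynolds
number, velocity sweeps and design-comparison summaries.

For creeping flow through a porous slab of thickness L, Darcy's law
relates the superficial velocity u to the pressure drop:

    k0 = u * mu * L / dP        (intrinsic permeability, m^2)

The relation holds while the interstitial Reynolds number
Re = rho * u * d / mu (d = pore size) stays below about 8.6; above
that, inertial losses make the apparent permeability velocity-dependent
and the estimate is flagged invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .flow import FlowSolution, FluidProperties, SolverConfig, solve_steady_flow
from .voxel import VoxelDomain
from .wss import WSS_VIABILITY_THRESHOLD, compute_wss, viability_fraction

__all__ = [
    "PerfusionReport",
    "pressure_drop",
    "darcy_permeability",
    "reynolds_number",
    "darcy_validity",
    "velocity_sweep",
    "summarize_table",
    "reference_viability_table",
    "DARCY_REYNOLDS_LIMIT",
    "DEFAULT_VELOCITIES_MM_S",
]

#: Interstitial Reynolds number above which Darcy's law is invalid.
DARCY_REYNOLDS_LIMIT = 8.6

#: Standard inlet-velocity grid, mm/s.
DEFAULT_VELOCITIES_MM_S = (1.0, 3.0, 5.0, 7.0, 9.0)


@dataclass
class PerfusionReport:
    """Metrics of one (scaffold, inlet velocity) perfusion condition."""

    scaffold_id: str
    inlet_velocity: float  # m/s
    pressure_drop: float | None = None  # Pa
    permeability: float | None = None  # m^2
    reynolds: float | None = None
    darcy_valid: bool | None = None
    mean_wss: float | None = None  # Pa
    max_wss: float | None = None  # Pa
    viable_fraction: float | None = None  # % of wall area below threshold
    converged: bool = False
    failed: bool = False
    error: str | None = None

    def as_row(self) -> dict:
        """Flat record with I/O units (mm/s, mPa)."""
        return {
            "scaffold": self.scaffold_id,
            "u_mm_s": round(self.inlet_velocity * 1e3, 9),
            "dP_Pa": self.pressure_drop,
            "k0_m2": self.permeability,
            "Re": self.reynolds,
            "darcy_valid": self.darcy_valid,
            "mean_wss_mPa": None if self.mean_wss is None else self.mean_wss * 1e3,
            "max_wss_mPa": None if self.max_wss is None else self.max_wss * 1e3,
            "viable_pct": self.viable_fraction,
            "converged": self.converged,
            "failed": self.failed,
        }


def pressure_drop(solution: FlowSolution, domain: VoxelDomain | None = None) -> float:
    """Pressure drop across the scaffold slab, Pa.

    Plane-averaged pressure on the probe planes one voxel upstream and
    one voxel downstream of the scaffold extent (plane averages rather
    than point probes, to suppress voxel-scale noise).
    """
    domain = domain or solution.domain
    k0, k1 = domain.scaffold_range
    nzc = domain.shape[2]
    ku, kd = k0 - 1, k1
    if ku < 0 or kd >= nzc:
        raise ValueError("probe plane outside domain: scaffold touches the domain ends")
    F = domain.fluid
    up = solution.p[:, :, ku][F[:, :, ku]]
    dn = solution.p[:, :, kd][F[:, :, kd]]
    if up.size == 0 or dn.size == 0:
        raise ValueError("probe plane outside domain: no fluid on a probe plane")
    return float(up.mean() - dn.mean())


def darcy_permeability(u: float, mu: float, L: float, dP: float) -> float:
    """Intrinsic permeability k0 = u*mu*L/dP (SI units in, m^2 out)."""
    if L <= 0:
        raise ValueError("L: scaffold length must be > 0")
    if dP <= 0:
        raise ValueError("no resistance measured: pressure drop must be > 0")
    return u * mu * L / dP


def reynolds_number(rho: float, u: float, d: float, mu: float) -> float:
    """Interstitial Reynolds number Re = rho*u*d/mu (d = pore size, m)."""
    if u == 0:
        return 0.0
    if rho <= 0 or u < 0 or d <= 0 or mu <= 0:
        raise ValueError("reynolds_number: all inputs must be positive")
    return rho * u * d / mu


def darcy_validity(Re: float) -> bool:
    """Darcy's law is taken as valid up to and including Re = 8.6."""
    if Re < 0:
        raise ValueError("Re: must be >= 0")
    return Re <= DARCY_REYNOLDS_LIMIT


def velocity_sweep(
    domain: VoxelDomain,
    fluid: FluidProperties,
    velocities: "list[float] | tuple[float, ...]" = None,
    pore_sizes: "list[float] | float | None" = None,
    scaffold_id: str = "scaffold",
    wss_threshold: float = WSS_VIABILITY_THRESHOLD,
    config_template: SolverConfig | None = None,
    warm_start: bool = True,
) -> list[PerfusionReport]:
    """Solve the domain over an inlet-velocity grid and report metrics.

    ``velocities`` are in m/s (default 1-9 mm/s grid).  ``pore_sizes``
    feed the Reynolds number; for graded designs the maximum pore gives
    a conservative validity check.  A failed solve does not abort the
    sweep: the entry is flagged and the remaining velocities run.
    Successive solves warm-start from the previous velocity.
    """
    if velocities is None:
        velocities = [v * 1e-3 for v in DEFAULT_VELOCITIES_MM_S]
    velocities = sorted(float(v) for v in velocities)
    if not velocities or any(v <= 0 for v in velocities):
        raise ValueError("velocities: need a non-empty list of positive velocities")
    d_max = None if pore_sizes is None else float(np.max(pore_sizes))

    reports: list[PerfusionReport] = []
    prev = None
    for vel in velocities:
        rep = PerfusionReport(scaffold_id=scaffold_id, inlet_velocity=vel)
        try:
            if config_template is None:
                cfg = SolverConfig(inlet_velocity=vel)
            else:
                cfg = replace(config_template, inlet_velocity=vel)
            sol = solve_steady_flow(domain, fluid, cfg, initial=prev if warm_start else None)
            if warm_start:
                prev = sol
            rep.converged = sol.converged
            dP = pressure_drop(sol, domain)
            rep.pressure_drop = dP
            L = domain.L * 1e-3
            rep.permeability = darcy_permeability(vel, fluid.dynamic_viscosity, L, dP)
            if d_max is not None:
                rep.reynolds = reynolds_number(fluid.density, vel, d_max * 1e-3, fluid.dynamic_viscosity)
                rep.darcy_valid = darcy_validity(rep.reynolds)
            field = compute_wss(sol, domain, fluid)
            rep.mean_wss = field.mean_tau()
            rep.max_wss = field.max_tau()
            rep.viable_fraction = viability_fraction(field, wss_threshold).viable_fraction
        except Exception as exc:  # noqa: BLE001 - sweep must survive single failures
            rep.failed = True
            rep.error = str(exc)
            warnings.warn(f"sweep entry at {vel * 1e3:g} mm/s failed: {exc}", RuntimeWarning, stacklevel=2)
        reports.append(rep)
    return reports


def reports_frame(reports: list[PerfusionReport]) -> pd.DataFrame:
    """Tidy DataFrame of sweep reports (one row per scaffold x velocity)."""
    return pd.DataFrame([r.as_row() for r in reports])


def summarize_table(viability: pd.DataFrame) -> pd.DataFrame:
    """Per-scaffold mean viable fraction over a shared velocity grid.

    ``viability`` is tidy with columns (scaffold, u_mm_s, viable_pct).
    Returns one row per scaffold with the arithmetic mean over the
    velocity grid plus pairwise differences of means; all scaffolds
    must share the same grid.
    """
    need = {"scaffold", "u_mm_s", "viable_pct"}
    if not need.issubset(viability.columns):
        raise ValueError(f"viability table needs columns {sorted(need)}")
    grids = viability.groupby("scaffold")["u_mm_s"].apply(lambda s: tuple(sorted(s)))
    if grids.nunique() != 1:
        raise ValueError("mismatched velocity grids across scaffolds")
    means = viability.groupby("scaffold")["viable_pct"].mean()
    out = means.to_frame("mean_viable_pct")
    for other in means.index:
        out[f"diff_vs_{other}"] = means - means[other]
    return out.reset_index()


def reference_viability_table() -> pd.DataFrame:
    """Published reference viability percentages for the four catalogue
    designs (share of surface with WSS < 30 mPa, per inlet velocity).

    These serve as comparison data for the summary arithmetic; they are
    not produced by this package's solver.
    """
    rows = {
        "1C": [83.4, 75.3, 70.3, 56.0, 22.8],
        "1B": [82.6, 74.8, 69.1, 56.8, 24.9],
        "1A": [82.7, 75.3, 68.9, 54.9, 15.4],
        "2": [99.8, 98.1, 90.9, 81.0, 59.5],
    }
    recs = [
        {"scaffold": sc, "u_mm_s": u, "viable_pct": pct}
        for sc, col in rows.items()
        for u, pct in zip(DEFAULT_VELOCITIES_MM_S, col)
    ]
    return pd.DataFrame(recs)
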