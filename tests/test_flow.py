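"""Flow solver: analytic fixtures, invariants, and a sparse-matrix oracle."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from scaffoldflow.flow import (
    FluidProperties,
    SolverConfig,
    check_convergence,
    solve_steady_flow,
)
from scaffoldflow.metrics import pressure_drop
from scaffoldflow.voxel import VoxelDomain, make_channel_fixture, unit_cell_domain
from scaffoldflow.geometry import ScaffoldSpec

from conftest import INLET_1MM_S, PLATE_GAP_MM


class TestValidation:
    def test_fluid_and_config_invariants(self):
        with pytest.raises(ValueError, match="density"):
            FluidProperties(density=-1.0)
        with pytest.raises(ValueError, match="viscosity"):
            FluidProperties(dynamic_viscosity=0.0)
        with pytest.raises(ValueError, match="inlet_velocity"):
            SolverConfig(inlet_velocity=0.0)
        fl = FluidProperties.blood()
        assert fl.density == 1056.0
        assert fl.dynamic_viscosity == 0.0045

    def test_impermeable_domain_rejected(self, blood):
        solid = np.zeros((5, 5, 8), dtype=bool)
        solid[:, :, 4] = True  # blocking plate
        dom = VoxelDomain(solid=solid, spacing=0.05, scaffold=solid.copy(), scaffold_range=(3, 6))
        with pytest.raises(ValueError, match="impermeable"):
            solve_steady_flow(dom, blood, SolverConfig(inlet_velocity=1e-3))


class TestCheckConvergence:
    def test_monotone_decay_crossing_tolerance(self):
        assert check_convergence([1e-1, 1e-2, 1e-3, 5e-5], tolerance=1e-4)

    def test_plateau_above_tolerance(self):
        assert not check_convergence([1e-2, 9e-3, 9e-3, 9e-3], tolerance=1e-4)

    def test_both_criteria_must_hold_simultaneously(self):
        trace = [(1e-3, 1e-2), (5e-5, 1e-3)]  # residual ok, still changing
        assert not check_convergence(trace, tolerance=1e-4, change_tolerance=1e-6)
        trace.append((2e-4, 1e-8))  # settled but residual back above
        assert not check_convergence(trace, tolerance=1e-4, change_tolerance=1e-6)
        trace.append((5e-5, 1e-8))
        assert check_convergence(trace, tolerance=1e-4, change_tolerance=1e-6)

    def test_needs_two_entries(self):
        with pytest.raises(ValueError, match="2"):
            check_convergence([1e-5])


class TestAnalyticFixtures:
    def test_plane_poiseuille_centreline_ratio(self, plate_case):
        dom, sol = plate_case
        kmid = sum(dom.scaffold_range) // 2
        prof = sol.w[1:-1, :, kmid].mean(axis=1)
        assert prof.max() / prof.mean() == pytest.approx(1.5, rel=0.02)

    def test_tube_centreline_ratio(self, tube_case):
        dom, sol = tube_case
        kmid = sum(dom.scaffold_range) // 2
        R = 0.5e-3
        Umean = sol.flux(0) / (np.pi * R * R)
        assert sol.w[:, :, kmid].max() / Umean == pytest.approx(2.0, rel=0.03)

    @pytest.mark.parametrize("case", ["plate_case", "tube_case"])
    def test_global_mass_balance(self, case, request):
        _, sol = request.getfixturevalue(case)
        assert sol.mass_imbalance() < 1e-3

    def test_discrete_divergence_vanishes(self, plate_case):
        _, sol = plate_case
        div = sol.divergence()
        assert np.abs(div).max() * sol.h / INLET_1MM_S < 1e-4


class TestStokesInvariants:
    def test_doubling_inlet_velocity_doubles_pressure_drop(self, plate_case, blood):
        dom, sol1 = plate_case
        sol2 = solve_steady_flow(
            dom, blood, SolverConfig(inlet_velocity=2 * INLET_1MM_S), initial=sol1
        )
        assert sol2.converged
        ratio = pressure_drop(sol2, dom) / pressure_drop(sol1, dom)
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_quarter_turn_of_unit_cell_preserves_solution(self, blood):
        spec = ScaffoldSpec.case_1a()
        dom = unit_cell_domain(spec, 0.09, entry_length=0.5, exit_length=0.5)
        cfg = SolverConfig(inlet_velocity=INLET_1MM_S)
        sol = solve_steady_flow(dom, blood, cfg)
        rot = VoxelDomain(
            solid=np.rot90(dom.solid, axes=(0, 1)).copy(),
            spacing=dom.spacing,
            scaffold=np.rot90(dom.scaffold, axes=(0, 1)).copy(),
            scaffold_range=dom.scaffold_range,
            lateral=dict(dom.lateral),
        )
        sol_r = solve_steady_flow(rot, blood, cfg)
        # the axial component is a scalar under a quarter turn about z;
        # both solves reach the same fixed point within convergence tol
        w_mapped = np.rot90(sol.w, axes=(0, 1))
        assert np.allclose(sol_r.w, w_mapped, atol=1e-5 * INLET_1MM_S)
        assert pressure_drop(sol_r, rot) == pytest.approx(pressure_drop(sol, dom), rel=1e-5)


class TestSparseOracle:
    """ΔP on a tiny duct against an independently assembled discrete
    Stokes system (Laplacian momentum + exact continuity)."""

    NX = NY = 7  # 5x5 fluid cells
    NZ = 20
    H_MM = 0.05

    def _domain(self):
        solid = np.zeros((self.NX, self.NY, self.NZ), dtype=bool)
        solid[0, :, :] = solid[-1, :, :] = True
        solid[:, 0, :] = solid[:, -1, :] = True
        return VoxelDomain(
            solid=solid, spacing=self.H_MM, scaffold=solid.copy(), scaffold_range=(5, 15)
        )

    def _assemble(self, dom, fluid, u_in):
        nx, ny, nz = dom.shape
        h = dom.spacing * 1e-3
        nu = fluid.kinematic_viscosity
        rho = fluid.density
        F = dom.fluid

        uidx, vidx, widx, pidx = {}, {}, {}, {}
        for i in range(1, nx):
            for j in range(ny):
                for k in range(nz):
                    if F[i - 1, j, k] and F[i, j, k]:
                        uidx[(i, j, k)] = len(uidx)
        off_v = len(uidx)
        for i in range(nx):
            for j in range(1, ny):
                for k in range(nz):
                    if F[i, j - 1, k] and F[i, j, k]:
                        vidx[(i, j, k)] = len(vidx) + off_v
        off_w = off_v + len(vidx)
        for i in range(nx):
            for j in range(ny):
                for k in range(1, nz):
                    if F[i, j, k - 1] and F[i, j, k]:
                        widx[(i, j, k)] = len(widx) + off_w
        off_p = off_w + len(widx)
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if F[i, j, k]:
                        pidx[(i, j, k)] = len(pidx) + off_p
        n = off_p + len(pidx)
        A = sp.lil_matrix((n, n))
        b = np.zeros(n)

        def mom_row(row, idx_map, key, axis):
            i, j, k = key
            diag = -6.0
            for ax, step in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
                nb = [i, j, k]
                nb[ax] += step
                nb = tuple(nb)
                if nb in idx_map:
                    A[row, idx_map[nb]] += nu / (h * h)
                    continue
                if ax == axis:
                    # normal-direction neighbour on a wall: exact zero
                    if axis == 2 and nb[2] == 0:
                        b[row] -= nu / (h * h) * u_in  # inlet Dirichlet
                    elif axis == 2 and nb[2] == nz:
                        diag += 1.0  # outflow copy w[nz] = w[nz-1]
                    continue
                # tangential ghost: -u at walls/inlet, +u past the outlet
                if ax == 2 and nb[2] >= nz:
                    diag += 1.0
                else:
                    diag -= 1.0
            A[row, idx_map[key]] += nu / (h * h) * diag

        for key, row in uidx.items():
            i, j, k = key
            mom_row(row, uidx, key, 0)
            A[row, pidx[(i, j, k)]] -= 1.0 / (rho * h)
            A[row, pidx[(i - 1, j, k)]] += 1.0 / (rho * h)
        for key, row in vidx.items():
            i, j, k = key
            mom_row(row, vidx, key, 1)
            A[row, pidx[(i, j, k)]] -= 1.0 / (rho * h)
            A[row, pidx[(i, j - 1, k)]] += 1.0 / (rho * h)
        for key, row in widx.items():
            i, j, k = key
            mom_row(row, widx, key, 2)
            A[row, pidx[(i, j, k)]] -= 1.0 / (rho * h)
            A[row, pidx[(i, j, k - 1)]] += 1.0 / (rho * h)

        # continuity per fluid cell
        for (i, j, k), row in pidx.items():
            for idx_map, key_hi, key_lo in (
                (uidx, (i + 1, j, k), (i, j, k)),
                (vidx, (i, j + 1, k), (i, j, k)),
            ):
                if key_hi in idx_map:
                    A[row, idx_map[key_hi]] += 1.0
                if key_lo in idx_map:
                    A[row, idx_map[key_lo]] -= 1.0
            if (i, j, k + 1) in widx:
                A[row, widx[(i, j, k + 1)]] += 1.0
            elif k == nz - 1 and (i, j, k) in widx:
                A[row, widx[(i, j, k)]] += 1.0  # outflow copy
            if (i, j, k) in widx:
                A[row, widx[(i, j, k)]] -= 1.0
            elif k == 0:
                b[row] += u_in  # inlet face carries the plug velocity

        # the pressure level is a nullspace direction (only gradients act);
        # border the system with a zero-mean-pressure Lagrange constraint
        A = A.tocsr()
        e = np.zeros(n)
        for row in pidx.values():
            e[row] = 1.0 / len(pidx)
        A_aug = sp.bmat([[A, e[:, None]], [e[None, :], None]], format="csr")
        b_aug = np.concatenate([b, [0.0]])
        x = spla.spsolve(A_aug, b_aug)
        assert abs(x[-1]) < 1e-8  # multiplier ~ 0: the system is consistent
        assert np.abs(A @ x[:-1] - b).max() < 1e-9
        p = np.zeros((nx, ny, nz))
        for key, row in pidx.items():
            p[key] = x[row]
        return p

    def test_pressure_drop_matches_direct_solve(self, blood):
        dom = self._domain()
        u_in = 1e-3
        cfg = SolverConfig(
            inlet_velocity=u_in,
            include_advection=False,
            convergence_tolerance=1e-9,
            velocity_change_tolerance=1e-11,
            check_every=500,
        )
        sol = solve_steady_flow(dom, blood, cfg)
        assert sol.converged
        p_oracle = self._assemble(dom, blood, u_in)
        F = dom.fluid
        k0, k1 = dom.scaffold_range
        dP_oracle = (
            p_oracle[:, :, k0 - 1][F[:, :, k0 - 1]].mean()
            - p_oracle[:, :, k1][F[:, :, k1]].mean()
        )
        assert pressure_drop(sol, dom) == pytest.approx(dP_oracle, rel=1e-6)
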