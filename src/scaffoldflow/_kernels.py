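"""Fused numba stepping kernels for the artificial-compressibility solver.

These reproduce, loop-for-loop, the vectorised numpy reference path in
``flow.py`` (same stencils, same ghost conventions); a consistency test
holds the two within round-off of each other.  The kernels exist purely
for speed on large voxel domains.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def momentum_kernel(
    u, v, w, p, du, dv, dw,
    u_act, v_act, w_act,
    u_wall, v_wall, w_wall,
    u_sym, v_sym, w_sym,
    h, nu, rho, per_x, per_y, include_adv,
):
    nx = p.shape[0]
    ny = p.shape[1]
    nz = p.shape[2]
    h2 = h * h

    def gu(i, j, k):
        # u fetch with face-periodic x (period nx), cell-periodic y
        if per_x:
            i = i % nx
        elif i < 0 or i > nx:
            return 0.0
        if per_y:
            j = j % ny
        elif j < 0 or j >= ny:
            return 0.0
        if k < 0 or k >= nz:
            return 0.0
        return u[i, j, k]

    def gv(i, j, k):
        if per_x:
            i = i % nx
        elif i < 0 or i >= nx:
            return 0.0
        if per_y:
            j = j % ny
        elif j < 0 or j > ny:
            return 0.0
        if k < 0 or k >= nz:
            return 0.0
        return v[i, j, k]

    def gw(i, j, k):
        if per_x:
            i = i % nx
        elif i < 0 or i >= nx:
            return 0.0
        if per_y:
            j = j % ny
        elif j < 0 or j >= ny:
            return 0.0
        if k < 0 or k > nz:
            return 0.0
        return w[i, j, k]

    # ---- u faces ----------------------------------------------------------
    for i in range(u.shape[0]):
        if per_x and i == nx:
            continue  # duplicate face, synced outside
        for j in range(ny):
            for k in range(nz):
                if not u_act[i, j, k]:
                    du[i, j, k] = 0.0
                    continue
                s = (
                    gu(i - 1, j, k) + gu(i + 1, j, k)
                    + gu(i, j - 1, k) + gu(i, j + 1, k)
                    + gu(i, j, k - 1) + gu(i, j, k + 1)
                )
                lap = (s - (6.0 + u_wall[i, j, k] - u_sym[i, j, k]) * u[i, j, k]) / h2
                im = i - 1
                if per_x:
                    im = im % nx
                gp = (p[i % nx if per_x else i, j, k] - p[im, j, k]) / h
                acc = nu * lap - gp / rho
                if include_adv:
                    uc_r = 0.5 * (u[i, j, k] + gu(i + 1, j, k))
                    uc_l = 0.5 * (gu(i - 1, j, k) + u[i, j, k])
                    adv = (uc_r * uc_r - uc_l * uc_l) / h
                    # y-corner fluxes: v averaged over cells i-1,i; u over j,j+1
                    v_hi = 0.5 * (gv(i - 1, j + 1, k) + gv(i, j + 1, k))
                    u_hi = 0.5 * (u[i, j, k] + gu(i, j + 1, k))
                    v_lo = 0.5 * (gv(i - 1, j, k) + gv(i, j, k))
                    u_lo = 0.5 * (gu(i, j - 1, k) + u[i, j, k])
                    adv += (v_hi * u_hi - v_lo * u_lo) / h
                    w_hi = 0.5 * (gw(i - 1, j, k + 1) + gw(i, j, k + 1))
                    uz_hi = 0.5 * (u[i, j, k] + gu(i, j, k + 1))
                    w_lo = 0.5 * (gw(i - 1, j, k) + gw(i, j, k))
                    uz_lo = 0.5 * (gu(i, j, k - 1) + u[i, j, k])
                    adv += (w_hi * uz_hi - w_lo * uz_lo) / h
                    acc -= adv
                du[i, j, k] = acc

    # ---- v faces ----------------------------------------------------------
    for i in range(nx):
        for j in range(v.shape[1]):
            if per_y and j == ny:
                continue
            for k in range(nz):
                if not v_act[i, j, k]:
                    dv[i, j, k] = 0.0
                    continue
                s = (
                    gv(i - 1, j, k) + gv(i + 1, j, k)
                    + gv(i, j - 1, k) + gv(i, j + 1, k)
                    + gv(i, j, k - 1) + gv(i, j, k + 1)
                )
                lap = (s - (6.0 + v_wall[i, j, k] - v_sym[i, j, k]) * v[i, j, k]) / h2
                jm = j - 1
                if per_y:
                    jm = jm % ny
                gp = (p[i, j % ny if per_y else j, k] - p[i, jm, k]) / h
                acc = nu * lap - gp / rho
                if include_adv:
                    vc_hi = 0.5 * (v[i, j, k] + gv(i, j + 1, k))
                    vc_lo = 0.5 * (gv(i, j - 1, k) + v[i, j, k])
                    adv = (vc_hi * vc_hi - vc_lo * vc_lo) / h
                    u_hi = 0.5 * (gu(i + 1, j - 1, k) + gu(i + 1, j, k))
                    vx_hi = 0.5 * (v[i, j, k] + gv(i + 1, j, k))
                    u_lo = 0.5 * (gu(i, j - 1, k) + gu(i, j, k))
                    vx_lo = 0.5 * (gv(i - 1, j, k) + v[i, j, k])
                    adv += (u_hi * vx_hi - u_lo * vx_lo) / h
                    w_hi = 0.5 * (gw(i, j - 1, k + 1) + gw(i, j, k + 1))
                    vz_hi = 0.5 * (v[i, j, k] + gv(i, j, k + 1))
                    w_lo = 0.5 * (gw(i, j - 1, k) + gw(i, j, k))
                    vz_lo = 0.5 * (gv(i, j, k - 1) + v[i, j, k])
                    adv += (w_hi * vz_hi - w_lo * vz_lo) / h
                    acc -= adv
                dv[i, j, k] = acc

    # ---- w faces (interior; inlet/outlet handled outside) -----------------
    for i in range(nx):
        for j in range(ny):
            for k in range(1, nz):
                if not w_act[i, j, k]:
                    dw[i, j, k] = 0.0
                    continue
                s = (
                    gw(i - 1, j, k) + gw(i + 1, j, k)
                    + gw(i, j - 1, k) + gw(i, j + 1, k)
                    + gw(i, j, k - 1) + gw(i, j, k + 1)
                )
                lap = (s - (6.0 + w_wall[i, j, k] - w_sym[i, j, k]) * w[i, j, k]) / h2
                gp = (p[i, j, k] - p[i, j, k - 1]) / h
                acc = nu * lap - gp / rho
                if include_adv:
                    wc_hi = 0.5 * (w[i, j, k] + gw(i, j, k + 1))
                    wc_lo = 0.5 * (gw(i, j, k - 1) + w[i, j, k])
                    adv = (wc_hi * wc_hi - wc_lo * wc_lo) / h
                    u_hi = 0.5 * (gu(i + 1, j, k - 1) + gu(i + 1, j, k))
                    wx_hi = 0.5 * (w[i, j, k] + gw(i + 1, j, k))
                    u_lo = 0.5 * (gu(i, j, k - 1) + gu(i, j, k))
                    wx_lo = 0.5 * (gw(i - 1, j, k) + w[i, j, k])
                    adv += (u_hi * wx_hi - u_lo * wx_lo) / h
                    v_hi = 0.5 * (gv(i, j + 1, k - 1) + gv(i, j + 1, k))
                    wy_hi = 0.5 * (w[i, j, k] + gw(i, j + 1, k))
                    v_lo = 0.5 * (gv(i, j, k - 1) + gv(i, j, k))
                    wy_lo = 0.5 * (gw(i, j - 1, k) + w[i, j, k])
                    adv += (v_hi * wy_hi - v_lo * wy_lo) / h
                    acc -= adv
                dw[i, j, k] = acc


@njit(cache=True, fastmath=False)
def apply_kernel(u, v, w, du, dv, dw, u_act, v_act, w_act, dt):
    """Explicit update on active faces; returns (sum of squares, count)
    of the momentum residual."""
    ss = 0.0
    n = 0
    nx1, ny, nz = u.shape
    for i in range(nx1):
        for j in range(ny):
            for k in range(nz):
                if u_act[i, j, k]:
                    u[i, j, k] += dt * du[i, j, k]
                    ss += du[i, j, k] * du[i, j, k]
                    n += 1
    nx, ny1, _ = v.shape
    for i in range(nx):
        for j in range(ny1):
            for k in range(nz):
                if v_act[i, j, k]:
                    v[i, j, k] += dt * dv[i, j, k]
                    ss += dv[i, j, k] * dv[i, j, k]
                    n += 1
    _, _, nz1 = w.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(1, nz1 - 1):
                if w_act[i, j, k]:
                    w[i, j, k] += dt * dw[i, j, k]
                    ss += dw[i, j, k] * dw[i, j, k]
                    n += 1
    return ss, n


@njit(cache=True, fastmath=False)
def pressure_kernel(u, v, w, p, fluid, h, dt_c2rho):
    nx, ny, nz = p.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if fluid[i, j, k]:
                    div = (
                        u[i + 1, j, k] - u[i, j, k]
                        + v[i, j + 1, k] - v[i, j, k]
                        + w[i, j, k + 1] - w[i, j, k]
                    ) / h
                    p[i, j, k] -= dt_c2rho * div
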