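"""Numba-compiled inner loops of the solver.

These kernels are straight ports of the finite-volume update formulas in
:mod:`implantflow.solver` (flux-limited reconstruction, CSF force with
wall adhesion, momentum predictor, scalar transport, Poisson operator),
compiled with ``@njit(cache=True)`` so a 3-second scenario run stays
desk-scale.  No ``fastmath`` is used: results are deterministic and
bit-reproducible.  Scheme ids: 0 = van Leer, 1 = superbee.
"""

from __future__ import annotations

import numpy as np
from numba import njit

VANLEER = 0
SUPERBEE = 1


@njit(cache=True, inline="always")
def _phi(r: float, scheme: int) -> float:
    if scheme == VANLEER:
        ar = abs(r)
        return (r + ar) / (1.0 + ar)
    a = min(1.0, 2.0 * r)
    b = min(2.0, r)
    m = a if a > b else b
    return m if m > 0.0 else 0.0


@njit(cache=True)
def limited_faces_x(q, w, scheme):
    """Limited upwind face values between consecutive nodes along axis 0.

    ``q``: (n, m) node values; ``w``: (n-1, m) advecting velocity at the
    internode faces; returns (n-1, m).  Faces lacking a second upwind
    node fall back to first-order upwind.  The upwind/local difference
    ratio uses a zero-safe product form (r -> 0 with the local
    difference, where the correction vanishes anyway).
    """
    n, m = q.shape
    out = np.empty((n - 1, m))
    for j in range(m):
        for i in range(n - 1):
            d = q[i + 1, j] - q[i, j]
            den = d * d + 1e-300
            if w[i, j] >= 0.0:
                r = (q[i, j] - q[i - 1, j]) * d / den if i >= 1 else 0.0
                out[i, j] = q[i, j] + 0.5 * _phi(r, scheme) * d
            else:
                r = (q[i + 2, j] - q[i + 1, j]) * d / den if i <= n - 3 else 0.0
                out[i, j] = q[i + 1, j] - 0.5 * _phi(r, scheme) * d
    return out


@njit(cache=True)
def limited_faces_y(q, w, scheme):
    """Same as :func:`limited_faces_x` along axis 1."""
    n, m = q.shape
    out = np.empty((n, m - 1))
    for i in range(n):
        for j in range(m - 1):
            d = q[i, j + 1] - q[i, j]
            den = d * d + 1e-300
            if w[i, j] >= 0.0:
                r = (q[i, j] - q[i, j - 1]) * d / den if j >= 1 else 0.0
                out[i, j] = q[i, j] + 0.5 * _phi(r, scheme) * d
            else:
                r = (q[i, j + 2] - q[i, j + 1]) * d / den if j <= m - 3 else 0.0
                out[i, j] = q[i, j + 1] - 0.5 * _phi(r, scheme) * d
    return out


@njit(cache=True)
def cell_properties(alpha, Y0, rho_fib, rho_pl, rho_rbc, mu_rbc, pieces):
    """Per-cell VOF-blended density and viscosity.

    ``pieces`` is the plasma viscosity law as rows ``(C_lo, a, b, c)``
    evaluating ``(a C^2 + b C + c)`` mPa.s on ``C >= C_lo``; the mixture
    density is the harmonic (volume-weighted) law and the phase blend is
    arithmetic in the plasma fraction.
    """
    nx, ny = alpha.shape
    rho = np.empty((nx, ny))
    mu = np.empty((nx, ny))
    npieces = pieces.shape[0]
    for i in range(nx):
        for j in range(ny):
            a = alpha[i, j]
            if a < 0.0:
                a = 0.0
            elif a > 1.0:
                a = 1.0
            y = Y0[i, j]
            rm = 1.0 / (y / rho_fib + (1.0 - y) / rho_pl)
            C = 0.1 * y * rm
            k = npieces - 1
            while k > 0 and C < pieces[k, 0]:
                k -= 1
            mm = (pieces[k, 1] * C * C + pieces[k, 2] * C + pieces[k, 3]) * 1e-3
            rho[i, j] = a * rm + (1.0 - a) * rho_rbc
            mu[i, j] = a * mm + (1.0 - a) * mu_rbc
    return rho, mu


@njit(cache=True)
def fill_and_smooth(alpha, fluid):
    """Solid cells filled from fluid neighbours (2 Jacobi passes, edge
    clamping) and the filled field smoothed by 2 binomial passes.
    Returns ``(afill, asm)``; shared by the CSF force and the
    interface-compression gate."""
    nx, ny = alpha.shape
    afill = alpha.copy()
    for _ in range(2):
        prev = afill.copy()
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            for j in range(ny):
                if not fluid[i, j]:
                    jm = j - 1 if j > 0 else 0
                    jp = j + 1 if j < ny - 1 else ny - 1
                    afill[i, j] = 0.25 * (prev[im, j] + prev[ip, j]
                                          + prev[i, jm] + prev[i, jp])
    asm = afill.copy()
    tmp = np.empty_like(asm)
    for _ in range(2):
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            for j in range(ny):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                tmp[i, j] = (asm[im, jm] + 2.0 * asm[i, jm] + asm[ip, jm]
                             + 2.0 * asm[im, j] + 4.0 * asm[i, j] + 2.0 * asm[ip, j]
                             + asm[im, jp] + 2.0 * asm[i, jp] + asm[ip, jp]) / 16.0
        asm, tmp = tmp, asm
    return afill, asm


@njit(cache=True)
def csf_force(alpha, afill, asm, wall_mask, wall_nx, wall_ny, cos_t, sin_t,
              sigma, dx, u_free, v_free):
    """CSF face force (N/m^3) with contact-angle wall adhesion.

    ``afill``/``asm`` come from :func:`fill_and_smooth`.  The interface
    normal is rotated at implant-adjacent cells to ``n_wall cos(theta) +
    t_wall sin(theta)``, curvature is the negative divergence of the
    unit normal clamped to the grid-resolvable 1/dx, and the force is
    gated to cells where the sharp |grad alpha| exceeds 1e-3 of its
    maximum.
    """
    nx, ny = alpha.shape
    gx = np.empty((nx, ny))
    gy = np.empty((nx, ny))
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(ny):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < ny - 1 else ny - 1
            gx[i, j] = (asm[ip, j] - asm[im, j]) / (2.0 * dx)
            gy[i, j] = (asm[i, jp] - asm[i, jm]) / (2.0 * dx)

    # contact-angle override on implant-adjacent cells
    for i in range(nx):
        for j in range(ny):
            if wall_mask[i, j]:
                nmag = np.hypot(gx[i, j], gy[i, j])
                if nmag <= 1e-12:
                    continue
                wx = wall_nx[i, j]
                wy = wall_ny[i, j]
                ndw = gx[i, j] * wx + gy[i, j] * wy
                tx = gx[i, j] - ndw * wx
                ty = gy[i, j] - ndw * wy
                tmag = np.hypot(tx, ty)
                if tmag <= 1e-12 * nmag:
                    continue
                tx /= tmag
                ty /= tmag
                gx[i, j] = nmag * (wx * cos_t + tx * sin_t)
                gy[i, j] = nmag * (wy * cos_t + ty * sin_t)

    nhx = np.empty((nx, ny))
    nhy = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            nmag = np.hypot(gx[i, j], gy[i, j]) + 1e-300
            nhx[i, j] = gx[i, j] / nmag
            nhy[i, j] = gy[i, j] / nmag

    # sharp-gradient magnitude (edge-clamped central differences)
    smax = 0.0
    smag = np.empty((nx, ny))
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(ny):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < ny - 1 else ny - 1
            sx = (afill[ip, j] - afill[im, j]) / (2.0 * dx)
            sy = (afill[i, jp] - afill[i, jm]) / (2.0 * dx)
            s = np.hypot(sx, sy)
            smag[i, j] = s
            if s > smax:
                smax = s
    gate_level = 1e-3 * (smax if smax > 1e-300 else 1e-300)

    kappa = np.empty((nx, ny))
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(ny):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < ny - 1 else ny - 1
            if smag[i, j] > gate_level:
                k = -((nhx[ip, j] - nhx[im, j])
                      + (nhy[i, jp] - nhy[i, jm])) / (2.0 * dx)
                # clamp to the grid-resolvable curvature (radius >= dx):
                # sub-cell structures would otherwise inject unphysical
                # capillary kicks
                kmax = 1.0 / dx
                if k > kmax:
                    k = kmax
                elif k < -kmax:
                    k = -kmax
                kappa[i, j] = k
            else:
                kappa[i, j] = 0.0

    ksm = kappa

    fsx = np.zeros((nx + 1, ny))
    fsy = np.zeros((nx, ny + 1))
    for i in range(1, nx):
        for j in range(ny):
            if u_free[i, j]:
                kf = 0.5 * (ksm[i - 1, j] + ksm[i, j])
                fsx[i, j] = sigma * kf * (alpha[i, j] - alpha[i - 1, j]) / dx
    for i in range(nx):
        for j in range(1, ny):
            if v_free[i, j]:
                kf = 0.5 * (ksm[i, j - 1] + ksm[i, j])
                fsy[i, j] = sigma * kf * (alpha[i, j] - alpha[i, j - 1]) / dx
    return fsx, fsy


@njit(cache=True)
def momentum_predictor(u, v, rho_c, mu_c, fsx, fsy, dt, dx,
                       u_mirror_n, u_mirror_s, v_mirror_e, v_mirror_w,
                       u_fixed, u_val, v_fixed, v_val, outflow):
    """Explicit predictor: limited-upwind advection + viscosity + CSF.

    Returns (u_star, v_star, rho_u, rho_v) with prescribed boundary
    values applied and the outlet faces extrapolated at zero gradient.
    """
    nxp1, ny = u.shape
    nx = nxp1 - 1
    dx2 = dx * dx

    rho_u = np.empty((nx + 1, ny))
    for j in range(ny):
        rho_u[0, j] = rho_c[0, j]
        rho_u[nx, j] = rho_c[nx - 1, j]
        for i in range(1, nx):
            rho_u[i, j] = 0.5 * (rho_c[i - 1, j] + rho_c[i, j])
    rho_v = np.empty((nx, ny + 1))
    for i in range(nx):
        rho_v[i, 0] = rho_c[i, 0]
        rho_v[i, ny] = rho_c[i, ny - 1]
        for j in range(1, ny):
            rho_v[i, j] = 0.5 * (rho_c[i, j - 1] + rho_c[i, j])

    # --- u component: advective fluxes ---
    flux_xx = np.empty((nx, ny))          # d(uu)/dx flux at cell centres
    for j in range(ny):
        for i in range(nx):
            w = 0.5 * (u[i, j] + u[i + 1, j])
            d = u[i + 1, j] - u[i, j]
            den = d * d + 1e-300
            if w >= 0.0:
                r = (u[i, j] - u[i - 1, j]) * d / den if i >= 1 else 0.0
                q = u[i, j] + 0.5 * _phi(r, VANLEER) * d
            else:
                r = (u[i + 2, j] - u[i + 1, j]) * d / den if i <= nx - 2 else 0.0
                q = u[i + 1, j] - 0.5 * _phi(r, VANLEER) * d
            flux_xx[i, j] = w * q

    flux_xy = np.empty((nx + 1, ny + 1))  # d(vu)/dy flux at corners
    for i in range(nx + 1):
        flux_xy[i, 0] = 0.0               # tangential u = 0 on the bottom
        for j in range(1, ny):
            if i == 0:
                w = v[0, j]
            elif i == nx:
                w = v[nx - 1, j]
            else:
                w = 0.5 * (v[i - 1, j] + v[i, j])
            d = u[i, j] - u[i, j - 1]
            den = d * d + 1e-300
            if w >= 0.0:
                r = (u[i, j - 1] - u[i, j - 2]) * d / den if j >= 2 else 0.0
                q = u[i, j - 1] + 0.5 * _phi(r, VANLEER) * d
            else:
                r = (u[i, j + 1] - u[i, j]) * d / den if j <= ny - 2 else 0.0
                q = u[i, j] - 0.5 * _phi(r, VANLEER) * d
            flux_xy[i, j] = w * q
        if i == 0:
            w = v[0, ny]
        elif i == nx:
            w = v[nx - 1, ny]
        else:
            w = 0.5 * (v[i - 1, ny] + v[i, ny])
        flux_xy[i, ny] = w * u[i, ny - 1]  # zero-gradient at the outlet

    # conservative viscous operator div(mu grad u): with sharp phase
    # interfaces the viscosity varies 10x cell-to-cell, and only the
    # flux (symmetric, dissipative) form is robust there
    u_star = np.empty((nx + 1, ny))
    for j in range(ny):
        jm = j - 1 if j > 0 else 0
        jp = j + 1 if j < ny - 1 else ny - 1
        for i in range(nx + 1):
            if u_fixed[i, j]:
                u_star[i, j] = u_val[i, j]
                continue
            uc = u[i, j]
            uE = u[i + 1, j]              # free faces have 1 <= i <= nx-1
            uW = u[i - 1, j]
            uN = -uc if u_mirror_n[i, j] else (u[i, j + 1] if j < ny - 1 else uc)
            uS = -uc if u_mirror_s[i, j] else (u[i, j - 1] if j > 0 else uc)
            mu_n = 0.25 * (mu_c[i - 1, j] + mu_c[i, j]
                           + mu_c[i - 1, jp] + mu_c[i, jp])
            mu_s = 0.25 * (mu_c[i - 1, j] + mu_c[i, j]
                           + mu_c[i - 1, jm] + mu_c[i, jm])
            visc = ((mu_c[i, j] * (uE - uc) - mu_c[i - 1, j] * (uc - uW))
                    + (mu_n * (uN - uc) - mu_s * (uc - uS))) / dx2
            adv = ((flux_xx[i, j] - flux_xx[i - 1, j]) / dx
                   + (flux_xy[i, j + 1] - flux_xy[i, j]) / dx)
            u_star[i, j] = uc + dt * (-adv + (visc + fsx[i, j]) / rho_u[i, j])

    # --- v component: advective fluxes ---
    flux_yy = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            w = 0.5 * (v[i, j] + v[i, j + 1])
            d = v[i, j + 1] - v[i, j]
            den = d * d + 1e-300
            if w >= 0.0:
                r = (v[i, j] - v[i, j - 1]) * d / den if j >= 1 else 0.0
                q = v[i, j] + 0.5 * _phi(r, VANLEER) * d
            else:
                r = (v[i, j + 2] - v[i, j + 1]) * d / den if j <= ny - 2 else 0.0
                q = v[i, j + 1] - 0.5 * _phi(r, VANLEER) * d
            flux_yy[i, j] = w * q

    flux_yx = np.empty((nx + 1, ny + 1))
    for j in range(ny + 1):
        flux_yx[0, j] = 0.0               # tangential v = 0 on left wall
        flux_yx[nx, j] = 0.0              # and on the implant wall
    for i in range(1, nx):
        for j in range(ny + 1):
            if j == 0:
                w = u[i, 0]
            elif j == ny:
                w = u[i, ny - 1]
            else:
                w = 0.5 * (u[i, j - 1] + u[i, j])
            d = v[i, j] - v[i - 1, j]
            den = d * d + 1e-300
            if w >= 0.0:
                r = (v[i - 1, j] - v[i - 2, j]) * d / den if i >= 2 else 0.0
                q = v[i - 1, j] + 0.5 * _phi(r, VANLEER) * d
            else:
                r = (v[i + 1, j] - v[i, j]) * d / den if i <= nx - 2 else 0.0
                q = v[i, j] - 0.5 * _phi(r, VANLEER) * d
            flux_yx[i, j] = w * q

    v_star = np.zeros((nx, ny + 1))
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(ny + 1):
            if v_fixed[i, j]:
                v_star[i, j] = v_val[i, j]
                continue
            if j == ny:
                continue                  # outlet faces extrapolated below
            vc = v[i, j]
            vN = v[i, j + 1]              # free faces have 1 <= j <= ny-1
            vS = v[i, j - 1]
            vE = -vc if v_mirror_e[i, j] else (v[i + 1, j] if i < nx - 1 else vc)
            vW = -vc if v_mirror_w[i, j] else (v[i - 1, j] if i > 0 else vc)
            mu_e = 0.25 * (mu_c[i, j - 1] + mu_c[i, j]
                           + mu_c[ip, j - 1] + mu_c[ip, j])
            mu_w = 0.25 * (mu_c[i, j - 1] + mu_c[i, j]
                           + mu_c[im, j - 1] + mu_c[im, j])
            visc = ((mu_c[i, j] * (vN - vc) - mu_c[i, j - 1] * (vc - vS))
                    + (mu_e * (vE - vc) - mu_w * (vc - vW))) / dx2
            adv = ((flux_yy[i, j] - flux_yy[i, j - 1]) / dx
                   + (flux_yx[i + 1, j] - flux_yx[i, j]) / dx)
            v_star[i, j] = vc + dt * (-adv + (visc + fsy[i, j]) / rho_v[i, j])
    for i in range(nx):
        if outflow[i]:
            v_star[i, ny] = v_star[i, ny - 1]
    return u_star, v_star, rho_u, rho_v


@njit(cache=True)
def scalar_fluxes(q, u, v, scheme, q_in_left, q_in_bottom, q_amb, outflow):
    """Advective face fluxes ``u_f * q_f`` of a cell scalar with limited
    upwind reconstruction.

    Inlet faces carry the prescribed inlet value; outlet faces are
    upwinded for outflow and clamped to the ambient composition for
    (rare) inflow; all solid and wall faces carry zero velocity, hence
    zero flux.  Returns ``(Fx, Fy)`` on the full face grids.
    """
    nx, ny = q.shape
    qFx = limited_faces_x(q, u[1:nx, :], scheme)
    qFy = limited_faces_y(q, v[:, 1:ny], scheme)
    Fx = np.zeros((nx + 1, ny))
    Fy = np.zeros((nx, ny + 1))
    for j in range(ny):
        Fx[0, j] = u[0, j] * (q_in_left[j] if u[0, j] >= 0.0 else q[0, j])
        Fx[nx, j] = u[nx, j] * q[nx - 1, j]
        for i in range(1, nx):
            Fx[i, j] = u[i, j] * qFx[i - 1, j]
    for i in range(nx):
        Fy[i, 0] = v[i, 0] * (q_in_bottom[i] if v[i, 0] >= 0.0 else q[i, 0])
        if outflow[i]:
            Fy[i, ny] = v[i, ny] * (q[i, ny - 1] if v[i, ny] >= 0.0 else q_amb)
        for j in range(1, ny):
            Fy[i, j] = v[i, j] * qFy[i, j - 1]
    return Fx, Fy


@njit(cache=True)
def apply_fluxes(q, Fx, Fy, fluid, dt, dx):
    """Conservative update ``q -= dt/dx div(F)``; solid cells untouched."""
    nx, ny = q.shape
    out = q.copy()
    for i in range(nx):
        for j in range(ny):
            if fluid[i, j]:
                out[i, j] = q[i, j] - dt * (Fx[i + 1, j] - Fx[i, j]
                                            + Fy[i, j + 1] - Fy[i, j]) / dx
    return out


@njit(cache=True)
def species_ride_fluxes(Y, rho_m, Fx, Fy, yrho_in, outflow):
    """Fibrinogen partial-density fluxes riding the plasma fluxes.

    Each face carries ``F_alpha * (rho_m Y)_face`` with the face value
    reconstructed by van-Leer-limited upwinding in the direction of the
    (already computed) plasma flux — advective and compressive alike.
    A cell that loses plasma therefore loses its dissolved fibrinogen at
    the same rate, and a uniform mass fraction is transported without
    change (exact consistency of the two fields, for any
    reconstruction).
    """
    nx, ny = Y.shape
    qs = rho_m * Y
    qs_x = limited_faces_x(qs, Fx[1:nx, :], SUPERBEE)
    qs_y = limited_faces_y(qs, Fy[:, 1:ny], SUPERBEE)
    Ffx = np.zeros((nx + 1, ny))
    Ffy = np.zeros((nx, ny + 1))
    for j in range(ny):
        F = Fx[0, j]
        Ffx[0, j] = F * (yrho_in if F >= 0.0 else qs[0, j])
        F = Fx[nx, j]
        Ffx[nx, j] = F * (qs[nx - 1, j] if F >= 0.0 else 0.0)
        for i in range(1, nx):
            Ffx[i, j] = Fx[i, j] * qs_x[i - 1, j]
    for i in range(nx):
        F = Fy[i, 0]
        Ffy[i, 0] = F * (yrho_in if F >= 0.0 else qs[i, 0])
        if outflow[i]:
            F = Fy[i, ny]
            Ffy[i, ny] = F * (qs[i, ny - 1] if F >= 0.0 else yrho_in)
        for j in range(1, ny):
            Ffy[i, j] = Fy[i, j] * qs_y[i, j - 1]
    return Ffx, Ffy


@njit(cache=True)
def vof_compress(alpha, asm, u, v, dt, dx, c_alpha, u_free, v_free, Fx, Fy):
    """Interface-compression pass: counter-gradient transfer
    ``c_alpha |u_f| n_hat alpha (1 - alpha)`` across interior faces.

    The compression direction and the interface gate come from the
    twice-smoothed alpha field ``asm`` (see :func:`fill_and_smooth`), so
    only coherent (grid-resolved) interfaces are sharpened — isolated
    speckle is left to the regular transport.  Implemented as sequential
    bounded transfers (each face moves at most what keeps both cells in
    [0, 1]), so the pass is exactly conservative and needs no clipping.
    Uniform regions and resting fluid are untouched.  Modifies ``alpha``
    in place and accumulates the applied transfers into the face-flux
    arrays ``Fx, Fy`` so that dissolved species can ride the same plasma
    motion.
    """
    nx, ny = alpha.shape
    gate = 0.03                            # min |d alpha_smooth| per cell
    for i in range(1, nx):
        for j in range(ny):
            if not u_free[i, j]:
                continue
            gxf = (asm[i, j] - asm[i - 1, j]) / dx
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < ny - 1 else ny - 1
            gyf = ((asm[i - 1, jp] - asm[i - 1, jm])
                   + (asm[i, jp] - asm[i, jm])) / (4.0 * dx)
            mag = np.hypot(gxf, gyf)
            if mag * dx < gate:
                continue
            w = c_alpha * abs(u[i, j]) * gxf / mag
            if w > 0.0:
                aL = alpha[i - 1, j]
                aR = alpha[i, j]
                amt = dt / dx * w * aL * (1.0 - aL)
                amt = min(amt, aL, 1.0 - aR)
                if amt > 0.0:
                    alpha[i - 1, j] = aL - amt
                    alpha[i, j] = aR + amt
                    Fx[i, j] += amt * dx / dt
            elif w < 0.0:
                aL = alpha[i - 1, j]
                aR = alpha[i, j]
                amt = dt / dx * (-w) * aR * (1.0 - aR)
                amt = min(amt, aR, 1.0 - aL)
                if amt > 0.0:
                    alpha[i, j] = aR - amt
                    alpha[i - 1, j] = aL + amt
                    Fx[i, j] -= amt * dx / dt
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(1, ny):
            if not v_free[i, j]:
                continue
            gyf = (asm[i, j] - asm[i, j - 1]) / dx
            gxf = ((asm[ip, j - 1] - asm[im, j - 1])
                   + (asm[ip, j] - asm[im, j])) / (4.0 * dx)
            mag = np.hypot(gxf, gyf)
            if mag * dx < gate:
                continue
            w = c_alpha * abs(v[i, j]) * gyf / mag
            if w > 0.0:
                aS = alpha[i, j - 1]
                aN = alpha[i, j]
                amt = dt / dx * w * aS * (1.0 - aS)
                amt = min(amt, aS, 1.0 - aN)
                if amt > 0.0:
                    alpha[i, j - 1] = aS - amt
                    alpha[i, j] = aN + amt
                    Fy[i, j] += amt * dx / dt
            elif w < 0.0:
                aS = alpha[i, j - 1]
                aN = alpha[i, j]
                amt = dt / dx * (-w) * aN * (1.0 - aN)
                amt = min(amt, aN, 1.0 - aS)
                if amt > 0.0:
                    alpha[i, j] = aN - amt
                    alpha[i, j - 1] = aS + amt
                    Fy[i, j] -= amt * dx / dt
    return alpha


@njit(cache=True)
def fib_partial_density(alpha, Y, r0, r1):
    """Fibrinogen partial density f = alpha * rho_m(Y) * Y and the
    mixture density rho_m (harmonic law, unchecked fast path)."""
    nx, ny = alpha.shape
    f = np.empty((nx, ny))
    rho_m = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            y = Y[i, j]
            rm = 1.0 / (y / r0 + (1.0 - y) / r1)
            rho_m[i, j] = rm
            f[i, j] = alpha[i, j] * rm * y
    return f, rho_m


@njit(cache=True)
def species_finalize(f_new, alpha, Y, rho_m, fluid, u_free, v_free,
                     D, dt, dx, r0, r1):
    """Add Fickian diffusion (fluxes weighted by the face plasma
    fraction) to the advected partial density and invert the harmonic
    mixing law back to the mass fraction Y0.  Cells with a vanishing
    plasma fraction carry no dissolved fibrinogen."""
    nx, ny = alpha.shape
    if D > 0.0:
        c = dt / dx * D / dx
        for i in range(nx - 1):
            for j in range(ny):
                if u_free[i + 1, j]:
                    af = 0.5 * (alpha[i, j] + alpha[i + 1, j])
                    rf = 0.5 * (rho_m[i, j] + rho_m[i + 1, j])
                    q = c * af * rf * (Y[i + 1, j] - Y[i, j])
                    f_new[i, j] += q
                    f_new[i + 1, j] -= q
        for i in range(nx):
            for j in range(ny - 1):
                if v_free[i, j + 1]:
                    af = 0.5 * (alpha[i, j] + alpha[i, j + 1])
                    rf = 0.5 * (rho_m[i, j] + rho_m[i, j + 1])
                    q = c * af * rf * (Y[i, j + 1] - Y[i, j])
                    f_new[i, j] += q
                    f_new[i, j + 1] -= q
    Y_out = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            if not fluid[i, j]:
                Y_out[i, j] = 0.0
                continue
            fv = f_new[i, j]
            if fv < 0.0:
                fv = 0.0
            a = alpha[i, j]
            if a > 1e-6:
                g = fv / a
            else:
                g = 0.0
            y = (g / r1) / (1.0 + g * (1.0 / r1 - 1.0 / r0))
            if y < 0.0:
                y = 0.0
            elif y > 1.0 - 1e-9:
                y = 1.0 - 1e-9
            Y_out[i, j] = y
    return Y_out


@njit(cache=True)
def correct_velocity(u_star, v_star, p, beta_x, beta_y, dt, dx,
                     u_fixed, u_val, v_fixed, v_val):
    """Projection correction u -= dt * beta * grad p (in place), with
    the outlet ghost p = 0 and prescribed faces re-imposed."""
    nxp1, ny = u_star.shape
    nx = nxp1 - 1
    for j in range(ny):
        for i in range(nx + 1):
            if u_fixed[i, j]:
                u_star[i, j] = u_val[i, j]
            elif 0 < i < nx:
                u_star[i, j] -= dt * beta_x[i, j] * (p[i, j] - p[i - 1, j]) / dx
    for i in range(nx):
        for j in range(ny + 1):
            if v_fixed[i, j]:
                v_star[i, j] = v_val[i, j]
            elif j == ny:
                v_star[i, j] -= dt * beta_y[i, ny] * (-2.0 * p[i, ny - 1]) / dx
            elif j > 0:
                v_star[i, j] -= dt * beta_y[i, j] * (p[i, j] - p[i, j - 1]) / dx
    return u_star, v_star


@njit(cache=True)
def residual_norm(p, b, beta_x, beta_y, fluid, dx2, project_mean):
    """Residual ``r = b - div(beta grad p)`` over fluid cells and its
    2-norm, with optional mean projection (pure-Neumann problems).
    Fused to keep the defect-correction loop cheap."""
    nx, ny = p.shape
    r = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            if not fluid[i, j]:
                continue
            acc = 0.0
            if i < nx - 1:
                acc += beta_x[i + 1, j] * (p[i + 1, j] - p[i, j])
            if i > 0:
                acc -= beta_x[i, j] * (p[i, j] - p[i - 1, j])
            if j < ny - 1:
                acc += beta_y[i, j + 1] * (p[i, j + 1] - p[i, j])
            else:
                acc += beta_y[i, ny] * (-2.0 * p[i, j])
            if j > 0:
                acc -= beta_y[i, j] * (p[i, j] - p[i, j - 1])
            r[i, j] = b[i, j] - acc / dx2
    if project_mean:
        s = 0.0
        n = 0
        for i in range(nx):
            for j in range(ny):
                if fluid[i, j]:
                    s += r[i, j]
                    n += 1
        mean = s / n if n > 0 else 0.0
        for i in range(nx):
            for j in range(ny):
                if fluid[i, j]:
                    r[i, j] -= mean
    rn = 0.0
    for i in range(nx):
        for j in range(ny):
            rn += r[i, j] * r[i, j]
    return r, np.sqrt(rn)


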