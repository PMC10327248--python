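"""Numba-compiled hot loops for the Langevin engine.

These kernels duplicate the vectorized numpy reference implementations in
``energy_model`` / ``dynamic_fitting`` (equivalence is enforced by tests);
they exist purely because the integrator calls them tens of thousands of
times per run.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def afm_cc_grad(coords, e_heights, x0, y0, px, r_t, R, tau, want_grad):
    """Soft pseudo-image, CC against e_heights, and dCC/dr.

    Mirrors synthesize_surface_soft + the CC chain rule.  Returns
    (cc, grad, heights) where grad is (n_beads, 3); grad stays zero when
    want_grad is false, and cc = -2 flags a degenerate simulated image.
    """
    n = coords.shape[0]
    ny, nx = e_heights.shape
    beta = 2.0 * R * tau
    lam = R / 2.0

    c_all = np.empty((ny, nx, n))
    dcq_all = np.empty((ny, nx, n))
    p_all = np.empty((ny, nx, n))
    h = np.empty((ny, nx))

    A = 0.0
    B = 0.0
    C = 0.0
    for iy in range(ny):
        y = y0 + iy * px
        for ix in range(nx):
            x = x0 + ix * px
            cmax = 0.0
            for i in range(n):
                dxv = x - coords[i, 0]
                dyv = y - coords[i, 1]
                q = R * R - (dxv * dxv + dyv * dyv)
                t = np.sqrt(q * q + beta * beta)
                root = np.sqrt(0.5 * (t + q) + 1e-12)
                c = coords[i, 2] - r_t + root - 0.5 * (t - q) / lam
                c_all[iy, ix, i] = c
                qt = q / t
                dcq_all[iy, ix, i] = (qt + 1.0) / (4.0 * root) \
                    + (1.0 - qt) / (2.0 * lam)
                if c > cmax:
                    cmax = c
            s = np.exp(-cmax / tau)
            for i in range(n):
                arg = (c_all[iy, ix, i] - cmax) / tau
                if arg > -45.0:
                    e = np.exp(arg)
                    p_all[iy, ix, i] = e
                    s += e
                else:
                    p_all[iy, ix, i] = 0.0
            hval = cmax + tau * np.log(s)
            h[iy, ix] = hval
            for i in range(n):
                p_all[iy, ix, i] /= s
            e = e_heights[iy, ix]
            A += e * hval
            B += e * e
            C += hval * hval

    grad = np.zeros((n, 3))
    if C < 1e-20 or B == 0.0:
        return -2.0, grad, h
    sq = np.sqrt(B * C)
    cc = A / sq
    if not want_grad:
        return cc, grad, h

    for iy in range(ny):
        y = y0 + iy * px
        for ix in range(nx):
            x = x0 + ix * px
            g = e_heights[iy, ix] / sq - cc * h[iy, ix] / C
            if g == 0.0:
                continue
            for i in range(n):
                p = p_all[iy, ix, i]
                if p == 0.0:
                    continue
                dxv = x - coords[i, 0]
                dyv = y - coords[i, 1]
                common = g * p * dcq_all[iy, ix, i] * 2.0
                grad[i, 0] += common * dxv
                grad[i, 1] += common * dyv
                grad[i, 2] += g * p
    return cc, grad, h


@njit(cache=True, fastmath=False)
def structure_forces(coords,
                     bonds, bond_r0, bond_k,
                     angles, angle_t0, angle_k,
                     dihedrals, dihedral_p0, dihedral_k,
                     go_pairs, go_r0, go_eps,
                     pair_terms, pair_r0, pair_k,
                     stack_terms, stack_r0, stack_k,
                     ev_pairs, ev_sigma, ev_eps,
                     elec_pairs, elec_k, elec_lambda,
                     th_c, th_stack, th_pair, th_contact):
    n = coords.shape[0]
    f = np.zeros((n, 3))

    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        mag = -th_c * bond_k * (r - bond_r0[b]) / r
        f[i, 0] += mag * dx; f[i, 1] += mag * dy; f[i, 2] += mag * dz
        f[j, 0] -= mag * dx; f[j, 1] -= mag * dy; f[j, 2] -= mag * dz

    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ux /= nu; uy /= nu; uz /= nu
        vx /= nv; vy /= nv; vz /= nv
        cos = ux * vx + uy * vy + uz * vz
        if cos > 1.0:
            cos = 1.0
        elif cos < -1.0:
            cos = -1.0
        sin = np.sqrt(max(1.0 - cos * cos, 1e-12))
        t = np.arccos(cos)
        dEdt = th_c * angle_k * (t - angle_t0[a])
        gix = (cos * ux - vx) / (nu * sin)
        giy = (cos * uy - vy) / (nu * sin)
        giz = (cos * uz - vz) / (nu * sin)
        gkx = (cos * vx - ux) / (nv * sin)
        gky = (cos * vy - uy) / (nv * sin)
        gkz = (cos * vz - uz) / (nv * sin)
        f[i, 0] -= dEdt * gix; f[i, 1] -= dEdt * giy; f[i, 2] -= dEdt * giz
        f[k, 0] -= dEdt * gkx; f[k, 1] -= dEdt * gky; f[k, 2] -= dEdt * gkz
        f[j, 0] += dEdt * (gix + gkx)
        f[j, 1] += dEdt * (giy + gky)
        f[j, 2] += dEdt * (giz + gkz)

    for d in range(dihedrals.shape[0]):
        i, j, k, l = dihedrals[d, 0], dihedrals[d, 1], dihedrals[d, 2], dihedrals[d, 3]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        sn1 = n1x * n1x + n1y * n1y + n1z * n1z
        sn2 = n2x * n2x + n2y * n2y + n2z * n2z
        if sn1 < 1e-12 or sn2 < 1e-12:
            continue
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        yv = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        xv = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(yv, xv)
        dEdp = th_c * dihedral_k * np.sin(phi - dihedral_p0[d])
        s1 = -nb2 / sn1
        s2 = nb2 / sn2
        dpix = s1 * n1x; dpiy = s1 * n1y; dpiz = s1 * n1z
        dplx = s2 * n2x; dply = s2 * n2y; dplz = s2 * n2z
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        dpjx = -(1.0 + c12) * dpix + c32 * dplx
        dpjy = -(1.0 + c12) * dpiy + c32 * dply
        dpjz = -(1.0 + c12) * dpiz + c32 * dplz
        dpkx = -dpix - dpjx - dplx
        dpky = -dpiy - dpjy - dply
        dpkz = -dpiz - dpjz - dplz
        f[i, 0] -= dEdp * dpix; f[i, 1] -= dEdp * dpiy; f[i, 2] -= dEdp * dpiz
        f[j, 0] -= dEdp * dpjx; f[j, 1] -= dEdp * dpjy; f[j, 2] -= dEdp * dpjz
        f[k, 0] -= dEdp * dpkx; f[k, 1] -= dEdp * dpky; f[k, 2] -= dEdp * dpkz
        f[l, 0] -= dEdp * dplx; f[l, 1] -= dEdp * dply; f[l, 2] -= dEdp * dplz

    for g in range(go_pairs.shape[0]):
        i, j = go_pairs[g, 0], go_pairs[g, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        s = go_r0[g] / r
        s10 = s ** 10
        mag = th_contact * go_eps * 60.0 * (s10 * s * s - s10) / r2
        f[i, 0] += mag * dx; f[i, 1] += mag * dy; f[i, 2] += mag * dz
        f[j, 0] -= mag * dx; f[j, 1] -= mag * dy; f[j, 2] -= mag * dz

    for p in range(pair_terms.shape[0]):
        i, j = pair_terms[p, 0], pair_terms[p, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        mag = -th_pair * pair_k * (r - pair_r0[p]) / r
        f[i, 0] += mag * dx; f[i, 1] += mag * dy; f[i, 2] += mag * dz
        f[j, 0] -= mag * dx; f[j, 1] -= mag * dy; f[j, 2] -= mag * dz

    for p in range(stack_terms.shape[0]):
        i, j = stack_terms[p, 0], stack_terms[p, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        mag = -th_stack * stack_k * (r - stack_r0[p]) / r
        f[i, 0] += mag * dx; f[i, 1] += mag * dy; f[i, 2] += mag * dz
        f[j, 0] -= mag * dx; f[j, 1] -= mag * dy; f[j, 2] -= mag * dz

    sig2 = ev_sigma * ev_sigma
    for p in range(ev_pairs.shape[0]):
        i, j = ev_pairs[p, 0], ev_pairs[p, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= sig2:
            continue
        r = np.sqrt(r2)
        rc = max(r, 0.2 * ev_sigma)
        s6 = (ev_sigma / rc) ** 6
        mag = 12.0 * ev_eps * s6 * s6 / (rc * rc)
        f[i, 0] += mag * dx; f[i, 1] += mag * dy; f[i, 2] += mag * dz
        f[j, 0] -= mag * dx; f[j, 1] -= mag * dy; f[j, 2] -= mag * dz

    for p in range(elec_pairs.shape[0]):
        i, j = elec_pairs[p, 0], elec_pairs[p, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        x = np.exp(-r / elec_lambda)
        mag = elec_k * x * (1.0 / (r * r) + 1.0 / (elec_lambda * r)) / r
        f[i, 0] += mag * dx; f[i, 1] += mag * dy; f[i, 2] += mag * dz
        f[j, 0] -= mag * dx; f[j, 1] -= mag * dy; f[j, 2] -= mag * dz

    return f
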