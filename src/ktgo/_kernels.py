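"""Compiled inner loops: force evaluation and the BBK Langevin stepper.

Plain scalar-loop implementations of the same functional forms as
:mod:`ktgo.energetics`, jitted with numba when it is importable (they run,
slowly, as pure Python otherwise).  The reference numpy implementation in
``energetics`` is the source of truth; the test suite asserts the two agree
to near machine precision.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn
        return wrap

MIN_PAIR_DISTANCE = 0.1


@njit(cache=True)
def _switch(r, r_on, r_off):
    if r <= r_on:
        return 1.0, 0.0
    if r >= r_off:
        return 0.0, 0.0
    a = r_off * r_off - r * r
    b = r_off * r_off + 2.0 * r * r - 3.0 * r_on * r_on
    denom = (r_off * r_off - r_on * r_on) ** 3
    s = a * a * b / denom
    ds = 12.0 * r * a * (r_on * r_on - r * r) / denom
    return s, ds


@njit(cache=True)
def compute_forces(x, f,
                   bond_idx, bond_k, bond_r0,
                   ang_idx, ang_k, ang_t0,
                   dih_idx, dih_k, dih_n, dih_delta,
                   imp_idx, imp_k, imp_w0,
                   well_idx, well_r0, well_eps,
                   rep_idx, rep_sigma, rep_eps,
                   r_on, r_off):
    """Total potential energy; fills ``f`` with forces (kcal/mol/A)."""
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e = 0.0

    # bonds
    for t in range(bond_idx.shape[0]):
        i = bond_idx[t, 0]
        j = bond_idx[t, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = (dx * dx + dy * dy + dz * dz) ** 0.5
        dr = r - bond_r0[t]
        e += bond_k[t] * dr * dr
        g = -2.0 * bond_k[t] * dr / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz

    # angles
    for t in range(ang_idx.shape[0]):
        i = ang_idx[t, 0]
        j = ang_idx[t, 1]
        k = ang_idx[t, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = (ux * ux + uy * uy + uz * uz) ** 0.5
        nv = (vx * vx + vy * vy + vz * vz) ** 0.5
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st2 = 1.0 - ct * ct
        if st2 < 1e-12:
            st2 = 1e-12
        st = st2 ** 0.5
        dt_ = theta - ang_t0[t]
        e += ang_k[t] * dt_ * dt_
        pref = 2.0 * ang_k[t] * dt_ / st
        fix = pref * (vx / (nu * nv) - ct * ux / (nu * nu))
        fiy = pref * (vy / (nu * nv) - ct * uy / (nu * nu))
        fiz = pref * (vz / (nu * nv) - ct * uz / (nu * nu))
        fkx = pref * (ux / (nu * nv) - ct * vx / (nv * nv))
        fky = pref * (uy / (nu * nv) - ct * vy / (nv * nv))
        fkz = pref * (uz / (nu * nv) - ct * vz / (nv * nv))
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz

    # torsions (proper dihedrals and harmonic impropers share the geometry)
    for block in range(2):
        idx = dih_idx if block == 0 else imp_idx
        for t in range(idx.shape[0]):
            p0 = idx[t, 0]
            p1 = idx[t, 1]
            p2 = idx[t, 2]
            p3 = idx[t, 3]
            b1x = x[p1, 0] - x[p0, 0]
            b1y = x[p1, 1] - x[p0, 1]
            b1z = x[p1, 2] - x[p0, 2]
            b2x = x[p2, 0] - x[p1, 0]
            b2y = x[p2, 1] - x[p1, 1]
            b2z = x[p2, 2] - x[p1, 2]
            b3x = x[p3, 0] - x[p2, 0]
            b3y = x[p3, 1] - x[p2, 1]
            b3z = x[p3, 2] - x[p2, 2]
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            nb2 = (b2x * b2x + b2y * b2y + b2z * b2z) ** 0.5
            mx = (b2y * n1z - b2z * n1y) / nb2
            my = (b2z * n1x - b2x * n1z) / nb2
            mz = (b2x * n1y - b2y * n1x) / nb2
            xx = n1x * n2x + n1y * n2y + n1z * n2z
            yy = mx * n2x + my * n2y + mz * n2z
            phi = np.arctan2(yy, xx)
            n1sq = n1x * n1x + n1y * n1y + n1z * n1z
            n2sq = n2x * n2x + n2y * n2y + n2z * n2z
            g0x = -nb2 / n1sq * n1x
            g0y = -nb2 / n1sq * n1y
            g0z = -nb2 / n1sq * n1z
            g3x = nb2 / n2sq * n2x
            g3y = nb2 / n2sq * n2y
            g3z = nb2 / n2sq * n2z
            s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
            s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
            g1x = -(1.0 + s12) * g0x + s32 * g3x
            g1y = -(1.0 + s12) * g0y + s32 * g3y
            g1z = -(1.0 + s12) * g0z + s32 * g3z
            g2x = -(g0x + g1x + g3x)
            g2y = -(g0y + g1y + g3y)
            g2z = -(g0z + g1z + g3z)
            if block == 0:
                arg = dih_n[t] * phi - dih_delta[t]
                e += dih_k[t] * (1.0 + np.cos(arg))
                dedphi = -dih_k[t] * dih_n[t] * np.sin(arg)
            else:
                d = phi - imp_w0[t]
                while d > np.pi:
                    d -= 2.0 * np.pi
                while d <= -np.pi:
                    d += 2.0 * np.pi
                e += imp_k[t] * d * d
                dedphi = 2.0 * imp_k[t] * d
            f[p0, 0] -= dedphi * g0x
            f[p0, 1] -= dedphi * g0y
            f[p0, 2] -= dedphi * g0z
            f[p1, 0] -= dedphi * g1x
            f[p1, 1] -= dedphi * g1y
            f[p1, 2] -= dedphi * g1z
            f[p2, 0] -= dedphi * g2x
            f[p2, 1] -= dedphi * g2y
            f[p2, 2] -= dedphi * g2z
            f[p3, 0] -= dedphi * g3x
            f[p3, 1] -= dedphi * g3y
            f[p3, 2] -= dedphi * g3z

    # 12-6 wells (native contacts and hydrogen bonds)
    for t in range(well_idx.shape[0]):
        i = well_idx[t, 0]
        j = well_idx[t, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = (dx * dx + dy * dy + dz * dz) ** 0.5
        if r >= r_off:
            continue
        if r < MIN_PAIR_DISTANCE:
            r = MIN_PAIR_DISTANCE
        x6 = (well_r0[t] / r) ** 6
        v = well_eps[t] * (x6 * x6 - 2.0 * x6)
        dv = -12.0 * well_eps[t] / r * (x6 * x6 - x6)
        s, ds = _switch(r, r_on, r_off)
        e += v * s
        g = -(dv * s + v * ds) / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz

    # excluded-volume repulsion
    for t in range(rep_idx.shape[0]):
        i = rep_idx[t, 0]
        j = rep_idx[t, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = (dx * dx + dy * dy + dz * dz) ** 0.5
        if r >= r_off:
            continue
        if r < MIN_PAIR_DISTANCE:
            r = MIN_PAIR_DISTANCE
        v = rep_eps * (rep_sigma[t] / r) ** 12
        dv = -12.0 * v / r
        s, ds = _switch(r, r_on, r_off)
        e += v * s
        g = -(dv * s + v * ds) / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz

    return e


@njit(cache=True)
def langevin_block(x, v, f, masses, dt, gamma, kT, normals, step0, save_interval,
                   frames, epot, ekin, save_start,
                   bond_idx, bond_k, bond_r0,
                   ang_idx, ang_k, ang_t0,
                   dih_idx, dih_k, dih_n, dih_delta,
                   imp_idx, imp_k, imp_w0,
                   well_idx, well_r0, well_eps,
                   rep_idx, rep_sigma, rep_eps,
                   r_on, r_off):
    """Run ``len(normals)`` BBK steps in place; returns (#frames saved, E_pot).

    ``masses`` are in kcal/mol/(A/ps)^2 units; ``f`` must hold the forces for
    the incoming ``x``.  Frames (positions, potential and kinetic energy) are
    recorded whenever the global step counter hits a multiple of
    ``save_interval``.
    """
    n = x.shape[0]
    nsteps = normals.shape[0]
    c1 = 1.0 - 0.5 * gamma * dt
    c2 = 1.0 / (1.0 + 0.5 * gamma * dt)
    count = save_start
    e = 0.0
    for s in range(nsteps):
        for i in range(n):
            std = (2.0 * gamma * masses[i] * kT / dt) ** 0.5
            hdt = 0.5 * dt / masses[i]
            for d in range(3):
                R = std * normals[s, i, d]
                v[i, d] = c1 * v[i, d] + hdt * (f[i, d] + R)
                x[i, d] += dt * v[i, d]
        e = compute_forces(x, f,
                           bond_idx, bond_k, bond_r0,
                           ang_idx, ang_k, ang_t0,
                           dih_idx, dih_k, dih_n, dih_delta,
                           imp_idx, imp_k, imp_w0,
                           well_idx, well_r0, well_eps,
                           rep_idx, rep_sigma, rep_eps,
                           r_on, r_off)
        ke = 0.0
        for i in range(n):
            std = (2.0 * gamma * masses[i] * kT / dt) ** 0.5
            hdt = 0.5 * dt / masses[i]
            for d in range(3):
                R = std * normals[s, i, d]
                v[i, d] = c2 * (v[i, d] + hdt * (f[i, d] + R))
                ke += 0.5 * masses[i] * v[i, d] * v[i, d]
        if (step0 + s + 1) % save_interval == 0:
            for i in range(n):
                for d in range(3):
                    frames[count, i, d] = x[i, d]
            epot[count] = e
            ekin[count] = ke
            count += 1
    return count, e
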