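"""Numba-compiled force, integration and energy kernels.

Everything here works on plain numpy arrays in reduced units.  The driver
code in :mod:`mesocat.integrate` and :mod:`mesocat.runner` owns the arrays
and calls these kernels in blocks; a block ends either after the requested
number of steps or early, when a reactive bead enters the capture volume of
an accepting catalyst site (the reaction bookkeeping is python-side).

Conventions
-----------
- ``bonds``: (B, 2) int64 bead pairs; ``bond_kind`` 0 = FENE (Kremer-Grest
  chain bond, FENE + the always-on WCA), 1 = harmonic reaction bond.
- ``angles``: (A, 3) int64 triplets, centre bead in the middle.
- ``tether_bead`` / ``tether_anchor``: harmonic springs from a bead to a
  fixed point in space (the catalyst "metal" anchors).
- ``pbc``: (3,) uint8 periodic flags; minimum image only along periodic
  axes.
- ``wall_kind``: 0 none (bulk), 1 planar walls at x=0 and x=Lx,
  2 slit membrane (solid slabs for x in [0, l] outside the gap
  [z_lo, z_hi]), 3 cylindrical membrane (solid for x in [0, l] at radial
  distance >= r_pore from the box axis).  ``wall_p`` packs the geometry:
  kind 1: unused; kind 2: (l, z_lo, z_hi); kind 3: (l, r_pore, yc, zc).
- Catalyst cores are fixed soft spheres: WCA with length scale
  ``core_sig`` (the core radius), so a bead touching the core surface sits
  at about one epsilon of repulsion.

Box lengths and periodicity flags are hoisted into scalars inside every
hot loop (array loads would be reloaded each iteration because the
compiler cannot prove they do not alias the force array).

Status codes returned by the block integrator:
0 = completed, 1 = binding event, 2 = diverged FENE bond, 3 = particle
inside wall material or non-finite coordinate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Pair energies above this value are treated as hard overlap by the GCMC
#: energy helper (the move is rejected outright).
E_CAP = 400.0


@njit(cache=True, inline="always")
def _mi1(d, L, per):
    """Minimum image along one axis (scalar box length / flag)."""
    if per:
        d -= L * np.rint(d / L)
    return d


@njit(cache=True, inline="always")
def _wca_ef(r2, eps, sig2, rc2):
    """WCA energy and force/r at squared separation r2 (0 beyond cutoff)."""
    if r2 >= rc2:
        return 0.0, 0.0
    sr2 = sig2 / r2
    sr6 = sr2 * sr2 * sr2
    sr12 = sr6 * sr6
    e = 4.0 * eps * (sr12 - sr6) + eps
    f_over_r = 24.0 * eps * (2.0 * sr12 - sr6) / r2
    return e, f_over_r


@njit(cache=True, inline="always")
def _wall_dist_s(x, y, z, wall_kind, p0, p1, p2, p3, bx):
    """Distance from a point to the nearest wall material and the unit
    gradient of that distance (pointing away from the material).

    d < 0 flags a point inside the material; 1e30 means no wall nearby.
    Only the nearest solid matters because the WCA range is far smaller
    than any wall separation used here.
    """
    if wall_kind == 0:
        return 1.0e30, 0.0, 0.0, 0.0
    if wall_kind == 1:
        d_lo = x
        d_hi = bx - x
        if d_lo <= d_hi:
            return d_lo, 1.0, 0.0, 0.0
        return d_hi, -1.0, 0.0, 0.0
    # membrane kinds: pore material occupies x in [0, l] (periodic x)
    l = p0
    xx = x % bx
    if xx <= l:
        dxo = 0.0
        face = 0.0
    elif xx - l <= bx - xx:
        dxo = xx - l
        face = 1.0  # nearer the face at x = l, outward is +x
    else:
        dxo = bx - xx
        face = -1.0  # nearer the wrapped face at x = 0, outward is -x
    if wall_kind == 2:
        d_up = p2 - z  # below the upper solid
        d_dn = z - p1  # above the lower solid
        if d_up <= d_dn:
            dperp = d_up
            gz = -1.0
        else:
            dperp = d_dn
            gz = 1.0
        if dxo == 0.0:
            return dperp, 0.0, 0.0, gz
        if dperp <= 0.0:
            return dxo, face, 0.0, 0.0
        d = np.sqrt(dxo * dxo + dperp * dperp)
        return d, face * dxo / d, 0.0, gz * dperp / d
    # wall_kind == 3, cylinder
    yy = y - p2
    zz = z - p3
    rr = np.sqrt(yy * yy + zz * zz)
    dperp = p1 - rr
    if rr > 1.0e-12:
        gy = -yy / rr
        gz = -zz / rr
    else:
        gy = 0.0
        gz = 0.0
    if dxo == 0.0:
        return dperp, 0.0, gy, gz
    if dperp <= 0.0:
        return dxo, face, 0.0, 0.0
    d = np.sqrt(dxo * dxo + dperp * dperp)
    return d, face * dxo / d, gy * dperp / d, gz * dperp / d


@njit(cache=True)
def _wall_dist(x, y, z, wall_kind, wall_p, box):
    """Array-argument wrapper around the scalar wall distance."""
    return _wall_dist_s(
        x, y, z, wall_kind, wall_p[0], wall_p[1], wall_p[2], wall_p[3], box[0]
    )


@njit(cache=True)
def build_pairs(pos, box, pbc, rlist):
    """All bead pairs within ``rlist`` (cell list; brute force fallback).

    Returns an (M, 2) int64 array; a superset usable until any bead has
    moved more than half the skin ``rlist - cutoff``.
    """
    n = pos.shape[0]
    rl2 = rlist * rlist
    bx, by, bz = box[0], box[1], box[2]
    px, py, pz = pbc[0] != 0, pbc[1] != 0, pbc[2] != 0
    ncx = max(1, int(bx / rlist))
    ncy = max(1, int(by / rlist))
    ncz = max(1, int(bz / rlist))
    # for dilute systems, cap the grid at ~2 cells per bead so the empty
    # neighbour-cell visits do not dominate over the pair loop
    ncell_total = float(ncx) * float(ncy) * float(ncz)
    target = 2.0 * n
    if ncell_total > target:
        shrink = (target / ncell_total) ** (1.0 / 3.0)
        ncx = max(3 if px else 1, int(ncx * shrink))
        ncy = max(3 if py else 1, int(ncy * shrink))
        ncz = max(3 if pz else 1, int(ncz * shrink))
    use_cells = n > 40
    if (px and ncx < 3) or (py and ncy < 3) or (pz and ncz < 3):
        use_cells = False
    if not use_cells:
        cap = n * (n - 1) // 2
        pairs = np.empty((cap, 2), dtype=np.int64)
        m = 0
        for i in range(n):
            xi = pos[i, 0]
            yi = pos[i, 1]
            zi = pos[i, 2]
            for j in range(i + 1, n):
                dx = _mi1(xi - pos[j, 0], bx, px)
                dy = _mi1(yi - pos[j, 1], by, py)
                dz = _mi1(zi - pos[j, 2], bz, pz)
                if dx * dx + dy * dy + dz * dz < rl2:
                    pairs[m, 0] = i
                    pairs[m, 1] = j
                    m += 1
        return pairs[:m].copy()
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cellof = np.empty((n, 3), dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / bx * ncx) % ncx
        cy = int(pos[i, 1] / by * ncy) % ncy
        cz = int(pos[i, 2] / bz * ncz) % ncz
        if cx < 0:
            cx += ncx
        if cy < 0:
            cy += ncy
        if cz < 0:
            cz += ncz
        cellof[i, 0] = cx
        cellof[i, 1] = cy
        cellof[i, 2] = cz
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i
    cap = 1024
    pairs = np.empty((cap, 2), dtype=np.int64)
    m = 0
    # occupant-centric sweep: for each bead, scan the 27 cells around its
    # own cell and keep j > i (each unordered pair is found exactly once;
    # periodic cell counts are >= 3, so wrapped neighbours are distinct)
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        cx = cellof[i, 0]
        cy = cellof[i, 1]
        cz = cellof[i, 2]
        for ox in range(-1, 2):
            nx = cx + ox
            if nx < 0:
                if not px:
                    continue
                nx += ncx
            elif nx >= ncx:
                if not px:
                    continue
                nx -= ncx
            base_x = nx * ncy
            for oy in range(-1, 2):
                ny = cy + oy
                if ny < 0:
                    if not py:
                        continue
                    ny += ncy
                elif ny >= ncy:
                    if not py:
                        continue
                    ny -= ncy
                base_xy = (base_x + ny) * ncz
                for oz in range(-1, 2):
                    nz = cz + oz
                    if nz < 0:
                        if not pz:
                            continue
                        nz += ncz
                    elif nz >= ncz:
                        if not pz:
                            continue
                        nz -= ncz
                    j = head[base_xy + nz]
                    while j >= 0:
                        if j > i:
                            dx = _mi1(xi - pos[j, 0], bx, px)
                            dy = _mi1(yi - pos[j, 1], by, py)
                            dz = _mi1(zi - pos[j, 2], bz, pz)
                            if dx * dx + dy * dy + dz * dz < rl2:
                                if m >= cap:
                                    cap *= 2
                                    newp = np.empty((cap, 2), dtype=np.int64)
                                    newp[:m] = pairs[:m]
                                    pairs = newp
                                pairs[m, 0] = i
                                pairs[m, 1] = j
                                m += 1
                        j = nxt[j]
    return pairs[:m].copy()


@njit(cache=True)
def compute_forces(
    pos,
    forces,
    pairs,
    bonds,
    bond_kind,
    angles,
    tether_bead,
    tether_anchor,
    box,
    pbc,
    wall_kind,
    wall_p,
    core_pos,
    core_sig,
    eps,
    sigma,
    fene_k,
    fene_rmax,
    harm_k,
    harm_r0,
    k_angle,
    want_energy,
):
    """Fill ``forces`` with minus the potential gradient.

    Returns (epot, status, bad_i, bad_j); the potential energy is only
    accumulated when ``want_energy`` is set (the FENE logarithm is the
    most expensive term of the hot loop).
    """
    n = pos.shape[0]
    bx, by, bz = box[0], box[1], box[2]
    px, py, pz = pbc[0] != 0, pbc[1] != 0, pbc[2] != 0
    wp0, wp1, wp2, wp3 = wall_p[0], wall_p[1], wall_p[2], wall_p[3]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    epot = 0.0
    sig2 = sigma * sigma
    rc2 = 2.0 ** (1.0 / 3.0) * sig2
    # non-bonded WCA
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = _mi1(pos[i, 0] - pos[j, 0], bx, px)
        dy = _mi1(pos[i, 1] - pos[j, 1], by, py)
        dz = _mi1(pos[i, 2] - pos[j, 2], bz, pz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            e, fr = _wca_ef(r2, eps, sig2, rc2)
            epot += e
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz
    # bonds
    rmax2 = fene_rmax * fene_rmax
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _mi1(pos[i, 0] - pos[j, 0], bx, px)
        dy = _mi1(pos[i, 1] - pos[j, 1], by, py)
        dz = _mi1(pos[i, 2] - pos[j, 2], bz, pz)
        r2 = dx * dx + dy * dy + dz * dz
        if bond_kind[b] == 0:
            if r2 >= rmax2:
                return epot, 2, i, j
            x = r2 / rmax2
            if want_energy:
                epot += -0.5 * fene_k * rmax2 * np.log(1.0 - x)
            fr = -fene_k / (1.0 - x)
        else:
            r = np.sqrt(r2)
            s_ = r - harm_r0
            # force-capped spring: linear potential beyond 0.5 sigma
            # stretch, so a bond formed far from rest cannot detonate the
            # surrounding FENE bonds
            if s_ > 0.5:
                if want_energy:
                    epot += 0.5 * harm_k * 0.25 + harm_k * 0.5 * (s_ - 0.5)
                fmag = -harm_k * 0.5
            elif s_ < -0.5:
                if want_energy:
                    epot += 0.5 * harm_k * 0.25 - harm_k * 0.5 * (s_ + 0.5)
                fmag = harm_k * 0.5
            else:
                if want_energy:
                    epot += 0.5 * harm_k * s_ * s_
                fmag = -harm_k * s_
            if r > 1.0e-12:
                fr = fmag / r
            else:
                fr = 0.0
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    # angles (centre bead second)
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ux = _mi1(pos[i, 0] - pos[j, 0], bx, px)
        uy = _mi1(pos[i, 1] - pos[j, 1], by, py)
        uz = _mi1(pos[i, 2] - pos[j, 2], bz, pz)
        vx = _mi1(pos[k, 0] - pos[j, 0], bx, px)
        vy = _mi1(pos[k, 1] - pos[j, 1], by, py)
        vz = _mi1(pos[k, 2] - pos[j, 2], bz, pz)
        nu2 = ux * ux + uy * uy + uz * uz
        nv2 = vx * vx + vy * vy + vz * vz
        if nu2 < 1.0e-24 or nv2 < 1.0e-24:
            continue
        inv_nunv = 1.0 / np.sqrt(nu2 * nv2)
        c = (ux * vx + uy * vy + uz * vz) * inv_nunv
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        phi = np.arccos(c)
        dphi = phi - np.pi
        if want_energy:
            epot += 0.5 * k_angle * dphi * dphi
        s = np.sqrt(1.0 - c * c)
        # dU/dphi / sin(phi); finite limit -K as phi -> pi
        if s < 1.0e-6:
            coef = -k_angle
        else:
            coef = k_angle * dphi / s
        inv_nu2 = 1.0 / nu2
        inv_nv2 = 1.0 / nv2
        fix = coef * (vx * inv_nunv - c * ux * inv_nu2)
        fiy = coef * (vy * inv_nunv - c * uy * inv_nu2)
        fiz = coef * (vz * inv_nunv - c * uz * inv_nu2)
        fkx = coef * (ux * inv_nunv - c * vx * inv_nv2)
        fky = coef * (uy * inv_nunv - c * vy * inv_nv2)
        fkz = coef * (uz * inv_nunv - c * vz * inv_nv2)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
    # tethers (harmonic spring to a fixed anchor)
    for t in range(tether_bead.shape[0]):
        i = tether_bead[t]
        dx = _mi1(pos[i, 0] - tether_anchor[t, 0], bx, px)
        dy = _mi1(pos[i, 1] - tether_anchor[t, 1], by, py)
        dz = _mi1(pos[i, 2] - tether_anchor[t, 2], bz, pz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        s_ = r - harm_r0
        if s_ > 0.5:
            if want_energy:
                epot += 0.5 * harm_k * 0.25 + harm_k * 0.5 * (s_ - 0.5)
            fmag = -harm_k * 0.5
        elif s_ < -0.5:
            if want_energy:
                epot += 0.5 * harm_k * 0.25 - harm_k * 0.5 * (s_ + 0.5)
            fmag = harm_k * 0.5
        else:
            if want_energy:
                epot += 0.5 * harm_k * s_ * s_
            fmag = -harm_k * s_
        if r > 1.0e-12:
            fr = fmag / r
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
    # walls
    if wall_kind != 0:
        for i in range(n):
            d, gx, gy, gz = _wall_dist_s(
                pos[i, 0], pos[i, 1], pos[i, 2], wall_kind, wp0, wp1, wp2, wp3, bx
            )
            if d <= 0.0:
                return epot, 3, i, -1
            if d * d < rc2:
                e, fr = _wca_ef(d * d, eps, sig2, rc2)
                epot += e
                fmag = fr * d
                forces[i, 0] += fmag * gx
                forces[i, 1] += fmag * gy
                forces[i, 2] += fmag * gz
    # catalyst cores (WCA with length scale core_sig)
    if core_pos.shape[0] > 0:
        cs2 = core_sig * core_sig
        crc2 = 2.0 ** (1.0 / 3.0) * cs2
        for ci in range(core_pos.shape[0]):
            cxp = core_pos[ci, 0]
            cyp = core_pos[ci, 1]
            czp = core_pos[ci, 2]
            for i in range(n):
                dx = _mi1(pos[i, 0] - cxp, bx, px)
                dy = _mi1(pos[i, 1] - cyp, by, py)
                dz = _mi1(pos[i, 2] - czp, bz, pz)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < crc2:
                    e, fr = _wca_ef(r2, eps, cs2, crc2)
                    epot += e
                    forces[i, 0] += fr * dx
                    forces[i, 1] += fr * dy
                    forces[i, 2] += fr * dz
    return epot, 0, -1, -1


@njit(cache=True)
def md_block(
    pos,
    vel,
    forces,
    nsteps,
    noise,
    dt,
    gamma,
    temperature,
    bonds,
    bond_kind,
    angles,
    tether_bead,
    tether_anchor,
    box,
    pbc,
    wall_kind,
    wall_p,
    core_pos,
    core_sig,
    eps,
    sigma,
    fene_k,
    fene_rmax,
    harm_k,
    harm_r0,
    k_angle,
    rlist,
    site_pos,
    site_accept,
    reactive_idx,
    in_capture,
    rcap2,
    check_reactions,
):
    """Advance up to ``nsteps`` BAOAB Langevin steps.

    Binding detection is entry-triggered: a reactive bead fires only on
    the step it crosses from outside into the capture sphere of an
    accepting site (``in_capture`` tracks the per-bead inside state and
    is updated every step).  Exits early with status 1 reporting the
    closest such (site, bead) pair.  Returns (status, steps_done, a, b).
    """
    n = pos.shape[0]
    if n == 0:
        return 0, nsteps, -1, -1
    bx, by, bz = box[0], box[1], box[2]
    px, py, pz = pbc[0] != 0, pbc[1] != 0, pbc[2] != 0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * temperature)
    skin_half = 0.5 * (rlist - 2.0 ** (1.0 / 6.0) * sigma)
    skin_half2 = skin_half * skin_half
    pairs = build_pairs(pos, box, pbc, rlist)
    ref = pos.copy()
    epot, status, a, b = compute_forces(
        pos, forces, pairs, bonds, bond_kind, angles, tether_bead,
        tether_anchor, box, pbc, wall_kind, wall_p, core_pos, core_sig,
        eps, sigma, fene_k, fene_rmax, harm_k, harm_r0, k_angle, False,
    )
    if status != 0:
        return status, 0, a, b
    half = 0.5 * dt
    n_accept = site_pos.shape[0]
    for step in range(nsteps):
        for i in range(n):
            vx = vel[i, 0] + half * forces[i, 0]
            vy = vel[i, 1] + half * forces[i, 1]
            vz = vel[i, 2] + half * forces[i, 2]
            x = pos[i, 0] + half * vx
            y = pos[i, 1] + half * vy
            z = pos[i, 2] + half * vz
            vx = c1 * vx + c2 * noise[step, i, 0]
            vy = c1 * vy + c2 * noise[step, i, 1]
            vz = c1 * vz + c2 * noise[step, i, 2]
            x += half * vx
            y += half * vy
            z += half * vz
            if px and (x < 0.0 or x >= bx):
                x -= bx * np.floor(x / bx)
            if py and (y < 0.0 or y >= by):
                y -= by * np.floor(y / by)
            if pz and (z < 0.0 or z >= bz):
                z -= bz * np.floor(z / bz)
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
        # neighbour list validity
        maxd2 = 0.0
        for i in range(n):
            dx = _mi1(pos[i, 0] - ref[i, 0], bx, px)
            dy = _mi1(pos[i, 1] - ref[i, 1], by, py)
            dz = _mi1(pos[i, 2] - ref[i, 2], bz, pz)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > skin_half2:
            pairs = build_pairs(pos, box, pbc, rlist)
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]
                ref[i, 2] = pos[i, 2]
        epot, status, a, b = compute_forces(
            pos, forces, pairs, bonds, bond_kind, angles, tether_bead,
            tether_anchor, box, pbc, wall_kind, wall_p, core_pos, core_sig,
            eps, sigma, fene_k, fene_rmax, harm_k, harm_r0, k_angle, False,
        )
        if status != 0:
            return status, step, a, b
        for i in range(n):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
        if not np.isfinite(pos[0, 0]):
            return 3, step + 1, 0, -1
        if check_reactions and n_accept > 0:
            best = 1.0e30
            bsite = -1
            bbead = -1
            for t in range(reactive_idx.shape[0]):
                i = reactive_idx[t]
                inside = np.uint8(0)
                xi = pos[i, 0]
                yi = pos[i, 1]
                zi = pos[i, 2]
                for s in range(n_accept):
                    if site_accept[s] == 0:
                        continue
                    dx = _mi1(xi - site_pos[s, 0], bx, px)
                    dy = _mi1(yi - site_pos[s, 1], by, py)
                    dz = _mi1(zi - site_pos[s, 2], bz, pz)
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 < rcap2:
                        inside = np.uint8(1)
                        if in_capture[i] == 0 and d2 < best:
                            best = d2
                            bsite = s
                            bbead = i
                in_capture[i] = inside
            if bsite >= 0:
                return 1, step + 1, bsite, bbead
    return 0, nsteps, -1, -1


@njit(cache=True)
def total_energy(
    pos,
    bonds,
    bond_kind,
    angles,
    tether_bead,
    tether_anchor,
    box,
    pbc,
    wall_kind,
    wall_p,
    core_pos,
    core_sig,
    eps,
    sigma,
    fene_k,
    fene_rmax,
    harm_k,
    harm_r0,
    k_angle,
):
    """Total potential energy via a full pair search (no neighbour list)."""
    forces = np.zeros_like(pos)
    rlist = 2.0 ** (1.0 / 6.0) * sigma * 1.001
    pairs = build_pairs(pos, box, pbc, rlist)
    epot, status, a, b = compute_forces(
        pos, forces, pairs, bonds, bond_kind, angles, tether_bead,
        tether_anchor, box, pbc, wall_kind, wall_p, core_pos, core_sig,
        eps, sigma, fene_k, fene_rmax, harm_k, harm_r0, k_angle, True,
    )
    return epot, status


@njit(cache=True)
def external_energy(
    trial_pos,
    pos,
    mol_id,
    exclude_mol,
    box,
    pbc,
    wall_kind,
    wall_p,
    core_pos,
    core_sig,
    eps,
    sigma,
):
    """Intermolecular + wall + core energy of a set of trial beads.

    Beads of molecule ``exclude_mol`` are skipped (pass -1 to include
    everything).  Used by the grand-canonical insertion and deletion moves;
    returns early with a value above ``E_CAP`` on hard overlap.
    """
    bx, by, bz = box[0], box[1], box[2]
    px, py, pz = pbc[0] != 0, pbc[1] != 0, pbc[2] != 0
    sig2 = sigma * sigma
    rc2 = 2.0 ** (1.0 / 3.0) * sig2
    cs2 = core_sig * core_sig
    crc2 = 2.0 ** (1.0 / 3.0) * cs2
    etot = 0.0
    for t in range(trial_pos.shape[0]):
        tx = trial_pos[t, 0]
        ty = trial_pos[t, 1]
        tz = trial_pos[t, 2]
        if wall_kind != 0:
            d, gx, gy, gz = _wall_dist_s(
                tx, ty, tz, wall_kind, wall_p[0], wall_p[1], wall_p[2],
                wall_p[3], bx,
            )
            if d <= 0.0:
                return E_CAP + 1.0
            if d * d < rc2:
                e, fr = _wca_ef(d * d, eps, sig2, rc2)
                etot += e
        for ci in range(core_pos.shape[0]):
            dx = _mi1(tx - core_pos[ci, 0], bx, px)
            dy = _mi1(ty - core_pos[ci, 1], by, py)
            dz = _mi1(tz - core_pos[ci, 2], bz, pz)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < crc2:
                e, fr = _wca_ef(r2, eps, cs2, crc2)
                etot += e
        for i in range(pos.shape[0]):
            if mol_id[i] == exclude_mol:
                continue
            dx = _mi1(tx - pos[i, 0], bx, px)
            dy = _mi1(ty - pos[i, 1], by, py)
            dz = _mi1(tz - pos[i, 2], bz, pz)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                e, fr = _wca_ef(r2, eps, sig2, rc2)
                etot += e
        if etot > E_CAP:
            return etot
    return etot
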