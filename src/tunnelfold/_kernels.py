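"""Numba kernels for Langevin dynamics of a tethered chain in a static
repulsive scaffold.

The integrator is a BAOAB-style Langevin discretization in reduced units
(unit bead mass, energies in epsilon, lengths in angstrom). Scaffold beads
never move and enter only through a truncated force-shifted r^-12 repulsion,
looked up through a precomputed uniform cell grid. The optional external
double-well term on bead 0 supports single-bead test fixtures with an exact
two-state partition function.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_BLOWUP = 1


@njit(cache=True)
def _add_pair_force(f, pos, i, j, dvdr_over_r):
    dx = pos[j, 0] - pos[i, 0]
    dy = pos[j, 1] - pos[i, 1]
    dz = pos[j, 2] - pos[i, 2]
    f[i, 0] += dvdr_over_r * dx
    f[i, 1] += dvdr_over_r * dy
    f[i, 2] += dvdr_over_r * dz
    f[j, 0] -= dvdr_over_r * dx
    f[j, 1] -= dvdr_over_r * dy
    f[j, 2] -= dvdr_over_r * dz


@njit(cache=True)
def _forces(pos, f, radii,
            bonds, bond_r0, k_bond,
            tether_i, tether_j, k_tether, tether_r0,
            angles, theta0, k_angle,
            dihedrals, phi0, kd1, kd3,
            contacts, sigma, eps_contact,
            rep_pairs, ev_sigma, eps,
            scaf_pos, scaf_rad,
            grid_origin, cell_size, grid_dims, cell_start, cell_items,
            anchor_idx, anchor_pos, k_anchor,
            dw_on, dw_a, dw_b, dw_c, dw_kxy):
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0

    # harmonic bonds V = k (r - r0)^2
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dvdr = 2.0 * k_bond * (r - bond_r0[b])
        _add_pair_force(f, pos, i, j, dvdr / r)

    # tether pseudobond V = 0.5 k (r - r0)^2  (force gauge)
    if tether_i != tether_j and k_tether > 0.0:
        dx = pos[tether_j, 0] - pos[tether_i, 0]
        dy = pos[tether_j, 1] - pos[tether_i, 1]
        dz = pos[tether_j, 2] - pos[tether_i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dvdr = k_tether * (r - tether_r0)
        _add_pair_force(f, pos, tether_i, tether_j, dvdr / r)

    # angles V = ka (theta - theta0)^2
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        s = np.sqrt(max(1.0 - c * c, 1e-12))
        th = np.arccos(c)
        dvdth = 2.0 * k_angle[a] * (th - theta0[a])
        # d(theta)/d(ri) = -(v/(|u||v|) - c u/|u|^2)/s   (and symmetric for k)
        gix = -(vx / (nu * nv) - c * ux / (nu * nu)) / s
        giy = -(vy / (nu * nv) - c * uy / (nu * nu)) / s
        giz = -(vz / (nu * nv) - c * uz / (nu * nu)) / s
        gkx = -(ux / (nu * nv) - c * vx / (nv * nv)) / s
        gky = -(uy / (nu * nv) - c * vy / (nv * nv)) / s
        gkz = -(uz / (nu * nv) - c * vz / (nv * nv)) / s
        f[i, 0] -= dvdth * gix
        f[i, 1] -= dvdth * giy
        f[i, 2] -= dvdth * giz
        f[k, 0] -= dvdth * gkx
        f[k, 1] -= dvdth * gky
        f[k, 2] -= dvdth * gkz
        f[j, 0] += dvdth * (gix + gkx)
        f[j, 1] += dvdth * (giy + gky)
        f[j, 2] += dvdth * (giz + gkz)

    # dihedrals V = kd1 (1 - cos(dphi)) + kd3 (1 - cos(3 dphi))
    for d in range(dihedrals.shape[0]):
        i = dihedrals[d, 0]
        j = dihedrals[d, 1]
        k = dihedrals[d, 2]
        l = dihedrals[d, 3]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        y = (mx * n2x + my * n2y + mz * n2z) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, x)
        dphi = phi - phi0[d]
        dvdphi = kd1 * np.sin(dphi) + 3.0 * kd3 * np.sin(3.0 * dphi)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        dpix = nb2 / n1sq * n1x
        dpiy = nb2 / n1sq * n1y
        dpiz = nb2 / n1sq * n1z
        dplx = -nb2 / n2sq * n2x
        dply = -nb2 / n2sq * n2y
        dplz = -nb2 / n2sq * n2z
        sfac = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        tfac = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        dpjx = -(1.0 + sfac) * dpix + tfac * dplx
        dpjy = -(1.0 + sfac) * dpiy + tfac * dply
        dpjz = -(1.0 + sfac) * dpiz + tfac * dplz
        dpkx = sfac * dpix - (1.0 + tfac) * dplx
        dpky = sfac * dpiy - (1.0 + tfac) * dply
        dpkz = sfac * dpiz - (1.0 + tfac) * dplz
        f[i, 0] -= dvdphi * dpix
        f[i, 1] -= dvdphi * dpiy
        f[i, 2] -= dvdphi * dpiz
        f[j, 0] -= dvdphi * dpjx
        f[j, 1] -= dvdphi * dpjy
        f[j, 2] -= dvdphi * dpjz
        f[k, 0] -= dvdphi * dpkx
        f[k, 1] -= dvdphi * dpky
        f[k, 2] -= dvdphi * dpkz
        f[l, 0] -= dvdphi * dplx
        f[l, 1] -= dvdphi * dply
        f[l, 2] -= dvdphi * dplz

    # native contacts: 12-10 well, V = eps (5 (s/r)^12 - 6 (s/r)^10)
    for cidx in range(contacts.shape[0]):
        i = contacts[cidx, 0]
        j = contacts[cidx, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        xr = sigma[cidx] / r
        x10 = xr ** 10
        x12 = x10 * xr * xr
        dvdr = eps_contact * (-60.0 * x12 + 60.0 * x10) / r
        _add_pair_force(f, pos, i, j, dvdr / r)

    # excluded volume within the chain: force-shifted r^-12, zero beyond ev_sigma
    ev2 = ev_sigma * ev_sigma
    for p in range(rep_pairs.shape[0]):
        i = rep_pairs[p, 0]
        j = rep_pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < ev2:
            r = np.sqrt(r2)
            dvdr = eps * (-12.0 * ev_sigma ** 12 / r ** 13 + 12.0 / ev_sigma)
            _add_pair_force(f, pos, i, j, dvdr / r)

    # chain-scaffold repulsion via the static cell grid
    if scaf_pos.shape[0] > 0:
        for i in range(n):
            cx = int(np.floor((pos[i, 0] - grid_origin[0]) / cell_size))
            cy = int(np.floor((pos[i, 1] - grid_origin[1]) / cell_size))
            cz = int(np.floor((pos[i, 2] - grid_origin[2]) / cell_size))
            for ox in range(-1, 2):
                gx = cx + ox
                if gx < 0 or gx >= grid_dims[0]:
                    continue
                for oy in range(-1, 2):
                    gy = cy + oy
                    if gy < 0 or gy >= grid_dims[1]:
                        continue
                    for oz in range(-1, 2):
                        gz = cz + oz
                        if gz < 0 or gz >= grid_dims[2]:
                            continue
                        cell = (gx * grid_dims[1] + gy) * grid_dims[2] + gz
                        for q in range(cell_start[cell], cell_start[cell + 1]):
                            j = cell_items[q]
                            dx = scaf_pos[j, 0] - pos[i, 0]
                            dy = scaf_pos[j, 1] - pos[i, 1]
                            dz = scaf_pos[j, 2] - pos[i, 2]
                            s = radii[i] + scaf_rad[j]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < s * s:
                                r = np.sqrt(r2)
                                dvdr = eps * (-12.0 * s ** 12 / r ** 13
                                              + 12.0 / s)
                                # force on chain bead only; scaffold is static
                                f[i, 0] += dvdr / r * dx
                                f[i, 1] += dvdr / r * dy
                                f[i, 2] += dvdr / r * dz

    # position restraint of the anchored bead
    if anchor_idx >= 0 and k_anchor > 0.0:
        f[anchor_idx, 0] -= k_anchor * (pos[anchor_idx, 0] - anchor_pos[0])
        f[anchor_idx, 1] -= k_anchor * (pos[anchor_idx, 1] - anchor_pos[1])
        f[anchor_idx, 2] -= k_anchor * (pos[anchor_idx, 2] - anchor_pos[2])

    # external double-well on bead 0 (test fixtures):
    # V = a (z^2 - b^2)^2 + c z + 0.5 kxy (x^2 + y^2)
    if dw_on:
        z = pos[0, 2]
        f[0, 2] -= 4.0 * dw_a * z * (z * z - dw_b * dw_b) + dw_c
        f[0, 0] -= dw_kxy * pos[0, 0]
        f[0, 1] -= dw_kxy * pos[0, 1]


@njit(cache=True)
def run_baoab(pos_init, radii,
              bonds, bond_r0, k_bond,
              tether_i, tether_j, k_tether, tether_r0,
              angles, theta0, k_angle,
              dihedrals, phi0, kd1, kd3,
              contacts, sigma, eps_contact, q_tol,
              rep_pairs, ev_sigma, eps,
              scaf_pos, scaf_rad,
              grid_origin, cell_size, grid_dims, cell_start, cell_items,
              anchor_idx, anchor_pos, k_anchor,
              dw_on, dw_a, dw_b, dw_c, dw_kxy,
              pull_dir,
              kT, gamma, dt, n_steps, equil, stride, seed, max_disp):
    """Integrate and record (Q, projected tether elongation, bead-0
    position) every ``stride`` steps after ``equil`` equilibration steps.

    The recorded tether observable is (r - r0) * cos(angle to pull_dir):
    the elongation of the pseudobond projected on the pulling axis, whose
    mean times the spring constant is the mean pulling force. The
    projection removes the radial-Jacobian offset (~2 kT / r0) that a bare
    mean of (r - r0) would carry at zero load.

    Returns (q_series, ext_series, pos0_series, final_pos, status).
    """
    np.random.seed(seed)
    n = pos_init.shape[0]
    pos = pos_init.copy()
    vel = np.empty((n, 3))
    skT = np.sqrt(kT)
    for i in range(n):
        for d in range(3):
            vel[i, d] = skT * np.random.normal(0.0, 1.0)
    f = np.empty((n, 3))
    _forces(pos, f, radii, bonds, bond_r0, k_bond,
            tether_i, tether_j, k_tether, tether_r0,
            angles, theta0, k_angle, dihedrals, phi0, kd1, kd3,
            contacts, sigma, eps_contact, rep_pairs, ev_sigma, eps,
            scaf_pos, scaf_rad, grid_origin, cell_size, grid_dims,
            cell_start, cell_items, anchor_idx, anchor_pos, k_anchor,
            dw_on, dw_a, dw_b, dw_c, dw_kxy)

    total = equil + n_steps
    n_rec = n_steps // stride
    q_series = np.zeros(n_rec)
    ext_series = np.zeros(n_rec)
    pos0_series = np.zeros((n_rec, 3))
    rec = 0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1) * skT
    half = 0.5 * dt
    status = STATUS_OK

    for step in range(total):
        maxd2 = 0.0
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * f[i, d]
        for i in range(n):
            for d in range(3):
                dx = half * vel[i, d]
                pos[i, d] += dx
                if dx * dx > maxd2:
                    maxd2 = dx * dx
        for i in range(n):
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * np.random.normal(0.0, 1.0)
        for i in range(n):
            for d in range(3):
                dx = half * vel[i, d]
                pos[i, d] += dx
                if dx * dx > maxd2:
                    maxd2 = dx * dx
        _forces(pos, f, radii, bonds, bond_r0, k_bond,
                tether_i, tether_j, k_tether, tether_r0,
                angles, theta0, k_angle, dihedrals, phi0, kd1, kd3,
                contacts, sigma, eps_contact, rep_pairs, ev_sigma, eps,
                scaf_pos, scaf_rad, grid_origin, cell_size, grid_dims,
                cell_start, cell_items, anchor_idx, anchor_pos, k_anchor,
                dw_on, dw_a, dw_b, dw_c, dw_kxy)
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * f[i, d]
        if maxd2 > max_disp * max_disp:
            status = STATUS_BLOWUP
            break
        if step >= equil and (step - equil) % stride == stride - 1 and rec < n_rec:
            if contacts.shape[0] > 0:
                formed = 0
                for cidx in range(contacts.shape[0]):
                    i = contacts[cidx, 0]
                    j = contacts[cidx, 1]
                    dx = pos[j, 0] - pos[i, 0]
                    dy = pos[j, 1] - pos[i, 1]
                    dz = pos[j, 2] - pos[i, 2]
                    r = np.sqrt(dx * dx + dy * dy + dz * dz)
                    if r <= q_tol * sigma[cidx]:
                        formed += 1
                q_series[rec] = formed / contacts.shape[0]
            else:
                q_series[rec] = 1.0 if pos[0, 2] > 0.0 else 0.0
            if tether_i != tether_j:
                # vector from the anchored bead (tether_j) outward
                dx = pos[tether_i, 0] - pos[tether_j, 0]
                dy = pos[tether_i, 1] - pos[tether_j, 1]
                dz = pos[tether_i, 2] - pos[tether_j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                proj = (dx * pull_dir[0] + dy * pull_dir[1]
                        + dz * pull_dir[2]) / r
                ext_series[rec] = (r - tether_r0) * proj
            pos0_series[rec, 0] = pos[0, 0]
            pos0_series[rec, 1] = pos[0, 1]
            pos0_series[rec, 2] = pos[0, 2]
            rec += 1

    return q_series[:rec], ext_series[:rec], pos0_series[:rec], pos, status


def build_cell_grid(scaf_pos: np.ndarray, cell_size: float = 6.0):
    """CSR cell grid over static scaffold beads for neighbour lookup."""
    scaf_pos = np.asarray(scaf_pos, dtype=float).reshape(-1, 3)
    if len(scaf_pos) == 0:
        return (np.zeros(3), cell_size, np.ones(3, dtype=np.int64),
                np.zeros(2, dtype=np.int64), np.zeros(0, dtype=np.int64))
    origin = scaf_pos.min(axis=0) - cell_size
    extent = scaf_pos.max(axis=0) - origin + cell_size
    dims = np.maximum(np.ceil(extent / cell_size).astype(np.int64), 1)
    coords = np.floor((scaf_pos - origin) / cell_size).astype(np.int64)
    coords = np.minimum(np.maximum(coords, 0), dims - 1)
    flat = (coords[:, 0] * dims[1] + coords[:, 1]) * dims[2] + coords[:, 2]
    order = np.argsort(flat, kind="stable")
    ncells = int(dims[0] * dims[1] * dims[2])
    start = np.zeros(ncells + 1, dtype=np.int64)
    np.add.at(start, flat + 1, 1)
    start = np.cumsum(start)
    return origin, cell_size, dims, start, order.astype(np.int64)
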