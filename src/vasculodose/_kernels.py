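"""Numba kernels for the history-based photon/electron transport.

Geometry: the labeled cube occupies [0, side]^3 um; it is surrounded by a
uniform soft-tissue padding box (electronic-equilibrium shell).  Photons
are tracked analytically through the padding and by Woodcock
delta-tracking (majorant = densest material present) inside the cube.
Electrons slow down continuously along straight (or per-step isotropically
resampled) paths using tabulated collision stopping power.

Energy is tallied in keV into per-(tally-cell, label) bins inside the
cube; deposition in the padding and energy leaving the world are
accumulated separately so that every batch closes its energy balance
exactly.  All randomness comes from numba's per-batch seeded MT19937.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# accumulator slots
EMITTED, ESCAPED, PAD_DEP = 0, 1, 2

ELECTRON_REST = 510.99895  # keV


@njit(cache=True, inline="always")
def _interp_loglin(loge0, dloge, n, table_row, e):
    """Linear interpolation on the dense log-energy grid."""
    f = (np.log(e) - loge0) / dloge
    if f <= 0.0:
        return table_row[0]
    if f >= n - 1:
        return table_row[n - 1]
    i = int(f)
    w = f - i
    return table_row[i] * (1.0 - w) + table_row[i + 1] * w


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999999:
        sign = 1.0 if uz > 0.0 else -1.0
        return sint * cosp, sign * sint * sinp, sign * cost
    s = np.sqrt(1.0 - uz * uz)
    nx = ux * cost + sint * (ux * uz * cosp - uy * sinp) / s
    ny = uy * cost + sint * (uy * uz * cosp + ux * sinp) / s
    nz = uz * cost - s * sint * cosp
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _isotropic():
    cost = 1.0 - 2.0 * np.random.random()
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * np.pi * np.random.random()
    return sint * np.cos(phi), sint * np.sin(phi), cost


@njit(cache=True, inline="always")
def _ray_box(x, y, z, ux, uy, uz, lo0, lo1, lo2, hi0, hi1, hi2):
    """Entry/exit distances of a ray with an axis-aligned box.

    Returns (t_in, t_out); no intersection ahead gives t_in > t_out.
    """
    tmin = -1.0e30
    tmax = 1.0e30
    for axis in range(3):
        if axis == 0:
            o, d, lo, hi = x, ux, lo0, hi0
        elif axis == 1:
            o, d, lo, hi = y, uy, lo1, hi1
        else:
            o, d, lo, hi = z, uz, lo2, hi2
        if abs(d) < 1e-12:
            if o < lo or o > hi:
                return 1.0, -1.0
        else:
            t1 = (lo - o) / d
            t2 = (hi - o) / d
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    return tmin, tmax


@njit(cache=True, inline="always")
def _deposit(dose, acc, labels, n_vox, voxel_um, cell_um, side,
             wlox, whix, wloz, whiz, x, y, z, e):
    """Tally energy e (keV) at a point: cube bin, padding, or escaped."""
    if 0.0 <= x < side and 0.0 <= y < side and 0.0 <= z < side:
        ix = min(int(x / voxel_um), n_vox - 1)
        iy = min(int(y / voxel_um), n_vox - 1)
        iz = min(int(z / voxel_um), n_vox - 1)
        lab = labels[ix, iy, iz]
        icx = min(int(x / cell_um), dose.shape[0] - 1)
        icy = min(int(y / cell_um), dose.shape[1] - 1)
        icz = min(int(z / cell_um), dose.shape[2] - 1)
        dose[icx, icy, icz, lab] += e
    elif wlox <= x <= whix and wlox <= y <= whix and wloz <= z <= whiz:
        acc[PAD_DEP] += e
    else:
        acc[ESCAPED] += e


@njit(cache=True)
def _electron(e0, x, y, z, ux, uy, uz, mode,
              labels, n_vox, voxel_um, cell_um, side,
              wlox, whix, wloz, whiz,
              se_loge0, se_dloge, se_n, sdens, rng_um, densities,
              electron_cutoff, dose, acc):
    """CSDA electron slow-down; returns (x, y, z, ended_inside_world)."""
    e = e0
    if mode == 0:  # local deposition
        _deposit(dose, acc, labels, n_vox, voxel_um, cell_um, side,
                 wlox, whix, wloz, whiz, x, y, z, e)
        return x, y, z, True
    while e > electron_cutoff:
        # material at current position (padding = soft tissue, index 0)
        if 0.0 <= x < side and 0.0 <= y < side and 0.0 <= z < side:
            mat = labels[min(int(x / voxel_um), n_vox - 1),
                         min(int(y / voxel_um), n_vox - 1),
                         min(int(z / voxel_um), n_vox - 1)]
        else:
            mat = 0
        sd = _interp_loglin(se_loge0, se_dloge, se_n, sdens[mat], e)  # keV/um
        rr = _interp_loglin(se_loge0, se_dloge, se_n, rng_um[mat], e)  # um
        step = min(cell_um, 0.1 * rr)
        if step < 1e-3:
            step = 1e-3
        de = sd * step
        if de >= e:
            _deposit(dose, acc, labels, n_vox, voxel_um, cell_um, side,
                     wlox, whix, wloz, whiz, x, y, z, e)
            return x, y, z, True
        _deposit(dose, acc, labels, n_vox, voxel_um, cell_um, side,
                 wlox, whix, wloz, whiz, x, y, z, de)
        e -= de
        x += step * ux
        y += step * uy
        z += step * uz
        if not (wlox <= x <= whix and wlox <= y <= whix and wloz <= z <= whiz):
            acc[ESCAPED] += e
            return x, y, z, False
        if mode == 2:
            ux, uy, uz = _isotropic()
    _deposit(dose, acc, labels, n_vox, voxel_um, cell_um, side,
             wlox, whix, wloz, whiz, x, y, z, e)
    return x, y, z, True


@njit(cache=True)
def run_batch(seed, n_hist,
              labels, voxel_um, side, pad_um, margin_um,
              spec_e, spec_cdf,
              loge0, dloge, n_e,
              mu_pe, mu_inc, mu_coh, mu_pair, mu_tot, mu_maj,
              se_loge0, se_dloge, se_n, sdens, rng_um, densities,
              bind_eff, k_edge, k_xray, k_yield, k_frac,
              photon_cutoff, electron_cutoff, electron_mode,
              cell_um, dose, depth_hist, depth_z0, depth_dz):
    """Transport one batch of photon histories; returns the accumulator
    [emitted, escaped, padding-deposit] in keV."""
    np.random.seed(seed)
    acc = np.zeros(3)
    n_vox = labels.shape[0]
    lat = max(pad_um, margin_um)
    wlox, whix = -lat, side + lat
    wloz, whiz = -pad_um, side + pad_um

    max_stack = 64
    st_e = np.zeros(max_stack)
    st_x = np.zeros(max_stack)
    st_y = np.zeros(max_stack)
    st_z = np.zeros(max_stack)
    st_ux = np.zeros(max_stack)
    st_uy = np.zeros(max_stack)
    st_uz = np.zeros(max_stack)
    st_pr = np.zeros(max_stack, dtype=np.uint8)

    for _ in range(n_hist):
        u = np.random.random()
        k = np.searchsorted(spec_cdf, u)
        if k >= spec_e.shape[0]:
            k = spec_e.shape[0] - 1
        e0 = spec_e[k]
        acc[EMITTED] += e0
        nsp = 0
        st_e[0] = e0
        st_x[0] = -margin_um + (side + 2.0 * margin_um) * np.random.random()
        st_y[0] = -margin_um + (side + 2.0 * margin_um) * np.random.random()
        st_z[0] = wloz + 1e-9
        st_ux[0] = 0.0
        st_uy[0] = 0.0
        st_uz[0] = 1.0
        st_pr[0] = 1
        nsp = 1
        while nsp > 0:
            nsp -= 1
            e = st_e[nsp]
            x = st_x[nsp]
            y = st_y[nsp]
            z = st_z[nsp]
            ux = st_ux[nsp]
            uy = st_uy[nsp]
            uz = st_uz[nsp]
            primary = st_pr[nsp]
            alive = True
            while alive:
                if e < photon_cutoff:
                    _deposit(dose, acc, labels, n_vox, voxel_um, cell_um, side,
                             wlox, whix, wloz, whiz, x, y, z, e)
                    break
                in_cube = (0.0 <= x < side and 0.0 <= y < side and 0.0 <= z < side)
                mat = -1
                if not in_cube:
                    mu = _interp_loglin(loge0, dloge, n_e, mu_tot[0], e)
                    s = -np.log(np.random.random()) / mu
                    t_in, t_cout = _ray_box(x, y, z, ux, uy, uz,
                                            0.0, 0.0, 0.0, side, side, side)
                    t_win, t_wout = _ray_box(x, y, z, ux, uy, uz,
                                             wlox, wlox, wloz, whix, whix, whiz)
                    hits_cube = t_in > 1e-9 and t_in <= t_cout
                    if hits_cube and t_in < s:
                        d = t_in + 1e-6
                        x += d * ux
                        y += d * uy
                        z += d * uz
                        continue
                    if s < t_wout:
                        x += s * ux
                        y += s * uy
                        z += s * uz
                        mat = 0
                    else:
                        acc[ESCAPED] += e
                        break
                else:
                    mu_m = _interp_loglin(loge0, dloge, n_e, mu_maj, e)
                    s = -np.log(np.random.random()) / mu_m
                    t_in, t_cout = _ray_box(x, y, z, ux, uy, uz,
                                            0.0, 0.0, 0.0, side, side, side)
                    if s >= t_cout:
                        d = t_cout + 1e-6
                        x += d * ux
                        y += d * uy
                        z += d * uz
                        continue
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    m = labels[min(int(x / voxel_um), n_vox - 1),
                               min(int(y / voxel_um), n_vox - 1),
                               min(int(z / voxel_um), n_vox - 1)]
                    mt = _interp_loglin(loge0, dloge, n_e, mu_tot[m], e)
                    if np.random.random() * mu_m > mt:
                        continue  # virtual collision
                    mat = m
                # --- real interaction at (x, y, z) in material mat ---
                if primary == 1:
                    ib = int((z - depth_z0) / depth_dz)
                    if 0 <= ib < depth_hist.shape[0]:
                        depth_hist[ib] += 1
                    primary = 0
                p_pe = _interp_loglin(loge0, dloge, n_e, mu_pe[mat], e)
                p_inc = _interp_loglin(loge0, dloge, n_e, mu_inc[mat], e)
                p_coh = _interp_loglin(loge0, dloge, n_e, mu_coh[mat], e)
                p_pair = _interp_loglin(loge0, dloge, n_e, mu_pair[mat], e)
                r = np.random.random() * (p_pe + p_inc + p_coh + p_pair)
                if r < p_pe:
                    # photoelectric absorption
                    if mat == 3 and e > k_edge and np.random.random() < k_frac:
                        e_el = e - k_edge
                        if np.random.random() < k_yield and nsp < max_stack - 1:
                            dxn, dyn, dzn = _isotropic()
                            st_e[nsp] = k_xray
                            st_x[nsp] = x
                            st_y[nsp] = y
                            st_z[nsp] = z
                            st_ux[nsp] = dxn
                            st_uy[nsp] = dyn
                            st_uz[nsp] = dzn
                            st_pr[nsp] = 0
                            nsp += 1
                            _deposit(dose, acc, labels, n_vox, voxel_um, cell_um,
                                     side, wlox, whix, wloz, whiz, x, y, z,
                                     k_edge - k_xray)
                        else:
                            _deposit(dose, acc, labels, n_vox, voxel_um, cell_um,
                                     side, wlox, whix, wloz, whiz, x, y, z, k_edge)
                    else:
                        b = bind_eff[mat]
                        if b > 0.9 * e:
                            b = 0.9 * e
                        e_el = e - b
                        _deposit(dose, acc, labels, n_vox, voxel_um, cell_um, side,
                                 wlox, whix, wloz, whiz, x, y, z, b)
                    dxn, dyn, dzn = _isotropic()
                    _electron(e_el, x, y, z, dxn, dyn, dzn, electron_mode,
                              labels, n_vox, voxel_um, cell_um, side,
                              wlox, whix, wloz, whiz,
                              se_loge0, se_dloge, se_n, sdens, rng_um, densities,
                              electron_cutoff, dose, acc)
                    break
                elif r < p_pe + p_inc:
                    # incoherent (Compton) scattering on a free electron
                    kk = e / ELECTRON_REST
                    xmin = 1.0 / (1.0 + 2.0 * kk)
                    a1 = np.log(1.0 / xmin)
                    a2 = 0.5 * (1.0 - xmin * xmin)
                    while True:
                        if np.random.random() < a1 / (a1 + a2):
                            xs = xmin * np.exp(a1 * np.random.random())
                        else:
                            xs = np.sqrt(xmin * xmin
                                         + (1.0 - xmin * xmin) * np.random.random())
                        cost = 1.0 - (1.0 - xs) / (kk * xs)
                        sin2 = max(0.0, 1.0 - cost * cost)
                        g = 1.0 - xs * sin2 / (1.0 + xs * xs)
                        if np.random.random() < g:
                            break
                    e_sc = xs * e
                    e_el = e - e_sc
                    phi = 2.0 * np.pi * np.random.random()
                    # recoil electron direction from momentum conservation
                    if e_el > electron_cutoff:
                        pe_c = np.sqrt(e_el * (e_el + 2.0 * ELECTRON_REST))
                        cost_e = (e - e_sc * cost) / pe_c
                        if cost_e > 1.0:
                            cost_e = 1.0
                        elif cost_e < -1.0:
                            cost_e = -1.0
                        ex, ey, ez = _rotate(ux, uy, uz, cost_e, phi + np.pi)
                        _electron(e_el, x, y, z, ex, ey, ez, electron_mode,
                                  labels, n_vox, voxel_um, cell_um, side,
                                  wlox, whix, wloz, whiz,
                                  se_loge0, se_dloge, se_n, sdens, rng_um,
                                  densities, electron_cutoff, dose, acc)
                    else:
                        _deposit(dose, acc, labels, n_vox, voxel_um, cell_um, side,
                                 wlox, whix, wloz, whiz, x, y, z, e_el)
                    ux, uy, uz = _rotate(ux, uy, uz, cost, phi)
                    e = e_sc
                elif r < p_pe + p_inc + p_coh:
                    # coherent scattering: Thomson angle, no energy loss
                    while True:
                        cost = 1.0 - 2.0 * np.random.random()
                        if np.random.random() < 0.5 * (1.0 + cost * cost):
                            break
                    ux, uy, uz = _rotate(ux, uy, uz, cost,
                                         2.0 * np.pi * np.random.random())
                else:
                    # pair production
                    e_kin = e - 2.0 * ELECTRON_REST
                    fe = np.random.random()
                    e_el = fe * e_kin
                    e_po = e_kin - e_el
                    _electron(e_el, x, y, z, ux, uy, uz, electron_mode,
                              labels, n_vox, voxel_um, cell_um, side,
                              wlox, whix, wloz, whiz,
                              se_loge0, se_dloge, se_n, sdens, rng_um, densities,
                              electron_cutoff, dose, acc)
                    px, py, pz, inside = _electron(
                        e_po, x, y, z, ux, uy, uz, electron_mode,
                        labels, n_vox, voxel_um, cell_um, side,
                        wlox, whix, wloz, whiz,
                        se_loge0, se_dloge, se_n, sdens, rng_um, densities,
                        electron_cutoff, dose, acc)
                    if inside:
                        dxn, dyn, dzn = _isotropic()
                        for sgn in (1.0, -1.0):
                            if nsp < max_stack - 1:
                                st_e[nsp] = ELECTRON_REST
                                st_x[nsp] = px
                                st_y[nsp] = py
                                st_z[nsp] = pz
                                st_ux[nsp] = sgn * dxn
                                st_uy[nsp] = sgn * dyn
                                st_uz[nsp] = sgn * dzn
                                st_pr[nsp] = 0
                                nsp += 1
                            else:
                                acc[ESCAPED] += ELECTRON_REST
                    else:
                        acc[ESCAPED] += 2.0 * ELECTRON_REST
                    break
    return acc
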