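"""Compiled photon-transport kernel.

Transports photons through the scene's axis-aligned volumes with three
interaction processes in the crystals (photoelectric absorption, Compton
scattering with Klein-Nishina angle sampling, pair production with two
transported 511 keV annihilation photons) and attenuation in the water
phantom (removal by default; optional single Compton re-emission).

Free paths are sampled exponentially against the total attenuation
coefficient; the process is chosen proportionally to the partial
coefficients.  Photons falling below ``E_LOCAL_ABSORB`` inside a crystal
are deposited locally (the photoelectric mean free path is far below a
millimetre there); outside a crystal they are terminated.  Deposits below
``E_DEPOSIT_FLOOR`` are ignored.

The module mirrors the formulas of :mod:`pgcam.physics` in numba-compiled
form; consistency between the two is covered by tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MEC2 = 511.0
C_MM_PER_NS = 299.792458
E_LOCAL_ABSORB = 30.0  # keV
E_DEPOSIT_FLOOR = 1.0  # keV
_EPS = 1e-6  # mm, boundary nudge
_MAX_STACK = 64
_MAX_STEPS = 400

PHANTOM_REMOVAL = 0
PHANTOM_SINGLE_SCATTER = 1


@njit(cache=True, inline="always")
def _interp_loglog(log_grid, log_vals, loge):
    n = log_grid.size
    if loge <= log_grid[0]:
        return np.exp(log_vals[0])
    if loge >= log_grid[n - 1]:
        return np.exp(log_vals[n - 1])
    i = np.searchsorted(log_grid, loge) - 1
    f = (loge - log_grid[i]) / (log_grid[i + 1] - log_grid[i])
    return np.exp(log_vals[i] + f * (log_vals[i + 1] - log_vals[i]))


@njit(cache=True, inline="always")
def _interp_lin(grid, vals, e):
    n = grid.size
    if e <= grid[0]:
        return vals[0]
    if e >= grid[n - 1]:
        return vals[n - 1]
    i = np.searchsorted(grid, e) - 1
    f = (e - grid[i]) / (grid[i + 1] - grid[i])
    return vals[i] + f * (vals[i + 1] - vals[i])


@njit(cache=True, inline="always")
def _kn_dcs(alpha, c):
    p = 1.0 / (1.0 + alpha * (1.0 - c))
    return 0.5 * p * p * (p + 1.0 / p - (1.0 - c * c))


@njit(cache=True, inline="always")
def _sample_kn_cos(alpha):
    # rejection against the flat envelope 1.0 (forward-scattering value)
    while True:
        c = 2.0 * np.random.random() - 1.0
        if np.random.random() < _kn_dcs(alpha, c):
            return c


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, cos_t, phi):
    """Rotate unit vector d by polar angle acos(cos_t), azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    # orthonormal basis perpendicular to d
    if abs(dz) < 0.9:
        ux, uy, uz = -dy, dx, 0.0
    else:
        ux, uy, uz = 0.0, -dz, dy
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    cp = np.cos(phi)
    sp = np.sin(phi)
    nx = cos_t * dx + sin_t * (cp * ux + sp * vx)
    ny = cos_t * dy + sin_t * (cp * uy + sp * vy)
    nz = cos_t * dz + sin_t * (cp * uz + sp * vz)
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / nn, ny / nn, nz / nn


@njit(cache=True, inline="always")
def _box_intersect(px, py, pz, dx, dy, dz, lo, hi):
    """Slab intersection; returns (t0, t1) with t1 <= t0 meaning miss."""
    t0 = -1.0e30
    t1 = 1.0e30
    for k in range(3):
        o = px if k == 0 else (py if k == 1 else pz)
        d = dx if k == 0 else (dy if k == 1 else dz)
        if abs(d) < 1e-15:
            if o < lo[k] or o > hi[k]:
                return 1.0, -1.0
        else:
            ta = (lo[k] - o) / d
            tb = (hi[k] - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t0, t1


@njit(cache=True, inline="always")
def _inside(px, py, pz, lo, hi):
    return (
        lo[0] <= px <= hi[0]
        and lo[1] <= py <= hi[1]
        and lo[2] <= pz <= hi[2]
    )


@njit(cache=True)
def transport_batch(
    pos,
    dirn,
    energy,
    time0,
    hist_offset,
    boxes_lo,
    boxes_hi,
    ph_lo,
    ph_hi,
    has_phantom,
    phantom_mode,
    xl_loge,
    xl_log_pe,
    xl_log_c,
    xl_e,
    xl_pair,
    wa_loge,
    wa_log_pe,
    wa_log_c,
    wa_e,
    wa_pair,
    seed,
    hit_hist,
    hit_crystal,
    hit_x,
    hit_y,
    hit_z,
    hit_e,
    hit_t,
):
    """Transport a batch of primary photons; returns the number of hits
    written, or -1 if the output buffers overflowed."""
    np.random.seed(seed)
    n = pos.shape[0]
    n_boxes = boxes_lo.shape[0]
    cap = hit_hist.shape[0]
    nhit = 0

    st_x = np.empty(_MAX_STACK)
    st_y = np.empty(_MAX_STACK)
    st_z = np.empty(_MAX_STACK)
    st_dx = np.empty(_MAX_STACK)
    st_dy = np.empty(_MAX_STACK)
    st_dz = np.empty(_MAX_STACK)
    st_e = np.empty(_MAX_STACK)
    st_t = np.empty(_MAX_STACK)

    for i in range(n):
        ns = 1
        st_x[0], st_y[0], st_z[0] = pos[i, 0], pos[i, 1], pos[i, 2]
        st_dx[0], st_dy[0], st_dz[0] = dirn[i, 0], dirn[i, 1], dirn[i, 2]
        st_e[0] = energy[i]
        st_t[0] = time0[i]
        phantom_scatters = 0

        while ns > 0:
            ns -= 1
            px, py, pz = st_x[ns], st_y[ns], st_z[ns]
            dx, dy, dz = st_dx[ns], st_dy[ns], st_dz[ns]
            e = st_e[ns]
            t = st_t[ns]

            for _step in range(_MAX_STEPS):
                if e < E_DEPOSIT_FLOOR:
                    break
                # locate current medium
                cid = -1
                for b in range(n_boxes):
                    if _inside(px, py, pz, boxes_lo[b], boxes_hi[b]):
                        cid = b
                        break
                if cid >= 0:
                    # --- inside a crystal ---
                    if e < E_LOCAL_ABSORB:
                        if nhit >= cap:
                            return -1
                        hit_hist[nhit] = hist_offset + i
                        hit_crystal[nhit] = cid
                        hit_x[nhit], hit_y[nhit], hit_z[nhit] = px, py, pz
                        hit_e[nhit] = e
                        hit_t[nhit] = t
                        nhit += 1
                        break
                    loge = np.log(e)
                    mu_pe = _interp_loglog(xl_loge, xl_log_pe, loge)
                    mu_c = _interp_loglog(xl_loge, xl_log_c, loge)
                    mu_pp = _interp_lin(xl_e, xl_pair, e) if e > 2.0 * MEC2 else 0.0
                    mu_tot = mu_pe + mu_c + mu_pp
                    t0, t1 = _box_intersect(px, py, pz, dx, dy, dz, boxes_lo[cid], boxes_hi[cid])
                    chord = t1
                    s = -np.log(np.random.random()) / mu_tot
                    if s >= chord:
                        adv = chord + _EPS
                        px += dx * adv
                        py += dy * adv
                        pz += dz * adv
                        t += adv / C_MM_PER_NS
                        continue
                    px += dx * s
                    py += dy * s
                    pz += dz * s
                    t += s / C_MM_PER_NS
                    u = np.random.random() * mu_tot
                    if u < mu_pe:
                        dep = e
                        if dep >= E_DEPOSIT_FLOOR:
                            if nhit >= cap:
                                return -1
                            hit_hist[nhit] = hist_offset + i
                            hit_crystal[nhit] = cid
                            hit_x[nhit], hit_y[nhit], hit_z[nhit] = px, py, pz
                            hit_e[nhit] = dep
                            hit_t[nhit] = t
                            nhit += 1
                        break
                    elif u < mu_pe + mu_c:
                        alpha = e / MEC2
                        c = _sample_kn_cos(alpha)
                        e_sc = e / (1.0 + alpha * (1.0 - c))
                        dep = e - e_sc
                        if dep >= E_DEPOSIT_FLOOR:
                            if nhit >= cap:
                                return -1
                            hit_hist[nhit] = hist_offset + i
                            hit_crystal[nhit] = cid
                            hit_x[nhit], hit_y[nhit], hit_z[nhit] = px, py, pz
                            hit_e[nhit] = dep
                            hit_t[nhit] = t
                            nhit += 1
                        phi = 2.0 * np.pi * np.random.random()
                        dx, dy, dz = _rotate(dx, dy, dz, c, phi)
                        e = e_sc
                        continue
                    else:
                        # pair production: local deposit + two 511 keV photons
                        dep = e - 2.0 * MEC2
                        if dep >= E_DEPOSIT_FLOOR:
                            if nhit >= cap:
                                return -1
                            hit_hist[nhit] = hist_offset + i
                            hit_crystal[nhit] = cid
                            hit_x[nhit], hit_y[nhit], hit_z[nhit] = px, py, pz
                            hit_e[nhit] = dep
                            hit_t[nhit] = t
                            nhit += 1
                        cu = 2.0 * np.random.random() - 1.0
                        su = np.sqrt(max(0.0, 1.0 - cu * cu))
                        ph = 2.0 * np.pi * np.random.random()
                        ax, ay, az = su * np.cos(ph), su * np.sin(ph), cu
                        if ns + 2 <= _MAX_STACK:
                            for sgn in (1.0, -1.0):
                                st_x[ns], st_y[ns], st_z[ns] = px, py, pz
                                st_dx[ns], st_dy[ns], st_dz[ns] = sgn * ax, sgn * ay, sgn * az
                                st_e[ns] = MEC2
                                st_t[ns] = t
                                ns += 1
                        break
                elif has_phantom and _inside(px, py, pz, ph_lo, ph_hi):
                    # --- inside the phantom ---
                    if e < E_LOCAL_ABSORB:
                        break
                    loge = np.log(e)
                    mu_pe = _interp_loglog(wa_loge, wa_log_pe, loge)
                    mu_c = _interp_loglog(wa_loge, wa_log_c, loge)
                    mu_pp = _interp_lin(wa_e, wa_pair, e) if e > 2.0 * MEC2 else 0.0
                    mu_tot = mu_pe + mu_c + mu_pp
                    t0, t1 = _box_intersect(px, py, pz, dx, dy, dz, ph_lo, ph_hi)
                    chord = t1
                    s = -np.log(np.random.random()) / mu_tot
                    if s >= chord:
                        adv = chord + _EPS
                        px += dx * adv
                        py += dy * adv
                        pz += dz * adv
                        t += adv / C_MM_PER_NS
                        continue
                    if phantom_mode == PHANTOM_SINGLE_SCATTER and phantom_scatters == 0:
                        px += dx * s
                        py += dy * s
                        pz += dz * s
                        t += s / C_MM_PER_NS
                        u = np.random.random() * mu_tot
                        if u < mu_c:
                            alpha = e / MEC2
                            c = _sample_kn_cos(alpha)
                            e_sc = e / (1.0 + alpha * (1.0 - c))
                            phi = 2.0 * np.pi * np.random.random()
                            dx, dy, dz = _rotate(dx, dy, dz, c, phi)
                            e = e_sc
                            phantom_scatters = 1
                            continue
                        break  # absorbed
                    break  # attenuation-removal: absorbed-or-scattered
                else:
                    # --- in air: fly to the nearest volume, if any ---
                    t_near = 1.0e30
                    for b in range(n_boxes):
                        t0, t1 = _box_intersect(px, py, pz, dx, dy, dz, boxes_lo[b], boxes_hi[b])
                        if t1 > max(t0, 0.0) and t0 > _EPS and t0 < t_near:
                            t_near = t0
                    if has_phantom:
                        t0, t1 = _box_intersect(px, py, pz, dx, dy, dz, ph_lo, ph_hi)
                        if t1 > max(t0, 0.0) and t0 > _EPS and t0 < t_near:
                            t_near = t0
                    if t_near >= 1.0e29:
                        break  # escapes the scene
                    adv = t_near + _EPS
                    px += dx * adv
                    py += dy * adv
                    pz += dz * adv
                    t += adv / C_MM_PER_NS
                    continue
    return nhit
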