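"""Numba kernels for the photon transport engine.

Everything here is nopython-compiled and deliberately free of Python
objects: the caller (:mod:`kvbeam.transport`) flattens phantom, material
tables and tallies into plain arrays.

Random numbers inside the kernel come from an explicit-state PCG32 stream
(state carried in a 2-element uint64 array), so a run is bit-reproducible
for a given seed and independent of numpy's global state.
"""
from __future__ import annotations

import numpy as np
from numba import njit

M_E = 510.99895  # electron rest energy, keV

_PCG_MULT = np.uint64(6364136223846793005)


@njit(cache=True, inline="always")
def pcg_init(seed, stream):
    """PCG32 state array from a 64-bit seed and stream id."""
    s = np.empty(2, dtype=np.uint64)
    s[1] = (np.uint64(stream) << np.uint64(1)) | np.uint64(1)  # odd increment
    s[0] = np.uint64(0)
    _ = pcg_next(s)
    s[0] = s[0] + np.uint64(seed)
    _ = pcg_next(s)
    return s


@njit(cache=True, inline="always")
def pcg_next(s):
    """Uniform float64 in [0, 1) from a PCG32-XSH-RR step."""
    old = s[0]
    s[0] = old * _PCG_MULT + s[1]
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.int64(old >> np.uint64(59))
    r = np.uint32((xorshifted >> np.uint32(rot)) |
                  (xorshifted << np.uint32((32 - rot) & 31)))
    return (np.float64(r) + 0.5) / 4294967296.0


@njit(cache=True, inline="always")
def _lookup(table, mat, e, e0, de):
    """Linear interpolation of table[mat, :] at energy e (fine uniform grid)."""
    f = (e - e0) / de
    if f <= 0.0:
        return table[mat, 0]
    i = int(f)
    if i >= table.shape[1] - 1:
        return table[mat, table.shape[1] - 1]
    w = f - i
    return table[mat, i] * (1.0 - w) + table[mat, i + 1] * w


@njit(cache=True)
def kahn_sample(e_kev, s):
    """Klein-Nishina incoherent scatter via Kahn's method.

    Returns (cos_theta, eps) with eps = E'/E; eps is bounded below by the
    180-degree Compton kinematics limit 1/(1+2k).
    """
    k = e_kev / M_E
    while True:
        r1 = pcg_next(s)
        r2 = pcg_next(s)
        r3 = pcg_next(s)
        if r1 <= (1.0 + 2.0 * k) / (9.0 + 2.0 * k):
            eta = 1.0 + 2.0 * k * r2
            if r3 <= 4.0 * (1.0 / eta - 1.0 / (eta * eta)):
                cos_t = 1.0 - (eta - 1.0) / k
                return cos_t, 1.0 / eta
        else:
            eta = (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2)
            cos_t = 1.0 - (eta - 1.0) / k
            if r3 <= 0.5 * (cos_t * cos_t + 1.0 / eta):
                return cos_t, 1.0 / eta


@njit(cache=True)
def thomson_cos(s):
    """Coherent (Thomson-shaped) scattering angle: pdf proportional to 1+cos^2."""
    while True:
        c = 2.0 * pcg_next(s) - 1.0
        if pcg_next(s) <= 0.5 * (1.0 + c * c):
            return c


@njit(cache=True, inline="always")
def rotate(ux, uy, uz, cos_t, phi):
    """Rotate a unit vector by polar angle acos(cos_t), azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.999999:
        sign = 1.0 if uz > 0.0 else -1.0
        return sin_t * cp, sin_t * sp, sign * cos_t
    denom = np.sqrt(1.0 - uz * uz)
    vx = ux * cos_t + sin_t * (ux * uz * cp - uy * sp) / denom
    vy = uy * cos_t + sin_t * (uy * uz * cp + ux * sp) / denom
    vz = uz * cos_t - sin_t * denom * cp
    n = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / n, vy / n, vz / n


@njit(cache=True, inline="always")
def _box_entry(x, y, z, ux, uy, uz, lo, hi):
    """Slab-method ray/box intersection; returns (hit, t_entry)."""
    t0 = 0.0
    t1 = 1.0e30
    for a in range(3):
        p = x if a == 0 else (y if a == 1 else z)
        u = ux if a == 0 else (uy if a == 1 else uz)
        if abs(u) < 1e-12:
            if p < lo[a] or p > hi[a]:
                return False, 0.0
        else:
            ta = (lo[a] - p) / u
            tb = (hi[a] - p) / u
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    return t1 > t0, t0


@njit(cache=True, inline="always")
def _seg_overlap(px, py, pz, ux, uy, uz, seg, tb, it):
    """Length of the segment [p, p+seg*u] inside tally box ``it``."""
    t0 = 0.0
    t1 = seg
    for a in range(3):
        p = px if a == 0 else (py if a == 1 else pz)
        u = ux if a == 0 else (uy if a == 1 else uz)
        lo = tb[it, 2 * a]
        hi = tb[it, 2 * a + 1]
        if abs(u) < 1e-12:
            if p < lo or p > hi:
                return 0.0
        else:
            ta = (lo - p) / u
            tc = (hi - p) / u
            if ta > tc:
                ta, tc = tc, ta
            if ta > t0:
                t0 = ta
            if tc < t1:
                t1 = tc
    return max(0.0, t1 - t0)


@njit(cache=True)
def run_histories(dirs, energies, seed, mat, rho, lo, hi, spacing,
                  mu_tab, pe_tab, coh_tab, muen_tab, e0, de,
                  cutoff, tally_bounds, tally_score, tally_sum, tally_sum2,
                  dep_hist, esc_hist, primary_only, score_tracklength):
    """Transport all histories; fills per-tally sums and per-history energy books.

    dirs (n,3): unit emission directions from the origin; energies (n): keV.
    mat/rho: (nx,ny,nz) voxel arrays; lo/hi: phantom box corners (cm).
    tally_bounds: (nt,6) [xlo,xhi,ylo,yhi,zlo,zhi]; tally_score: (nt,) scratch.
    dep_hist/esc_hist: (n,) energy deposited inside / escaped, per history.
    Scoring: collision (energy imparted at interaction sites) or track-length
    kerma (E x muen/rho x rho x length) when ``score_tracklength``.
    """
    n = dirs.shape[0]
    nx, ny, nz = mat.shape
    nt = tally_bounds.shape[0]
    s = pcg_init(seed, 54)

    for h in range(n):
        ux = dirs[h, 0]
        uy = dirs[h, 1]
        uz = dirs[h, 2]
        e = energies[h]
        for it in range(nt):
            tally_score[it] = 0.0
        deposited = 0.0
        escaped = 0.0

        # fly from the source origin to the phantom box
        hit, t0 = _box_entry(0.0, 0.0, 0.0, ux, uy, uz, lo, hi)
        if not hit:
            esc_hist[h] = e
            dep_hist[h] = 0.0
            continue
        x = ux * (t0 + 1e-9)
        y = uy * (t0 + 1e-9)
        z = uz * (t0 + 1e-9)

        alive = True
        while alive:
            ix = int(np.floor((x - lo[0]) / spacing[0]))
            iy = int(np.floor((y - lo[1]) / spacing[1]))
            iz = int(np.floor((z - lo[2]) / spacing[2]))
            if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
                escaped += e
                break
            tau = -np.log(pcg_next(s))
            acc = 0.0
            interacted = False
            while True:
                # distance to the next voxel boundary along u
                step = 1.0e30
                if ux > 1e-12:
                    step = min(step, (lo[0] + (ix + 1) * spacing[0] - x) / ux)
                elif ux < -1e-12:
                    step = min(step, (lo[0] + ix * spacing[0] - x) / ux)
                if uy > 1e-12:
                    step = min(step, (lo[1] + (iy + 1) * spacing[1] - y) / uy)
                elif uy < -1e-12:
                    step = min(step, (lo[1] + iy * spacing[1] - y) / uy)
                if uz > 1e-12:
                    step = min(step, (lo[2] + (iz + 1) * spacing[2] - z) / uz)
                elif uz < -1e-12:
                    step = min(step, (lo[2] + iz * spacing[2] - z) / uz)
                if step < 0.0:
                    step = 0.0
                step += 1e-9  # nudge across the boundary

                m = mat[ix, iy, iz]
                r = rho[ix, iy, iz]
                mu = _lookup(mu_tab, m, e, e0, de) * r
                seg = step
                if acc + mu * step >= tau and mu > 0.0:
                    seg = (tau - acc) / mu
                    interacted = True

                if score_tracklength and nt > 0:
                    muen = _lookup(muen_tab, m, e, e0, de) * r
                    for it in range(nt):
                        ov = _seg_overlap(x, y, z, ux, uy, uz, seg,
                                          tally_bounds, it)
                        if ov > 0.0:
                            tally_score[it] += e * muen * ov

                x += ux * seg
                y += uy * seg
                z += uz * seg
                if interacted:
                    break
                acc += mu * step
                ix = int(np.floor((x - lo[0]) / spacing[0]))
                iy = int(np.floor((y - lo[1]) / spacing[1]))
                iz = int(np.floor((z - lo[2]) / spacing[2]))
                if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
                    escaped += e
                    alive = False
                    break
            if not alive or not interacted:
                break

            # interaction in voxel (ix, iy, iz) at (x, y, z)
            m = mat[ix, iy, iz]
            pe = _lookup(pe_tab, m, e, e0, de)
            coh = _lookup(coh_tab, m, e, e0, de)
            u = pcg_next(s)
            e_dep = 0.0
            if primary_only:
                e_dep = e
                alive = False
            elif u < pe:
                e_dep = e          # photoelectric: local absorption
                alive = False
            elif u < pe + coh:
                cth = thomson_cos(s)
                phi = 2.0 * np.pi * pcg_next(s)
                ux, uy, uz = rotate(ux, uy, uz, cth, phi)
            else:
                cth, eps = kahn_sample(e, s)
                e_dep = e * (1.0 - eps)
                e = e * eps
                phi = 2.0 * np.pi * pcg_next(s)
                ux, uy, uz = rotate(ux, uy, uz, cth, phi)
                if e < cutoff:      # below cutoff: deposit locally, stop
                    e_dep += e
                    e = 0.0
                    alive = False
            if e_dep > 0.0:
                deposited += e_dep
                if not score_tracklength:
                    for it in range(nt):
                        if (tally_bounds[it, 0] <= x <= tally_bounds[it, 1] and
                                tally_bounds[it, 2] <= y <= tally_bounds[it, 3] and
                                tally_bounds[it, 4] <= z <= tally_bounds[it, 5]):
                            tally_score[it] += e_dep

        dep_hist[h] = deposited
        esc_hist[h] = escaped
        for it in range(nt):
            tally_sum[it] += tally_score[it]
            tally_sum2[it] += tally_score[it] * tally_score[it]


@njit(cache=True)
def voxel_chords(x, y, z, ux, uy, uz, lo, hi, spacing, dims, out_len, out_idx):
    """Record per-voxel chord lengths along a ray until exit.

    Fills out_len (lengths, cm) and out_idx (flat voxel indices); returns the
    number of voxels crossed.  Shares the traversal arithmetic of
    :func:`run_histories`.
    """
    nx, ny, nz = dims
    hit, t0 = _box_entry(x, y, z, ux, uy, uz, lo, hi)
    if not hit:
        return 0
    x += ux * (t0 + 1e-9)
    y += uy * (t0 + 1e-9)
    z += uz * (t0 + 1e-9)
    count = 0
    while count < out_len.shape[0]:
        ix = int(np.floor((x - lo[0]) / spacing[0]))
        iy = int(np.floor((y - lo[1]) / spacing[1]))
        iz = int(np.floor((z - lo[2]) / spacing[2]))
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            break
        step = 1.0e30
        if ux > 1e-12:
            step = min(step, (lo[0] + (ix + 1) * spacing[0] - x) / ux)
        elif ux < -1e-12:
            step = min(step, (lo[0] + ix * spacing[0] - x) / ux)
        if uy > 1e-12:
            step = min(step, (lo[1] + (iy + 1) * spacing[1] - y) / uy)
        elif uy < -1e-12:
            step = min(step, (lo[1] + iy * spacing[1] - y) / uy)
        if uz > 1e-12:
            step = min(step, (lo[2] + (iz + 1) * spacing[2] - z) / uz)
        elif uz < -1e-12:
            step = min(step, (lo[2] + iz * spacing[2] - z) / uz)
        out_len[count] = step
        out_idx[count] = (ix * ny + iy) * nz + iz
        count += 1
        x += ux * (step + 1e-9)
        y += uy * (step + 1e-9)
        z += uz * (step + 1e-9)
    return count


@njit(cache=True)
def free_path(x, y, z, ux, uy, uz, e, lo, hi, spacing, mat, rho,
              mu_tab, e0, de, s):
    """Optical-depth sampling along the voxel traversal.

    Returns (reached_interaction, x, y, z, geometric_path) for a single
    photon starting inside or outside the box.
    """
    nx, ny, nz = mat.shape
    hit, t0 = _box_entry(x, y, z, ux, uy, uz, lo, hi)
    if not hit:
        return False, x, y, z, 0.0
    if t0 > 0.0:
        x += ux * (t0 + 1e-9)
        y += uy * (t0 + 1e-9)
        z += uz * (t0 + 1e-9)
    tau = -np.log(pcg_next(s))
    acc = 0.0
    path = 0.0
    while True:
        ix = int(np.floor((x - lo[0]) / spacing[0]))
        iy = int(np.floor((y - lo[1]) / spacing[1]))
        iz = int(np.floor((z - lo[2]) / spacing[2]))
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            return False, x, y, z, path
        step = 1.0e30
        if ux > 1e-12:
            step = min(step, (lo[0] + (ix + 1) * spacing[0] - x) / ux)
        elif ux < -1e-12:
            step = min(step, (lo[0] + ix * spacing[0] - x) / ux)
        if uy > 1e-12:
            step = min(step, (lo[1] + (iy + 1) * spacing[1] - y) / uy)
        elif uy < -1e-12:
            step = min(step, (lo[1] + iy * spacing[1] - y) / uy)
        if uz > 1e-12:
            step = min(step, (lo[2] + (iz + 1) * spacing[2] - z) / uz)
        elif uz < -1e-12:
            step = min(step, (lo[2] + iz * spacing[2] - z) / uz)
        if step < 0.0:
            step = 0.0
        step += 1e-9
        mu = _lookup(mu_tab, mat[ix, iy, iz], e, e0, de) * rho[ix, iy, iz]
        if acc + mu * step >= tau and mu > 0.0:
            seg = (tau - acc) / mu
            return True, x + ux * seg, y + uy * seg, z + uz * seg, path + seg
        acc += mu * step
        path += step
        x += ux * step
        y += uy * step
        z += uz * step
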