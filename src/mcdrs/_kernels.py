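"""Numba kernels: layered photon transport and Beer-Lambert record sums.

Geometry convention: z grows downward into the medium, the surface is z = 0.
Layer boundaries sit at z1 (epidermis / upper dermis) and z2 (upper / lower
dermis); all layers share the scattering coefficient, so internal boundaries
are transparent and only the top surface refracts.  Lengths in mm.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["mc_node", "bl_intensity"]


@njit(cache=True, inline="always")
def _fresnel_reflectance(cos_i: float, n1: float, n2: float) -> float:
    """Unpolarized Fresnel reflectance for internal incidence cosine cos_i."""
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = sin_i * n1 / n2
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def mc_node(seed, n_photons, mus, g, n_tissue, n_ambient, z1, z2,
            src_r, det_off, det_r, na, mua1, mua2, mua3,
            smax, rmax, cap):
    """Trace photons through the three-zone medium, recording detected paths.

    Returns per-channel path-length records (s_epi, s_derm1, s_derm2), their
    weights, stored/seen counts, and the total escaped weight (all channels
    and the rest of the surface combined) for energy accounting.
    """
    nch = det_off.shape[0]
    S = np.zeros((nch, cap, 3))
    Z = np.zeros((nch, cap))           # per-record maximum depth reached
    W = np.zeros((nch, cap))
    n_stored = np.zeros(nch, dtype=np.int64)
    n_seen = np.zeros(nch, dtype=np.int64)
    escape_w = 0.0

    np.random.seed(seed)
    sin_acc = na / n_tissue            # NA acceptance: n_tissue*sin(theta) <= NA
    cos_cone = math.sqrt(max(0.0, 1.0 - sin_acc * sin_acc))
    absorbing = (mua1 > 0.0) or (mua2 > 0.0) or (mua3 > 0.0)

    for _ in range(n_photons):
        # launch: flat field over the source fiber face, uniform solid angle
        # within the (refracted) NA cone
        rr = src_r * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        x = rr * math.cos(phi)
        y = rr * math.sin(phi)
        z = 0.0
        cth = 1.0 - np.random.random() * (1.0 - cos_cone)
        sth = math.sqrt(max(0.0, 1.0 - cth * cth))
        phi = 2.0 * math.pi * np.random.random()
        ux = sth * math.cos(phi)
        uy = sth * math.sin(phi)
        uz = cth
        w = 1.0
        s1 = 0.0
        s2 = 0.0
        s3 = 0.0
        stot = 0.0
        zmax = 0.0
        alive = True

        while alive:
            step = -math.log(np.random.random() + 1e-300) / mus
            while step > 0.0:
                hit_surface = False
                seg = step
                if uz < 0.0:
                    s_srf = -z / uz
                    if s_srf <= seg:
                        seg = s_srf
                        hit_surface = True
                # accumulate per-zone path of this segment
                zb = z + uz * seg
                zlo = z if z < zb else zb
                zhi = zb if z < zb else z
                if abs(uz) > 1e-12:
                    o1 = min(zhi, z1) - zlo
                    if o1 < 0.0:
                        o1 = 0.0
                    o2 = min(zhi, z2) - max(zlo, z1)
                    if o2 < 0.0:
                        o2 = 0.0
                    d1 = o1 / abs(uz)
                    d2 = o2 / abs(uz)
                    d3 = seg - d1 - d2
                    if d3 < 0.0:
                        d3 = 0.0
                else:
                    d1 = seg if z < z1 else 0.0
                    d2 = seg if (z >= z1 and z < z2) else 0.0
                    d3 = seg - d1 - d2
                s1 += d1
                s2 += d2
                s3 += d3
                stot += seg
                if absorbing:
                    w *= math.exp(-(mua1 * d1 + mua2 * d2 + mua3 * d3))
                x += ux * seg
                y += uy * seg
                z = zb
                if z > zmax:
                    zmax = z
                step -= seg

                if hit_surface:
                    z = 0.0
                    cos_i = -uz
                    refl = _fresnel_reflectance(cos_i, n_tissue, n_ambient)
                    if np.random.random() < refl:
                        uz = -uz           # (total) internal reflection
                    else:
                        escape_w += w
                        r_exit = math.sqrt(x * x + y * y)
                        sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
                        if sin_i <= sin_acc:
                            for c in range(nch):
                                if abs(r_exit - det_off[c]) <= det_r:
                                    n_seen[c] += 1
                                    if n_stored[c] < cap:
                                        k = n_stored[c]
                                        n_stored[c] += 1
                                    else:
                                        j = int(np.random.random() * n_seen[c])
                                        k = j if j < cap else -1
                                    if k >= 0:
                                        S[c, k, 0] = s1
                                        S[c, k, 1] = s2
                                        S[c, k, 2] = s3
                                        Z[c, k] = zmax
                                        W[c, k] = w
                        alive = False
                        break
                if stot > smax or (x * x + y * y) > rmax * rmax:
                    alive = False
                    break
            if not alive:
                break
            # Henyey-Greenstein scatter
            if g == 0.0:
                cth = 2.0 * np.random.random() - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                cth = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cth > 1.0:
                    cth = 1.0
                elif cth < -1.0:
                    cth = -1.0
            sth = math.sqrt(max(0.0, 1.0 - cth * cth))
            phi = 2.0 * math.pi * np.random.random()
            cphi = math.cos(phi)
            sphi = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sth * cphi
                uy = sth * sphi
                uz = cth if uz > 0.0 else -cth
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux_n = sth * (ux * uz * cphi - uy * sphi) / den + ux * cth
                uy_n = sth * (uy * uz * cphi + ux * sphi) / den + uy * cth
                uz_n = -sth * cphi * den + uz * cth
                norm = math.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm
                uy = uy_n / norm
                uz = uz_n / norm
            # roulette (relevant only for absorbing runs)
            if w < 1e-4:
                if np.random.random() < 0.1:
                    w *= 10.0
                else:
                    alive = False

    return S, Z, W, n_stored, n_seen, escape_w


@njit(cache=True)
def bl_intensity(S, Z, W, offsets, scale, i_lo, i_hi, w_lo,
                 tepi_grid_mm, musp_grid, musp_lam, mua_lam, frac_mode):
    """Beer-Lambert sum over LUT records with bilinear node mixing.

    S : (N, 3) concatenated per-layer path lengths for one channel
    Z : (N,) per-record maximum depth reached, mm
    W : (N,) record weights
    offsets : (n_tepi, n_musp, 2) start/stop indices into S/W
    scale : (n_tepi, n_musp) per-node normalization (thinning x 1/n_photons
        x detector geometry factor)
    i_lo, i_hi, w_lo : epidermis-thickness bracket (node indices and the
        weight of the lower node; w_hi = 1 - w_lo)
    musp_lam : (n_lam,) reduced scattering at each wavelength
    mua_lam : (3, n_lam) per-layer absorption at each wavelength
    frac_mode : 0 = intensity only, 1 = per-layer path-length sums,
        2 = partition of detected weight by deepest layer visited

    Returns intensity (n_lam,) and per-layer sums (n_lam, 3) (zeros when
    ``frac_mode`` is 0).
    """
    n_lam = musp_lam.shape[0]
    n_musp = musp_grid.shape[0]
    I = np.zeros(n_lam)
    F = np.zeros((n_lam, 3))
    for il in range(n_lam):
        m = musp_lam[il]
        # bracket m in musp_grid (callers guarantee inside hull)
        j_hi = 1
        while j_hi < n_musp - 1 and musp_grid[j_hi] < m:
            j_hi += 1
        j_lo = j_hi - 1
        wj_lo = (musp_grid[j_hi] - m) / (musp_grid[j_hi] - musp_grid[j_lo])
        mu1 = mua_lam[0, il]
        mu2 = mua_lam[1, il]
        mu3 = mua_lam[2, il]
        for ii in range(2):
            i = i_lo if ii == 0 else i_hi
            wi = w_lo if ii == 0 else 1.0 - w_lo
            if wi == 0.0:
                continue
            for jj in range(2):
                j = j_lo if jj == 0 else j_hi
                wj = wj_lo if jj == 0 else 1.0 - wj_lo
                if wj == 0.0:
                    continue
                wnode = wi * wj * scale[i, j]
                a = offsets[i, j, 0]
                b = offsets[i, j, 1]
                z1 = tepi_grid_mm[i]
                z2 = z1 + 0.2
                acc = 0.0
                f1 = 0.0
                f2 = 0.0
                f3 = 0.0
                for k in range(a, b):
                    e = W[k] * math.exp(
                        -(mu1 * S[k, 0] + mu2 * S[k, 1] + mu3 * S[k, 2])
                    )
                    acc += e
                    if frac_mode == 1:
                        f1 += e * S[k, 0]
                        f2 += e * S[k, 1]
                        f3 += e * S[k, 2]
                    elif frac_mode == 2:
                        if Z[k] > z2:
                            f3 += e
                        elif Z[k] > z1:
                            f2 += e
                        else:
                            f1 += e
                I[il] += wnode * acc
                if frac_mode != 0:
                    F[il, 0] += wnode * f1
                    F[il, 1] += wnode * f2
                    F[il, 2] += wnode * f3
            if i_lo == i_hi:
                break
    return I, F
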