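"""Numba kernels for the Metropolis sweep.

All cached per-cell quantities (area, perimeter-as-bond-count, coordinate
sums and second moments) are updated incrementally inside the sweep; the
increments are exact integers, so the caches stay bit-identical to a full
recomputation.  The energy difference of a candidate copy touches only the
two affected cells' area/perimeter terms, the bonds incident to the target
site, and the motile work of any motile participant.

Motile work conventions (``pixel_work`` flag): in pixel mode the work of a
copy is F . s with s the unit step from the source pixel to the target
pixel, applied to both affected cells (the convention CPM motility plugins
use per copy attempt); in com mode it is F . dr_com with dr_com the exact
center-of-mass displacement the copy would cause.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = np.int64(1 << 60)


@njit(cache=True, inline="always")
def _delta_energy(grid, y, x, b, step_y, step_x,
                  bond_dy, bond_dx,
                  area, perim, sx, sy,
                  lam_area, lam_cont, a0, adh, ctype, fx, fy,
                  phi, use_motility, pixel_work, work_sign):
    """(dE, dL_a, dL_b) for copying id ``b`` onto site (y, x) holding id a.

    ``(step_y, step_x)`` is the unit source->target step (pixel work mode).
    """
    h, w = grid.shape
    a = grid[y, x]
    nb = bond_dy.shape[0]
    cnt_a = 0
    cnt_b = 0
    dphi = 0.0
    ta = ctype[a]
    tb = ctype[b]
    for m in range(nb):
        ny = y + bond_dy[m]
        nx = x + bond_dx[m]
        if ny < 0 or ny >= h or nx < 0 or nx >= w:
            continue  # domain edge: counts as "other" for L, carries no phi
        c = grid[ny, nx]
        if c == a:
            cnt_a += 1
        if c == b:
            cnt_b += 1
        tc = ctype[c]
        if c != a:
            dphi -= phi[ta, tc] * adh[a] * adh[c]
        if c != b:
            dphi += phi[tb, tc] * adh[b] * adh[c]
    de = dphi
    aa = area[a]
    ab = area[b]
    da0 = aa - a0[a]
    db0 = ab - a0[b]
    de += lam_area[a] * ((da0 - 1.0) ** 2 - da0 ** 2)
    de += lam_area[b] * ((db0 + 1.0) ** 2 - db0 ** 2)
    dla = 2 * cnt_a - nb
    dlb = nb - 2 * cnt_b
    la = perim[a]
    lb = perim[b]
    de += lam_cont[a] * (float((la + dla) ** 2 - la ** 2))
    de += lam_cont[b] * (float((lb + dlb) ** 2 - lb ** 2))
    if use_motility:
        if pixel_work:
            fsx = fx[a] + fx[b]
            fsy = fy[a] + fy[b]
            if fsx != 0.0 or fsy != 0.0:
                de += work_sign * (fsx * step_x + fsy * step_y)
        else:
            if (fx[a] != 0.0 or fy[a] != 0.0) and aa > 1:
                cx0 = sx[a] / aa
                cy0 = sy[a] / aa
                cx1 = (sx[a] - x) / (aa - 1.0)
                cy1 = (sy[a] - y) / (aa - 1.0)
                de += work_sign * (fx[a] * (cx1 - cx0) + fy[a] * (cy1 - cy0))
            if fx[b] != 0.0 or fy[b] != 0.0:
                cx0 = sx[b] / ab
                cy0 = sy[b] / ab
                cx1 = (sx[b] + x) / (ab + 1.0)
                cy1 = (sy[b] + y) / (ab + 1.0)
                de += work_sign * (fx[b] * (cx1 - cx0) + fy[b] * (cy1 - cy0))
    return de, dla, dlb


@njit(cache=True)
def delta_energy_site(grid, y, x, b, step_y, step_x,
                      bond_dy, bond_dx,
                      area, perim, sx, sy,
                      lam_area, lam_cont, a0, adh, ctype, fx, fy,
                      phi, use_motility, pixel_work, work_sign):
    de, _, _ = _delta_energy(grid, y, x, b, step_y, step_x, bond_dy, bond_dx,
                             area, perim, sx, sy,
                             lam_area, lam_cont, a0, adh, ctype, fx, fy,
                             phi, use_motility, pixel_work, work_sign)
    return de


@njit(cache=True, inline="always")
def _apply_copy(grid, y, x, b, dla, dlb,
                area, perim, sx, sy, sxx, syy, sxy):
    a = grid[y, x]
    grid[y, x] = b
    area[a] -= 1
    area[b] += 1
    perim[a] += dla
    perim[b] += dlb
    sx[a] -= x
    sy[a] -= y
    sxx[a] -= x * x
    syy[a] -= y * y
    sxy[a] -= x * y
    sx[b] += x
    sy[b] += y
    sxx[b] += x * x
    syy[b] += y * y
    sxy[b] += x * y


@njit(cache=True)
def apply_copy(grid, y, x, b, dla, dlb, area, perim, sx, sy, sxx, syy, sxy):
    _apply_copy(grid, y, x, b, dla, dlb, area, perim, sx, sy, sxx, syy, sxy)


@njit(cache=True)
def run_sweep(grid, frozen, nzy, nzx,
              u_site, u_src, u_acc,
              src_dy, src_dx, bond_dy, bond_dx,
              area, perim, sx, sy, sxx, syy, sxy,
              lam_area, lam_cont, a0, adh, ctype, fx, fy,
              phi, temperature, use_motility, pixel_work, work_sign):
    """One Monte Carlo sweep: len(u_site) elementary copy attempts.

    Each attempt draws a uniformly random non-frozen site and a uniformly
    random copy-neighborhood source; attempts whose source is off-grid,
    frozen, or holds the same id are no-ops.  Returns the number of
    accepted copies.
    """
    h, w = grid.shape
    n_sites = nzy.shape[0]
    n_src = src_dy.shape[0]
    accepted = 0
    for k in range(u_site.shape[0]):
        idx = int(u_site[k] * n_sites)
        y = nzy[idx]
        x = nzx[idx]
        m = int(u_src[k] * n_src)
        yy = y + src_dy[m]
        xx = x + src_dx[m]
        if yy < 0 or yy >= h or xx < 0 or xx >= w:
            continue
        if frozen[yy, xx]:
            continue  # wall ids never spread
        b = grid[yy, xx]
        if b == grid[y, x]:
            continue
        sdy = float(y - yy)
        sdx = float(x - xx)
        if sdy != 0.0 and sdx != 0.0:  # diagonal step: normalize
            sdy *= 0.7071067811865476
            sdx *= 0.7071067811865476
        de, dla, dlb = _delta_energy(grid, y, x, b, sdy, sdx,
                                     bond_dy, bond_dx,
                                     area, perim, sx, sy,
                                     lam_area, lam_cont, a0, adh, ctype, fx, fy,
                                     phi, use_motility, pixel_work, work_sign)
        if de <= 0.0 or u_acc[k] < np.exp(-de / temperature):
            _apply_copy(grid, y, x, b, dla, dlb,
                        area, perim, sx, sy, sxx, syy, sxy)
            accepted += 1
    return accepted


@njit(cache=True)
def minmax_x(grid, n_ids):
    """Per-cell min and max pixel x coordinate (single grid pass)."""
    minx = np.full(n_ids, BIG, dtype=np.int64)
    maxx = np.full(n_ids, -1, dtype=np.int64)
    h, w = grid.shape
    for y in range(h):
        for x in range(w):
            c = grid[y, x]
            if x < minx[c]:
                minx[c] = x
            if x > maxx[c]:
                maxx[c] = x
    return minx, maxx
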