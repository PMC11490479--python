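"""Stochastic cell division, death and extrusion.

Division: each alive cell whose area has reached its target area divides
with a fixed per-MCS probability B.  The pixel set is split by a straight
line through the center of mass perpendicular to the cell's principal
(longest) axis; pixels are ordered by signed distance along that axis and
split at the median, so the daughters hold floor(A/2) and ceil(A/2)
pixels.  Both daughters keep the parent's target area and start with zero
polarization; they regrow toward A0 under the area term of the energy.

Death: each alive cell dies with a fixed per-MCS probability M, independent
of size.  A dead cell's adhesion, contractility and target area are zeroed
and its area stiffness is raised (default 500), so it shrinks and is
extruded — removed from the registry — once its area reaches the extrusion
threshold (default 0 pixels).

Within one MCS a cell can either divide or die, not both (division is
checked first).
"""

from __future__ import annotations

import math

import numpy as np

from .params import ModelParams
from .state import CellTable, LatticeState, neighborhood
from .types import CellType


def _geom_from_pixels(grid: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                      cid: int, bond: np.ndarray) -> tuple:
    """(area, perim, sx, sy, sxx, syy, sxy) of the pixel set labelled cid."""
    h, w = grid.shape
    perim = 0
    for dy, dx in bond:
        ny, nx = ys + dy, xs + dx
        inside = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        perim += int(np.count_nonzero(~inside))
        perim += int(np.count_nonzero(grid[ny[inside], nx[inside]] != cid))
    return (len(ys), perim, int(xs.sum()), int(ys.sum()),
            int((xs * xs).sum()), int((ys * ys).sum()), int((xs * ys).sum()))


def _store_geom(cells: CellTable, cid: int, geom: tuple) -> None:
    (cells.area[cid], cells.perim[cid], cells.sx[cid], cells.sy[cid],
     cells.sxx[cid], cells.syy[cid], cells.sxy[cid]) = geom
    a = max(int(cells.area[cid]), 1)
    cells.prev_cx[cid] = cells.sx[cid] / a
    cells.prev_cy[cid] = cells.sy[cid] / a


def _principal_axis(cells: CellTable, cid: int) -> tuple[float, float]:
    """Unit vector along the principal (longest) axis of the pixel cloud."""
    a = float(cells.area[cid])
    cx = cells.sx[cid] / a
    cy = cells.sy[cid] / a
    cxx = cells.sxx[cid] / a - cx * cx
    cyy = cells.syy[cid] / a - cy * cy
    cxy = cells.sxy[cid] / a - cx * cy
    theta = 0.5 * math.atan2(2.0 * cxy, cxx - cyy)
    return math.cos(theta), math.sin(theta)


def divide_cell(lattice: LatticeState, cells: CellTable, params: ModelParams,
                cid: int, rng: np.random.Generator) -> int | None:
    """Split one cell; returns the new daughter id, or None if the geometry
    is degenerate (fewer than 2 pixels)."""
    grid = lattice.grid
    ys, xs = np.nonzero(grid == cid)
    if len(ys) < 2:
        return None
    ux, uy = _principal_axis(cells, cid)
    a = float(cells.area[cid])
    cx = cells.sx[cid] / a
    cy = cells.sy[cid] / a
    for _ in range(4):  # retry with a random orientation on degenerate splits
        d = (xs - cx) * ux + (ys - cy) * uy
        order = np.argsort(d, kind="stable")
        half = len(order) // 2
        upper = order[half:]
        lower = order[:half]
        if len(upper) and len(lower):
            break
        angle = rng.uniform(0.0, math.pi)
        ux, uy = math.cos(angle), math.sin(angle)
    else:
        return None
    ctype = CellType(int(cells.ctype[cid]))
    did = cells.new_cell(ctype, params, a0=float(cells.a0[cid]))
    cells.lam_area[did] = cells.lam_area[cid]
    cells.lam_cont[did] = cells.lam_cont[cid]
    grid[ys[upper], xs[upper]] = did
    bond = neighborhood(params.bond_neighborhood)
    _store_geom(cells, cid, _geom_from_pixels(grid, ys[lower], xs[lower], cid, bond))
    _store_geom(cells, did, _geom_from_pixels(grid, ys[upper], xs[upper], did, bond))
    for c in (cid, did):  # motility stops during division
        cells.rx[c] = cells.ry[c] = 0.0
        cells.fx[c] = cells.fy[c] = 0.0
    return did


def division_sweep(lattice: LatticeState, cells: CellTable, params: ModelParams,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Divide each eligible cell (alive, A >= A0) with probability B(type).

    Returns (parent id, daughter id) pairs.
    """
    tp = params.turnover
    if tp.birth_motile == 0.0 and tp.birth_nonmotile == 0.0:
        return []
    n = cells.n_ids
    eligible = (cells.present[:n] & cells.alive[:n]
                & (cells.ctype[:n] != int(CellType.WALL))
                & (cells.area[:n] >= cells.a0[:n]))
    ids = np.nonzero(eligible)[0]
    if ids.size == 0:
        return []
    b = np.where(cells.ctype[ids] == int(CellType.MOTILE),
                 tp.birth_motile, tp.birth_nonmotile)
    chosen = ids[rng.random(ids.size) < b]
    out = []
    for cid in chosen:
        did = divide_cell(lattice, cells, params, int(cid), rng)
        if did is not None:
            out.append((int(cid), did))
    return out


def death_sweep(cells: CellTable, params: ModelParams, rng: np.random.Generator,
                exclude: set[int] | frozenset = frozenset()) -> list[int]:
    """Kill each alive cell with probability M(type); returns new dead ids.

    ``exclude`` holds ids that divided this MCS (division and death are
    mutually exclusive within one MCS).
    """
    tp = params.turnover
    if tp.death_motile == 0.0 and tp.death_nonmotile == 0.0:
        return []
    n = cells.n_ids
    candidates = (cells.present[:n] & cells.alive[:n]
                  & (cells.ctype[:n] != int(CellType.WALL)))
    ids = np.nonzero(candidates)[0]
    if exclude:
        ids = np.array([i for i in ids if int(i) not in exclude], dtype=np.int64)
    if ids.size == 0:
        return []
    m = np.where(cells.ctype[ids] == int(CellType.MOTILE),
                 tp.death_motile, tp.death_nonmotile)
    dead = ids[rng.random(ids.size) < m]
    for cid in dead:
        cells.mark_dead(int(cid), params)
    return [int(c) for c in dead]


def extrusion_sweep(lattice: LatticeState, cells: CellTable,
                    params: ModelParams) -> list[int]:
    """Remove dead cells whose area has shrunk to the extrusion threshold.

    Any remaining pixels (threshold > 0) are handed to the neighboring cell
    sharing the longest boundary.
    """
    n = cells.n_ids
    done = (cells.present[:n] & ~cells.alive[:n]
            & (cells.ctype[:n] != int(CellType.WALL))
            & (cells.area[:n] <= params.turnover.extrusion_area_threshold))
    removed = []
    bond = neighborhood(params.bond_neighborhood)
    for cid in np.nonzero(done)[0]:
        cid = int(cid)
        if cells.area[cid] > 0:
            _reassign_pixels(lattice, cells, cid, bond)
        cells.present[cid] = False
        removed.append(cid)
    return removed


def _reassign_pixels(lattice: LatticeState, cells: CellTable, cid: int,
                     bond: np.ndarray) -> None:
    """Hand all pixels of ``cid`` to the neighbor with the longest shared
    boundary (ties broken by lowest id)."""
    grid = lattice.grid
    h, w = grid.shape
    ys, xs = np.nonzero(grid == cid)
    counts: dict[int, int] = {}
    for dy, dx in bond:
        ny, nx = ys + dy, xs + dx
        inside = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        for c in grid[ny[inside], nx[inside]]:
            c = int(c)
            if c != cid and not cells.ctype[c] == int(CellType.WALL):
                counts[c] = counts.get(c, 0) + 1
    if not counts:
        return
    target = min(c for c, k in counts.items() if k == max(counts.values()))
    grid[ys, xs] = target
    tys, txs = np.nonzero(grid == target)
    _store_geom(cells, target,
                _geom_from_pixels(grid, tys, txs, target, bond))
    _store_geom(cells, cid, (0, 0, 0, 0, 0, 0, 0))
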