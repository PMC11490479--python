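"""Lattice and per-cell state.

The lattice is a 2-D integer grid of cell ids plus a frozen mask (wall and
barrier pixels whose id never changes).  Per-cell state lives in a
struct-of-arrays :class:`CellTable` indexed directly by cell id: cached
area, perimeter (heterotypic 4-neighbor bond count), coordinate sums and
second moments (for exact incremental center-of-mass and principal-axis
computations), per-cell energy coefficients (so death can re-parameterize a
single cell), polarization and motile force.

Coordinates are 0-based with x = column, y = row; centers of mass are in
continuous pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .params import ModelParams
from .types import CellType, UnknownCellError

#: 4-neighborhood (von Neumann) offsets as (dy, dx)
VON_NEUMANN = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)], dtype=np.int64)
#: 8-neighborhood (Moore) offsets as (dy, dx)
MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


def neighborhood(order: int) -> np.ndarray:
    return VON_NEUMANN if order == 4 else MOORE


class LatticeState:
    """2-D grid of cell ids plus frozen-wall mask."""

    def __init__(self, grid: np.ndarray, frozen: np.ndarray | None = None):
        self.grid = np.ascontiguousarray(grid, dtype=np.int32)
        if frozen is None:
            frozen = np.zeros_like(self.grid, dtype=bool)
        self.frozen = np.ascontiguousarray(frozen, dtype=bool)
        if self.frozen.shape != self.grid.shape:
            raise ValueError("frozen mask shape must match grid shape")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    def nonfrozen_sites(self) -> tuple[np.ndarray, np.ndarray]:
        """(ys, xs) of all pixels whose id may change, in row-major order."""
        ys, xs = np.nonzero(~self.frozen)
        return ys.astype(np.int64), xs.astype(np.int64)

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.frozen.copy())


@dataclass
class CellRecord:
    """Read-only snapshot of one cell's cached state."""

    id: int
    cell_type: CellType
    alive: bool
    area: int
    perimeter: int
    com: tuple[float, float]
    target_area: float
    polarization: tuple[float, float]
    prev_com: tuple[float, float]


class CellTable:
    """Struct-of-arrays registry of cells, indexed by id.

    Ids are never reused; ``present`` marks ids still on the lattice
    (extruded cells are dropped).  All cached quantities are maintained
    incrementally by the sweep kernel and can be audited against
    :func:`recompute_cell_geometry`.
    """

    _FLOAT_FIELDS = ("a0", "lam_area", "lam_cont", "adh", "rx", "ry", "fx", "fy",
                     "prev_cx", "prev_cy")
    _INT_FIELDS = ("area", "perim", "sx", "sy", "sxx", "syy", "sxy")

    def __init__(self, capacity: int = 64):
        self._grow_to(capacity, init=True)
        self.n_ids = 0

    def _grow_to(self, capacity: int, init: bool = False) -> None:
        def expand(old, dtype, fill=0):
            new = np.full(capacity, fill, dtype=dtype)
            if old is not None:
                new[: old.shape[0]] = old
            return new

        old = None if init else self
        self.ctype = expand(getattr(old, "ctype", None), np.int8)
        self.alive = expand(getattr(old, "alive", None), bool, False)
        self.present = expand(getattr(old, "present", None), bool, False)
        for name in self._INT_FIELDS:
            setattr(self, name, expand(getattr(old, name, None), np.int64))
        for name in self._FLOAT_FIELDS:
            setattr(self, name, expand(getattr(old, name, None), np.float64))
        self.capacity = capacity

    def new_cell(self, ctype: CellType, params: ModelParams, a0: float | None = None) -> int:
        if self.n_ids >= self.capacity:
            self._grow_to(2 * self.capacity)
        cid = self.n_ids
        self.n_ids += 1
        self.ctype[cid] = int(ctype)
        self.alive[cid] = True
        self.present[cid] = True
        self.a0[cid] = 0.0 if ctype == CellType.WALL else (a0 if a0 is not None else 100.0)
        self.lam_area[cid] = 0.0 if ctype == CellType.WALL else params.lam_area
        self.lam_cont[cid] = params.lam_cont(ctype)
        self.adh[cid] = 1.0
        return cid

    def check_id(self, cid: int) -> None:
        if not (0 <= cid < self.n_ids) or not self.present[cid]:
            raise UnknownCellError(f"cell id {cid} is not in the registry")

    def com(self, cid: int) -> tuple[float, float]:
        a = self.area[cid]
        if a == 0:
            return (np.nan, np.nan)
        return (self.sx[cid] / a, self.sy[cid] / a)

    def record(self, cid: int) -> CellRecord:
        self.check_id(cid)
        return CellRecord(
            id=cid,
            cell_type=CellType(int(self.ctype[cid])),
            alive=bool(self.alive[cid]),
            area=int(self.area[cid]),
            perimeter=int(self.perim[cid]),
            com=self.com(cid),
            target_area=float(self.a0[cid]),
            polarization=(float(self.rx[cid]), float(self.ry[cid])),
            prev_com=(float(self.prev_cx[cid]), float(self.prev_cy[cid])),
        )

    def ids(self, *, wall: bool | None = None, alive: bool | None = None) -> np.ndarray:
        mask = self.present[: self.n_ids].copy()
        if wall is not None:
            mask &= (self.ctype[: self.n_ids] == int(CellType.WALL)) == wall
        if alive is not None:
            mask &= self.alive[: self.n_ids] == alive
        return np.nonzero(mask)[0]

    def mark_dead(self, cid: int, params: ModelParams) -> None:
        """Apply dead-cell parameters: phi, lambda_cont, A0 zeroed; stiff area term."""
        self.alive[cid] = False
        self.adh[cid] = 0.0
        self.lam_cont[cid] = 0.0
        self.a0[cid] = 0.0
        self.lam_area[cid] = params.turnover.dead_lam_area
        self.rx[cid] = self.ry[cid] = 0.0
        self.fx[cid] = self.fy[cid] = 0.0


def recompute_cell_geometry(
    lattice: LatticeState, cid: int, bond_neighborhood: int = 4
) -> tuple[int, int, tuple[float, float]]:
    """Recompute (area, perimeter, com) of one cell directly from the grid.

    The perimeter is the number of bond-neighborhood bonds from a pixel of
    the cell to a pixel of any other cell; wall pixels and the domain edge
    count as "other".  This is the ground-truth oracle for the cached state.
    """
    mask = lattice.grid == cid
    area = int(mask.sum())
    if area == 0:
        raise UnknownCellError(f"cell id {cid} does not occur in the lattice")
    ys, xs = np.nonzero(mask)
    perim = 0
    h, w = lattice.grid.shape
    for dy, dx in neighborhood(bond_neighborhood):
        ny, nx = ys + dy, xs + dx
        inside = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        perim += int(np.count_nonzero(~inside))
        perim += int(np.count_nonzero(lattice.grid[ny[inside], nx[inside]] != cid))
    com = (float(xs.mean()), float(ys.mean()))
    return area, perim, com


def rebuild_caches(lattice: LatticeState, cells: CellTable,
                   bond_neighborhood: int = 4) -> None:
    """Recompute every present cell's cached geometry from the lattice."""
    grid = lattice.grid.astype(np.int64)
    n = cells.n_ids
    cells.area[:n] = np.bincount(grid.ravel(), minlength=n)[:n]
    h, w = grid.shape
    ys, xs = np.mgrid[0:h, 0:w]
    for name, coord in (("sx", xs), ("sy", ys), ("sxx", xs * xs),
                        ("syy", ys * ys), ("sxy", xs * ys)):
        arr = np.bincount(grid.ravel(), weights=coord.ravel().astype(np.float64),
                          minlength=n)[:n]
        getattr(cells, name)[:n] = np.rint(arr).astype(np.int64)
    perim = np.zeros(n, dtype=np.int64)
    for dy, dx in neighborhood(bond_neighborhood):
        shifted = np.full_like(grid, -1)
        ys0, ys1 = max(dy, 0), h + min(dy, 0)
        xs0, xs1 = max(dx, 0), w + min(dx, 0)
        shifted[ys0:ys1, xs0:xs1] = grid[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
        diff = grid != shifted
        perim += np.bincount(grid.ravel()[diff.ravel()], minlength=n)[:n]
    cells.perim[:n] = perim
    cells.perim[:n][cells.area[:n] == 0] = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cx = np.where(cells.area[:n] > 0, cells.sx[:n] / np.maximum(cells.area[:n], 1), 0.0)
        cy = np.where(cells.area[:n] > 0, cells.sy[:n] / np.maximum(cells.area[:n], 1), 0.0)
    cells.prev_cx[:n] = cx
    cells.prev_cy[:n] = cy


def check_conservation(lattice: LatticeState, cells: CellTable) -> None:
    """Sum of all cached areas must equal the pixel count (exact integers)."""
    total = int(cells.area[: cells.n_ids].sum())
    if total != lattice.grid.size:
        raise AssertionError(
            f"area conservation violated: cached {total} != {lattice.grid.size} pixels"
        )


def fragmented_cells(lattice: LatticeState, cells: CellTable) -> list[int]:
    """Diagnostic: ids of non-wall cells whose pixel set is not 4-connected.

    No connectivity constraint is enforced by the dynamics; this makes the
    effect observable.
    """
    out = []
    for cid in cells.ids(wall=False):
        if cells.area[cid] == 0:
            continue
        _, n_comp = ndimage.label(lattice.grid == cid)
        if n_comp > 1:
            out.append(int(cid))
    return out
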