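"""Deterministic small lattices with hand-checkable geometry for tests."""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .state import CellTable, LatticeState, rebuild_caches
from .types import CellType

KINDS = ("two_cell_block", "striped", "random_voronoi", "dead_cell", "dividing_cell")


def make_fixture(kind: str, size: int = 6, rng: np.random.Generator | None = None,
                 params: ModelParams | None = None
                 ) -> tuple[LatticeState, CellTable, dict]:
    """Build a small reference lattice.

    Returns (lattice, cells, reference) where ``reference`` holds
    precomputed geometry for the hand-checkable kinds.
    """
    if params is None:
        params = ModelParams()
    if rng is None:
        rng = np.random.default_rng(0)
    if kind == "two_cell_block":
        return _two_cell_block(size, params)
    if kind == "striped":
        return _striped(size, params)
    if kind == "random_voronoi":
        return _random_voronoi(size, rng, params)
    if kind == "dead_cell":
        lattice, cells, ref = _two_cell_block(size, params)
        cells.mark_dead(1, params)
        ref["dead_id"] = 1
        return lattice, cells, ref
    if kind == "dividing_cell":
        return _dividing_cell(size, params)
    raise ValueError(f"unknown fixture kind {kind!r}; one of {KINDS}")


def _finish(grid: np.ndarray, cells: CellTable, params: ModelParams,
            ref: dict) -> tuple[LatticeState, CellTable, dict]:
    lattice = LatticeState(grid)
    rebuild_caches(lattice, cells, params.bond_neighborhood)
    return lattice, cells, ref


def _two_cell_block(size: int, params: ModelParams):
    """Two side-by-side blocks, e.g. 6x6 -> two 3x6 cells of area 18.

    Each block's perimeter counts its outer edge bonds plus the shared
    interface bonds (``size`` of them).
    """
    half = size // 2
    grid = np.zeros((size, size), dtype=np.int32)
    cells = CellTable()
    a = cells.new_cell(CellType.MOTILE, params, a0=half * size)
    b = cells.new_cell(CellType.NON_MOTILE, params, a0=(size - half) * size)
    grid[:, :half] = a
    grid[:, half:] = b
    ref = {
        "areas": {a: half * size, b: (size - half) * size},
        "perimeters": {a: 2 * half + 2 * size, b: 2 * (size - half) + 2 * size},
        "interface_bonds": size,
    }
    return _finish(grid, cells, params, ref)


def _striped(size: int, params: ModelParams):
    grid = np.zeros((size, size), dtype=np.int32)
    cells = CellTable()
    width = 2
    ids = []
    for x0 in range(0, size, width):
        w = min(width, size - x0)
        cid = cells.new_cell(
            CellType.MOTILE if len(ids) % 2 == 0 else CellType.NON_MOTILE,
            params, a0=w * size)
        grid[:, x0:x0 + w] = cid
        ids.append(cid)
    return _finish(grid, cells, params, {"stripe_ids": ids, "stripe_width": width})


def _random_voronoi(size: int, rng: np.random.Generator, params: ModelParams):
    """Nearest-seed tessellation (ties to the lowest id); seeded -> identical."""
    k = max(2, size * size // 18)
    seeds = rng.integers(0, size, size=(k, 2))
    ys, xs = np.mgrid[0:size, 0:size]
    d2 = ((ys[..., None] - seeds[:, 0]) ** 2 + (xs[..., None] - seeds[:, 1]) ** 2)
    grid = np.argmin(d2, axis=-1).astype(np.int32)
    cells = CellTable()
    areas = np.bincount(grid.ravel(), minlength=k)
    for i in range(k):
        cells.new_cell(CellType.MOTILE if i % 2 == 0 else CellType.NON_MOTILE,
                       params, a0=max(int(areas[i]), 1))
    # empty seeds stay present with area 0; harmless for energy oracles
    return _finish(grid, cells, params, {"n_seeds": k})


def _dividing_cell(size: int, params: ModelParams):
    """A wide rectangular cell (eligible to divide) inside a background cell."""
    size = max(size, 10)
    grid = np.zeros((size, size), dtype=np.int32)
    cells = CellTable()
    bg = cells.new_cell(CellType.NON_MOTILE, params, a0=size * size)
    w, h = 8, 4
    inner = cells.new_cell(CellType.MOTILE, params, a0=w * h)
    y0 = (size - h) // 2
    x0 = (size - w) // 2
    grid[y0:y0 + h, x0:x0 + w] = inner
    cells.a0[bg] = size * size - w * h
    ref = {"dividing_id": inner, "area": w * h,
           "expected_daughter_areas": {w * h // 2, w * h - w * h // 2},
           "principal_axis": "x"}
    return _finish(grid, cells, params, ref)
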