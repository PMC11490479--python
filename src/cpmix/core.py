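"""Energy function, Metropolis copy attempts and the Monte-Carlo sweep.

The effective energy of a configuration is

    E = lam_area * sum_a (A_a - A0_a)^2          (area elasticity)
      + lam_cont * sum_a L_a^2                   (cortex contractility)
      + sum_bonds phi(type_i, type_j)            (adhesion, heterotypic bonds)
      [+ motile work, applied per copy attempt]

with the perimeter ``L_a`` counted as 4-neighbor bonds to pixels of any
other cell (wall and domain edge included), each unordered bond counted
once, and wall cells contributing no area/perimeter terms.  The motile term
is not a state function — it enters the dynamics as the work
``work_sign * F . dr_com`` a candidate copy would perform on each motile
cell's center of mass.

An elementary step proposes copying a neighboring pixel's cell id onto a
random non-frozen site and accepts with the Metropolis rule at temperature
T; one Monte Carlo step (MCS) makes as many attempts as there are
non-frozen sites.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels, motility, turnover
from .params import ModelParams
from .state import CellTable, LatticeState, neighborhood
from .types import CellType


def metropolis_probability(delta_e: float, temperature: float) -> float:
    """min(1, exp(-dE/T)): acceptance probability of a candidate copy."""
    if delta_e <= 0.0:
        return 1.0
    return math.exp(-delta_e / temperature)


def total_energy(lattice: LatticeState, cells: CellTable, params: ModelParams) -> float:
    """First three energy terms, computed directly from the lattice.

    Independent of the cached per-cell geometry; used as the oracle against
    incremental energy differences.
    """
    n = cells.n_ids
    grid = lattice.grid.astype(np.int64)
    h, w = grid.shape
    areas = np.bincount(grid.ravel(), minlength=n)[:n].astype(np.float64)

    perim = np.zeros(n, dtype=np.int64)
    e_phi = 0.0
    phi = params.phi_matrix()
    ctype = cells.ctype[:n].astype(np.int64)
    adh = cells.adh[:n]
    offsets = neighborhood(params.bond_neighborhood)
    for dy, dx in offsets:
        shifted = np.full_like(grid, -1)
        ys0, ys1 = max(dy, 0), h + min(dy, 0)
        xs0, xs1 = max(dx, 0), w + min(dx, 0)
        shifted[ys0:ys1, xs0:xs1] = grid[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
        diff = grid != shifted
        perim += np.bincount(grid.ravel()[diff.ravel()], minlength=n)[:n]
        if dy > 0 or (dy == 0 and dx > 0):  # each unordered bond once
            both = diff & (shifted >= 0)
            a = grid[both]
            b = shifted[both]
            e_phi += float(np.sum(phi[ctype[a], ctype[b]] * adh[a] * adh[b]))

    present = cells.present[:n]
    e_area = float(np.sum(cells.lam_area[:n][present]
                          * (areas[present] - cells.a0[:n][present]) ** 2))
    e_cont = float(np.sum(cells.lam_cont[:n] * perim.astype(np.float64) ** 2))
    return e_area + e_cont + e_phi


def _check_copy_args(lattice: LatticeState, site, source) -> tuple[int, int, int, int]:
    x, y = site
    sx_, sy_ = source
    if lattice.frozen[y, x]:
        raise ValueError(f"site {site} is frozen; copy attempts must skip it")
    if lattice.grid[sy_, sx_] == lattice.grid[y, x]:
        raise ValueError("source id equals site id; caller must skip this attempt")
    return x, y, sx_, sy_


def delta_energy_copy(lattice: LatticeState, cells: CellTable, params: ModelParams,
                      site: tuple[int, int], source: tuple[int, int],
                      use_motility: bool = True) -> float:
    """Incremental energy change of copying ``source``'s id onto ``site``.

    ``site`` and ``source`` are (x, y) pixel coordinates.  Includes the
    motile work term for any motile, alive participant (their cached force
    vectors), unless ``use_motility`` is false.
    """
    x, y, sx_, sy_ = _check_copy_args(lattice, site, source)
    bond = neighborhood(params.bond_neighborhood)
    step = np.array([y - sy_, x - sx_], dtype=float)
    norm = math.hypot(*step)
    if norm > 0:
        step /= norm
    return float(_kernels.delta_energy_site(
        lattice.grid, y, x, int(lattice.grid[sy_, sx_]), step[0], step[1],
        np.ascontiguousarray(bond[:, 0]), np.ascontiguousarray(bond[:, 1]),
        cells.area, cells.perim, cells.sx, cells.sy,
        cells.lam_area, cells.lam_cont, cells.a0, cells.adh, cells.ctype,
        cells.fx, cells.fy, params.phi_matrix(),
        use_motility, params.motility.work_mode == "pixel",
        float(params.motility.work_sign)))


def attempt_copy(lattice: LatticeState, cells: CellTable, params: ModelParams,
                 site: tuple[int, int], source: tuple[int, int],
                 rng: np.random.Generator, use_motility: bool = True) -> bool:
    """One Metropolis copy attempt; on acceptance, updates grid and caches."""
    de = delta_energy_copy(lattice, cells, params, site, source, use_motility)
    if de > 0.0 and not rng.random() < math.exp(-de / params.temperature):
        return False
    x, y, sx_, sy_ = _check_copy_args(lattice, site, source)
    a = int(lattice.grid[y, x])
    b = int(lattice.grid[sy_, sx_])
    # bond-count deltas for the two affected perimeters
    nb = 0
    cnt_a = cnt_b = 0
    for dy, dx in neighborhood(params.bond_neighborhood):
        nb += 1
        ny, nx = y + dy, x + dx
        if 0 <= ny < lattice.height and 0 <= nx < lattice.width:
            c = int(lattice.grid[ny, nx])
            cnt_a += c == a
            cnt_b += c == b
    _kernels.apply_copy(lattice.grid, y, x, b,
                        2 * cnt_a - nb, nb - 2 * cnt_b,
                        cells.area, cells.perim, cells.sx, cells.sy,
                        cells.sxx, cells.syy, cells.sxy)
    return True


class Simulation:
    """Mutable simulation state: lattice + cell registry + parameters.

    One :meth:`step` advances a single MCS in the fixed order
    copy sweep -> division -> death -> extrusion -> polarization update.
    All randomness flows from the single generator ``rng`` in that order,
    so runs are bit-reproducible under a fixed seed.
    """

    def __init__(self, lattice: LatticeState, cells: CellTable, params: ModelParams,
                 rng: np.random.Generator,
                 motility_on: bool = False, turnover_on: bool = False,
                 midline_x: float | None = None):
        params.validate()
        self.lattice = lattice
        self.cells = cells
        self.params = params
        self.rng = rng
        self.motility_on = motility_on
        self.turnover_on = turnover_on
        self.midline_x = midline_x
        self.time = 0
        self.births = {CellType.MOTILE: 0, CellType.NON_MOTILE: 0}
        self.deaths = {CellType.MOTILE: 0, CellType.NON_MOTILE: 0}
        self._phi = params.phi_matrix()
        bond = neighborhood(params.bond_neighborhood)
        src = neighborhood(params.copy_neighborhood)
        self._bond_dy = np.ascontiguousarray(bond[:, 0])
        self._bond_dx = np.ascontiguousarray(bond[:, 1])
        self._src_dy = np.ascontiguousarray(src[:, 0])
        self._src_dx = np.ascontiguousarray(src[:, 1])
        self.refresh_sites()

    def refresh_sites(self) -> None:
        """Re-enumerate non-frozen sites (call after barrier removal)."""
        self._nzy, self._nzx = self.lattice.nonfrozen_sites()

    @property
    def n_attempts_per_mcs(self) -> int:
        return self._nzy.shape[0]

    def monte_carlo_step(self) -> int:
        """One sweep of copy attempts; returns the number accepted."""
        n = self.n_attempts_per_mcs
        if n == 0:
            return 0
        u_site = self.rng.random(n)
        u_src = self.rng.random(n)
        u_acc = self.rng.random(n)
        c = self.cells
        return int(_kernels.run_sweep(
            self.lattice.grid, self.lattice.frozen, self._nzy, self._nzx,
            u_site, u_src, u_acc,
            self._src_dy, self._src_dx, self._bond_dy, self._bond_dx,
            c.area, c.perim, c.sx, c.sy, c.sxx, c.syy, c.sxy,
            c.lam_area, c.lam_cont, c.a0, c.adh, c.ctype, c.fx, c.fy,
            self._phi, self.params.temperature,
            self.motility_on, self.params.motility.work_mode == "pixel",
            float(self.params.motility.work_sign)))

    def step(self, n_mcs: int = 1) -> None:
        for _ in range(n_mcs):
            self.monte_carlo_step()
            if self.turnover_on:
                divided = turnover.division_sweep(self.lattice, self.cells,
                                                  self.params, self.rng)
                for parent, _ in divided:
                    self.births[CellType(int(self.cells.ctype[parent]))] += 1
                skip = {cid for pair in divided for cid in pair}
                for cid in turnover.death_sweep(self.cells, self.params, self.rng,
                                                exclude=skip):
                    self.deaths[CellType(int(self.cells.ctype[cid]))] += 1
                turnover.extrusion_sweep(self.lattice, self.cells, self.params)
            motility.end_of_sweep_update(self.cells, self.params,
                                         polarize=self.motility_on)
            self.time += 1

    # ------------------------------------------------------------------
    # observables

    def counts(self) -> dict[CellType, int]:
        """Alive, on-lattice cell count per non-wall type."""
        c = self.cells
        n = c.n_ids
        live = c.present[:n] & c.alive[:n] & (c.area[:n] > 0)
        out = {}
        for t in (CellType.MOTILE, CellType.NON_MOTILE):
            out[t] = int(np.count_nonzero(live & (c.ctype[:n] == int(t))))
        return out

    def crossed_counts(self) -> tuple[int, int]:
        """(crossed motile, crossed non-motile): alive cells whose every
        pixel lies strictly on the opposite side of the midline from their
        type's initial side (motile start left)."""
        if self.midline_x is None:
            return (0, 0)
        c = self.cells
        n = c.n_ids
        minx, maxx = _kernels.minmax_x(self.lattice.grid, n)
        live = c.present[:n] & c.alive[:n] & (c.area[:n] > 0)
        motile_m = live & (c.ctype[:n] == int(CellType.MOTILE))
        nonmot_m = live & (c.ctype[:n] == int(CellType.NON_MOTILE))
        crossed_m = int(np.count_nonzero(motile_m & (minx > self.midline_x)))
        crossed_nm = int(np.count_nonzero(nonmot_m & (maxx < self.midline_x)))
        return crossed_m, crossed_nm

    def sample(self) -> dict:
        """One trajectory row of summary statistics at the current time."""
        c = self.cells
        n = c.n_ids
        counts = self.counts()
        crossed_m, crossed_nm = self.crossed_counts()
        live = (c.present[:n] & c.alive[:n] & (c.area[:n] > 0)
                & (c.ctype[:n] != int(CellType.WALL)))
        motile_live = live & (c.ctype[:n] == int(CellType.MOTILE))
        rho_mag = np.hypot(c.rx[:n][motile_live], c.ry[:n][motile_live])
        on_lattice = c.present[:n] & (c.ctype[:n] != int(CellType.WALL)) & (c.area[:n] > 0)
        n_total = int(np.count_nonzero(on_lattice))
        n_dead = int(np.count_nonzero(on_lattice & ~c.alive[:n]))
        with np.errstate(invalid="ignore"):
            area_dev = np.abs(c.area[:n][live] - c.a0[:n][live]) / c.a0[:n][live]
        return {
            "t": self.time,
            "n_motile": counts[CellType.MOTILE],
            "n_nonmotile": counts[CellType.NON_MOTILE],
            "crossed_motile": crossed_m,
            "crossed_nonmotile": crossed_nm,
            "mean_rho": float(rho_mag.mean()) if rho_mag.size else 0.0,
            "dead_fraction": n_dead / n_total if n_total else 0.0,
            "mean_abs_area_dev": float(area_dev.mean()) if area_dev.size else 0.0,
            "births_motile": self.births[CellType.MOTILE],
            "births_nonmotile": self.births[CellType.NON_MOTILE],
            "deaths_motile": self.deaths[CellType.MOTILE],
            "deaths_nonmotile": self.deaths[CellType.NON_MOTILE],
        }
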