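"""Domain construction and the two experiment drivers.

The standard domain is a 302x150-pixel interior wrapped by a frozen wall
frame, with a 2-pixel frozen barrier column on the midline separating 225
motile cells (left half) from 225 non-motile cells (right half), each
seeded as near-square tiles of about A0 = 100 pixels.  The contact energy
between wall and cells is zero.

Schedule: (1) relax with motility off until the cells reach their
equilibrium shapes; (2) let the motile cells polarize spontaneously behind
the barrier (turnover already on in invasion runs so both sides reach
their equilibrium density); (3) remove the barrier, handing its pixels to
the bordering cells; (4) main run.  MIXING runs keep per-type cell counts
constant (no turnover); INVASION runs include stochastic division/death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Simulation
from .params import ModelParams, ScenarioConfig
from .state import CellTable, LatticeState, rebuild_caches
from .types import CellType, ConfigError, Experiment


@dataclass
class Trajectory:
    """Sampled time series of one run plus scheduling metadata."""

    samples: list[dict] = field(default_factory=list)
    n_initial: dict = field(default_factory=dict)
    barrier_removal_mcs: int = 0
    experiment: Experiment = Experiment.MIXING
    phase_boundaries: dict = field(default_factory=dict)

    def append(self, row: dict) -> None:
        self.samples.append(row)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _tile_counts(n: int, width: int, height: int) -> list[int]:
    """Cells per row for tiling ``n`` near-square seeds into width x height."""
    k = max(1, round(math.sqrt(n * height / width)))
    k = min(k, n)
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _split(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _tile_region(grid: np.ndarray, cells: CellTable, params: ModelParams,
                 ctype: CellType, a0: float, n: int,
                 x0: int, x1: int, y0: int, y1: int) -> None:
    per_row = _tile_counts(n, x1 - x0, y1 - y0)
    heights = _split(y1 - y0, len(per_row))
    y = y0
    for m, h in zip(per_row, heights):
        widths = _split(x1 - x0, m)
        x = x0
        for w in widths:
            cid = cells.new_cell(ctype, params, a0=a0)
            grid[y:y + h, x:x + w] = cid
            x += w
        y += h


def init_confluent(config: ScenarioConfig, params: ModelParams,
                   rng: np.random.Generator | None = None
                   ) -> tuple[LatticeState, CellTable, dict]:
    """Build the initial confluent two-population lattice.

    Returns (lattice, cells, meta) where meta holds the barrier cell id,
    the midline x coordinate and the interior bounds.
    """
    config.validate()
    params.validate()
    wt = config.wall_thickness
    width = config.width + 2 * wt
    height = config.height + 2 * wt
    grid = np.zeros((height, width), dtype=np.int32)
    frozen = np.zeros((height, width), dtype=bool)
    cells = CellTable(capacity=2 * config.n_per_type + 16)

    # wall: four frozen rectangles around the interior
    wall_rects = [(0, height, 0, wt), (0, height, width - wt, width),
                  (0, wt, wt, width - wt), (height - wt, height, wt, width - wt)]
    for y0, y1, x0, x1 in wall_rects:
        cid = cells.new_cell(CellType.WALL, params)
        grid[y0:y1, x0:x1] = cid
        frozen[y0:y1, x0:x1] = True

    xb0 = wt + config.half_width
    barrier_id = None
    if config.barrier_width > 0:
        barrier_id = cells.new_cell(CellType.WALL, params)
        grid[wt:height - wt, xb0:xb0 + config.barrier_width] = barrier_id
        frozen[wt:height - wt, xb0:xb0 + config.barrier_width] = True

    _tile_region(grid, cells, params, CellType.MOTILE, config.a0,
                 config.n_per_type, wt, xb0, wt, height - wt)
    _tile_region(grid, cells, params, CellType.NON_MOTILE, config.a0,
                 config.n_per_type,
                 xb0 + config.barrier_width, width - wt, wt, height - wt)

    lattice = LatticeState(grid, frozen)
    rebuild_caches(lattice, cells, params.bond_neighborhood)
    meta = {
        "barrier_id": barrier_id,
        "midline_x": xb0 + (config.barrier_width - 1) / 2.0,
        "interior": (wt, height - wt, wt, width - wt),
    }
    return lattice, cells, meta


def build_simulation(config: ScenarioConfig, params: ModelParams,
                     rng: np.random.Generator) -> tuple[Simulation, dict]:
    lattice, cells, meta = init_confluent(config, params, rng)
    sim = Simulation(lattice, cells, params, rng, midline_x=meta["midline_x"])
    return sim, meta


def remove_barrier(sim: Simulation, barrier_id: int) -> None:
    """Hand each barrier pixel to the bordering cell with the longest shared
    boundary (ties to the lowest id) and unfreeze the column."""
    lattice, cells = sim.lattice, sim.cells
    grid = lattice.grid
    h, w = grid.shape
    mask = grid == barrier_id
    barrier_pixels = mask.copy()
    while mask.any():
        ys, xs = np.nonzero(mask)
        decided = []
        for y, x in zip(ys, xs):
            counts: dict[int, int] = {}
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w):
                    continue
                c = int(grid[ny, nx])
                if c == barrier_id or cells.ctype[c] == int(CellType.WALL):
                    continue
                counts[c] = counts.get(c, 0) + 1
            if counts:
                best = max(counts.values())
                decided.append((y, x, min(c for c, k in counts.items() if k == best)))
        if not decided:
            raise ConfigError("barrier removal stalled: no adjacent cells")
        for y, x, c in decided:
            grid[y, x] = c
        mask = grid == barrier_id
    lattice.frozen[barrier_pixels] = False
    cells.present[barrier_id] = False
    rebuild_caches(lattice, cells, sim.params.bond_neighborhood)
    sim.refresh_sites()


def run_schedule(config: ScenarioConfig, params: ModelParams,
                 rng: np.random.Generator | None = None,
                 stop_when_decided: bool = True,
                 snapshot_hook=None) -> tuple[Trajectory, Simulation]:
    """Run the full four-phase schedule; returns (trajectory, final state).

    ``snapshot_hook(sim, label)`` is called at phase boundaries if given.
    In INVASION mode the run stops early once one type is eliminated
    (unless ``stop_when_decided`` is false).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sim, meta = build_simulation(config, params, rng)
    sched = config.schedule
    invasion = config.experiment == Experiment.INVASION
    traj = Trajectory(
        n_initial={t.value: n for t, n in sim.counts().items()},
        barrier_removal_mcs=sched.barrier_removal_mcs,
        experiment=config.experiment,
        phase_boundaries={"relax_end": sched.relax_mcs,
                          "barrier_removal": sched.barrier_removal_mcs,
                          "total": sched.total_mcs},
    )

    def advance(until: int) -> bool:
        while sim.time < until:
            sim.step(1)
            if sim.time % sched.sample_every == 0:
                row = sim.sample()
                traj.append(row)
                if invasion and stop_when_decided and sim.time > sched.barrier_removal_mcs:
                    if row["n_motile"] == 0 or row["n_nonmotile"] == 0:
                        return True
        return False

    traj.append(sim.sample())
    advance(sched.relax_mcs)
    if snapshot_hook:
        snapshot_hook(sim, "relaxed")
    sim.motility_on = True
    sim.turnover_on = invasion
    advance(sched.barrier_removal_mcs)
    if meta["barrier_id"] is not None:
        remove_barrier(sim, meta["barrier_id"])
    if snapshot_hook:
        snapshot_hook(sim, "barrier_removed")
    advance(sched.total_mcs)
    if snapshot_hook:
        snapshot_hook(sim, "final")
    return traj, sim


@dataclass
class SingleTypeResult:
    """Equilibrium density of a single cell type filling the whole domain."""

    rho0: float  #: time-averaged alive cell count per domain (L = 1 units)
    extinct: bool
    trajectory: Trajectory


def run_single_type(config: ScenarioConfig, params: ModelParams,
                    ctype: CellType = CellType.MOTILE,
                    rng: np.random.Generator | None = None) -> SingleTypeResult:
    """Fill the whole interior with one cell type, run it with its turnover
    rates to stationarity, and time-average the alive count over the second
    half of the run."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = ScenarioConfig(
        width=config.width, height=config.height,
        n_per_type=config.n_per_type, a0=config.a0,
        barrier_width=0, wall_thickness=config.wall_thickness,
        experiment=Experiment.INVASION, schedule=config.schedule, seed=config.seed)
    cfg.validate()
    wt = cfg.wall_thickness
    width = cfg.width + 2 * wt
    height = cfg.height + 2 * wt
    grid = np.zeros((height, width), dtype=np.int32)
    frozen = np.zeros((height, width), dtype=bool)
    cells = CellTable(capacity=4 * cfg.n_per_type + 16)
    for y0, y1, x0, x1 in [(0, height, 0, wt), (0, height, width - wt, width),
                           (0, wt, wt, width - wt),
                           (height - wt, height, wt, width - wt)]:
        cid = cells.new_cell(CellType.WALL, params)
        grid[y0:y1, x0:x1] = cid
        frozen[y0:y1, x0:x1] = True
    _tile_region(grid, cells, params, ctype, cfg.a0, 2 * cfg.n_per_type,
                 wt, width - wt, wt, height - wt)
    lattice = LatticeState(grid, frozen)
    rebuild_caches(lattice, cells, params.bond_neighborhood)
    sim = Simulation(lattice, cells, params, rng)
    sched = cfg.schedule
    traj = Trajectory(experiment=Experiment.INVASION)
    traj.append(sim.sample())
    key = "n_motile" if ctype == CellType.MOTILE else "n_nonmotile"
    while sim.time < sched.total_mcs:
        if sim.time == sched.relax_mcs:
            sim.motility_on = True
            sim.turnover_on = True
        sim.step(1)
        if sim.time % sched.sample_every == 0:
            traj.append(sim.sample())
            if traj.samples[-1][key] == 0:
                return SingleTypeResult(float("nan"), True, traj)
    df = traj.frame
    window = df[df["t"] >= sched.total_mcs / 2]
    rho0 = float(window[key].mean())
    return SingleTypeResult(rho0, rho0 == 0.0, traj)
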