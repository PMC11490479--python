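"""Division (area-gated, principal-axis split), size-independent death,
and extrusion of dead cells."""

import numpy as np
import pytest

from cpmix import (CellTable, CellType, LatticeState, ModelParams, Simulation,
                   check_conservation, division_sweep, death_sweep,
                   extrusion_sweep, make_fixture, rebuild_caches,
                   recompute_cell_geometry)
from cpmix.turnover import divide_cell


def _params(b=0.0, m=0.0):
    p = ModelParams()
    p.turnover.birth_motile = p.turnover.birth_nonmotile = b
    p.turnover.death_motile = p.turnover.death_nonmotile = m
    return p


def test_division_gate_requires_target_area(rng):
    """A cell below its target area never divides, even at B=1."""
    params = _params(b=1.0)
    lattice, cells, ref = make_fixture("dividing_cell", 12, params=params)
    cid = ref["dividing_id"]
    n = cells.n_ids
    cells.a0[:n] = cells.area[:n] + 1  # every cell at A = A0 - 1
    assert division_sweep(lattice, cells, params, rng) == []


def test_no_turnover_preserves_cell_ids(toy_config, rng):
    from cpmix.scenarios import build_simulation
    params = _params()
    sim, _ = build_simulation(toy_config, params, np.random.default_rng(1))
    sim.turnover_on = True
    ids_before = set(sim.cells.ids())
    sim.step(30)
    assert set(sim.cells.ids()) == ids_before


@pytest.mark.parametrize("w,h", [(8, 4), (7, 7)])
def test_division_split_halves_pixels(w, h, rng):
    """Daughters hold floor(A/2) and ceil(A/2) pixels and together exactly
    the parent's pixels; polarization is reset to zero."""
    params = _params(b=1.0)
    grid = np.zeros((12, 12), dtype=np.int32)
    cells = CellTable()
    bg = cells.new_cell(CellType.NON_MOTILE, params, a0=1)
    cid = cells.new_cell(CellType.MOTILE, params, a0=w * h)
    grid[2:2 + h, 2:2 + w] = cid
    lattice = LatticeState(grid)
    rebuild_caches(lattice, cells)
    cells.rx[cid] = 1.5
    parent_area = int(cells.area[cid])
    did = divide_cell(lattice, cells, params, cid, rng)
    assert did is not None
    areas = {int(cells.area[cid]), int(cells.area[did])}
    assert areas == {parent_area // 2, parent_area - parent_area // 2}
    assert int(cells.area[cid] + cells.area[did]) == parent_area
    for c in (cid, did):
        assert cells.rx[c] == cells.ry[c] == 0.0
        a, p, _ = recompute_cell_geometry(lattice, c)
        assert (a, p) == (int(cells.area[c]), int(cells.perim[c]))


def test_division_splits_perpendicular_to_principal_axis(rng):
    """An 8x4 cell (principal axis along x) splits into two 4x4 halves."""
    params = _params(b=1.0)
    lattice, cells, ref = make_fixture("dividing_cell", 12, params=params)
    cid = ref["dividing_id"]
    did = divide_cell(lattice, cells, params, cid, rng)
    for c in (cid, did):
        ys, xs = np.nonzero(lattice.grid == c)
        assert xs.max() - xs.min() == 3  # 4 wide
        assert ys.max() - ys.min() == 3  # 4 tall


def test_death_marks_dead_parameters(rng):
    """Dead cells get (phi, lam_cont, A0) = 0 and lam_area = 500."""
    params = _params(m=1.0)
    lattice, cells, ref = make_fixture("two_cell_block", 6, params=params)
    dead = death_sweep(cells, params, rng)
    assert sorted(dead) == [0, 1]
    for cid in dead:
        assert cells.adh[cid] == 0.0
        assert cells.lam_cont[cid] == 0.0
        assert cells.a0[cid] == 0.0
        assert cells.lam_area[cid] == 500.0
        assert not cells.alive[cid]
        assert cells.rx[cid] == cells.ry[cid] == 0.0


def test_no_death_at_zero_rate(rng):
    params = _params(m=0.0)
    lattice, cells, _ = make_fixture("two_cell_block", 6, params=params)
    for _ in range(50):
        assert death_sweep(cells, params, rng) == []


def test_cumulative_death_count_matches_expectation():
    """450 cells at M=0.001 over 1000 MCS: about 450*(1-0.999^1000) = 285
    cumulative deaths, within 4 sigma of the closed form."""
    params = _params(m=0.001)
    cells = CellTable(capacity=512)
    for _ in range(450):
        cells.new_cell(CellType.NON_MOTILE, params, a0=100)
    rng = np.random.default_rng(77)
    total = 0
    for _ in range(1000):
        total += len(death_sweep(cells, params, rng))
    p = 1 - 0.999 ** 1000
    expect = 450 * p
    sigma = np.sqrt(450 * p * (1 - p))
    assert abs(total - expect) < 4 * sigma


def test_extrusion_removes_only_fully_shrunk_dead_cells(rng):
    params = _params()
    lattice, cells, ref = make_fixture("dead_cell", 6, params=params)
    dead_id = ref["dead_id"]
    # alive cells or dead cells with pixels are never extruded at threshold 0
    assert extrusion_sweep(lattice, cells, params) == []
    # hand the dead cell's pixels to the other cell -> area 0 -> removed
    other = 0
    lattice.grid[lattice.grid == dead_id] = other
    rebuild_caches(lattice, cells)
    assert extrusion_sweep(lattice, cells, params) == [dead_id]
    assert not cells.present[dead_id]
    assert other in cells.ids()


def test_dead_cell_shrinks_and_is_extruded(toy_config):
    """Under lam_area=500 and A0=0 a dead cell's area shrinks to zero and
    the cell leaves the registry in finite time (division active, so the
    neighbors can share the reclaimed space)."""
    from cpmix.scenarios import build_simulation
    lifetimes = []
    for seed in range(5):
        params = _params(b=0.1)
        sim, _ = build_simulation(toy_config, params, np.random.default_rng(seed))
        sim.turnover_on = True
        victim = int(sim.cells.ids(wall=False)[0])
        sim.cells.mark_dead(victim, params)
        for t in range(1, 2001):
            sim.step(1)
            if not sim.cells.present[victim]:
                lifetimes.append(t)
                break
        check_conservation(sim.lattice, sim.cells)
    assert len(lifetimes) == 5  # every dead cell extruded
    assert np.median(lifetimes) < 2000


def test_homeostatic_count_is_stationary():
    """Single-type turnover at B=0.1, M=0.001 settles to a stationary count
    (no significant Mann-Kendall trend over the second half)."""
    from scipy import stats

    from cpmix import ScenarioConfig, ScheduleConfig, run_single_type
    from cpmix.types import Experiment
    cfg = ScenarioConfig(width=60, height=40, n_per_type=12, a0=100,
                         experiment=Experiment.INVASION, seed=4,
                         schedule=ScheduleConfig(relax_mcs=200, polarize_mcs=0,
                                                 total_mcs=4000, sample_every=50))
    params = _params(b=0.1, m=0.001)
    params.motility.f_max = 0.0
    res = run_single_type(cfg, params)
    assert not res.extinct
    df = res.trajectory.frame
    tail = df[df["t"] >= 2000]
    tau, pval = stats.kendalltau(tail["t"], tail["n_motile"])
    assert pval > 0.01  # no trend at the 1% level
    assert res.rho0 > 0
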