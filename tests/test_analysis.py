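"""Crossing counts, mixing/outcome classifiers, polarity-loss detection,
and the invasion-speed estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpmix import (CellTable, CellType, LatticeState, MixingClass,
                   ModelParams, Winner, classify_mixing, classify_outcome,
                   count_crossed, detect_polarity_loss, invasion_speed,
                   rebuild_caches, sweep_phase_diagram)


# ---------------------------------------------------------------- crossing

def _three_cell_lattice(motile_cols, params):
    """10x4 lattice, midline at x=4.5: one motile cell over ``motile_cols``,
    non-motile cells elsewhere."""
    grid = np.full((4, 10), 0, dtype=np.int32)
    cells = CellTable()
    nm1 = cells.new_cell(CellType.NON_MOTILE, params, a0=1)
    m = cells.new_cell(CellType.MOTILE, params, a0=1)
    grid[:, motile_cols[0]:motile_cols[1]] = m
    lattice = LatticeState(grid)
    rebuild_caches(lattice, cells)
    return lattice, cells, m


def test_crossed_cell_counted(params):
    """A motile cell wholly right of the midline counts as crossed."""
    lattice, cells, m = _three_cell_lattice((6, 9), params)
    assert count_crossed(lattice, cells, midline_x=4.5) == (1, 0)


def test_straddling_cell_not_counted(params):
    lattice, cells, m = _three_cell_lattice((3, 7), params)
    assert count_crossed(lattice, cells, midline_x=4.5) == (0, 0)


def test_initial_configuration_has_no_crossings(params):
    lattice, cells, m = _three_cell_lattice((0, 4), params)
    assert count_crossed(lattice, cells, midline_x=4.5)[0] == 0


def test_dead_cells_excluded_from_crossing(params):
    lattice, cells, m = _three_cell_lattice((6, 9), params)
    cells.mark_dead(m, params)
    assert count_crossed(lattice, cells, midline_x=4.5) == (0, 0)


# ------------------------------------------------------------- classifiers

def test_classify_mixing_thresholds():
    assert classify_mixing([0, 0, 0], 225) is MixingClass.NONE
    assert classify_mixing([0, 40, 113], 225) is MixingClass.WELL_MIXED
    assert classify_mixing([0, 40, 72], 225) is MixingClass.PARTIAL  # ~32%


@settings(deadline=None, max_examples=80, derandomize=True)
@given(st.lists(st.integers(0, 225), min_size=1, max_size=30),
       st.integers(0, 29), st.integers(1, 50))
def test_classify_mixing_is_monotone(series, idx, bump):
    """Raising any crossing count never demotes the class."""
    order = [MixingClass.NONE, MixingClass.PARTIAL, MixingClass.WELL_MIXED]
    before = order.index(classify_mixing(series, 225))
    bumped = list(series)
    bumped[idx % len(bumped)] = min(225, bumped[idx % len(bumped)] + bump)
    after = order.index(classify_mixing(bumped, 225))
    assert after >= before


def test_polarity_loss_detection():
    t = np.arange(0, 20001, 100, dtype=float)
    beta = 1.0
    persistent = np.full_like(t, 2.5)
    assert detect_polarity_loss(t, persistent, beta) is None
    # decays at t=5000 and stays low for 15000 MCS
    lost = np.where(t < 5000, 2.5, 0.02)
    assert detect_polarity_loss(t, lost, beta) == 5000.0
    # brief dip then recovery
    dip = np.where((t > 5000) & (t < 7000), 0.02, 2.5)
    assert detect_polarity_loss(t, dip, beta) is None
    # loss too close to the end of the run fails the persistence window
    late = np.where(t < 19000, 2.5, 0.02)
    assert detect_polarity_loss(t, late, beta) is None


def test_classify_outcome_elimination_and_coexistence():
    t = np.arange(0, 30001, 500)

    def frame(nm, nn):
        return pd.DataFrame({"t": t, "n_motile": nm, "n_nonmotile": nn})

    nm = np.linspace(120, 240, t.size).round()
    nn = np.linspace(120, 0, t.size).round()
    assert classify_outcome(frame(nm, nn), 2000) is Winner.MOTILE
    assert classify_outcome(frame(nn, nm), 2000) is Winner.NON_MOTILE
    # stable coexistence at ~50/50
    wob = 120 + 5 * np.sin(t / 900.0)
    assert classify_outcome(frame(wob, wob[::-1]), 2000) is Winner.COEXIST
    # neither eliminated, but occupancy leaves the band -> run too short
    drift = np.linspace(120, 239, t.size)
    assert classify_outcome(frame(drift, 240 - drift), 2000) is Winner.UNDECIDED


def test_classify_outcome_motile_iff_nonmotile_extinct():
    """MOTILE classification is logically equivalent to N_nm reaching 0."""
    t = np.arange(0, 10001, 500)
    rng = np.random.default_rng(5)
    for _ in range(30):
        nm = rng.integers(1, 200, t.size)
        nn = rng.integers(0, 200, t.size)
        frame = pd.DataFrame({"t": t, "n_motile": nm, "n_nonmotile": nn})
        got = classify_outcome(frame, 0)
        assert (got is Winner.MOTILE) == (nn.min() == 0)


# ---------------------------------------------------------- invasion speed

def test_invasion_speed_flat_series_is_zero():
    t = np.arange(0, 5001, 50, dtype=float)
    v, _ = invasion_speed(t, np.full_like(t, 100.0), rho0=450.0)
    assert v == pytest.approx(0.0, abs=1e-12)


def test_invasion_speed_known_slope():
    """dN/dt = 0.02 cells/MCS with rho0 = 450 and L = 1 gives
    v = 4.44e-5 domain-lengths/MCS."""
    t = np.arange(0, 5001, 50, dtype=float)
    v, _ = invasion_speed(t, 100 + 0.02 * t, rho0=450.0)
    assert v == pytest.approx(0.02 / 450.0, rel=1e-9)
    assert v == pytest.approx(4.44e-5, rel=1e-2)


def test_invasion_speed_recovers_noisy_ramp_and_subsampling():
    """A noisy linear ramp with 1000 samples is recovered within 2%, and
    subsampling the trajectory changes the estimate by < 5%."""
    rng = np.random.default_rng(11)
    t = np.linspace(0, 20000, 1000)
    slope = 0.015
    n = 50 + slope * t + rng.normal(0, 3.0, t.size)
    v, _ = invasion_speed(t, n, rho0=450.0)
    assert v == pytest.approx(slope / 450.0, rel=0.02)
    v_sub, _ = invasion_speed(t[::10], n[::10], rho0=450.0)
    assert v_sub == pytest.approx(v, rel=0.05)


def test_invasion_speed_requires_density():
    t = np.arange(0.0, 100.0, 10.0)
    with pytest.raises(ValueError):
        invasion_speed(t, t, rho0=0.0)
    with pytest.raises(ValueError):
        invasion_speed(t, t, rho0=float("nan"))


def test_invasion_speed_fit_window_stops_at_occupancy():
    """The fit window ends once the winner holds 75% of all cells."""
    t = np.arange(0, 10001, 100, dtype=float)
    nm = 100 + 0.05 * t          # reaches 75% of 400 (=300) at t=4000
    total = np.full_like(t, 400.0)
    _, window = invasion_speed(t, nm, rho0=400.0, n_total=total)
    assert window[1] == pytest.approx(4000.0)


# ------------------------------------------------------------- phase sweep

def test_sweep_bookkeeping(toy_config, params):
    """A 2x2 grid with 3 replicates yields 12 rows and a 4-row summary;
    identical seeds give identical tables."""
    grid = {"motility.f_max": [0.0, 50.0],
            "lam_cont_nonmotile": [0.5, 2.0]}
    runs1, summary1 = sweep_phase_diagram(toy_config, params, grid,
                                          replicates=3, seed=5)
    runs2, _ = sweep_phase_diagram(toy_config, params, grid,
                                   replicates=3, seed=5)
    assert len(runs1) == 12
    assert len(summary1) == 4
    assert runs1["error"].isna().all()
    assert runs1.equals(runs2)
    assert {"majority", "unanimous", "n_runs"} <= set(summary1.columns)
    assert (summary1["n_runs"] == 3).all()
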