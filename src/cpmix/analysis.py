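"""Summary statistics and outcome classifiers.

Mixing runs are classified from the crossing count Ñ_m(t) — the number of
motile cells located fully in the opposite half of the domain relative to
their initial side: WELL_MIXED if Ñ_m ever reaches half the motile
population, NONE if no cell ever crosses, PARTIAL otherwise.  Polarity
loss is the first time after which the mean polarization magnitude of the
motile cells stays below 0.1*beta for the remainder of the run (and for at
least a persistence window).

Invasion runs are classified by elimination: a type wins when the other
type's alive count reaches zero; sustained intermediate occupancy of both
types is coexistence.  The invasion speed converts the fitted slope of the
winner's cell count, over the initial stage of the invasion, into a front
speed v = (dN/dt) * L / rho0, with L = 1 the domain length unit and rho0
the single-type equilibrium density (cells per domain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .params import ModelParams, ScenarioConfig
from .scenarios import Trajectory, run_schedule
from .state import CellTable, LatticeState
from .types import CellType, MixingClass, Winner


def count_crossed(lattice: LatticeState, cells: CellTable,
                  midline_x: float, com_based: bool = False) -> tuple[int, int]:
    """(Ñ_m, Ñ_nm): alive cells fully on the opposite side of the midline.

    Motile cells start on the left, non-motile on the right; a cell
    straddling the midline is not counted.  Dead cells are excluded.  With
    ``com_based`` the looser center-of-mass criterion is used instead
    (sensitivity variant).
    """
    n = cells.n_ids
    live = cells.present[:n] & cells.alive[:n] & (cells.area[:n] > 0)
    motile = live & (cells.ctype[:n] == int(CellType.MOTILE))
    nonmot = live & (cells.ctype[:n] == int(CellType.NON_MOTILE))
    if com_based:
        with np.errstate(invalid="ignore", divide="ignore"):
            cx = cells.sx[:n] / np.maximum(cells.area[:n], 1)
        right = cx > midline_x
        left = cx < midline_x
    else:
        minx, maxx = _kernels.minmax_x(lattice.grid, n)
        right = minx > midline_x
        left = maxx < midline_x
    return (int(np.count_nonzero(motile & right)),
            int(np.count_nonzero(nonmot & left)))


def classify_mixing(crossed_motile: np.ndarray | pd.Series,
                    n_motile: int) -> MixingClass:
    """Classify a mixing trajectory from its crossing-count series."""
    peak = int(np.max(crossed_motile)) if len(crossed_motile) else 0
    if peak >= n_motile / 2:
        return MixingClass.WELL_MIXED
    if peak == 0:
        return MixingClass.NONE
    return MixingClass.PARTIAL


def first_time_below(t: np.ndarray, series: np.ndarray,
                     threshold: float) -> float | None:
    """First time t* such that ``series`` stays strictly below ``threshold``
    from t* to the end of the record; None if it never settles."""
    t = np.asarray(t, dtype=float)
    series = np.asarray(series, dtype=float)
    below = series < threshold
    if not below.size or not below[-1]:
        return None
    above = np.nonzero(~below)[0]
    start = above[-1] + 1 if above.size else 0
    return float(t[start]) if start < t.size else None


def detect_polarity_loss(t: np.ndarray, mean_rho: np.ndarray, beta: float,
                         persist_mcs: float = 5000.0,
                         threshold_factor: float = 0.1) -> float | None:
    """First time t* after which mean |rho| stays below 0.1*beta for the
    rest of the run and for at least ``persist_mcs``; None if polarity
    persists (or only dips briefly)."""
    t = np.asarray(t, dtype=float)
    mean_rho = np.asarray(mean_rho, dtype=float)
    below = mean_rho < threshold_factor * beta
    if not below.size or not below[-1]:
        return None
    # last index where the series was at/above threshold
    above = np.nonzero(~below)[0]
    start = above[-1] + 1 if above.size else 0
    if start >= t.size:
        return None
    t_star = float(t[start])
    if t[-1] - t_star < persist_mcs:
        return None
    return t_star


def invasion_speed(t: np.ndarray, n_winner: np.ndarray, rho0: float,
                   domain_length: float = 1.0,
                   t_start: float | None = None,
                   occupancy_stop: float = 0.75,
                   n_total: np.ndarray | None = None) -> tuple[float, tuple]:
    """Front speed v = (dN/dt) * L / rho0 from the initial invasion stage.

    Fits a least-squares slope to the winner-type count between ``t_start``
    (default: the first sample) and the time the winner first holds
    ``occupancy_stop`` of all cells (needs ``n_total``), in
    domain-lengths/MCS.  Returns (v, (fit_t0, fit_t1)).
    """
    if not np.isfinite(rho0) or rho0 <= 0:
        raise ValueError("rho0 must be positive and finite (single-type density)")
    t = np.asarray(t, dtype=float)
    n_winner = np.asarray(n_winner, dtype=float)
    mask = np.ones_like(t, dtype=bool)
    if t_start is not None:
        mask &= t >= t_start
    if n_total is not None:
        frac = n_winner / np.maximum(np.asarray(n_total, dtype=float), 1.0)
        hit = np.nonzero(mask & (frac >= occupancy_stop))[0]
        if hit.size:
            mask &= t <= t[hit[0]]
    if mask.sum() < 2:
        raise ValueError("fit window holds fewer than 2 samples")
    slope = float(np.polyfit(t[mask], n_winner[mask], 1)[0])
    window = (float(t[mask][0]), float(t[mask][-1]))
    return slope * domain_length / rho0, window


def classify_outcome(frame: pd.DataFrame, barrier_removal_mcs: float,
                     coexist_band: tuple[float, float] = (0.05, 0.95)
                     ) -> Winner:
    """Winner of an invasion run from its count series.

    MOTILE/NON_MOTILE when the other type's alive count reaches zero;
    COEXIST when both types persist with occupancy fractions inside
    ``coexist_band`` throughout the final third of the run; UNDECIDED
    otherwise (run too short to call).
    """
    nm = frame["n_motile"].to_numpy(dtype=float)
    nn = frame["n_nonmotile"].to_numpy(dtype=float)
    t = frame["t"].to_numpy(dtype=float)
    after = t >= barrier_removal_mcs
    if np.any(after & (nn == 0)):
        return Winner.MOTILE
    if np.any(after & (nm == 0)):
        return Winner.NON_MOTILE
    final = t >= t[-1] - (t[-1] - barrier_removal_mcs) / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = nm / np.maximum(nm + nn, 1.0)
    lo, hi = coexist_band
    if np.all((frac[final] >= lo) & (frac[final] <= hi)):
        return Winner.COEXIST
    return Winner.UNDECIDED


@dataclass
class OutcomeReport:
    """Classification of one run."""

    experiment: str
    mixing_class: MixingClass | None = None
    polarity_lost: bool = False
    polarity_loss_time: float | None = None
    invasion_speed: float | None = None
    winner: Winner | None = None
    slope: float | None = None  #: dN/dt of the winner type, cells/MCS
    fit_window: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "mixing_class": self.mixing_class.value if self.mixing_class else None,
            "polarity_lost": self.polarity_lost,
            "polarity_loss_time": self.polarity_loss_time,
            "invasion_speed": self.invasion_speed,
            "winner": self.winner.value if self.winner else None,
            "slope": self.slope,
            "fit_window": list(self.fit_window) if self.fit_window else None,
        }


def report_mixing(traj: Trajectory, beta: float,
                  persist_mcs: float = 5000.0) -> OutcomeReport:
    df = traj.frame
    n_m = traj.n_initial.get("motile", int(df["n_motile"].iloc[0]))
    cls = classify_mixing(df["crossed_motile"].to_numpy(), n_m)
    after = df[df["t"] >= traj.barrier_removal_mcs]
    t_loss = detect_polarity_loss(after["t"].to_numpy(),
                                  after["mean_rho"].to_numpy(), beta,
                                  persist_mcs=persist_mcs)
    return OutcomeReport(experiment="mixing", mixing_class=cls,
                         polarity_lost=t_loss is not None,
                         polarity_loss_time=t_loss)


def report_invasion(traj: Trajectory, rho0: float | None = None) -> OutcomeReport:
    df = traj.frame
    winner = classify_outcome(df, traj.barrier_removal_mcs)
    rep = OutcomeReport(experiment="invasion", winner=winner)
    if winner in (Winner.MOTILE, Winner.NON_MOTILE):
        key = "n_motile" if winner == Winner.MOTILE else "n_nonmotile"
        after = df[df["t"] >= traj.barrier_removal_mcs]
        try:
            slope_v, window = invasion_speed(
                after["t"].to_numpy(), after[key].to_numpy(),
                rho0 if rho0 is not None else 1.0,
                t_start=traj.barrier_removal_mcs,
                n_total=(after["n_motile"] + after["n_nonmotile"]).to_numpy())
            rep.fit_window = window
            dt = window[1] - window[0]
            rep.slope = slope_v * (rho0 if rho0 is not None else 1.0) if dt > 0 else None
            rep.invasion_speed = slope_v if rho0 is not None else None
        except ValueError:
            pass
    return rep


def sweep_phase_diagram(base_config: ScenarioConfig, base_params: ModelParams,
                        grid: dict[str, list], replicates: int = 3,
                        seed: int = 0,
                        classify=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a grid of configurations with replicate seeds.

    ``grid`` maps dotted parameter paths (e.g. ``"motility.f_max"``,
    ``"lam_cont_motile"``, ``"scenario.schedule.total_mcs"``; paths without
    the ``scenario.`` prefix address ModelParams) to value lists.  Returns
    (runs, summary): one row per run with all swept values and the outcome,
    and a per-point majority vote with a unanimity flag.  Individual run
    failures are recorded per row, not fatal.
    """
    import copy
    import itertools

    names = list(grid)
    rows = []
    ss = np.random.SeedSequence(seed)
    points = list(itertools.product(*(grid[n] for n in names)))
    child_seeds = ss.spawn(len(points) * replicates)
    k = 0
    for values in points:
        for rep in range(replicates):
            cfg = copy.deepcopy(base_config)
            par = copy.deepcopy(base_params)
            for name, value in zip(names, values):
                _set_path(cfg, par, name, value)
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            row = {name: value for name, value in zip(names, values)}
            row["replicate"] = rep
            try:
                traj, sim = run_schedule(cfg, par, rng=rng)
                if classify is not None:
                    rep_out = classify(traj, sim)
                elif cfg.experiment.value == "invasion":
                    rep_out = report_invasion(traj)
                else:
                    rep_out = report_mixing(traj, par.motility.beta)
                row["outcome"] = (rep_out.winner.value if rep_out.winner
                                  else rep_out.mixing_class.value)
                row["polarity_lost"] = rep_out.polarity_lost
                row["error"] = None
            except Exception as exc:  # recorded, not fatal
                row["outcome"] = None
                row["error"] = repr(exc)
            rows.append(row)
    runs = pd.DataFrame(rows)
    grouped = runs.groupby(names, dropna=False)["outcome"]
    summary = grouped.agg(
        majority=lambda s: s.mode().iloc[0] if s.notna().any() else None,
        unanimous=lambda s: s.nunique(dropna=True) == 1,
        n_runs="size").reset_index()
    return runs, summary


def _set_path(cfg: ScenarioConfig, par: ModelParams, path: str, value) -> None:
    if path.startswith("scenario."):
        obj, parts = cfg, path.split(".")[1:]
    else:
        obj, parts = par, path.split(".")
    for p in parts[:-1]:
        obj = getattr(obj, p)
    if not hasattr(obj, parts[-1]):
        raise AttributeError(f"unknown parameter path: {path}")
    setattr(obj, parts[-1], value)
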