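"""Polarization feedback and the Hill-saturated motile force.

Each motile cell carries a polarization vector rho obeying

    d rho / dt = zeta * v - gamma * rho

where v is the center-of-mass velocity (displacement over the last ``dt``
MCS, no smoothing).  Movement reinforces polarization; an immobilized cell
depolarizes at rate gamma.  The motile force is a Hill function of |rho|,

    F = f_max * (rho/|rho|) * |rho|^mu / (|rho|^mu + beta^mu),

so |rho| = beta yields exactly half the maximal force and rho = 0 yields
zero force (the singular direction resolves to the zero vector).  The
force enters copy attempts as the work term ``work_sign * F . dr_com``
(default ``work_sign = -1``: displacement of the center of mass along F
lowers the energy, i.e. motion along F is favored).
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, MotilityParams
from .types import CellType


def update_polarization(rho: np.ndarray, v: np.ndarray,
                        params: MotilityParams) -> np.ndarray:
    """One forward-Euler step: rho' = rho + dt * (zeta*v - gamma*rho)."""
    rho = np.asarray(rho, dtype=float)
    v = np.asarray(v, dtype=float)
    return rho + params.dt * (params.zeta * v - params.gamma * rho)


def motile_force(rho: np.ndarray, params: MotilityParams) -> np.ndarray:
    """Hill-saturated motile force along rho; zero vector at rho = 0."""
    rho = np.asarray(rho, dtype=float)
    mag = float(np.hypot(rho[0], rho[1]))
    if mag == 0.0:
        return np.zeros(2)
    hill = mag ** params.mu / (mag ** params.mu + params.beta ** params.mu)
    return params.f_max * (rho / mag) * hill


def motile_work_delta(forces: list[np.ndarray], displacements: list[np.ndarray],
                      params: MotilityParams) -> float:
    """Work term of a candidate copy: sum of work_sign * F . dr_com over the
    (at most two) motile, alive cells whose center of mass would move."""
    total = 0.0
    for f, dr in zip(forces, displacements):
        total += params.work_sign * float(np.dot(f, dr))
    return total


def end_of_sweep_update(cells, params: ModelParams, polarize: bool = True) -> None:
    """Per-MCS polarization/force update for every cell (vectorized).

    Estimates each cell's velocity from its center-of-mass displacement
    since the previous update, advances rho for motile alive cells, zeroes
    rho and F for dead and wall cells, refreshes the cached force vectors
    and stores the current com for the next estimate.  With ``polarize``
    false (motility-off initialization phase) only the com bookkeeping
    runs and polarizations stay at zero.
    """
    n = cells.n_ids
    if n == 0:
        return
    mp = params.motility
    area = cells.area[:n]
    has_pixels = area > 0
    safe = np.maximum(area, 1)
    cx = np.where(has_pixels, cells.sx[:n] / safe, cells.prev_cx[:n])
    cy = np.where(has_pixels, cells.sy[:n] / safe, cells.prev_cy[:n])

    motile = (cells.ctype[:n] == int(CellType.MOTILE)) & cells.alive[:n] \
        & cells.present[:n] & has_pixels
    if polarize:
        vx = (cx - cells.prev_cx[:n]) / mp.dt
        vy = (cy - cells.prev_cy[:n]) / mp.dt
        rx = cells.rx[:n]
        ry = cells.ry[:n]
        rx[motile] += mp.dt * (mp.zeta * vx[motile] - mp.gamma * rx[motile])
        ry[motile] += mp.dt * (mp.zeta * vy[motile] - mp.gamma * ry[motile])
    cells.rx[:n][~motile] = 0.0
    cells.ry[:n][~motile] = 0.0

    mag = np.hypot(cells.rx[:n], cells.ry[:n])
    with np.errstate(invalid="ignore", divide="ignore"):
        hill = np.where(mag > 0.0,
                        mag ** mp.mu / (mag ** mp.mu + mp.beta ** mp.mu), 0.0)
        scale = np.where(mag > 0.0, mp.f_max * hill / np.maximum(mag, 1e-300), 0.0)
    cells.fx[:n] = np.where(motile, scale * cells.rx[:n], 0.0)
    cells.fy[:n] = np.where(motile, scale * cells.ry[:n], 0.0)

    cells.prev_cx[:n] = cx
    cells.prev_cy[:n] = cy
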