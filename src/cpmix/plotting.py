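"""Optional matplotlib rendering of lattice snapshots and trajectories.

Matplotlib is imported lazily; install the ``plots`` extra to use this
module.  Snapshots color non-motile cells blue, dead cells red, the wall
black, and motile cells by their polarization magnitude (the style used
for monolayer snapshots with a polarity color scale).
"""

from __future__ import annotations

import numpy as np

from .state import CellTable, LatticeState
from .types import CellType


def lattice_image(lattice: LatticeState, cells: CellTable,
                  rho_scale: float = 3.0) -> np.ndarray:
    """RGB array of the current lattice state."""
    n = cells.n_ids
    grid = lattice.grid
    rho = np.hypot(cells.rx[:n], cells.ry[:n])
    rgb = np.zeros((n, 3))
    for cid in range(n):
        t = cells.ctype[cid]
        if t == int(CellType.WALL):
            rgb[cid] = (0.05, 0.05, 0.05)
        elif not cells.alive[cid]:
            rgb[cid] = (0.75, 0.1, 0.1)
        elif t == int(CellType.NON_MOTILE):
            rgb[cid] = (0.15, 0.25, 0.7)
        else:  # motile: dark green -> bright green with |rho|
            s = min(rho[cid] / rho_scale, 1.0)
            rgb[cid] = (0.2 + 0.5 * s, 0.55 + 0.45 * s, 0.25)
    img = rgb[grid]
    # darken cell boundaries
    edge = np.zeros_like(grid, dtype=bool)
    edge[:, 1:] |= grid[:, 1:] != grid[:, :-1]
    edge[1:, :] |= grid[1:, :] != grid[:-1, :]
    img[edge] *= 0.45
    return img


def plot_lattice(lattice: LatticeState, cells: CellTable, ax=None,
                 title: str | None = None, rho_scale: float = 3.0):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.imshow(lattice_image(lattice, cells, rho_scale), origin="upper",
              interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    return ax


def plot_counts(trajectory, ax=None):
    """Cell numbers of both types versus time, with the barrier-removal
    time marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = trajectory.frame
    ax.plot(df["t"], df["n_motile"], color="tab:green", label="motile")
    ax.plot(df["t"], df["n_nonmotile"], color="tab:blue", label="non-motile")
    ax.axvline(trajectory.barrier_removal_mcs, color="0.6", ls="--",
               label="barrier removed")
    ax.set_xlabel("time (MCS)")
    ax.set_ylabel("alive cells")
    ax.legend()
    return ax
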