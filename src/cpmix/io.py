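"""Configuration files, lattice snapshots and run manifests.

Config files are TOML with ``[scenario]``, ``[params]``,
``[params.motility]`` and ``[params.turnover]`` tables; unknown keys are
rejected by name and invariant violations by the invariant.  Snapshots are
a TSV integer matrix of cell ids (one line per lattice row) plus a JSON
sidecar holding per-cell metadata (type, alive, polarization, target area,
frozen flag); a round trip is lossless, with caches rebuilt and audited on
read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .params import (ModelParams, ScenarioConfig, _update_dataclass)
from .state import CellTable, LatticeState, rebuild_caches
from .types import CellType, ConfigError, SnapshotError


def load_config(path=None, *, scenario_overrides: dict | None = None,
                params_overrides: dict | None = None
                ) -> tuple[ScenarioConfig, ModelParams]:
    """Resolve (ScenarioConfig, ModelParams) from a TOML file and overrides.

    With no file and no overrides this returns the package defaults (the
    standard parameter table of the model).  Override dicts use the same
    nesting as the file and win over file values.
    """
    data = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    unknown = [k for k in data if k not in ("scenario", "params")]
    if unknown:
        raise ConfigError(f"unknown top-level sections: {', '.join(sorted(unknown))}")
    config = ScenarioConfig()
    params = ModelParams()
    _update_dataclass(config, data.get("scenario", {}), "scenario")
    _update_dataclass(params, data.get("params", {}), "params")
    if scenario_overrides:
        _update_dataclass(config, scenario_overrides, "scenario")
    if params_overrides:
        _update_dataclass(params, params_overrides, "params")
    config.validate()
    params.validate()
    return config, params


def write_snapshot(lattice: LatticeState, cells: CellTable, path) -> None:
    """Write grid TSV plus ``<path>.meta.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, lattice.grid, fmt="%d", delimiter="\t")
    meta = {
        "shape": list(lattice.grid.shape),
        "n_ids": int(cells.n_ids),
        "cells": {},
    }
    for cid in range(cells.n_ids):
        if not cells.present[cid]:
            continue
        meta["cells"][str(cid)] = {
            "type": CellType(int(cells.ctype[cid])).name,
            "alive": bool(cells.alive[cid]),
            "rho": [float(cells.rx[cid]), float(cells.ry[cid])],
            "prev_com": [float(cells.prev_cx[cid]), float(cells.prev_cy[cid])],
            "a0": float(cells.a0[cid]),
            "lam_area": float(cells.lam_area[cid]),
            "lam_cont": float(cells.lam_cont[cid]),
            "adh": float(cells.adh[cid]),
            "frozen": bool(np.all(lattice.frozen[lattice.grid == cid]))
            if np.any(lattice.grid == cid) else False,
        }
    sidecar(path).write_text(json.dumps(meta, indent=1))


def sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


def read_snapshot(path, params: ModelParams
                  ) -> tuple[LatticeState, CellTable]:
    """Read a snapshot pair back; rebuilds and audits cached geometry."""
    path = Path(path)
    try:
        grid = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise SnapshotError(f"cannot parse grid TSV {path}: {exc}") from exc
    try:
        meta = json.loads(sidecar(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SnapshotError(f"cannot read sidecar for {path}: {exc}") from exc
    if list(grid.shape) != meta["shape"]:
        raise SnapshotError(
            f"dimension mismatch: grid is {list(grid.shape)}, sidecar says {meta['shape']}")
    known = {int(k) for k in meta["cells"]}
    on_grid = {int(v) for v in np.unique(grid)}
    missing = sorted(on_grid - known)
    if missing:
        raise SnapshotError(f"grid ids absent from sidecar: {missing}")
    n_ids = int(meta["n_ids"])
    cells = CellTable(capacity=max(n_ids, 1))
    cells.n_ids = n_ids
    cells.present[:n_ids] = False
    frozen = np.zeros_like(grid, dtype=bool)
    for key, info in meta["cells"].items():
        cid = int(key)
        if cid >= n_ids:
            raise SnapshotError(f"cell id {cid} >= n_ids {n_ids}")
        cells.present[cid] = True
        cells.ctype[cid] = int(CellType[info["type"]])
        cells.alive[cid] = info["alive"]
        cells.rx[cid], cells.ry[cid] = info["rho"]
        cells.a0[cid] = info["a0"]
        cells.lam_area[cid] = info["lam_area"]
        cells.lam_cont[cid] = info["lam_cont"]
        cells.adh[cid] = info["adh"]
        if info["frozen"]:
            frozen[grid == cid] = True
    lattice = LatticeState(grid.astype(np.int32), frozen)
    rebuild_caches(lattice, cells, params.bond_neighborhood)
    for key, info in meta["cells"].items():
        cells.prev_cx[int(key)], cells.prev_cy[int(key)] = info["prev_com"]
    return lattice, cells


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly: resolved config,
    seed, code version, phase boundaries and output checksums."""

    seed: int
    config: dict
    params: dict
    version: str = __version__
    phase_boundaries: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    @classmethod
    def from_run(cls, config: ScenarioConfig, params: ModelParams,
                 phase_boundaries: dict | None = None) -> "RunManifest":
        cfg = dataclasses.asdict(config)
        cfg["experiment"] = config.experiment.value
        return cls(seed=config.seed, config=cfg,
                   params=dataclasses.asdict(params),
                   phase_boundaries=phase_boundaries or {})

    def add_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))
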