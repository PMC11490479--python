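"""Model and scenario parameters.

Defaults reproduce the headline parameter set of the model: an epithelial
monolayer on a 302x150-pixel domain, 225 motile + 225 non-motile cells of
target area A0 = 100 pixels, area stiffness lambda_area = 70, cortex
contractility lambda_cont = 0.5 (soft regime; 7 in the hard regime),
cell-cell contact energy phi = -10 (zero against the wall), Metropolis
temperature T = 50, and polarization feedback with gain zeta = 1,
depolarization rate gamma = 0.1/MCS, Hill half-saturation beta = 1 and
Hill coefficient mu = 10.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .types import CellType, ConfigError, Experiment


@dataclass
class MotilityParams:
    """Polarization dynamics and Hill-saturated motile force.

    The polarization vector of each motile cell follows
    ``d rho/dt = zeta*v - gamma*rho`` (forward Euler, step ``dt`` in MCS),
    where ``v`` is the center-of-mass velocity over the last ``dt`` MCS.
    The motile force magnitude is ``f_max * |rho|^mu / (|rho|^mu + beta^mu)``
    directed along rho.
    """

    f_max: float = 1000.0
    beta: float = 1.0
    mu: float = 10.0
    zeta: float = 1.0
    gamma: float = 0.1
    dt: float = 1.0
    #: -1 means a copy displacing the cell along F lowers the energy
    #: (motion along F favored); +1 flips the sign for sensitivity checks.
    work_sign: int = -1
    #: "pixel": the work of a copy is F . s with s the unit source->target
    #: step (the convention CPM motility plugins apply per copy attempt);
    #: "com": F . dr_com with dr_com the center-of-mass displacement the
    #: copy causes (the literal reading of the F . r energy term).
    work_mode: str = "pixel"

    def validate(self) -> None:
        if not self.beta > 0:
            raise ConfigError("motility invariant violated: beta > 0")
        if self.gamma < 0:
            raise ConfigError("motility invariant violated: gamma >= 0")
        if not self.dt > 0:
            raise ConfigError("motility invariant violated: dt > 0")
        if self.work_sign not in (-1, 1):
            raise ConfigError("motility invariant violated: work_sign in {-1, 1}")
        if self.work_mode not in ("pixel", "com"):
            raise ConfigError("motility invariant violated: work_mode in {pixel, com}")


@dataclass
class TurnoverParams:
    """Stochastic division/death rates and dead-cell mechanics.

    ``birth_*`` is the per-cell per-MCS division probability, applied only
    when the cell area has reached its target area; ``death_*`` the per-cell
    per-MCS death probability, independent of size.  Dying cells get
    phi = 0, lambda_cont = 0, A0 = 0 and lambda_area = ``dead_lam_area`` so
    they shrink and are extruded once their area reaches
    ``extrusion_area_threshold``.
    """

    birth_motile: float = 0.0
    birth_nonmotile: float = 0.0
    death_motile: float = 0.0
    death_nonmotile: float = 0.0
    dead_lam_area: float = 500.0
    extrusion_area_threshold: int = 0

    def birth(self, ctype: CellType) -> float:
        return self.birth_motile if ctype == CellType.MOTILE else self.birth_nonmotile

    def death(self, ctype: CellType) -> float:
        return self.death_motile if ctype == CellType.MOTILE else self.death_nonmotile

    def validate(self) -> None:
        for name in ("birth_motile", "birth_nonmotile", "death_motile", "death_nonmotile"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"turnover invariant violated: {name} in [0, 1]")
        if not self.dead_lam_area > 0:
            raise ConfigError("turnover invariant violated: dead_lam_area > 0")
        if self.extrusion_area_threshold < 0:
            raise ConfigError("turnover invariant violated: extrusion_area_threshold >= 0")


@dataclass
class ModelParams:
    """All energy-function coefficients plus temperature and sub-parameters.

    The energy is ``E = lam_area*sum (A-A0)^2 + lam_cont*sum L^2 +
    sum_bonds phi + motile work``, with the perimeter L counted as
    4-neighbor bonds to pixels of any other cell (wall and domain edge
    included) and each unordered bond counted once.
    """

    lam_area: float = 70.0
    lam_cont_motile: float = 0.5
    lam_cont_nonmotile: float = 0.5
    phi_cell_cell: float = -10.0
    phi_cell_wall: float = 0.0
    temperature: float = 50.0
    motility: MotilityParams = field(default_factory=MotilityParams)
    turnover: TurnoverParams = field(default_factory=TurnoverParams)
    #: neighborhood for adhesion/perimeter bonds (4 = von Neumann)
    bond_neighborhood: int = 4
    #: neighborhood for copy-source candidates (8 = Moore)
    copy_neighborhood: int = 8

    def lam_cont(self, ctype: CellType) -> float:
        if ctype == CellType.WALL:
            return 0.0
        return self.lam_cont_motile if ctype == CellType.MOTILE else self.lam_cont_nonmotile

    def contact_energy(self, t1: CellType, t2: CellType) -> float:
        """Symmetric contact energy phi(type_i, type_j) for a heterotypic bond."""
        if t1 == CellType.WALL or t2 == CellType.WALL:
            return self.phi_cell_wall
        return self.phi_cell_cell

    def phi_matrix(self) -> np.ndarray:
        """3x3 contact-energy lookup indexed by CellType codes."""
        m = np.zeros((3, 3), dtype=np.float64)
        for t1 in CellType:
            for t2 in CellType:
                m[t1, t2] = self.contact_energy(t1, t2)
        return m

    def validate(self) -> None:
        if not self.temperature > 0:
            raise ConfigError("params invariant violated: T > 0")
        if self.bond_neighborhood not in (4, 8):
            raise ConfigError("params invariant violated: bond_neighborhood in {4, 8}")
        if self.copy_neighborhood not in (4, 8):
            raise ConfigError("params invariant violated: copy_neighborhood in {4, 8}")
        self.motility.validate()
        self.turnover.validate()


@dataclass
class ScheduleConfig:
    """Phase durations in MCS.

    Phase 1 (0..relax_mcs): motility off, no turnover — cells relax to
    equilibrium shapes.  Phase 2 (..barrier removal): motility on behind the
    barrier; turnover also on in invasion runs so each side reaches its
    equilibrium density.  Phase 3: the barrier is removed instantaneously.
    Phase 4 (..total_mcs): the main run.
    """

    relax_mcs: int = 400
    polarize_mcs: int = 1600
    total_mcs: int = 25000
    sample_every: int = 50

    @property
    def barrier_removal_mcs(self) -> int:
        return self.relax_mcs + self.polarize_mcs

    def validate(self) -> None:
        if min(self.relax_mcs, self.polarize_mcs) < 0 or self.sample_every <= 0:
            raise ConfigError("schedule invariant violated: nonnegative phases, sample_every > 0")
        if self.total_mcs < self.barrier_removal_mcs:
            raise ConfigError("schedule invariant violated: total_mcs >= barrier removal time")


@dataclass
class ScenarioConfig:
    """Geometry and schedule of a two-population experiment.

    ``width``/``height`` are the cell interior in pixels; the frozen wall
    frame is added outside, and a ``barrier_width``-pixel frozen column
    straddles the midline until removal.
    """

    width: int = 302
    height: int = 150
    n_per_type: int = 225
    a0: float = 100.0
    barrier_width: int = 2
    wall_thickness: int = 1
    experiment: Experiment = Experiment.MIXING
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    seed: int = 0

    @property
    def half_width(self) -> int:
        return (self.width - self.barrier_width) // 2

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("scenario invariant violated: positive domain")
        if self.barrier_width < 0 or (self.width - self.barrier_width) % 2:
            raise ConfigError(
                "scenario invariant violated: barrier straddles the midline "
                "(width - barrier_width must be even)"
            )
        if self.n_per_type * self.a0 > self.half_width * self.height:
            raise ConfigError(
                "scenario invariant violated: n_per_type * A0 <= interior half area"
            )
        if self.wall_thickness < 1:
            raise ConfigError("scenario invariant violated: wall_thickness >= 1")
        self.schedule.validate()


def _update_dataclass(obj, data: dict, path: str) -> None:
    names = {f.name: f for f in dataclasses.fields(obj)}
    unknown = [k for k in data if k not in names]
    if unknown:
        raise ConfigError(f"unknown keys under [{path}]: {', '.join(sorted(unknown))}")
    for key, value in data.items():
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and not isinstance(current, type):
            if not isinstance(value, dict):
                raise ConfigError(f"{path}.{key} must be a table")
            _update_dataclass(current, value, f"{path}.{key}")
        elif key == "experiment":
            setattr(obj, key, Experiment(value))
        else:
            setattr(obj, key, value)
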