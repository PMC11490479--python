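"""Initialization phase: cells relax from square seeds to equilibrium shapes.

Builds the standard two-population domain at reduced size, runs the
motility-off relaxation phase, and prints how the mean perimeter grows
(soft cells develop protrusions; adhesion phi=-10 rewards boundary) while
areas stay pinned at the target by the stiff area term.
"""

import numpy as np

from cpmix import ModelParams, ScenarioConfig, ScheduleConfig, total_energy
from cpmix.scenarios import build_simulation
from cpmix.types import Experiment

config = ScenarioConfig(
    width=152, height=76, n_per_type=56, a0=100,
    experiment=Experiment.MIXING, seed=0,
    schedule=ScheduleConfig(relax_mcs=400, polarize_mcs=0,
                            total_mcs=400, sample_every=50))
params = ModelParams()
sim, meta = build_simulation(config, params, np.random.default_rng(config.seed))

nonwall = sim.cells.ids(wall=False)
print(f"{len(nonwall)} cells on a {config.width}x{config.height} interior, "
      f"A0={config.a0:g} px, soft regime (lam_cont=0.5), T=50")
print(f"{'t (MCS)':>8} {'mean L':>8} {'mean |A-A0|/A0':>15} {'energy':>12}")
for t in range(0, 401, 50):
    if t:
        sim.step(50)
    dev = np.abs(sim.cells.area[nonwall] - config.a0).mean() / config.a0
    mean_l = sim.cells.perim[nonwall].mean()
    e = total_energy(sim.lattice, sim.cells, params)
    print(f"{sim.time:8d} {mean_l:8.1f} {dev:15.4f} {e:12.0f}")

print("\nThe perimeter climbs from the square-seed value (~40 bonds) to its")
print("equilibrium plateau within ~100 MCS while the area deviation stays")
print("at the percent level: shape, not size, is what relaxes during the")
print("motility-off phase.")
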