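"""Competitive invasion with turnover: motility alone decides the winner
when both types share identical birth/death rates.

Runs the scaled-down invasion experiment (B=0.1, M=0.001 for both types),
prints the population curves, the winner, and the invasion front speed
v = (dN/dt) * L / rho0 with rho0 the single-type equilibrium density.
Takes about half a minute.
"""

from cpmix import (CellType, ModelParams, ScenarioConfig, ScheduleConfig,
                   report_invasion, run_schedule, run_single_type)
from cpmix.types import Experiment

config = ScenarioConfig(
    width=152, height=76, n_per_type=56, a0=100,
    experiment=Experiment.INVASION, seed=0,
    schedule=ScheduleConfig(relax_mcs=400, polarize_mcs=1600,
                            total_mcs=40000, sample_every=100))
params = ModelParams()
params.motility.f_max = 1000.0
params.turnover.birth_motile = params.turnover.birth_nonmotile = 0.1
params.turnover.death_motile = params.turnover.death_nonmotile = 0.001

# equilibrium density of the invader filling the whole domain alone
density_cfg = ScenarioConfig(
    width=config.width, height=config.height, n_per_type=config.n_per_type,
    a0=config.a0, experiment=Experiment.INVASION, seed=1,
    schedule=ScheduleConfig(relax_mcs=400, polarize_mcs=0,
                            total_mcs=8000, sample_every=100))
rho0 = run_single_type(density_cfg, params, CellType.MOTILE).rho0
print(f"single-type equilibrium density rho0 = {rho0:.1f} cells/domain")

traj, sim = run_schedule(config, params)
df = traj.frame
print(f"\n{'t (MCS)':>8} {'N_motile':>9} {'N_non-motile':>13} {'dead frac':>10}")
for _, row in df[df["t"] % 1000 == 0].iterrows():
    if row.t % 2000 == 0:
        print(f"{row.t:8.0f} {row.n_motile:9.0f} {row.n_nonmotile:13.0f} "
              f"{row.dead_fraction:10.3f}")

report = report_invasion(traj, rho0=rho0)
print(f"\nwinner: {report.winner.value}")
if report.invasion_speed is not None:
    print(f"fitted slope dN/dt = {report.slope:.4f} cells/MCS over "
          f"t in {report.fit_window}")
    print(f"invasion speed v = dN/dt * L / rho0 = {report.invasion_speed:.2e} "
          f"domain-lengths/MCS")
print("\nThe motile front advances until the non-motile population is")
print("eliminated; the dead fraction stays at the ~1% level because dead")
print("cells (lam_area=500, A0=0) are extruded within tens of MCS.")
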