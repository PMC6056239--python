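#!/usr/bin/env python
"""Langevin NVT dynamics of the CG complex (310 K, 1000 fs damping):
assign per-site charges/sigmas/masses, integrate, and track the kinetic
temperature and the radial shift of the FHL center of mass relative to the
filament axis (positive = toward the axis = toward the incoming-subunit
site, the closed-state direction)."""

from pathlib import Path

import numpy as np

from formincg import analysis, dynamics, edcg, enm, forcefield, pipeline
from formincg.constants import KCAL_PER_MOL_IN_MD_UNITS as MDU

OUT = Path("results/cg_dynamics")
OUT.mkdir(parents=True, exist_ok=True)

structure = pipeline.build_demo_complex()
traj = pipeline.reference_trajectory(structure, n_frames=400, seed=1)
mapping = pipeline.coarse_grain(structure, traj, sites_per_chain=5)
cg_traj = edcg.map_trajectory(traj, mapping, structure=structure)
ref = cg_traj.frames.mean(axis=0)

net = enm.build_network(ref, 40.0)
target = enm.trajectory_fluctuations(cg_traj, net, 310.0)
net, _ = enm.fit_fluctuations(net, target, max_iter=200, tol=0.05)
ff = forcefield.assign_site_params(structure, mapping)

bound = 0.1 * 2 * np.pi * np.sqrt(ff.mass.min() / (net.k.max() * MDU))
ts = min(10.0, 0.25 * bound)
system = dynamics.CGSystem(positions=ref.copy(), masses=ff.mass,
                           network=net, forcefield=ff)
params = dynamics.SimParams(temperature=310.0, damping_fs=1000.0,
                            timestep_fs=ts, n_steps=50000, seed=2, stride=100)
run, series = dynamics.run_langevin(system, params)

site_chain = np.array([seg[0] for seg in sorted(mapping.segments,
                                                key=lambda s: s[3])])
fhl_sites = np.flatnonzero(site_chain == structure.chain_of("FHL"))
point, axis = analysis.filament_axis(structure)
from formincg.structure import AtomGroup, AtomicStructure
shift = []
for f in range(run.n_frames):
    coms = ff.mass[fhl_sites] @ run.frames[f][fhl_sites] / ff.mass[fhl_sites].sum()
    rel = coms - point
    r = np.linalg.norm(rel - (rel @ axis) * axis)
    shift.append(r)
shift = np.asarray(shift)
pct = 100.0 * (shift[0] - shift) / shift[0]
np.savetxt(OUT / "fhl_radial_shift.tsv",
           np.column_stack([run.times_ns, pct]),
           header="time_ns radial_shift_pct", fmt="%.5f")

print(f"timestep {ts:.2f} fs ({params.n_steps} steps, "
      f"{params.n_steps * ts / 1e6:.2f} ns nominal CG time)")
print(f"mean kinetic temperature: {series['T_kin'][5:].mean():.1f} K (target 310)")
print(f"FHL COM radial shift: start {shift[0]:.1f} A, "
      f"final {shift[-1]:.1f} A ({pct[-1]:+.1f}%)")
print("the synthetic FHL fluctuates about its initial radius; sustained "
      "positive shifts in the production systems signal steric closing")
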