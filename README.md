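# formincg

Coarse-grained modeling and barbed-end analysis of formin FH2 dimers on
actin filaments.

## The problem

Formins nucleate unbranched actin filaments and stay processively bound to
the fast-growing (barbed) end through a head-to-tail dimer of FH2 domains
(a leading chain, FHL, and a trailing chain, FHT, encircling the end).
Bound FH2 dimers slow elongation by "gating": the fraction of time the end
can accept a new subunit ranges from ~0.95 (mDia1) through 0.5–0.7 (Bni1)
down to ~0.05 (Cdc12).  Two physical mechanisms drive gating: the FH2
chains sterically occlude the incoming subunit's binding site, and they
flatten the helical twist of the terminal subunits away from the ~167°
per-subunit twist of a free filament (toward the 180° of the co-crystal
state), misaligning the binding site.

This package implements the computational machinery used to study those
mechanisms on desk-scale synthetic systems:

- **structure I/O** — fixed-column PDB read/write, role-labeled selections
  (`A1`…`A7` from the barbed end, `FHL`, `FHT`), trajectories, series
  tables (`formincg.structure`, `formincg.pdbio`, `formincg.tables`);
- **synthetic data** — ideal and end-flattened helical filaments,
  Gaussian elastic-network trajectories with known parameters, toy charged
  complexes, twist-series generators (`formincg.synth`);
- **ED-CG** — essential-dynamics coarse-graining: contiguous residue
  segments per chain minimizing the residual
  χ² = (1/3N) Σ_I (1/n_I) Σ_{i<j∈I} ⟨|d_i^ED − d_j^ED|²⟩
  over the retained principal-component subspace, solved exactly by
  dynamic programming (`formincg.edcg`);
- **heteroENM** — harmonic springs between CG sites within a cutoff, each
  k_ij fitted by damped multiplicative fluctuation matching against target
  ⟨δd_ij²⟩, with the analytic route C = k_B T H⁺ (`formincg.enm`);
- **CG force field** — intermolecular U = U_LJ + U_Coulomb with the
  repulsive 12–6 branch cut at σ_ij (ε = 10 kcal/mol, σ_i = site radius of
  gyration) and a screened Coulomb term
  U_C = k_e q_i q_j exp(−r/λ_D)/(ε_r r) with λ_D = 8 Å, a 30 Å cutoff and
  interface dielectric ε_r ∈ {1, 3} (`formincg.forcefield`);
- **dynamics** — BAOAB Langevin NVT at 310 K with 1000 fs damping, plus
  well-tempered metabasin metadynamics (hills of 0.001 kcal/mol and 0.3 Å
  every 50 fs, bias factor 10, 6 kcal/mol domain offset) and free-energy
  reconstruction F(s) = −(γ/(γ−1)) V(s) (`formincg.dynamics`);
- **gating observables** — helical twist (rotation angle of the
  inter-subunit superposition), steric overlap fractions (Cα pairs < 4 Å),
  contacts (Cα ≤ 12 Å), salt-bridge occupancies (N–O ≤ 4 Å), buried
  surface area, RMSD/RMSF, COM radial shifts, and ideal-geometry placement
  of the incoming subunit (`formincg.analysis`).

Two published salt-bridge occupancy tables (FH2 knob/barbed-end-groove and
lasso/linker bridges for Cdc12, Bni1 and mDia1) ship with the package and
feed the bridge-counting analyses.

## Worked example

Count the published knob/barbed-end-groove salt bridges and measure a
filament twist:

```python
from formincg import analysis, synth, tables

table = tables.load_salt_bridge_table("knob_groove_salt_bridges")
for formin in ("Cdc12", "Bni1", "mDia1"):
    n = tables.count_bridges(table, formin, "occupancy_C_5mer_350ns")
    print(formin, n)

fil = synth.build_ideal_filament(synth.make_bent_rod_template(20), 7,
                                 synth.HelixGeometry(twist_deg=167.0))
a1 = fil.select(role="A1", atoms="calpha").coords
a2 = fil.select(role="A2", atoms="calpha").coords
print(round(analysis.twist_angle(a1, a2), 3))
```

prints

```
Cdc12 9
Bni1 2
mDia1 1
167.0
```

— Cdc12, the tightest gater, anchors nine salt bridges between its knob
helices and the barbed-end grooves where mDia1 keeps one, and the
construction/measurement closure returns the built 167° twist exactly.

The numbered drivers under `analysis/` run the full study on synthetic
structures (build → reference fluctuations → ED-CG → heteroENM → Langevin
→ metadynamics → observables), each printing what it found and writing its
tables under `results/`:

```sh
python analysis/01_build_structures.py
python analysis/02_reference_fluctuations.py
...
python analysis/07_gating_observables.py
```

A `formincg` console script exposes the same stages as subcommands
(`synth`, `cgmap`, `enmfit`, `ffbuild`, `cgsim`, `metad`, `analyze`,
`run`).

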