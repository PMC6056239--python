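# Methods

Units repo-wide: lengths in Å, energies in kcal/mol, masses in amu, charges
in e, temperatures in K; integration time in fs, trajectory timestamps in
ps.  k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, k_e = 332.0636 kcal Å mol⁻¹ e⁻².

## Filament geometry and the twist observable

A filament is generated by a screw operator: subunit i+1 is subunit i
rotated by the inter-subunit twist about the filament axis (left-handed by
default) and translated by the rise.  The rise is set to 27.6 Å per
subunit — the standard actin value, configurable — and twist is reported
as a magnitude in (0°, 180°], matching the field's 167°/180° convention
(zero is admitted only as a degenerate untwisted stack).

The measured twist between two subunits is the **total rotation angle of
the least-squares (Kabsch) superposition** carrying one set of Cα atoms
onto the other, θ = arccos((tr R − 1)/2), evaluated through the quaternion
magnitude, which stays well-conditioned where arccos loses precision near
180°.  The decomposition into axial twist versus tilt is deliberately not
separated; for ideal helices the two coincide, and the
construction/measurement closure (build at t, measure t to 1e-6°) is
enforced by test for t ∈ (0°, 180°].  If a consumer needs an
axis-projected angle the screw-axis estimator below provides the axis.

The **filament axis** is estimated from the screw transforms between
consecutive interior subunits (A3…A6 by default; mobile end subunits
excluded): the rotation axis of each inter-subunit superposition *is* the
helix axis; axes are averaged and an axis point solved from
(I − R) p = t⊥.  This is exact on ideal geometry, unlike a principal-axis
fit of the Cα cloud, which is biased by the near-180° zigzag of the
subunit centroids (~1% axis error on a 167° seven-mer).

**Incoming-subunit placement**: the screw transform with the configured
(ideal) twist and rise about the fitted axis, signed so it carries A3 onto
A2, applied to A2 — i.e. one ideal step past the barbed end.  Removing the
terminal subunit of an (n+1)-mer and placing the incoming subunit on the
remainder regenerates the removed subunit to < 1e-6 Å RMSD (tested).

## ED-CG

Essential modes are the eigenvectors of the 3N×3N covariance of a Cα
trajectory after iterative least-squares superposition onto its mean
(three passes).  The essential subspace defaults to the smallest mode
count capturing ≥ 90% of the variance (overridable); this choice is not
dictated by any published value, so all partition tests are
normalization-independent (argmin equivalence, zero cases).

The CG sites of one chain are contiguous residue segments minimizing

    χ² = (1/3N) Σ_sites (1/n_I) Σ_{i<j∈I} ⟨|d_i^ED(t) − d_j^ED(t)|²⟩,

where d_i^ED is residue i's displacement projected onto the essential
subspace.  The pairwise form equals the within-site variance about the
site mean displacement (Σ_{i<j}|d_i−d_j|²/n = Σ_i|d_i − d̄|²), so χ² = 0
iff every site translates rigidly in that subspace.  The pair statistics
⟨d_i·d_j⟩ come from the essential covariance blocks, so no per-frame pass
is needed.  The optimum over contiguous partitions is found **exactly** by
dynamic programming over segment boundaries (backward recursion,
reconstruction from the left); among equal-χ² partitions the
lexicographically smallest boundary vector is returned.  Equality with
exhaustive enumeration is enforced on random instances (N ≤ 20, ≤ 4
sites).  The production resolution is 45 sites per subunit (~8–9 residues
per site); the synthetic demo uses 5 sites per 20–24-residue chain at the
same ratio.

## heteroENM

Sites within a cutoff are joined by harmonic springs at their reference
lengths.  Model fluctuations are computed analytically: Hessian from
blocks −k_ij ê_ij ê_ijᵀ, covariance C = k_B T H⁺ with the rigid-body modes
excluded (graph connectivity decides disconnection; a disconnected network
is an error naming its components), per-bond ⟨δd²⟩ = êᵀ(C_ii+C_jj−2C_ij)ê,
RMSF_i = √tr C_ii.  Fitting is a damped multiplicative update

    k_ij ← k_ij (⟨δd_ij²⟩_model / ⟨δd_ij²⟩_target)^α,   α = 0.5,

with fluctuations recomputed analytically each pass, stopping when the
worst relative bond-fluctuation error drops below `tol` (default 0.05).
The update preserves positivity by construction; bonds whose target
fluctuation exceeds an optional ceiling are pruned to k = 0 and reported.
The analytic route was chosen over re-simulating the CG model each
iteration because it is deterministic and desk-scale; Gaussian sampling
exists for validation only and matches the analytic fluctuations within
Monte-Carlo error by test.

Sampled targets measure the variance of the **projection of the relative
displacement onto the reference bond direction**, the same linearized
quantity the analytic route computes — using raw bond-length variances
instead mixes in second-order transverse terms and biases soft springs.

Cutoff selection re-fits the network at each candidate cutoff and scores
the RMSE of its analytic per-site RMSF against the trajectory RMSF; on a
trajectory generated by a known cutoff-12 Å lattice network the scan
recovers 12 Å (the same rule that selected 50 Å for FH2 chains and
20–30 Å for actin in the production systems).  Per-chain cutoffs are
supported.

Recovery performance, enforced by test on a 30-site perturbed-lattice
network with k ~ U[1, 10] kcal mol⁻¹ Å⁻²: every spring within 1% from
analytic targets in ≤ 200 iterations, and within 10% from a 10⁴-frame
Gaussian trajectory.

## Intermolecular force field

U_inter = U_LJ + U_Coulomb, additive.  The 12–6 LJ term is truncated at
σ_ij — its natural zero — so only the repulsive excluded-volume branch
acts; ε = 10 kcal/mol.  σ_i is the radius of gyration of the site's
mapped atoms (floored at 1 Å for degenerate one-atom sites) and pairs
combine arithmetically, σ_ij = (σ_i+σ_j)/2 (the per-site assignment fixes
no pair rule; the arithmetic mean is this package's choice).  The
electrostatic term is a screened Coulomb (Yukawa) potential

    U_C = k_e q_i q_j exp(−r/λ_D) / (ε_r r),   r < 30 Å,

with screening length λ_D = 8 Å representing physiological salt and
interface dielectric ε_r of 1 or 3 (the dielectric sweep: U_C scales
exactly as 1/ε_r).  The 0.8 nm parameter is implemented as a screening
*length* (exp(−r/λ_D)), the dimensionally consistent reading.  The 30 Å
cutoff is a hard truncation: at λ_D = 8 Å the discarded tail is below
e^(−3.75) ≈ 2% of the bare Coulomb term.  Site charges default to summed
residue formal charges at pH 7 (Asp/Glu −1, Lys/Arg +1, His 0); an
optional least-squares mode instead reproduces each chain's monopole and
dipole with the minimal-norm charge correction.

Nonbonded terms act between molecules — the actin filament is one
molecule, each FH2 chain its own — so intramolecular structure is carried
entirely by the elastic network; FHL–FHT nonbonded interactions are ON by
default and can be excluded per molecule-label pair (whether the
production systems treated the FH2 dimer as one molecule is not
documented; the default is the conservative choice).  Forces are analytic
and verified against central differences to 1e-4 kcal mol⁻¹ Å⁻¹.

## Langevin dynamics

BAOAB splitting; friction γ = 1/damping with a 1000 fs damping time at
310 K.  No published timestep exists for the production runs; the default
is 10 fs, guarded by the stability check ts ≤ 0.1·2π√(m_min/k_max_fitted)
(fitted heteroENM springs can be stiff, so the demo pipeline additionally
caps its timestep at a quarter of that bound and rounds it to divide the
hill pace).  Site masses are summed residue masses.  Velocities are drawn
from Maxwell–Boltzmann at the target temperature unless disabled.  The
kinetic temperature uses 3M degrees of freedom (the thermostat also
thermalizes the rigid-body modes).  Enforced by test: < 0.01 kcal/mol
energy drift over 10⁵ NVE steps of a harmonic dimer at ts = period/100;
mean kinetic temperature within 2% of 310 K over 10⁶ steps of a 10-site
fitted network; bitwise-identical trajectories at a fixed seed.  Nominal
CG integration time is reported as-is; no claim maps it to physical time.

## Metadynamics

Well-tempered deposition on a discretized CV grid (0.1 Å spacing, hills
truncated at 4σ): every 50 fs a Gaussian of width 0.3 Å and height
w = w₀ exp(−V(s)/k_B ΔT), ΔT = (γ_b − 1)T, is added at the current CV
value; w₀ = 0.001 kcal/mol, γ_b = 10 (γ_b → ∞ recovers standard
metadynamics).  The first hill is exactly w₀ and heights are
non-increasing at any fixed CV point.  CVs are mass-weighted COM distances
between site groups (the knob→A2 and post→A2 distances in the production
landscapes) or axis projections; bias forces enter through the chain rule
on the grid gradient.  The free-energy estimate is
F(s) = −(γ_b/(γ_b−1)) V(s), min-shifted to zero.

The **metabasin domain** is realized as a level set of the running FES on
the grid: the connected region around the walker with F ≤ min F + 6
kcal/mol, recomputed every 100 ps but only when the bias outside the
current domain has drifted by ≥ 0.5 kcal/mol since the last update.
Hills are not deposited outside the domain and the bias is held flat at
the boundary (no spurious boundary forces).  This grid-level construction
is a documented simplification of the published domain algorithm; the
deposition parameters are unchanged.  If the walker leaves the grid, the
grid auto-extends with a warning (edge-padding the bias).

Validation by test: pointwise well-tempered decay; FES of a biased
harmonic well within 0.3 kcal/mol of ½ks² over bins visited ≥ 100 times;
a 3 kcal/mol 1-D double-well barrier recovered within 0.5 k_BT after 10⁶
steps (runs at ~3.0 ± 0.1 kcal/mol across seeds).

## Gating observables

- **Steric overlap fraction**: fraction of the target subunit's Cα atoms
  with any blocker Cα strictly closer than 4 Å (one Cα diameter); the
  "fraction of time blocked" statistic counts frames strictly above the 1%
  overlap threshold.  Strict inequalities here, inclusive (≤) for
  contacts at 12 Å and salt bridges at 4 Å — each convention follows how
  its threshold is stated.
- **Salt bridges**: basic side-chain N (Lys NZ; Arg NE/NH1/NH2; His
  ND1/NE2 only when flagged protonated) to acidic side-chain O (Asp
  OD1/OD2, Glu OE1/OE2) within 4.0 Å; occupancy is the percentage of
  window frames with the bridge present.  Counting distinct bridges
  filters rows at occupancy > 0 and ≥ a caller threshold.
- **Twist statistics**: mean, population SD, and mode as the center of the
  tallest 0.5° histogram bin with ties to the lower bin (all three
  conventions configurable).
- **Buried surface area**: SASA(A) + SASA(B) − SASA(A∪B) with both buried
  faces counted; SASA by spherical point quadrature (960 points/atom,
  probe 1.4 Å, per-element van der Waals radii).  Exact on an isolated
  sphere; two-sphere overlaps agree with the analytic spherical-cap lens
  to 2%.
- **COM radial shift**: 100·(r(0) − r(t))/r(0) for the group COM distance
  from the filament axis; positive = toward the axis (toward the
  incoming-subunit site, the closed-state direction); axial motion is
  invisible by construction.
- Every threshold operator is checked against an O(N²) all-pairs
  reference on random instances.

## Synthetic data: what it does and does not emulate

The generator produces (a) helical filaments of rigid subunit templates
with configurable per-interface twist and rise, (b) exact Gaussian samples
from a known heterogeneous elastic network at temperature T (eigenbasis
sampling of k_B T H⁺), (c) toy charged complexes with known COMs, charges
and radii of gyration, and (d) stationary AR(1) twist-angle series with
configured mean, SD and a 40 ps correlation time at the published 40/20 ps
sampling — the stand-in for the published angle-vs-time tables, generated
at the printed final-window means and SDs per formin and interface.

These synthetic systems establish that the machinery is correct — closure,
parameter recovery, statistics — not that real FH2/actin systems behave
any particular way: the templates carry no side-chain geometry, no
nucleotide, no sequence-specific interfaces, and the AR(1) series carries
no slow drift or state-switching.  Passing tests therefore validate the
pipeline's arithmetic and conventions, while conclusions about real
formins rest on the published occupancy tables and settings the package
reproduces.

## Problem sizes and defaults

The bundled drivers and acceptance script run at desk scale as the
package's study conditions: a 9-chain demo complex of 188 pseudo-residues,
400-frame (40 ps-spaced) reference trajectories, a 30-site lattice network
for recovery tests, 10⁶-step integrations for the thermostat and
double-well checks, and 10⁴-frame Gaussian targets.  All stochastic
stages thread one root seed; no global random state is touched.

## Known limitations

- The ED-CG residual normalization and essential-subspace size are this
  package's declared conventions; alternative normalizations change χ²
  values but not the zero cases or (generically) the argmin.
- The heteroENM update rule is likewise declared normative here, with
  parameter recovery as its acceptance surface.
- The twist observable is the full rotation angle of the inter-subunit
  transform; a consumer wanting the axis-projected component must project
  via the screw-axis estimator.
- The metabasin domain is grid-based; continuous-space domain boundaries
  and boundary corrections of the original algorithm are not reproduced.
- The LJ term keeps only the repulsive branch (cut at σ_ij); dispersion
  attraction between molecules is intentionally absent, as in the model
  this package implements.
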