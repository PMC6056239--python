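"""Intermolecular CG force field: repulsive-truncated Lennard-Jones plus a
screened Coulomb (Yukawa) potential.

    U_inter = U_LJ + U_Coulomb                         (additive, DLVO-style)
    U_LJ(r) = 4 eps [ (sigma_ij/r)^12 - (sigma_ij/r)^6 ]   for r < sigma_ij
    U_C(r)  = k_e q_i q_j exp(-r/lambda_D) / (eps_r r)     for r < r_cut_C

The LJ term is cut at sigma_ij where it crosses zero, so only the repulsive
excluded-volume branch acts.  Defaults follow the formin/actin CG model:
eps = 10 kcal/mol, sigma_i = radius of gyration of the site's atoms,
Coulomb cutoff 30 A, screening length lambda_D = 8 A (physiological salt),
interface dielectric eps_r of 1 or 3.  sigma_ij combines arithmetically.
Nonbonded terms act between molecules (actin filament vs each FH2 chain;
FHL-FHT pairs on by default); intramolecular structure is carried by the
elastic network springs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (DEFAULT_RESIDUE_MASS, KE, RESIDUE_CHARGES, RESIDUE_MASSES)
from .edcg import CGMapping, map_structure_sites


@dataclass
class CGForceField:
    """Per-site parameters and pair rules of the intermolecular potential."""

    q: np.ndarray                       # site charges, e
    sigma: np.ndarray                   # site sizes, A
    mass: np.ndarray                    # site masses, amu
    molecule: np.ndarray                # molecule label per site (str)
    epsilon: float = 10.0               # kcal/mol
    r_cut_coulomb: float = 30.0         # A
    lambda_debye: float = 8.0           # A
    eps_r: float = 1.0                  # dimensionless
    sigma_min: float = 1.0              # floor for degenerate sites, A
    ke: float = KE
    exclude_pairs: tuple = ()           # molecule-label pairs with nonbonded OFF

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.sigma = np.asarray(self.sigma, float)
        self.mass = np.asarray(self.mass, float)
        self.molecule = np.asarray(self.molecule)
        if np.any(self.sigma <= 0) or self.lambda_debye <= 0:
            raise ValueError("sigma and lambda_D must be positive")
        if self.eps_r < 1 or self.r_cut_coulomb <= 0:
            raise ValueError("eps_r must be >= 1 and cutoffs positive")

    @property
    def n_sites(self) -> int:
        return len(self.q)

    def sigma_pair(self, i, j):
        return 0.5 * (self.sigma[i] + self.sigma[j])

    def nonbonded_pairs(self) -> np.ndarray:
        """(P, 2) indices of site pairs with nonbonded interactions: pairs in
        different molecules, minus any excluded molecule-label pairs."""
        i, j = np.triu_indices(self.n_sites, k=1)
        keep = self.molecule[i] != self.molecule[j]
        for a, b in self.exclude_pairs:
            keep &= ~(((self.molecule[i] == a) & (self.molecule[j] == b)) |
                      ((self.molecule[i] == b) & (self.molecule[j] == a)))
        return np.column_stack([i[keep], j[keep]])

    def save(self, path) -> None:
        pd.DataFrame({"site": np.arange(self.n_sites), "q": self.q,
                      "sigma": self.sigma, "mass": self.mass,
                      "molecule": self.molecule}).to_csv(path, sep="\t", index=False)


@dataclass
class EnergyReport:
    """Energy decomposition in kcal/mol; U_inter = U_LJ + U_Coulomb exactly."""

    U_LJ: float = 0.0
    U_Coulomb: float = 0.0
    U_bonded: float = 0.0
    U_external: float = 0.0
    per_group: dict = field(default_factory=dict)

    @property
    def U_inter(self) -> float:
        return self.U_LJ + self.U_Coulomb

    @property
    def U_total(self) -> float:
        return self.U_inter + self.U_bonded + self.U_external


def assign_site_params(structure, mapping: CGMapping, charge_mode: str = "formal",
                       molecule_of_chain=None, sigma_min: float = 1.0,
                       **ff_kwargs) -> CGForceField:
    """Build per-site parameters from a structure and its CG mapping.

    sigma_i = radius of gyration of the site's mapped atoms about the site
    centroid (floored at ``sigma_min`` for degenerate one-atom sites);
    mass = sum of residue masses; charge = sum of residue formal charges at
    pH 7 (``formal``) or a least-squares fit reproducing each chain's total
    charge and dipole (``lsq``).  ``molecule_of_chain`` maps chain ids to
    molecule labels (default: the chain's role, with actin subunits merged
    into one ``actin`` molecule).
    """
    groups, _ = map_structure_sites(structure, mapping, weights="uniform")
    n = mapping.n_sites
    sigma = np.empty(n)
    mass = np.empty(n)
    charge = np.zeros(n)
    molecule = np.empty(n, dtype=object)
    chain_of_site = {}
    for chain, lo, hi, site in mapping.segments:
        chain_of_site[site] = str(chain)

    for s, sel in enumerate(groups):
        pts = structure.coords[sel]
        centroid = pts.mean(axis=0)
        rg = np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
        if rg < sigma_min:
            warnings.warn(f"site {s}: radius of gyration {rg:.3f} A floored "
                          f"to sigma_min {sigma_min} A")
            rg = sigma_min
        sigma[s] = rg
        resnames = structure.res_name[sel]
        mass[s] = sum(RESIDUE_MASSES.get(rn, DEFAULT_RESIDUE_MASS) for rn in resnames)
        charge[s] = sum(RESIDUE_CHARGES.get(rn, 0.0) for rn in resnames)
        chain = chain_of_site[s]
        if molecule_of_chain is not None:
            molecule[s] = molecule_of_chain[chain]
        else:
            role = structure.role_of(chain)
            molecule[s] = "actin" if role.startswith("A") and role != "other" else \
                (role if role != "other" else chain)

    if charge_mode == "lsq":
        charge = _fit_charges_lsq(structure, mapping, groups, charge)
    elif charge_mode != "formal":
        raise ValueError(f"unknown charge mode {charge_mode!r}")
    return CGForceField(q=charge, sigma=sigma, mass=mass,
                        molecule=molecule.astype(str), sigma_min=sigma_min,
                        **ff_kwargs)


def _fit_charges_lsq(structure, mapping, groups, formal_charge):
    """Minimal-norm correction of site charges so each chain reproduces the
    monopole and dipole of its residue-level formal-charge distribution."""
    out = formal_charge.copy()
    chains = {}
    for chain, lo, hi, site in mapping.segments:
        chains.setdefault(str(chain), []).append(site)
    for chain, sites in chains.items():
        sel = (structure.chain_id == chain)
        res_q = np.array([RESIDUE_CHARGES.get(rn, 0.0)
                          for rn in structure.res_name[sel]])
        pos = structure.coords[sel]
        centers = np.array([structure.coords[groups[s]].mean(axis=0) for s in sites])
        b = np.concatenate([[res_q.sum()], res_q @ pos])
        A = np.vstack([np.ones(len(sites)), centers.T])
        q0 = out[sites]
        resid = b - A @ q0
        dq, *_ = np.linalg.lstsq(A, resid, rcond=None)
        out[sites] = q0 + dq
    return out


def pair_energy(ff: CGForceField, i: int, j: int, r: float):
    """(U_LJ, U_Coulomb) of one site pair at separation r (A)."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    sij = ff.sigma_pair(i, j)
    if r < sij:
        sr6 = (sij / r) ** 6
        u_lj = 4.0 * ff.epsilon * (sr6 * sr6 - sr6)
    else:
        u_lj = 0.0
    if r < ff.r_cut_coulomb and ff.q[i] != 0 and ff.q[j] != 0:
        u_c = ff.ke * ff.q[i] * ff.q[j] * np.exp(-r / ff.lambda_debye) / (ff.eps_r * r)
    else:
        u_c = 0.0
    return float(u_lj), float(u_c)


def _nonbonded_vectorized(ff, positions, pairs):
    i, j = pairs[:, 0], pairs[:, 1]
    d = positions[i] - positions[j]
    r = np.linalg.norm(d, axis=1)
    if np.any(r <= 0):
        raise ValueError("coincident nonbonded sites")
    u = d / r[:, None]
    sij = 0.5 * (ff.sigma[i] + ff.sigma[j])

    u_lj = np.zeros(len(r))
    f_lj = np.zeros(len(r))
    lj = r < sij
    sr6 = (sij[lj] / r[lj]) ** 6
    u_lj[lj] = 4.0 * ff.epsilon * (sr6 * sr6 - sr6)
    # dU/dr = -(4 eps / r)(12 sr12 - 6 sr6); force magnitude along +u on i
    f_lj[lj] = 4.0 * ff.epsilon * (12.0 * sr6 * sr6 - 6.0 * sr6) / r[lj]

    qq = ff.q[i] * ff.q[j]
    u_c = np.zeros(len(r))
    f_c = np.zeros(len(r))
    cc = (r < ff.r_cut_coulomb) & (qq != 0)
    pref = ff.ke * qq[cc] / ff.eps_r
    ex = np.exp(-r[cc] / ff.lambda_debye)
    u_c[cc] = pref * ex / r[cc]
    f_c[cc] = pref * ex * (1.0 / r[cc] ** 2 + 1.0 / (ff.lambda_debye * r[cc]))

    fmag = f_lj + f_c
    forces = np.zeros_like(positions)
    np.add.at(forces, i, fmag[:, None] * u)
    np.add.at(forces, j, -fmag[:, None] * u)
    return float(u_lj.sum()), float(u_c.sum()), forces


def bonded_energy_forces(network, positions):
    """Harmonic spring energy 0.5 k (d - r0)^2 and forces."""
    if network is None or network.n_bonds == 0:
        return 0.0, np.zeros_like(positions)
    i, j = network.bonds[:, 0], network.bonds[:, 1]
    d = positions[i] - positions[j]
    r = np.linalg.norm(d, axis=1)
    u = d / r[:, None]
    dr = r - network.r0
    energy = float(np.sum(0.5 * network.k * dr * dr))
    fmag = -network.k * dr
    forces = np.zeros_like(positions)
    np.add.at(forces, i, fmag[:, None] * u)
    np.add.at(forces, j, -fmag[:, None] * u)
    return energy, forces


def system_energy_forces(ff: CGForceField | None, network, positions,
                         pairs: np.ndarray | None = None,
                         external=None):
    """Total energy report and per-site forces (kcal mol^-1 A^-1).

    ``pairs`` may carry a precomputed nonbonded pair list (static across a
    simulation); ``external`` is an optional callable
    ``positions -> (U, forces)`` for auxiliary potentials.
    """
    positions = np.asarray(positions, float)
    if np.any(~np.isfinite(positions)):
        raise ValueError("non-finite positions")
    report = EnergyReport()
    forces = np.zeros_like(positions)
    u_b, f_b = bonded_energy_forces(network, positions)
    report.U_bonded = u_b
    forces += f_b
    if ff is not None:
        if pairs is None:
            pairs = ff.nonbonded_pairs()
        if len(pairs):
            u_lj, u_c, f_nb = _nonbonded_vectorized(ff, positions, pairs)
            report.U_LJ, report.U_Coulomb = u_lj, u_c
            forces += f_nb
    if external is not None:
        u_ext, f_ext = external(positions)
        report.U_external = float(u_ext)
        forces += f_ext
    return report, forces
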