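"""Heterogeneous elastic network model (heteroENM) with fluctuation matching.

CG sites within a cutoff are connected by harmonic springs; each spring
constant is then fitted iteratively so the network's analytic thermal
fluctuations match target (e.g. mapped all-atom) bond fluctuations:

    k_ij <- k_ij * (<dd_ij^2>_model / <dd_ij^2>_target)^alpha

with damping alpha (default 0.5).  Model fluctuations come from the Hessian
pseudoinverse (covariance C = k_B T H^+ over non-rigid modes), so each pass
is deterministic and cheap; sampling a CG trajectory is only needed for
validation.  The multiplicative update keeps every spring non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .constants import KB
from .structure import Trajectory


class DisconnectedNetworkError(ValueError):
    pass


@dataclass
class ElasticNetwork:
    """CG sites plus harmonic bonds (i < j, k in kcal mol^-1 A^-2, r0 in A)."""

    coords: np.ndarray                  # (M, 3) reference coordinates
    bonds: np.ndarray                   # (B, 2) int, i < j
    k: np.ndarray                       # (B,)
    r0: np.ndarray                      # (B,)
    cutoff: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.bonds = np.asarray(self.bonds, int).reshape(-1, 2)
        self.k = np.asarray(self.k, float)
        self.r0 = np.asarray(self.r0, float)
        if np.any(self.k < 0):
            raise ValueError("spring constants must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]

    def copy(self) -> "ElasticNetwork":
        return ElasticNetwork(self.coords.copy(), self.bonds.copy(),
                              self.k.copy(), self.r0.copy(), self.cutoff)

    def save(self, path) -> None:
        pd.DataFrame({"i": self.bonds[:, 0], "j": self.bonds[:, 1],
                      "k": self.k, "r0": self.r0}).to_csv(path, sep="\t", index=False)

    def components(self):
        """Connected components of the bond graph (springs with k > 0 only)."""
        live = self.bonds[self.k > 0]
        adj = coo_matrix((np.ones(len(live)), (live[:, 0], live[:, 1])),
                         shape=(self.n_sites, self.n_sites))
        n_comp, labels = connected_components(adj, directed=False)
        return n_comp, labels


@dataclass
class FluctuationTable:
    """Per-bond mean-square length fluctuations and per-site RMSF at T."""

    bond_fluct: np.ndarray   # (B,) <delta d_ij^2>, A^2
    rmsf: np.ndarray         # (M,), A
    temperature: float
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    def __post_init__(self):
        if np.any(self.bond_fluct < 0) or np.any(self.rmsf < 0):
            raise ValueError("fluctuations must be non-negative")


def build_network(coords, cutoff: float, k_init: float = 1.0) -> ElasticNetwork:
    """Connect every pair of sites within ``cutoff`` A by a spring of
    constant ``k_init`` at its reference length."""
    coords = np.asarray(coords, float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    if pairs.size == 0:
        warnings.warn(f"cutoff {cutoff} A yields an empty network")
        return ElasticNetwork(coords, np.empty((0, 2), int), np.empty(0),
                              np.empty(0), cutoff)
    r0 = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return ElasticNetwork(coords, pairs, np.full(len(pairs), float(k_init)), r0, cutoff)


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Dense 3M x 3M Hessian from per-bond blocks -k_ij e_ij e_ij^T."""
    M = network.n_sites
    H = np.zeros((3 * M, 3 * M))
    d = network.coords[network.bonds[:, 1]] - network.coords[network.bonds[:, 0]]
    e = d / np.linalg.norm(d, axis=1)[:, None]
    for (i, j), k, u in zip(network.bonds, network.k, e):
        blk = k * np.outer(u, u)
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] += blk
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] += blk
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= blk
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= blk
    return H


def hessian_eigensystem(network: ElasticNetwork, zero_tol: float = 1e-10):
    """Eigenvalues/vectors of the Hessian with the rigid-body modes zeroed.

    Connectivity is decided on the bond graph (springs with k > 0): a
    disconnected network raises :class:`DisconnectedNetworkError` naming the
    components, since it would carry more than 6 zero modes.  For a
    connected network the near-zero (rigid) eigenvalues are floored to 0;
    genuinely soft internal modes stay.
    """
    n_comp, labels = network.components()
    if n_comp > 1:
        groups = [[int(i) for i in np.flatnonzero(labels == c)]
                  for c in range(n_comp)]
        raise DisconnectedNetworkError(
            f"network is disconnected (> 6 zero modes); components: {groups}")
    H = hessian(network)
    evals, evecs = np.linalg.eigh(H)
    scale = max(evals.max(), 1.0) if evals.size else 1.0
    evals = evals.copy()
    evals[evals < zero_tol * scale] = 0.0
    return evals, evecs


def network_covariance(network: ElasticNetwork, temperature: float,
                       return_full: bool = False):
    """Analytic thermal fluctuations: C = k_B T H^+ over non-rigid modes.

    Per-bond <dd^2> = e_ij^T (C_ii + C_jj - 2 C_ij) e_ij; RMSF_i = sqrt(tr C_ii).
    """
    evals, evecs = hessian_eigensystem(network)
    soft = evals > 0
    C = (evecs[:, soft] / evals[soft]) @ evecs[:, soft].T * KB * temperature
    M = network.n_sites
    rmsf = np.sqrt(np.array([np.trace(C[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                             for i in range(M)]))
    d = network.coords[network.bonds[:, 1]] - network.coords[network.bonds[:, 0]]
    e = d / np.linalg.norm(d, axis=1)[:, None]
    bond_fluct = np.empty(network.n_bonds)
    for b, ((i, j), u) in enumerate(zip(network.bonds, e)):
        Cii = C[3 * i:3 * i + 3, 3 * i:3 * i + 3]
        Cjj = C[3 * j:3 * j + 3, 3 * j:3 * j + 3]
        Cij = C[3 * i:3 * i + 3, 3 * j:3 * j + 3]
        bond_fluct[b] = u @ (Cii + Cjj - Cij - Cij.T) @ u
    table = FluctuationTable(bond_fluct=bond_fluct, rmsf=rmsf,
                             temperature=temperature, bonds=network.bonds.copy())
    return (table, C) if return_full else table


def trajectory_fluctuations(traj: Trajectory, network: ElasticNetwork,
                            temperature: float) -> FluctuationTable:
    """Sampled fitting target: per-bond fluctuations and site RMSFs of a CG
    trajectory (no superposition: CG frames share the network frame).

    Bond fluctuations are variances of the relative displacement projected
    onto the reference bond direction, var[(r_i - r_j) . e_ij] -- the same
    quantity the analytic route computes, so matching is consistent."""
    i, j = network.bonds[:, 0], network.bonds[:, 1]
    dvec = network.coords[j] - network.coords[i]
    e = dvec / np.linalg.norm(dvec, axis=1)[:, None]
    proj = np.einsum("fba,ba->fb", traj.frames[:, i, :] - traj.frames[:, j, :], e)
    bond_fluct = proj.var(axis=0)
    mean = traj.frames.mean(axis=0)
    rmsf = np.sqrt(((traj.frames - mean) ** 2).sum(axis=2).mean(axis=0))
    return FluctuationTable(bond_fluct=bond_fluct, rmsf=rmsf,
                            temperature=temperature, bonds=network.bonds.copy())


def fit_fluctuations(network: ElasticNetwork, target: FluctuationTable,
                     max_iter: int = 200, tol: float = 0.05,
                     alpha: float = 0.5, fluct_ceiling: float | None = None,
                     verbose: bool = False):
    """Fluctuation matching: damped multiplicative updates of every spring
    until the worst relative per-bond fluctuation error drops below ``tol``.

    Bonds whose target fluctuation exceeds ``fluct_ceiling`` (if given) are
    pruned (k = 0) and reported.  Returns (fitted network, trace) where
    trace is the list of max relative errors per iteration.
    """
    if target.bond_fluct.shape[0] != network.n_bonds:
        raise ValueError("target does not cover all bonds")
    net = network.copy()
    active = np.ones(net.n_bonds, bool)
    if fluct_ceiling is not None:
        pruned = target.bond_fluct > fluct_ceiling
        if pruned.any():
            warnings.warn(f"pruning {int(pruned.sum())} bonds with target "
                          f"fluctuation above {fluct_ceiling} A^2")
            net.k[pruned] = 0.0
            active &= ~pruned
    if np.any(target.bond_fluct[active] <= 0):
        raise ValueError("target fluctuation <= 0 for an existing bond")
    trace = []
    for _ in range(max_iter):
        model = network_covariance(net, target.temperature)
        err = np.abs(model.bond_fluct[active] / target.bond_fluct[active] - 1.0)
        trace.append(float(err.max()) if err.size else 0.0)
        if trace[-1] < tol:
            break
        ratio = model.bond_fluct[active] / target.bond_fluct[active]
        net.k[active] *= ratio ** alpha
    return net, trace


def scan_cutoff(cg_traj: Trajectory, cutoffs, temperature: float,
                k_init: float = 1.0, max_iter: int = 100, tol: float = 0.01):
    """Fit a network at each candidate cutoff and score it by the RMSE of
    its analytic per-site RMSF against the trajectory's RMSF.

    Returns (best_cutoff, {cutoff: rmse}).  Cutoffs whose networks are
    disconnected are skipped; if all are, an error is raised.
    """
    cutoffs = list(cutoffs)
    if len(cutoffs) < 1:
        raise ValueError("need at least one candidate cutoff")
    ref = cg_traj.frames.mean(axis=0)
    errors = {}
    for rc in cutoffs:
        net = build_network(ref, rc, k_init)
        try:
            target = trajectory_fluctuations(cg_traj, net, temperature)
            fitted, _ = fit_fluctuations(net, target, max_iter=max_iter, tol=tol)
            model = network_covariance(fitted, temperature)
        except (DisconnectedNetworkError, ValueError):
            continue
        errors[rc] = float(np.sqrt(np.mean((model.rmsf - target.rmsf) ** 2)))
    if not errors:
        raise DisconnectedNetworkError("every candidate cutoff gave a disconnected network")
    best = min(errors, key=errors.get)
    return best, errors
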