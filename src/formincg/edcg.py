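"""Essential-dynamics coarse-graining (ED-CG).

CG sites are contiguous residue segments chosen so that residues grouped
into one site move together in the essential (principal-component) subspace
of a C-alpha trajectory.  The residual minimized here is

    chi^2 = (1 / 3N) * sum_sites (1 / n_I) * sum_{i<j in I} <|dED_i - dED_j|^2>

where dED_i(t) is residue i's displacement projected onto the retained
essential modes.  chi^2 is zero iff every site moves rigidly within that
subspace.  The optimum over contiguous partitions is found exactly by
dynamic programming; ties are broken toward the lexicographically smallest
boundary vector.  The target resolution used for the formin/actin systems
is 45 sites per subunit (roughly 8-9 residues per site).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import kabsch
from .structure import AtomGroup, Trajectory
from .constants import RESIDUE_MASSES, DEFAULT_RESIDUE_MASS


@dataclass
class EssentialModes:
    """PCA of an aligned C-alpha trajectory (3N-dimensional)."""

    mean: np.ndarray            # (3N,)
    modes: np.ndarray           # (n_modes, 3N), orthonormal rows
    variances: np.ndarray       # (n_modes,), A^2, non-increasing
    n_essential: int            # modes retained as "essential"
    total_variance: float = 0.0

    @property
    def retained_fraction(self) -> float:
        if self.total_variance == 0:
            return 1.0
        return float(self.variances[:self.n_essential].sum() / self.total_variance)

    def essential_covariance_blocks(self) -> np.ndarray:
        """(N, N) matrix of tr(C_ij) over the essential subspace, where C_ij
        is the 3x3 residue-pair covariance block."""
        V = self.modes[:self.n_essential]       # (m, 3N)
        lam = self.variances[:self.n_essential]
        n_res = V.shape[1] // 3
        Vr = V.reshape(-1, n_res, 3)            # (m, N, 3)
        # tr C_ij = sum_m lam_m * v_m[i] . v_m[j]
        return np.einsum("m,mia,mja->ij", lam, Vr, Vr)


def essential_modes(traj: Trajectory, group: AtomGroup | None = None,
                    n_modes: int | None = None,
                    variance_fraction: float = 0.9,
                    n_align_passes: int = 3) -> EssentialModes:
    """PCA of a trajectory after least-squares superposition onto its mean.

    ``n_modes`` fixes the essential-subspace size; otherwise the smallest
    number of modes capturing ``variance_fraction`` of the variance is kept.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for essential dynamics")
    X = traj.frames if group is None else traj.frames[:, group.indices, :]
    X = X.copy()
    mean = X[0]
    for _ in range(n_align_passes):
        for f in range(X.shape[0]):
            R, t = kabsch(mean, X[f])
            X[f] = X[f] @ R.T + t
        mean = X.mean(axis=0)
    n_frames, n_res, _ = X.shape
    flat = X.reshape(n_frames, 3 * n_res)
    mu = flat.mean(axis=0)
    centered = flat - mu
    # modes = eigenvectors of the 3N x 3N covariance, via thin SVD
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    variances = svals ** 2 / n_frames
    total = float(variances.sum())
    if n_modes is None:
        if total <= 0:
            n_modes = 1
        else:
            cum = np.cumsum(variances) / total
            n_modes = int(np.searchsorted(cum, variance_fraction) + 1)
    n_modes = min(n_modes, len(variances))
    if traj.n_frames <= n_modes:
        raise ValueError("more essential modes requested than frames available")
    return EssentialModes(mean=mu, modes=vt, variances=variances,
                          n_essential=n_modes, total_variance=total)


@dataclass
class CGMapping:
    """Contiguous residue segments per chain mapped to CG site indices.

    ``segments``: list of (chain_id, start_res, end_res, site_index) with
    1-based inclusive residue ranges; per-site mass (amu), charge (e) and
    sigma (A) arrays are indexed by site.
    """

    segments: list
    mass: np.ndarray | None = None
    charge: np.ndarray | None = None
    sigma: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return 1 + max(s[3] for s in self.segments)

    def sites_of_chain(self, chain_id) -> list:
        return [s for s in self.segments if s[0] == chain_id]

    def validate_partition(self, chain_id, residues) -> None:
        """Check the chain's segments partition ``residues`` without gaps."""
        segs = sorted(self.sites_of_chain(chain_id), key=lambda s: s[1])
        covered = []
        for _, lo, hi, _ in segs:
            covered.extend(range(lo, hi + 1))
        if covered != sorted(residues):
            raise ValueError(f"segments do not partition chain {chain_id!r}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.segments,
                          columns=["chain", "start_res", "end_res", "site"])
        for name in ("mass", "charge", "sigma"):
            arr = getattr(self, name)
            if arr is not None:
                df[name] = np.asarray(arr)[df["site"].to_numpy()]
        return df

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "CGMapping":
        df = pd.read_csv(path, sep="\t")
        segments = [tuple(r) for r in
                    df[["chain", "start_res", "end_res", "site"]].itertuples(index=False)]
        n = 1 + int(df["site"].max())
        kw = {}
        for name in ("mass", "charge", "sigma"):
            if name in df.columns:
                arr = np.zeros(n)
                arr[df["site"].to_numpy()] = df[name].to_numpy()
                kw[name] = arr
        return cls(segments=segments, **kw)


@dataclass
class EDCGResult:
    mapping: CGMapping
    chi2: float
    site_residuals: np.ndarray = field(default_factory=lambda: np.array([]))


def _segment_costs(M: np.ndarray) -> np.ndarray:
    """cost[a, b] = (1/n) * sum_{a<=i<j<=b} M_ij for every contiguous segment."""
    n = M.shape[0]
    P = np.zeros((n + 1, n + 1))
    P[1:, 1:] = M.cumsum(axis=0).cumsum(axis=1)
    cost = np.full((n, n), np.inf)
    for a in range(n):
        for b in range(a, n):
            block = P[b + 1, b + 1] - P[a, b + 1] - P[b + 1, a] + P[a, a]
            diag = np.trace(M[a:b + 1, a:b + 1])
            cost[a, b] = (block - diag) / 2.0 / (b - a + 1)
    return cost


def edcg_partition(modes: EssentialModes, residues, n_sites: int,
                   chain_id="A") -> EDCGResult:
    """Exact minimum-chi^2 contiguous partition of one chain into CG sites.

    ``residues``: ordered residue numbers of the chain (length N, matching
    the mode vectors).  Dynamic programming over segment boundaries; among
    equal-chi^2 partitions the lexicographically smallest boundary vector
    is returned.
    """
    residues = list(residues)
    N = len(residues)
    if n_sites > N:
        raise ValueError(f"cannot place {n_sites} sites on {N} residues")
    if 3 * N != modes.modes.shape[1]:
        raise ValueError("mode dimension does not match residue count")
    T = modes.essential_covariance_blocks()
    d = np.diag(T)
    M = d[:, None] + d[None, :] - 2.0 * T     # <|dED_i - dED_j|^2>
    cost = _segment_costs(M)

    # backward DP: g[k][a] = min cost of splitting residues a..N-1 into k sites
    INF = np.inf
    g = np.full((n_sites + 1, N + 1), INF)
    g[0, N] = 0.0
    for k in range(1, n_sites + 1):
        for a in range(N - 1, -1, -1):
            best = INF
            for b in range(a, N - (k - 1)):
                c = cost[a, b] + g[k - 1, b + 1]
                if c < best:
                    best = c
            g[k, a] = best
    # reconstruct from the left, preferring the earliest boundary on ties
    bounds = []
    a, k = 0, n_sites
    site_costs = []
    tol = 1e-12 * max(1.0, abs(g[n_sites, 0]))
    while k > 0:
        for b in range(a, N - (k - 1)):
            if cost[a, b] + g[k - 1, b + 1] <= g[k, a] + tol:
                bounds.append(b)
                site_costs.append(cost[a, b])
                a, k = b + 1, k - 1
                break
    segments = []
    lo = 0
    for site, b in enumerate(bounds):
        segments.append((chain_id, residues[lo], residues[b], site))
        lo = b + 1
    chi2 = float(sum(site_costs) / (3.0 * N))
    return EDCGResult(mapping=CGMapping(segments=segments),
                      chi2=chi2,
                      site_residuals=np.asarray(site_costs) / (3.0 * N))


def map_structure_sites(structure, mapping: CGMapping, weights: str = "mass"):
    """Per-site (index lists, weights) for the C-alpha atoms of a structure."""
    groups = [None] * mapping.n_sites
    wts = [None] * mapping.n_sites
    ca = structure.atom_name == "CA"
    for chain, lo, hi, site in mapping.segments:
        sel = np.flatnonzero(ca & (structure.chain_id == str(chain)) &
                             (structure.res_id >= lo) & (structure.res_id <= hi))
        if sel.size == 0:
            raise ValueError(f"segment {chain}:{lo}-{hi} matches no C-alpha atoms")
        groups[site] = sel
        if weights == "mass":
            w = np.array([RESIDUE_MASSES.get(rn, DEFAULT_RESIDUE_MASS)
                          for rn in structure.res_name[sel]])
        elif weights == "uniform":
            w = np.ones(sel.size)
        else:
            raise ValueError(f"unknown weighting {weights!r}")
        wts[site] = w / w.sum()
    if any(g is None for g in groups):
        raise ValueError("mapping has site indices with no segments")
    return groups, wts


def map_trajectory(traj: Trajectory, mapping: CGMapping, structure=None,
                   weights: str = "mass") -> Trajectory:
    """Map a C-alpha trajectory to CG resolution: each site is the
    (mass- or uniformly) weighted centroid of its residues' CA positions."""
    ref = structure if structure is not None else traj.reference
    if ref is None:
        raise ValueError("need a reference structure to resolve the mapping")
    groups, wts = map_structure_sites(ref, mapping, weights)
    out = np.empty((traj.n_frames, mapping.n_sites, 3))
    for s, (sel, w) in enumerate(zip(groups, wts)):
        out[:, s, :] = np.einsum("fia,i->fa", traj.frames[:, sel, :], w)
    return Trajectory(frames=out, dt=traj.dt, t0=traj.t0)
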