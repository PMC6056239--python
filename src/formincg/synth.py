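"""Synthetic inputs: helical filaments, elastic-network trajectories,
toy charged complexes, and twist-angle time series.

Everything the pipeline consumes can be generated here without external
downloads.  Helical geometry follows the actin convention: the inter-subunit
twist is reported as a magnitude in (0, 180] degrees (~167 deg in a free
filament, flattened toward 180 deg by some FH2 dimers) with a left-handed
rotation sense, and a rise of 27.6 A per subunit.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import AtomicStructure, Trajectory

DEFAULT_RISE = 27.6  # A per subunit (actin-literature value; not filament-specific input)
DEFAULT_RADIUS = 10.0  # A, distance of subunit centroid from the filament axis

# Final-50-ns twist statistics (deg, mean and SD) of seven-mer filaments
# bound to each FH2 dimer, and most-probable A2-A3 twists of the five-mer
# replicates.  These are the published study conditions that the synthetic
# twist-series generator emulates.
SEVEN_MER_TWIST_CONDITIONS = {
    "mDia1": {"A1-A2": (169.4, 0.7), "A2-A3": (167.2, 1.1)},
    "Cdc12": {"A1-A2": (171.3, 0.4), "A2-A3": (169.6, 0.5)},
    "Bni1": {"A1-A2": (170.7, 0.4), "A2-A3": (170.2, 0.5)},
}
FIVE_MER_TWIST_CONDITIONS = {
    "mDia1": [(168.2, 0.5), (170.3, 0.7)],
    "Bni1": [(172.2, 0.8), (171.6, 1.2)],
    "Cdc12": [(173.9, 0.8), (175.1, 0.7)],
}


@dataclass
class HelixGeometry:
    """Per-interface twist (deg, magnitude) and rise (A) of an ideal filament."""

    twist_deg: float = 167.0
    rise: float = DEFAULT_RISE
    axis: tuple = (0.0, 0.0, 1.0)
    handedness: int = -1  # -1: left-handed (actin), +1: right-handed

    def __post_init__(self):
        # 0 is admitted as the degenerate untwisted stack; helical filaments
        # use magnitudes in (0, 180]
        if not (0.0 <= self.twist_deg <= 180.0):
            raise ValueError("twist must lie in [0, 180] degrees")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        a = np.asarray(self.axis, dtype=float)
        self.axis = tuple(a / np.linalg.norm(a))


@dataclass
class SubunitTemplate:
    """Pseudo-residue C-alpha coordinates of one subunit in its local frame."""

    coords: np.ndarray
    charges: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.coords.shape[0] < 3:
            raise ValueError("template needs >= 3 residues")
        c = self.coords - self.coords.mean(axis=0)
        if np.linalg.matrix_rank(c, tol=1e-8) < 2:
            raise ValueError("template points are collinear; superposition degenerate")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def res_names(self) -> np.ndarray:
        """Residue names encoding the per-residue formal charge."""
        return np.array(["LYS" if q > 0 else "ASP" if q < 0 else "GLY"
                         for q in self.charges], dtype="U4")


def make_bent_rod_template(n_residues: int = 20) -> SubunitTemplate:
    """Deterministic bent-rod subunit: non-symmetric so rigid superposition
    is unique.  Charges alternate +1/0/-1/0 along the rod."""
    t = np.linspace(0.0, 1.0, n_residues)
    coords = np.column_stack([
        6.0 * np.sin(1.3 * np.pi * t),
        4.0 * t * t * 10.0 / 4.0,
        18.0 * t,
    ])
    charges = np.array([(1, 0, -1, 0)[i % 4] for i in range(n_residues)], dtype=float)
    return SubunitTemplate(coords=coords, charges=charges)


def make_actin_like_template(n_residues: int = 375) -> SubunitTemplate:
    """A reduced actin-scale template (375 pseudo-residues) for scale tests:
    a compact, slightly chiral blob of ~55 A extent, net charge about -11 e
    (actin is strongly anionic)."""
    rng = np.random.default_rng(375)  # fixed: the template is a constant
    t = np.linspace(0, 6 * np.pi, n_residues)
    spine = np.column_stack([9 * np.cos(t), 9 * np.sin(t), np.linspace(-14, 14, n_residues)])
    coords = spine + rng.normal(scale=2.0, size=(n_residues, 3))
    charges = np.zeros(n_residues)
    neg = rng.choice(n_residues, size=40, replace=False)
    charges[neg] = -1.0
    pos = rng.choice(np.setdiff1d(np.arange(n_residues), neg), size=29, replace=False)
    charges[pos] = +1.0
    return SubunitTemplate(coords=coords, charges=charges)


def _chain_ids(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n > len(letters):
        raise ValueError("too many subunits for single-letter chain ids")
    return list(letters[:n])


def _assemble(template: SubunitTemplate, cumulative_deg, rise, axis, handedness,
              radius=DEFAULT_RADIUS, title="") -> AtomicStructure:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # local template centered, then displaced off-axis so the filament is helical
    perp = np.array([1.0, 0.0, 0.0])
    if abs(perp @ axis) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    perp = perp - (perp @ axis) * axis
    perp /= np.linalg.norm(perp)
    local = template.coords - template.coords.mean(axis=0) + radius * perp

    n_sub = len(cumulative_deg)
    chains = _chain_ids(n_sub)
    blocks, chain_col = [], []
    for i, ang in enumerate(cumulative_deg):
        rot = Rotation.from_rotvec(np.deg2rad(handedness * ang) * axis)
        blocks.append(rot.apply(local) + i * rise * axis)
        chain_col.extend([chains[i]] * template.n_residues)
    coords = np.vstack(blocks)
    n_res = template.n_residues
    s = AtomicStructure(
        atom_name=np.full(coords.shape[0], "CA", dtype="U4"),
        element=np.full(coords.shape[0], "C", dtype="U2"),
        res_name=np.tile(template.res_names, n_sub),
        res_id=np.tile(np.arange(1, n_res + 1), n_sub),
        chain_id=np.array(chain_col, dtype="U4"),
        coords=coords,
        roles={chains[i]: f"A{i + 1}" for i in range(n_sub)},
        title=title,
    )
    s.validate()
    return s


def build_ideal_filament(template: SubunitTemplate, n_subunits: int,
                         geometry: HelixGeometry) -> AtomicStructure:
    """Ideal helical filament: subunit i+1 is subunit i rotated by the twist
    about the axis and translated by the rise.  Roles run A1 (barbed end)
    to A{n} (pointed end)."""
    if n_subunits < 2:
        raise ValueError("a filament needs at least 2 subunits")
    cumulative = [i * geometry.twist_deg for i in range(n_subunits)]
    return _assemble(template, cumulative, geometry.rise, geometry.axis,
                     geometry.handedness,
                     title=f"ideal filament twist={geometry.twist_deg} deg")


def build_flattened_filament(template: SubunitTemplate, n_subunits: int,
                             per_interface_twists, rise: float = DEFAULT_RISE,
                             axis=(0.0, 0.0, 1.0), handedness: int = -1) -> AtomicStructure:
    """Filament with per-interface twists (deg): flattened barbed ends with a
    natural interior are expressed as e.g. [173.9, 169.6, 167, 167]."""
    twists = np.asarray(per_interface_twists, dtype=float)
    if len(twists) != n_subunits - 1:
        raise ValueError(f"need {n_subunits - 1} interface twists, got {len(twists)}")
    if np.any((twists <= 0) | (twists > 180)):
        raise ValueError("interface twists must lie in (0, 180] degrees")
    cumulative = np.concatenate([[0.0], np.cumsum(twists)])
    return _assemble(template, cumulative, rise, axis, handedness,
                     title="flattened filament")


def make_lattice_sites(dims=(3, 2, 5), spacing: float = 8.0,
                       jitter: float = 1.0, seed: int = 0) -> np.ndarray:
    """Perturbed cubic-lattice CG sites (protein-like packing: ~8 A nearest
    neighbours, no near-coincident pairs) for elastic-network tests."""
    import itertools
    rng = np.random.default_rng(seed)
    pts = np.array(list(itertools.product(*[range(d) for d in dims])),
                   dtype=float) * spacing
    return pts + rng.normal(scale=jitter, size=pts.shape)


def sample_enm_trajectory(network, temperature: float, n_frames: int, seed: int,
                          mode: str = "gaussian", dt_ps: float = 1.0) -> Trajectory:
    """Draw a trajectory from an elastic network.

    ``gaussian``: exact i.i.d. draws from the analytic Gaussian ensemble with
    covariance k_B T H^+ (Hessian pseudoinverse over non-rigid modes).
    ``langevin``: integrate the network with the Langevin integrator
    (equilibrium samples after decorrelation, but with integration error).
    """
    from .enm import hessian_eigensystem
    if mode == "langevin":
        from .dynamics import CGSystem, SimParams, run_langevin
        system = CGSystem(network=network, positions=network.coords.copy(),
                          masses=np.full(network.n_sites, 100.0))
        params = SimParams(temperature=temperature, n_steps=n_frames,
                           timestep_fs=5.0, seed=seed, stride=1)
        traj, _ = run_langevin(system, params)
        traj.dt = dt_ps
        return traj
    if mode != "gaussian":
        raise ValueError(f"unknown mode {mode!r}")

    evals, evecs = hessian_eigensystem(network)  # raises if disconnected
    rng = np.random.default_rng(seed)
    from .constants import KB
    soft = evals > max(evals.max(), 1.0) * 1e-10
    amp = np.sqrt(KB * temperature / evals[soft])  # A per unit normal coordinate
    frames = np.empty((n_frames, network.n_sites, 3))
    ref = network.coords.ravel()
    xi = rng.standard_normal((n_frames, soft.sum()))
    disp = (xi * amp) @ evecs[:, soft].T
    frames[:] = (ref + disp).reshape(n_frames, network.n_sites, 3)
    return Trajectory(frames=frames, dt=dt_ps)


def make_toy_complex(n_domains: int = 2, charges=(+1.0, -1.0),
                     separation: float = 10.0, beads_per_domain: int = 1,
                     ring_radius: float = 5.0):
    """Toy charged complex: ``n_domains`` chains of beads with known COMs
    (spaced ``separation`` A along x), total charges, and radii of gyration
    (0 for single beads, = ``ring_radius`` for rings).  Returns the structure
    and a one-site-per-domain :class:`~formincg.edcg.CGMapping`."""
    from .edcg import CGMapping
    charges = np.asarray(charges, dtype=float)
    if len(charges) != n_domains:
        raise ValueError("need one charge per domain")
    if beads_per_domain < 1 or separation <= 0:
        raise ValueError("unphysical toy-complex parameters")
    chains = _chain_ids(n_domains)
    rows = {k: [] for k in ("name", "el", "res", "rid", "ch")}
    coords = []
    for d in range(n_domains):
        center = np.array([d * separation, 0.0, 0.0])
        if beads_per_domain == 1:
            pts = center[None, :]
        else:
            ang = 2 * np.pi * np.arange(beads_per_domain) / beads_per_domain
            pts = center + ring_radius * np.column_stack(
                [np.zeros_like(ang), np.cos(ang), np.sin(ang)])
        coords.append(pts)
        for b in range(beads_per_domain):
            rows["name"].append("CA")
            rows["el"].append("C")
            rows["res"].append("GLY")
            rows["rid"].append(b + 1)
            rows["ch"].append(chains[d])
    structure = AtomicStructure(
        atom_name=np.array(rows["name"], "U4"), element=np.array(rows["el"], "U2"),
        res_name=np.array(rows["res"], "U4"), res_id=np.array(rows["rid"]),
        chain_id=np.array(rows["ch"], "U4"), coords=np.vstack(coords),
        roles={chains[d]: "other" for d in range(n_domains)},
        title="toy charged complex",
    )
    segments = [(chains[d], 1, beads_per_domain, d) for d in range(n_domains)]
    mapping = CGMapping(segments=segments, charge=charges.copy(),
                        mass=np.full(n_domains, 100.0 * beads_per_domain),
                        sigma=np.full(n_domains, max(ring_radius if beads_per_domain > 1 else 1.0, 1.0)))
    return structure, mapping


def synthesize_twist_series(mean_deg: float, sd_deg: float, duration_ns: float = 50.0,
                            dt_ps: float = 40.0, tau_ps: float = 40.0,
                            seed: int = 0):
    """Stationary AR(1) twist-angle series (deg): Gaussian marginal with the
    requested mean and SD, exponential autocorrelation time ``tau_ps``.
    Emulates the published per-interface angle-vs-time tables (40 or 20 ps
    sampling); synthetic stand-in, not the published data."""
    import pandas as pd
    n = int(round(duration_ns * 1000.0 / dt_ps)) + 1
    rho = np.exp(-dt_ps / tau_ps)
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(mean_deg, sd_deg)
    innov = rng.normal(0.0, sd_deg * np.sqrt(1 - rho * rho), size=n - 1)
    for i in range(1, n):
        x[i] = mean_deg + rho * (x[i - 1] - mean_deg) + innov[i - 1]
    return pd.DataFrame({"time_ns": np.arange(n) * dt_ps / 1000.0, "angle_deg": x})
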