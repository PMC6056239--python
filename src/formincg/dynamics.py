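"""Langevin NVT dynamics and well-tempered / metabasin metadynamics.

Integration uses BAOAB splitting at 310 K with a 1000 fs damping time by
default (friction gamma = 1/damping).  The default 10 fs timestep is
validated against the stiffest spring (ts <= 0.1 * 2 pi sqrt(m_min/k_max)).
The metadynamics bias deposits Gaussian hills (initial height 0.001
kcal/mol, width 0.3 A, pace 50 fs, well-tempered bias factor 10) on a
discretized CV grid; the metabasin variant confines deposition to the
connected free-energy basin within a 6 kcal/mol offset of the running
minimum, re-evaluated every 100 ps when the exterior bias has drifted by
0.5 kcal/mol.  All randomness flows from the explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .constants import KB, KCAL_PER_MOL_IN_MD_UNITS as MDU
from .forcefield import system_energy_forces
from .structure import Trajectory


@dataclass
class SimParams:
    temperature: float = 310.0     # K
    damping_fs: float = 1000.0     # Langevin damping time; None -> NVE
    timestep_fs: float = 10.0
    n_steps: int = 1000
    seed: int = 0
    stride: int = 10               # save every `stride` steps
    init_velocities: bool = True   # Maxwell-Boltzmann draw at `temperature`

    def __post_init__(self):
        if self.timestep_fs <= 0 or self.n_steps < 0 or self.stride < 1:
            raise ValueError("invalid simulation parameters")

    @property
    def gamma(self) -> float:
        return 0.0 if self.damping_fs is None else 1.0 / self.damping_fs


@dataclass
class CGSystem:
    """Everything the integrator needs: masses, positions and force terms."""

    positions: np.ndarray
    masses: np.ndarray
    network: object | None = None          # ElasticNetwork (bonded springs)
    forcefield: object | None = None       # CGForceField (nonbonded)
    external: object | None = None         # callable positions -> (U, F)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.masses = np.asarray(self.masses, float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        self._pairs = (self.forcefield.nonbonded_pairs()
                       if self.forcefield is not None else None)

    def energy_forces(self, positions):
        return system_energy_forces(self.forcefield, self.network, positions,
                                    pairs=self._pairs, external=self.external)


def check_timestep(system: CGSystem, params: SimParams) -> None:
    net = system.network
    if net is None or net.n_bonds == 0 or net.k.max() == 0:
        return
    k_max = net.k.max() * MDU              # amu / fs^2
    m_min = system.masses.min()
    bound = 0.1 * 2.0 * np.pi * np.sqrt(m_min / k_max)
    if params.timestep_fs > bound:
        raise ValueError(f"timestep {params.timestep_fs} fs exceeds stability "
                         f"bound {bound:.2f} fs for the stiffest spring")


@dataclass
class CVSpec:
    """A collective variable: COM distance between two site groups, or the
    projection of a group COM onto a fixed axis."""

    kind: str                       # "com_distance" | "axis_position"
    group_a: np.ndarray
    group_b: np.ndarray | None = None
    axis_origin: np.ndarray | None = None
    axis_dir: np.ndarray | None = None
    label: str = "CV"

    def __post_init__(self):
        self.group_a = np.asarray(self.group_a, int)
        if self.kind == "com_distance":
            self.group_b = np.asarray(self.group_b, int)
            if self.group_a.size == 0 or self.group_b.size == 0:
                raise ValueError("CV groups must be non-empty")
        elif self.kind == "axis_position":
            self.axis_origin = np.asarray(self.axis_origin, float)
            d = np.asarray(self.axis_dir, float)
            self.axis_dir = d / np.linalg.norm(d)
        else:
            raise ValueError(f"unknown CV kind {self.kind!r}")


def cv_value(positions, masses, cv: CVSpec) -> float:
    """Evaluate a CV (A) at the given positions (mass-weighted COMs)."""
    w_a = masses[cv.group_a]
    com_a = w_a @ positions[cv.group_a] / w_a.sum()
    if cv.kind == "com_distance":
        w_b = masses[cv.group_b]
        com_b = w_b @ positions[cv.group_b] / w_b.sum()
        return float(np.linalg.norm(com_a - com_b))
    return float((com_a - cv.axis_origin) @ cv.axis_dir)


def _cv_gradient(positions, masses, cv: CVSpec):
    """(value, dvalue/dpositions) for the bias chain rule."""
    grad = np.zeros_like(positions)
    w_a = masses[cv.group_a]
    com_a = w_a @ positions[cv.group_a] / w_a.sum()
    if cv.kind == "com_distance":
        w_b = masses[cv.group_b]
        com_b = w_b @ positions[cv.group_b] / w_b.sum()
        diff = com_a - com_b
        s = np.linalg.norm(diff)
        u = diff / s if s > 0 else np.zeros(3)
        grad[cv.group_a] = (w_a / w_a.sum())[:, None] * u
        grad[cv.group_b] = -(w_b / w_b.sum())[:, None] * u
        return float(s), grad
    grad[cv.group_a] = (w_a / w_a.sum())[:, None] * cv.axis_dir
    return float((com_a - cv.axis_origin) @ cv.axis_dir), grad


@dataclass
class BiasState:
    """Well-tempered bias accumulated on a 1-D or 2-D CV grid."""

    grid_min: tuple
    grid_max: tuple
    spacing: float = 0.1            # A
    w0: float = 0.001               # initial hill height, kcal/mol
    width: float = 0.3              # hill sigma, A
    pace_fs: float = 50.0
    bias_factor: float = 10.0       # gamma_b; np.inf -> standard metadynamics
    metabasin: bool = False
    domain_offset: float = 6.0      # kcal/mol
    domain_update_ps: float = 100.0
    exterior_threshold: float = 0.5  # kcal/mol
    hill_trunc: float = 4.0         # truncate hills at this many sigma

    axes: tuple = field(init=False)
    V: np.ndarray = field(init=False)
    domain: np.ndarray | None = field(init=False, default=None)
    hills: list = field(default_factory=list, init=False)
    _exterior_ref: np.ndarray | None = field(init=False, default=None)

    def __post_init__(self):
        self.grid_min = tuple(np.atleast_1d(self.grid_min).astype(float))
        self.grid_max = tuple(np.atleast_1d(self.grid_max).astype(float))
        if len(self.grid_min) not in (1, 2):
            raise ValueError("bias supports 1 or 2 CVs")
        self._rebuild_axes()

    def _rebuild_axes(self, keep_V=None):
        axes = []
        for d, (lo, hi) in enumerate(zip(self.grid_min, self.grid_max)):
            if keep_V is not None:
                n = keep_V.shape[d]
            else:
                n = int(np.ceil((hi - lo) / self.spacing)) + 1
            axes.append(lo + self.spacing * np.arange(n))
        self.axes = tuple(axes)
        self.grid_max = tuple(a[-1] for a in axes)
        self.V = np.zeros(tuple(len(a) for a in axes)) if keep_V is None else keep_V

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def _index(self, s):
        return tuple(int(round((si - ax[0]) / self.spacing))
                     for si, ax in zip(np.atleast_1d(s), self.axes))

    def _ensure_covers(self, s):
        s = np.atleast_1d(s)
        pad_lo = [0] * self.ndim
        pad_hi = [0] * self.ndim
        grew = False
        for d in range(self.ndim):
            margin = self.hill_trunc * self.width
            while s[d] - margin < self.axes[d][0] - pad_lo[d] * self.spacing:
                pad_lo[d] += int(np.ceil(margin / self.spacing)) + 1
                grew = True
            while s[d] + margin > self.axes[d][-1] + pad_hi[d] * self.spacing:
                pad_hi[d] += int(np.ceil(margin / self.spacing)) + 1
                grew = True
        if grew:
            warnings.warn("CV left the bias grid; extending grid")
            self.grid_min = tuple(self.axes[d][0] - pad_lo[d] * self.spacing
                                  for d in range(self.ndim))
            self.grid_max = tuple(self.axes[d][-1] + pad_hi[d] * self.spacing
                                  for d in range(self.ndim))
            V = np.pad(self.V, list(zip(pad_lo, pad_hi)), mode="edge")
            dom = self.domain
            self._rebuild_axes(keep_V=V)
            if dom is not None:
                self.domain = np.pad(dom, list(zip(pad_lo, pad_hi)),
                                     constant_values=False)
            self._exterior_ref = None  # stale after a grid change

    def bias_value(self, s) -> float:
        idx = self._index(s)
        return float(self.V[idx])

    def bias_gradient(self, s) -> np.ndarray:
        """Central-difference dV/ds at the nearest grid cell (domain boundary
        is held flat: no bias force pushes the walker from outside values)."""
        idx = self._index(s)
        g = np.zeros(self.ndim)
        for d in range(self.ndim):
            lo = list(idx)
            hi = list(idx)
            lo[d] = max(idx[d] - 1, 0)
            hi[d] = min(idx[d] + 1, self.V.shape[d] - 1)
            denom = (hi[d] - lo[d]) * self.spacing
            if denom > 0:
                g[d] = (self.V[tuple(hi)] - self.V[tuple(lo)]) / denom
        return g

    def in_domain(self, s) -> bool:
        if not self.metabasin or self.domain is None:
            return True
        return bool(self.domain[self._index(s)])

    def deposit(self, s, time_fs: float) -> float | None:
        """Deposit a well-tempered hill at CV point ``s``; returns the height
        actually deposited, or None if outside the metabasin domain."""
        s = np.atleast_1d(np.asarray(s, float))
        self._ensure_covers(s)
        if not self.in_domain(s):
            return None
        v_here = self.bias_value(s)
        if np.isinf(self.bias_factor):
            h = self.w0
        else:
            if self._wt_delta_T <= 0:
                raise RuntimeError("call set_temperature() before depositing hills")
            h = self.w0 * np.exp(-v_here / (KB * self._wt_delta_T))
        window = []
        for d in range(self.ndim):
            ax = self.axes[d]
            lo = np.searchsorted(ax, s[d] - self.hill_trunc * self.width)
            hi = np.searchsorted(ax, s[d] + self.hill_trunc * self.width)
            window.append((lo, min(hi + 1, len(ax))))
        sub = [self.axes[d][window[d][0]:window[d][1]] for d in range(self.ndim)]
        if self.ndim == 1:
            g = h * np.exp(-0.5 * ((sub[0] - s[0]) / self.width) ** 2)
            self.V[window[0][0]:window[0][1]] += g
        else:
            gx = np.exp(-0.5 * ((sub[0] - s[0]) / self.width) ** 2)
            gy = np.exp(-0.5 * ((sub[1] - s[1]) / self.width) ** 2)
            self.V[window[0][0]:window[0][1], window[1][0]:window[1][1]] += \
                h * np.outer(gx, gy)
        self.hills.append((time_fs, *s, self.width, h))
        return float(h)

    _wt_delta_T: float = field(init=False, default=0.0)

    def set_temperature(self, temperature: float) -> None:
        """Fix the well-tempered Delta T = (gamma_b - 1) T before a run."""
        if np.isinf(self.bias_factor):
            self._wt_delta_T = np.inf
        else:
            if self.bias_factor <= 1:
                raise ValueError("bias factor must exceed 1")
            self._wt_delta_T = (self.bias_factor - 1.0) * temperature

    def update_domain(self, s, time_ps: float, force: bool = False) -> bool:
        """Recompute the metabasin domain around the walker: the connected
        CV region whose estimated free energy lies within ``domain_offset``
        of the basin minimum.  Skipped unless the bias outside the current
        domain changed by at least ``exterior_threshold`` since last update.
        """
        if not self.metabasin:
            return False
        if self.domain is not None and not force and self._exterior_ref is not None:
            exterior = ~self.domain
            if exterior.any():
                drift = np.abs(self.V[exterior] - self._exterior_ref).max()
                if drift < self.exterior_threshold:
                    return False
        factor = 1.0 if np.isinf(self.bias_factor) else \
            self.bias_factor / (self.bias_factor - 1.0)
        F = -factor * self.V
        level = F.min() + self.domain_offset
        candidate = F <= level
        labels, _ = ndimage.label(candidate)
        walker = labels[self._index(np.atleast_1d(s))]
        self.domain = labels == walker if walker > 0 else candidate
        self._exterior_ref = self.V[~self.domain].copy()
        return True

    def hill_log(self):
        import pandas as pd
        cols = ["time_fs"] + [f"s{d}" for d in range(self.ndim)] + ["width", "height"]
        return pd.DataFrame(self.hills, columns=cols)


def fes_estimate(bias: BiasState):
    """Free-energy surface from the accumulated bias:
    F(s) = -(gamma_b/(gamma_b - 1)) V(s), shifted so min F = 0.
    Returns (grid axes, F array in kcal/mol)."""
    factor = 1.0 if np.isinf(bias.bias_factor) else \
        bias.bias_factor / (bias.bias_factor - 1.0)
    F = -factor * bias.V
    return bias.axes, F - F.min()


def _integrate(system: CGSystem, params: SimParams, bias=None, cvs=None):
    check_timestep(system, params)
    rng = np.random.default_rng(params.seed)
    x = system.positions.copy()
    m = system.masses[:, None]
    dt = params.timestep_fs
    n_sites = x.shape[0]

    if params.init_velocities and params.temperature > 0:
        v = rng.standard_normal(x.shape) * np.sqrt(KB * params.temperature * MDU / m)
    else:
        v = np.zeros_like(x)

    gamma = params.gamma
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KB * params.temperature * MDU / m) \
        if gamma > 0 else np.zeros_like(m)

    if bias is not None:
        bias.set_temperature(params.temperature)
        pace_steps = int(round(bias.pace_fs / dt))
        if abs(pace_steps * dt - bias.pace_fs) > 1e-9 or pace_steps < 1:
            raise ValueError("hill pace must be a positive multiple of the timestep")
        domain_steps = max(int(round(bias.domain_update_ps * 1000.0 / dt)), 1)

    def total_force(pos):
        rep, f = system.energy_forces(pos)
        if bias is not None:
            svals, grads = [], []
            for cv in cvs:
                s, grad = _cv_gradient(pos, system.masses, cv)
                svals.append(s)
                grads.append(grad)
            svals = np.array(svals)
            g = bias.bias_gradient(svals)
            for d in range(len(cvs)):
                f -= g[d] * grads[d]
            return rep, f, svals
        return rep, f, None

    n_saved = params.n_steps // params.stride + 1
    frames = np.empty((n_saved, n_sites, 3))
    temps = np.empty(n_saved)
    pots = np.empty(n_saved)
    cv_series = np.empty((n_saved, len(cvs))) if bias is not None else None

    rep, F, svals = total_force(x)
    acc = F * MDU / m

    def record(slot):
        frames[slot] = x
        ke = 0.5 * float(np.sum(system.masses * np.sum(v * v, axis=1)))
        temps[slot] = 2.0 * ke / (3.0 * n_sites * KB * MDU)
        pots[slot] = rep.U_total
        if cv_series is not None:
            cv_series[slot] = svals

    record(0)
    slot = 1
    for step in range(1, params.n_steps + 1):
        v = v + 0.5 * dt * acc                 # B
        x = x + 0.5 * dt * v                   # A
        if gamma > 0:                          # O
            v = c1 * v + c2 * rng.standard_normal(v.shape)
        x = x + 0.5 * dt * v                   # A
        rep, F, svals = total_force(x)
        acc = F * MDU / m
        v = v + 0.5 * dt * acc                 # B
        if bias is not None:
            if step % pace_steps == 0:
                bias.deposit(svals, step * dt)
            if bias.metabasin and step % domain_steps == 0:
                bias.update_domain(svals, step * dt / 1000.0)
        if step % params.stride == 0:
            record(slot)
            slot += 1

    traj = Trajectory(frames=frames, dt=params.stride * dt / 1000.0)
    series = {"time_ps": traj.times_ps, "T_kin": temps, "U_pot": pots}
    if cv_series is not None:
        series["cv"] = cv_series
    return traj, series


def run_langevin(system: CGSystem, params: SimParams):
    """Langevin NVT (or NVE when damping is None).  Returns (trajectory,
    series dict with kinetic temperature and potential energy)."""
    return _integrate(system, params)


def run_metadynamics(system: CGSystem, params: SimParams, cvs, bias: BiasState):
    """Well-tempered (optionally metabasin-restricted) metadynamics.
    Returns (trajectory, bias with deposited hills, series dict)."""
    cvs = list(cvs)
    if len(cvs) != bias.ndim:
        raise ValueError("number of CVs must match bias grid dimension")
    traj, series = _integrate(system, params, bias=bias, cvs=cvs)
    return traj, bias, series
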