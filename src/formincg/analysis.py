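"""Barbed-end gating observables.

Twist angles between consecutive actin subunits (total rotation angle of the
least-squares inter-subunit superposition, reported as a magnitude in
(0, 180] deg), steric-overlap volume fractions (C-alpha pairs closer than
4 A, strict), residue contacts (C-alpha pairs within 12 A, inclusive),
salt-bridge occupancies (basic N to acidic O within 4 A, inclusive), buried
surface area, RMSD/RMSF, FH2 center-of-mass radial shifts relative to the
filament axis, and ideal-geometry placement of the incoming actin subunit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (ACIDIC_OXYGEN_ATOMS, BASIC_NITROGEN_ATOMS,
                        DEFAULT_VDW_RADIUS, HIS_NITROGEN_ATOMS, VDW_RADII)
from .geometry import kabsch, principal_axis, rotation_angle_deg, screw_transform
from .structure import AtomGroup, AtomicStructure, Trajectory


# -- helical twist -----------------------------------------------------------

def twist_angle(coords_i: np.ndarray, coords_j: np.ndarray) -> float:
    """Rotation angle (deg) of the rigid transform superposing subunit j
    onto subunit i, theta = arccos((tr R - 1)/2) in (0, 180]; an identity
    transform (pure translation) reports 0."""
    R, _ = kabsch(np.asarray(coords_i, float), np.asarray(coords_j, float))
    return rotation_angle_deg(R)


def twist_series(traj: Trajectory, structure: AtomicStructure,
                 pairs=None) -> pd.DataFrame:
    """Per-interface twist angle vs time (ns) for labeled subunit pairs.

    ``pairs`` defaults to every consecutive (A_i, A_{i+1}) present; columns
    are named ``twist_A1-A2`` etc.  Subunits must share residue numbering so
    C-alpha correspondences are positional.
    """
    roles = sorted((r for r in structure.roles.values() if r.startswith("A")),
                   key=lambda r: int(r[1:]))
    if pairs is None:
        pairs = [(roles[i], roles[i + 1]) for i in range(len(roles) - 1)]
    groups = {}
    for a, b in pairs:
        for role in (a, b):
            if role not in groups:
                groups[role] = structure.select(role=role, atoms="calpha")
    sizes = {len(groups[r]) for r in groups}
    if len(sizes) != 1:
        raise ValueError("subunits have differing C-alpha counts; no correspondence")
    out = {"time_ns": traj.times_ns}
    for a, b in pairs:
        ia, ib = groups[a].indices, groups[b].indices
        out[f"twist_{a}-{b}"] = [twist_angle(traj.frames[f][ia], traj.frames[f][ib])
                                 for f in range(traj.n_frames)]
    return pd.DataFrame(out)


def twist_stats(series: pd.DataFrame, column: str, window=None,
                bin_width: float = 0.5):
    """Mean, population SD, and modal angle (center of the tallest
    ``bin_width``-deg histogram bin; ties resolve to the lower bin) over a
    time window (ns, inclusive)."""
    df = series
    if window is not None:
        lo, hi = window
        df = df[(df["time_ns"] >= lo) & (df["time_ns"] <= hi)]
    if df.empty:
        raise ValueError("empty averaging window")
    x = df[column].to_numpy(float)
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    lo_edge = np.floor(x.min() / bin_width) * bin_width
    nbins = int(np.ceil((x.max() - lo_edge) / bin_width)) + 1
    edges = lo_edge + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    mode = float(edges[np.argmax(counts)] + bin_width / 2.0)
    return {"mean": mean, "sd": sd, "mode": mode, "n": len(x)}


# -- steric overlap ----------------------------------------------------------

def steric_overlap_fraction(blocker_coords, target_coords,
                            threshold: float = 4.0) -> float:
    """Fraction of target C-alpha atoms with at least one blocker C-alpha
    closer than ``threshold`` A (strict <): the volume-fraction proxy for
    occlusion of an incoming subunit's binding site."""
    target = np.asarray(target_coords, float)
    blocker = np.asarray(blocker_coords, float)
    if target.shape[0] == 0:
        raise ValueError("empty target subunit")
    if blocker.shape[0] == 0:
        return 0.0
    d, _ = cKDTree(blocker).query(target, k=1)
    return float(np.mean(d < threshold))


def overlap_series(traj: Trajectory, blocker: AtomGroup, target: AtomGroup,
                   threshold: float = 4.0) -> pd.DataFrame:
    vals = [steric_overlap_fraction(blocker.coords_in(traj.frames[f]),
                                    target.coords_in(traj.frames[f]), threshold)
            for f in range(traj.n_frames)]
    return pd.DataFrame({"time_ns": traj.times_ns, "overlap_fraction": vals})


def fraction_frames_above(series, threshold: float = 0.01,
                          column: str = "overlap_fraction") -> float:
    """Percent of frames whose value strictly exceeds ``threshold``."""
    x = series[column].to_numpy(float) if isinstance(series, pd.DataFrame) \
        else np.asarray(series, float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(100.0 * np.mean(x > threshold))


# -- contacts ----------------------------------------------------------------

def contact_counts(traj: Trajectory, group_a: AtomGroup, group_b: AtomGroup,
                   window=None, threshold: float = 12.0) -> pd.DataFrame:
    """Time-averaged residue-pair contact indicators over a window.

    A pair is in contact in a frame when its C-alpha distance is <= threshold
    (inclusive).  Returns one row per residue pair with the mean indicator;
    per-residue totals follow by summation.
    """
    frames = _window_frames(traj, window)
    if frames.size == 0:
        raise ValueError("empty averaging window")
    ia, ib = group_a.indices, group_b.indices
    acc = np.zeros((len(ia), len(ib)))
    for f in frames:
        a = traj.frames[f][ia]
        b = traj.frames[f][ib]
        d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
        acc += d2 <= threshold * threshold
    acc /= len(frames)
    sa, sb = group_a.structure, group_b.structure
    rows = []
    for p, i in enumerate(ia):
        for q, j in enumerate(ib):
            rows.append((sa.chain_id[i], int(sa.res_id[i]), sa.res_name[i],
                         sb.chain_id[j], int(sb.res_id[j]), sb.res_name[j],
                         acc[p, q]))
    return pd.DataFrame(rows, columns=["chain_a", "res_a", "resname_a",
                                       "chain_b", "res_b", "resname_b",
                                       "contact"])


def _window_frames(traj: Trajectory, window):
    t = traj.times_ns
    if window is None:
        return np.arange(traj.n_frames)
    lo, hi = window
    return np.flatnonzero((t >= lo) & (t <= hi))


# -- salt bridges ------------------------------------------------------------

def _sidechain_atoms(structure, group, table, protonated_his=False):
    """Residue -> atom index list for charged side-chain atoms in a group."""
    out = {}
    idx = group.indices
    names = structure.atom_name[idx]
    resn = structure.res_name[idx]
    for k, i in enumerate(idx):
        wanted = table.get(resn[k], ())
        if protonated_his and resn[k] == "HIS":
            wanted = tuple(wanted) + HIS_NITROGEN_ATOMS
        if names[k] in wanted:
            key = (structure.chain_id[i], int(structure.res_id[i]), resn[k])
            out.setdefault(key, []).append(i)
    return out


def salt_bridge_occupancy(traj: Trajectory, group_a: AtomGroup,
                          group_b: AtomGroup, window=None,
                          criterion: float = 4.0,
                          protonated_his: bool = False) -> pd.DataFrame:
    """Occupancy (percent of frames) of salt bridges between the groups.

    A bridge exists in a frame when any basic side-chain nitrogen (Lys NZ;
    Arg NE/NH1/NH2; His ND1/NE2 if ``protonated_his``) of one residue lies
    within ``criterion`` A (inclusive) of any acidic side-chain oxygen
    (Asp OD1/OD2; Glu OE1/OE2) of the partner.  Both donor->acceptor
    directions across the two groups are scanned.
    """
    frames = _window_frames(traj, window)
    if frames.size == 0:
        raise ValueError("empty averaging window")
    s = group_a.structure
    pairs = []
    for basic_grp, acidic_grp in ((group_a, group_b), (group_b, group_a)):
        basics = _sidechain_atoms(s, basic_grp, BASIC_NITROGEN_ATOMS, protonated_his)
        acidics = _sidechain_atoms(s, acidic_grp, ACIDIC_OXYGEN_ATOMS)
        for bres, batoms in basics.items():
            for ares, aatoms in acidics.items():
                pairs.append((bres, ares, np.array(batoms), np.array(aatoms)))
    rows = []
    for bres, ares, batoms, aatoms in pairs:
        present = 0
        for f in frames:
            d = np.linalg.norm(traj.frames[f][batoms][:, None, :] -
                               traj.frames[f][aatoms][None, :, :], axis=2)
            if d.min() <= criterion:
                present += 1
        occ = 100.0 * present / len(frames)
        rows.append((*bres, *ares, occ))
    df = pd.DataFrame(rows, columns=["chain_basic", "res_basic", "resname_basic",
                                     "chain_acidic", "res_acidic", "resname_acidic",
                                     "occupancy"])
    return df[df["occupancy"] > 0].reset_index(drop=True)


# -- buried surface area -----------------------------------------------------

def _element_radii(structure, indices):
    radii = np.empty(len(indices))
    for k, i in enumerate(indices):
        el = structure.element[i].upper()
        radii[k] = VDW_RADII.get(el, DEFAULT_VDW_RADIUS)
    return radii


def sasa(structure: AtomicStructure, group: AtomGroup | None = None,
         probe: float = 1.4, points: int = 960,
         coords: np.ndarray | None = None) -> float:
    """Solvent-accessible surface area (A^2) via spherical point quadrature
    (960 points/atom by default) with per-element van der Waals radii."""
    import biotite.structure as struc
    idx = group.indices if group is not None else np.arange(structure.n_atoms)
    arr = struc.AtomArray(len(idx))
    arr.coord = (structure.coords if coords is None else np.asarray(coords))[idx]
    arr.element = structure.element[idx]
    arr.atom_name = structure.atom_name[idx]
    arr.res_name = structure.res_name[idx]
    arr.res_id = structure.res_id[idx]
    arr.chain_id = np.array([c[:4] for c in structure.chain_id[idx]])
    vals = struc.sasa(arr, probe_radius=probe, point_number=points,
                      vdw_radii=_element_radii(structure, idx))
    return float(np.nansum(vals))


def buried_surface_area(structure: AtomicStructure, group_a: AtomGroup,
                        group_b: AtomGroup, probe: float = 1.4,
                        points: int = 960,
                        coords: np.ndarray | None = None) -> float:
    """BSA = SASA(A) + SASA(B) - SASA(A u B); both buried faces counted."""
    a = sasa(structure, group_a, probe, points, coords)
    b = sasa(structure, group_b, probe, points, coords)
    ab = sasa(structure, group_a | group_b, probe, points, coords)
    return a + b - ab


# -- RMSD / RMSF -------------------------------------------------------------

def rmsd_rmsf(traj: Trajectory, group: AtomGroup,
              reference: np.ndarray | None = None, align: bool = True):
    """RMSD series (A) vs the reference (first frame by default) after
    least-squares superposition, and per-atom RMSF about the aligned mean."""
    X = traj.frames[:, group.indices, :].copy()
    ref = X[0] if reference is None else np.asarray(reference)[group.indices]
    if align:
        for f in range(X.shape[0]):
            R, t = kabsch(ref, X[f])
            X[f] = X[f] @ R.T + t
    rmsd = np.sqrt(np.mean(np.sum((X - ref) ** 2, axis=2), axis=1))
    mean = X.mean(axis=0)
    if align:
        for f in range(X.shape[0]):
            R, t = kabsch(mean, X[f])
            X[f] = X[f] @ R.T + t
        mean = X.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    return rmsd, rmsf


# -- filament axis & COM radial shift ---------------------------------------

def filament_axis(structure: AtomicStructure, subunits=("A3", "A4", "A5", "A6")):
    """Filament axis from interior subunits (mobile end subunits excluded).

    The rotation axis of the screw transform carrying each subunit onto the
    next IS the helix axis; axes from consecutive interior interfaces are
    averaged and a point on the axis solved from (I - R) p = t_perp.
    Returns (point, unit direction), oriented from barbed to pointed end.
    """
    present = [r for r in subunits if r in structure.roles.values()]
    if len(present) < 2:
        raise ValueError("need at least two interior subunits to define the axis")
    present = sorted(present, key=lambda r: int(r[1:]))
    coords = {r: structure.select(role=r, atoms="calpha").coords for r in present}
    from scipy.spatial.transform import Rotation
    axes, points = [], []
    for a, b in zip(present, present[1:]):
        if int(b[1:]) != int(a[1:]) + 1:
            continue
        R, t = kabsch(coords[b], coords[a])  # x_b = R x_a + t
        rotvec = Rotation.from_matrix(R).as_rotvec()
        ang = np.linalg.norm(rotvec)
        if ang < 1e-8:
            continue
        n = rotvec / ang
        t_par = (t @ n) * n
        p, *_ = np.linalg.lstsq(np.eye(3) - R, t - t_par, rcond=None)
        axes.append(n)
        points.append(p)
    if not axes:
        raise ValueError("could not determine a filament axis (degenerate geometry)")
    ref = axes[0]
    axes = [n if n @ ref >= 0 else -n for n in axes]
    n = np.mean(axes, axis=0)
    n /= np.linalg.norm(n)
    point = np.mean(points, axis=0)
    first = coords[present[0]].mean(axis=0)
    last = coords[present[-1]].mean(axis=0)
    if (last - first) @ n < 0:
        n = -n
    return point, n


def com_radial_shift_percent(traj: Trajectory, group: AtomGroup,
                             axis_point, axis_dir,
                             masses: np.ndarray | None = None) -> pd.DataFrame:
    """Percent radial shift of the group COM toward the filament axis:
    100 * (r(0) - r(t)) / r(0); positive = toward the axis (closed-state
    direction), motion parallel to the axis contributes nothing."""
    axis_point = np.asarray(axis_point, float)
    n = np.asarray(axis_dir, float)
    n = n / np.linalg.norm(n)
    if masses is None:
        w = np.ones(len(group))
    else:
        w = np.asarray(masses, float)[group.indices]
    w = w / w.sum()
    coms = np.einsum("fia,i->fa", traj.frames[:, group.indices, :], w)
    rel = coms - axis_point
    perp = rel - np.outer(rel @ n, n)
    r = np.linalg.norm(perp, axis=1)
    if r[0] == 0:
        raise ValueError("group COM starts on the filament axis")
    return pd.DataFrame({"time_ns": traj.times_ns,
                         "radial_shift_percent": 100.0 * (r[0] - r) / r[0]})


# -- incoming-subunit placement ---------------------------------------------

def place_incoming_subunit(structure: AtomicStructure, twist_deg: float,
                           rise: float, reference_pair=("A2", "A3"),
                           subunits_for_axis=None) -> np.ndarray:
    """Coordinates for the incoming actin subunit (+A1/A1) from ideal
    filament geometry.

    The screw transform with the configured twist/rise about the filament
    axis is oriented so it maps the A3 C-alphas onto A2 (the barbed-end
    direction), then applied to A2 to generate the next subunit's position.
    """
    a2, a3 = reference_pair
    g2 = structure.select(role=a2, atoms="calpha")
    g3 = structure.select(role=a3, atoms="calpha")
    if len(g2) != len(g3):
        raise ValueError("reference subunits have no positional correspondence")
    if subunits_for_axis is None:
        roles = sorted((r for r in structure.roles.values() if r.startswith("A")),
                       key=lambda r: int(r[1:]))
        subunits_for_axis = roles
    point, axis = filament_axis(structure, subunits_for_axis)
    best = None
    for sign_a in (+1.0, -1.0):
        for sign_r in (+1.0, -1.0):
            R, t = screw_transform(point, axis, sign_a * twist_deg, sign_r * rise)
            moved = g3.coords @ R.T + t
            err = float(np.sqrt(np.mean(np.sum((moved - g2.coords) ** 2, axis=1))))
            if best is None or err < best[0]:
                best = (err, R, t)
    _, R, t = best
    return g2.coords @ R.T + t
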