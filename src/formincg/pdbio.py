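"""Fixed-column PDB reading and writing.

Dialect: only the first alternate location of an atom is kept; insertion
codes are carried alongside the integer residue number; HETATM records are
skipped unless requested (ligands such as ADP/Mg are irrelevant to the
C-alpha-based analyses this package performs).  Multi-MODEL files can be
read as a :class:`~formincg.structure.Trajectory`, and a plain per-frame
coordinate table is supported as a lightweight trajectory format.
"""

from __future__ import annotations

import os

import numpy as np

from .structure import AtomicStructure, Trajectory


def _parse_atom_line(line: str, lineno: int):
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ValueError(f"malformed coordinate field on line {lineno}: {line.rstrip()!r}") from exc
    name = line[12:16].strip()
    altloc = line[16].strip()
    res_name = line[17:20].strip()
    chain = line[21].strip() or "A"
    try:
        res_id = int(line[22:26])
    except ValueError as exc:
        raise ValueError(f"malformed residue number on line {lineno}") from exc
    icode = line[26].strip()
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]
    return name, altloc, res_name, chain, res_id, icode, element, (x, y, z)


def _records_to_structure(records, title="") -> AtomicStructure:
    if not records:
        raise ValueError("no parsable ATOM records")
    cols = list(zip(*records))
    return AtomicStructure(
        atom_name=np.array(cols[0], dtype="U4"),
        element=np.array(cols[1], dtype="U2"),
        res_name=np.array(cols[2], dtype="U4"),
        res_id=np.array(cols[3], dtype=int),
        chain_id=np.array(cols[4], dtype="U4"),
        coords=np.array(cols[5], dtype=float),
        ins_code=np.array(cols[6], dtype="U1"),
        title=title,
    )


def _read_models(path, include_hetatm=False):
    """Parse a PDB file into per-model record lists."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    models: list[list] = [[]]
    seen_altloc: set = set()
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL ":
                if models[-1]:
                    models.append([])
                seen_altloc = set()
            elif rec == "ATOM  " or (include_hetatm and rec == "HETATM"):
                name, altloc, res_name, chain, res_id, icode, element, xyz = \
                    _parse_atom_line(line, lineno)
                if altloc:
                    key = (chain, res_id, icode, name)
                    if key in seen_altloc:
                        continue  # keep only the first altloc
                    seen_altloc.add(key)
                models[-1].append((name, element, res_name, res_id, chain, xyz, icode))
    models = [m for m in models if m]
    if not models:
        raise ValueError(f"no parsable ATOM records in {path}")
    return models, title


def read_pdb(path, include_hetatm: bool = False) -> AtomicStructure:
    """Read the first model of a PDB file into an :class:`AtomicStructure`."""
    models, title = _read_models(path, include_hetatm)
    return _records_to_structure(models[0], title)


def read_pdb_trajectory(path, dt: float = 1.0, t0: float = 0.0,
                        include_hetatm: bool = False) -> Trajectory:
    """Read a multi-MODEL PDB as a trajectory (dt/t0 in ps, caller-supplied)."""
    models, title = _read_models(path, include_hetatm)
    ref = _records_to_structure(models[0], title)
    frames = np.empty((len(models), ref.n_atoms, 3))
    for i, m in enumerate(models):
        if len(m) != ref.n_atoms:
            raise ValueError(f"model {i + 1} has {len(m)} atoms, expected {ref.n_atoms}")
        frames[i] = [rec[5] for rec in m]
    return Trajectory(frames=frames, dt=dt, t0=t0, reference=ref)


def _format_atom_line(serial, name, res_name, chain, res_id, icode, xyz, element):
    # PDB convention: 1-3 character names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"ATOM  {serial:>5d} {name_field}{'':1s}{res_name:>3.3s} {chain:1.1s}"
            f"{res_id:>4d}{icode:1.1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2.2s}\n")


def write_pdb(structure: AtomicStructure, path) -> None:
    """Write a structure as fixed-column PDB, re-readable by :func:`read_pdb`."""
    if structure.n_atoms == 0:
        raise ValueError("refusing to write a structure with zero atoms")
    structure.validate()
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        _write_model(fh, structure, structure.coords)
        fh.write("END\n")


def write_pdb_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-MODEL PDB (requires a reference structure)."""
    if traj.reference is None:
        raise ValueError("trajectory has no reference structure")
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:>4d}\n")
            _write_model(fh, traj.reference, traj.frames[i])
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_model(fh, s: AtomicStructure, coords) -> None:
    prev_chain = None
    serial = 0
    for i in range(s.n_atoms):
        if prev_chain is not None and s.chain_id[i] != prev_chain:
            fh.write("TER\n")
        prev_chain = s.chain_id[i]
        serial += 1
        fh.write(_format_atom_line(serial, s.atom_name[i], s.res_name[i],
                                   s.chain_id[i], s.res_id[i], s.ins_code[i],
                                   coords[i], s.element[i]))


def write_coord_table(traj: Trajectory, path) -> None:
    """Plain whitespace-delimited trajectory: one row per atom per frame."""
    with open(path, "w") as fh:
        fh.write(f"# n_frames {traj.n_frames} n_atoms {traj.n_atoms} "
                 f"dt_ps {traj.dt} t0_ps {traj.t0}\n")
        fh.write("# frame atom x y z\n")
        for f in range(traj.n_frames):
            for a in range(traj.n_atoms):
                x, y, z = traj.frames[f, a]
                fh.write(f"{f} {a} {x:.6f} {y:.6f} {z:.6f}\n")


def read_coord_table(path) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().split()
    n_frames, n_atoms = int(header[2]), int(header[4])
    dt, t0 = float(header[6]), float(header[8])
    data = np.loadtxt(path, comments="#")
    frames = data[:, 2:5].reshape(n_frames, n_atoms, 3)
    return Trajectory(frames=frames, dt=dt, t0=t0)
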