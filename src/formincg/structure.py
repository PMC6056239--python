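"""In-memory containers for atomic structures, trajectories and selections.

The filament naming convention used throughout: actin subunits are labeled
``A1`` (barbed end, fast-growing) through ``A7`` (pointed-end side), the
leading FH2 chain is ``FHL`` and the trailing chain is ``FHT``.  Roles map
one-to-one onto PDB chain identifiers and can be assigned explicitly or by
the geometric heuristic in :func:`assign_roles`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FILAMENT_ROLES = tuple(f"A{i}" for i in range(1, 10))
FORMIN_ROLES = ("FHL", "FHT")


@dataclass
class AtomicStructure:
    """A flat atom table with chain/residue metadata and A coordinates.

    Attributes
    ----------
    atom_name, element, res_name : str arrays of length n_atoms
    res_id : int array (author residue numbers; insertion codes kept
        separately in ``ins_code``)
    chain_id : str array
    coords : (n_atoms, 3) float array, angstrom
    roles : dict mapping chain_id -> role label (``A1`` ... ``FHT``);
        each role maps to exactly one chain
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    ins_code: np.ndarray | None = None
    roles: dict = field(default_factory=dict)
    title: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        n = self.coords.shape[0]
        for name in ("atom_name", "element", "res_name", "res_id", "chain_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != n_atoms {n}")
            setattr(self, name, arr)
        if self.ins_code is None:
            self.ins_code = np.full(n, "", dtype="U1")
        self.res_id = self.res_id.astype(int)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        """Raise ValueError on non-finite coordinates, non-monotone residue
        numbering within a chain, or a role mapped to several chains."""
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for cid in self.chains():
            rid = self.res_id[self.chain_id == cid]
            if np.any(np.diff(rid) < 0):
                raise ValueError(f"residue numbers decrease within chain {cid!r}")
        seen: dict[str, str] = {}
        for cid, role in self.roles.items():
            if role in seen:
                raise ValueError(f"role {role!r} mapped to chains {seen[role]!r} and {cid!r}")
            seen[role] = cid

    def chains(self) -> list[str]:
        """Chain ids in first-appearance order."""
        _, idx = np.unique(self.chain_id, return_index=True)
        return list(self.chain_id[np.sort(idx)])

    def chain_of(self, role: str) -> str:
        for cid, r in self.roles.items():
            if r == role:
                return cid
        raise KeyError(f"unknown role label {role!r}; known: {sorted(self.roles.values())}")

    def role_of(self, chain: str) -> str:
        return self.roles.get(chain, "other")

    def copy(self) -> "AtomicStructure":
        return AtomicStructure(
            atom_name=self.atom_name.copy(), element=self.element.copy(),
            res_name=self.res_name.copy(), res_id=self.res_id.copy(),
            chain_id=self.chain_id.copy(), coords=self.coords.copy(),
            ins_code=self.ins_code.copy(), roles=dict(self.roles), title=self.title,
        )

    # -- selection ---------------------------------------------------------
    def select(self, role: str | None = None, chain: str | None = None,
               residues: tuple[int, int] | None = None,
               atoms: str | list | None = None,
               label: str | None = None) -> "AtomGroup":
        """Select atoms by role, chain, inclusive residue range and atom name.

        ``atoms='calpha'`` keeps exactly one CA atom per amino-acid residue;
        a string selects that atom name; a list selects any of the names.
        Filters combine by intersection.  An empty result is returned as an
        empty group, not an error; an unknown role label raises KeyError.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if role is not None:
            chain = self.chain_of(role)
        if chain is not None:
            mask &= self.chain_id == chain
        if residues is not None:
            lo, hi = residues
            mask &= (self.res_id >= lo) & (self.res_id <= hi)
        if atoms is not None:
            if atoms == "calpha":
                mask &= self.atom_name == "CA"
            elif isinstance(atoms, str):
                mask &= self.atom_name == atoms
            else:
                mask &= np.isin(self.atom_name, list(atoms))
        if label is None:
            parts = [p for p in (role or chain, atoms if isinstance(atoms, str) else None) if p]
            label = ":".join(parts)
        return AtomGroup(self, np.flatnonzero(mask), label)


@dataclass
class AtomGroup:
    """An ordered, duplicate-free index set into an :class:`AtomicStructure`."""

    structure: AtomicStructure
    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and (self.indices.min() < 0 or
                                  self.indices.max() >= self.structure.n_atoms):
            raise IndexError("atom index out of range")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("duplicate atom indices in group")

    def __len__(self) -> int:
        return len(self.indices)

    def __or__(self, other: "AtomGroup") -> "AtomGroup":
        if other.structure is not self.structure:
            raise ValueError("cannot combine groups over different structures")
        merged = np.union1d(self.indices, other.indices)
        return AtomGroup(self.structure, merged, f"{self.label}|{other.label}")

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords[self.indices]

    def coords_in(self, frame: np.ndarray) -> np.ndarray:
        """Group coordinates taken from an external (n_atoms, 3) frame."""
        return np.asarray(frame)[self.indices]


@dataclass
class Trajectory:
    """Frames sharing one atom order; dt in ps, t0 in ps."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float
    t0: float = 0.0
    reference: AtomicStructure | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    @property
    def times_ns(self) -> np.ndarray:
        return self.times_ps / 1000.0


def assign_roles(structure: AtomicStructure, mapping: dict | None = None,
                 n_actin: int | None = None) -> AtomicStructure:
    """Attach a chain -> role map to ``structure`` (in place; also returned).

    With ``mapping`` given (chain_id -> role), it is validated and used
    verbatim.  Otherwise a geometric heuristic is applied: the ``n_actin``
    chains with the most residues become the filament (ordered along the
    filament axis, barbed end nearest the formin chains), and the two
    remaining chains become FHL/FHT by proximity to A2 vs A3.
    """
    if mapping is not None:
        unknown = set(mapping) - set(structure.chains())
        if unknown:
            raise KeyError(f"role map references unknown chains {sorted(unknown)}")
        structure.roles = dict(mapping)
        structure.validate()
        return structure

    chains = structure.chains()
    if n_actin is None:
        n_actin = len(chains) - 2
    if n_actin < 2 or n_actin > len(chains):
        raise ValueError("cannot infer roles: need at least n_actin + 2 chains")

    def chain_ca(cid):
        sel = (structure.chain_id == cid) & (structure.atom_name == "CA")
        if not sel.any():  # fall back to all atoms for CA-free chains
            sel = structure.chain_id == cid
        return structure.coords[sel]

    # actin subunits share one residue count (the filament repeats), while
    # the two FH2 chains share another; pick the larger group as the filament
    sizes = {c: len(np.unique(structure.res_id[structure.chain_id == c])) for c in chains}
    counts: dict[int, list[str]] = {}
    for c in chains:
        counts.setdefault(sizes[c], []).append(c)
    actin_len = max(counts, key=lambda n: (len(counts[n]), -n))
    actin_chains = counts[actin_len][:n_actin]
    if len(actin_chains) < n_actin:  # fall back to closest-in-size chains
        rest = sorted((c for c in chains if c not in actin_chains),
                      key=lambda c: abs(sizes[c] - actin_len))
        actin_chains += rest[:n_actin - len(actin_chains)]
    formin_chains = [c for c in chains if c not in actin_chains]

    pts = np.vstack([chain_ca(c) for c in actin_chains])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    axis = vt[0]

    proj = {c: float((chain_ca(c).mean(axis=0) - centroid) @ axis) for c in actin_chains}
    ordered = sorted(actin_chains, key=lambda c: proj[c])
    if formin_chains:
        fcom = np.vstack([chain_ca(c) for c in formin_chains]).mean(axis=0)
        fproj = float((fcom - centroid) @ axis)
        # barbed end (A1) is the filament end nearest the FH2 dimer
        if abs(proj[ordered[-1]] - fproj) < abs(proj[ordered[0]] - fproj):
            ordered = ordered[::-1]
    roles = {c: f"A{i + 1}" for i, c in enumerate(ordered)}

    if len(formin_chains) >= 2:
        a2 = chain_ca(ordered[1]).mean(axis=0)
        a3 = chain_ca(ordered[2]).mean(axis=0)
        f0, f1 = formin_chains[:2]
        com0 = chain_ca(f0).mean(axis=0)
        com1 = chain_ca(f1).mean(axis=0)
        # FHL engages A2; FHT engages A3: pick the pairing with smaller
        # total COM distance
        direct = np.linalg.norm(com0 - a2) + np.linalg.norm(com1 - a3)
        swapped = np.linalg.norm(com1 - a2) + np.linalg.norm(com0 - a3)
        if direct <= swapped:
            roles[f0], roles[f1] = "FHL", "FHT"
        else:
            roles[f0], roles[f1] = "FHT", "FHL"
    structure.roles = roles
    structure.validate()
    return structure
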