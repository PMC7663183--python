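"""All-atom structure and trajectory containers plus PDB/xyz readers.

Coordinates are in Å. Residue indices are 0-based per chain and align
with :class:`fabqsar.imgt.ChainSequence` indices, so region annotations
address structure residues directly. Chains are stored under the logical
ids "heavy"/"light"; PDB chain letters are remapped on input (default
H→heavy, L→light).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingRadius

#: Van der Waals radii (Å) by element; pseudo-atoms carry explicit radii.
ELEMENT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}

DEFAULT_CHAIN_MAP = {"H": "heavy", "L": "light"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Structure:
    """Ordered atoms with coordinates, radii and residue assignment."""

    coords: np.ndarray          # (n_atoms, 3) Å
    elements: np.ndarray        # (n_atoms,) str
    radii: np.ndarray           # (n_atoms,) Å
    chain_ids: np.ndarray       # (n_atoms,) "heavy"/"light"
    res_ids: np.ndarray         # (n_atoms,) 0-based per-chain residue index
    res_letters: np.ndarray     # (n_atoms,) one-letter residue codes
    atom_names: np.ndarray = field(default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        n = len(self.coords)
        self.elements = np.asarray(self.elements, dtype=object)
        self.radii = np.asarray(self.radii, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_letters = np.asarray(self.res_letters, dtype=object)
        if self.atom_names is None:
            self.atom_names = np.asarray(["X"] * n, dtype=object)
        for arr in (self.elements, self.radii, self.chain_ids,
                    self.res_ids, self.res_letters, self.atom_names):
            if len(arr) != n:
                raise ValueError("per-atom arrays must share length")
        if np.isnan(self.radii).any() or (self.radii <= 0).any():
            raise MissingRadius("every atom needs a positive radius")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, res_id, letter) keys."""
        seen, out = set(), []
        for c, r, l in zip(self.chain_ids, self.res_ids, self.res_letters):
            key = (c, int(r), l)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def atom_mask(self, chain_id: str | None = None,
                  atom_name: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        return mask

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "Structure":
        return Structure(self.coords @ rotation.T + translation,
                         self.elements, self.radii, self.chain_ids,
                         self.res_ids, self.res_letters, self.atom_names)


@dataclass
class Trajectory:
    """Frame series sharing one set of atom metadata."""

    frames: np.ndarray   # (n_frames, n_atoms, 3) Å
    times: np.ndarray    # (n_frames,) ps, strictly increasing
    template: Structure

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.template.n_atoms:
            raise ValueError("atom count differs from template")
        if len(self.times) != len(self.frames):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        s = self.template
        return Structure(self.frames[i], s.elements, s.radii, s.chain_ids,
                         s.res_ids, s.res_letters, s.atom_names)


def assign_radii(elements, radii_table: dict[str, float] | None = None) -> np.ndarray:
    table = ELEMENT_RADII if radii_table is None else radii_table
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        r = table.get(str(el).upper())
        if r is None:
            raise MissingRadius(f"no radius for element {el!r}")
        out[i] = r
    return out


def _structure_from_atom_array(atoms, chain_map: dict[str, str]) -> Structure:
    chains, res_ids, letters = [], [], []
    per_chain_counter: dict[str, dict[int, int]] = {}
    for cid, rid, rname in zip(atoms.chain_id, atoms.res_id, atoms.res_name):
        logical = chain_map.get(str(cid), str(cid))
        chains.append(logical)
        counter = per_chain_counter.setdefault(logical, {})
        if int(rid) not in counter:
            counter[int(rid)] = len(counter)
        res_ids.append(counter[int(rid)])
        letters.append(_THREE_TO_ONE.get(str(rname).upper(), "G"))
    return Structure(
        coords=np.asarray(atoms.coord, dtype=float),
        elements=np.asarray([str(e).upper() for e in atoms.element], dtype=object),
        radii=assign_radii([str(e).upper() for e in atoms.element]),
        chain_ids=np.asarray(chains, dtype=object),
        res_ids=np.asarray(res_ids, dtype=int),
        res_letters=np.asarray(letters, dtype=object),
        atom_names=np.asarray([str(a) for a in atoms.atom_name], dtype=object),
    )


def read_pdb(path, chain_map: dict[str, str] | None = None) -> Structure:
    """Read a single-model PDB file (ATOM/HETATM records) via biotite."""
    import biotite.structure.io.pdb as pdb

    chain_map = DEFAULT_CHAIN_MAP if chain_map is None else chain_map
    pfile = pdb.PDBFile.read(str(path))
    atoms = pfile.get_structure(model=1)
    return _structure_from_atom_array(atoms, chain_map)


def read_pdb_trajectory(path, dt_ps: float = 40.0,
                        chain_map: dict[str, str] | None = None) -> Trajectory:
    """Read a multi-MODEL PDB as a trajectory (frame i at time i*dt_ps)."""
    import biotite.structure.io.pdb as pdb

    chain_map = DEFAULT_CHAIN_MAP if chain_map is None else chain_map
    pfile = pdb.PDBFile.read(str(path))
    stack = pfile.get_structure()  # AtomArrayStack
    template = _structure_from_atom_array(stack[0], chain_map)
    frames = np.asarray(stack.coord, dtype=float)
    times = np.arange(len(frames), dtype=float) * dt_ps
    return Trajectory(frames=frames, times=times, template=template)


def read_xyz_trajectory(path, template: Structure,
                        dt_ps: float = 40.0) -> Trajectory:
    """Plain whitespace xyz-per-frame format: blank-line-separated blocks of
    "x y z" rows, one row per atom in template order."""
    blocks, current = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if current:
                    blocks.append(current)
                    current = []
                continue
            current.append([float(v) for v in line.split()[:3]])
    if current:
        blocks.append(current)
    frames = np.asarray(blocks, dtype=float)
    times = np.arange(len(frames), dtype=float) * dt_ps
    return Trajectory(frames=frames, times=times, template=template)


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            for x, y, z in frame:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
            fh.write("\n")
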