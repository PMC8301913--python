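"""Structures, trajectories and selections.

Structures are read and written through :mod:`gemmi` (fixed-column PDB,
including CRYST1 cell + space-group symmetry, exposed as orthogonal-frame
operators).  Binary trajectory formats (DCD, XTC) are read through
:mod:`MDAnalysis`; multi-model PDB is supported as a plain-text fallback
trajectory format in both directions.

Author residue numbering is preserved verbatim throughout; a separate
0-based residue index is maintained for matrix work.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    ParseError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "AtomRecord",
    "CrystalSymmetry",
    "Structure",
    "Trajectory",
    "SelectionSpec",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
]

#: default time step (ns/frame) assumed when a trajectory carries no time data
DEFAULT_DT_NS = 0.1

_HYDROGEN = {"H", "D"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom as read from a coordinate file (author numbering kept)."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    coord: np.ndarray  # (3,) Å, model 1
    element: str
    occupancy: float = 1.0
    bfactor: float = 0.0
    icode: str = ""
    het: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.icode)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN


@dataclass(frozen=True)
class CrystalSymmetry:
    """Unit cell plus symmetry operators in the orthogonal (Å) frame."""

    cell: tuple[float, float, float, float, float, float]
    spacegroup: str
    operators: tuple[tuple[np.ndarray, np.ndarray], ...]  # (R 3x3, t 3)

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional-to-orthogonal conversion matrix (columns = cell axes)."""
        return _mat_to_np(gemmi.UnitCell(*self.cell).orth.mat)


@dataclass
class Structure:
    """An ordered atom list with one or more models sharing that atom list."""

    atoms: list[AtomRecord]
    model_coords: np.ndarray  # (M, N, 3) Å
    crystal_symmetry: CrystalSymmetry | None = None
    name: str = ""

    def __post_init__(self):
        self.model_coords = np.asarray(self.model_coords, dtype=float)
        if self.model_coords.ndim == 2:
            self.model_coords = self.model_coords[None]
        if len(self.atoms) == 0:
            raise EmptyStructureError("structure has no atoms")
        if self.model_coords.shape[1] != len(self.atoms):
            raise TopologyError(
                f"{self.model_coords.shape[1]} coordinates for "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.model_coords)):
            raise ParseError("non-finite coordinates in structure")

    # -- basic views --------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_models(self) -> int:
        return self.model_coords.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """Coordinates of the first model, shape (N, 3)."""
        return self.model_coords[0]

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Distinct residues in stable (chain, resid, icode) order."""
        keys = {a.residue_key for a in self.atoms}
        return sorted(keys)

    def atom_residue_index(self) -> tuple[list[tuple[str, int, str]], np.ndarray]:
        """Residue keys plus, per atom, the 0-based index of its residue."""
        keys = self.residue_keys()
        pos = {k: i for i, k in enumerate(keys)}
        return keys, np.array([pos[a.residue_key] for a in self.atoms])

    # -- derived structures -------------------------------------------------

    def subset(self, indices) -> "Structure":
        indices = np.asarray(indices, dtype=int)
        atoms = [
            replace(self.atoms[i], coord=self.model_coords[0, i].copy())
            for i in indices
        ]
        return Structure(
            atoms, self.model_coords[:, indices].copy(), self.crystal_symmetry,
            self.name,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        atoms = [
            replace(a, coord=coords[0, i].copy())
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, coords, self.crystal_symmetry, self.name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply x -> R x + t to every model."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return self.with_coords(self.model_coords @ R.T + t)

    def rename_chains(self, mapping: dict[str, str]) -> "Structure":
        atoms = [
            replace(a, chain=mapping.get(a.chain, a.chain)) for a in self.atoms
        ]
        return Structure(atoms, self.model_coords.copy(), self.crystal_symmetry,
                         self.name)

    def concatenate(self, other: "Structure") -> "Structure":
        if self.n_models != other.n_models:
            raise TopologyError("cannot concatenate structures with "
                                "different model counts")
        atoms = list(self.atoms) + list(other.atoms)
        coords = np.concatenate([self.model_coords, other.model_coords], axis=1)
        return Structure(atoms, coords, self.crystal_symmetry, self.name)


@dataclass
class Trajectory:
    """Ordered frames over a fixed atom set, with a frame-to-time mapping."""

    topology: Structure
    frames: np.ndarray  # (F, N, 3) Å
    dt: float = DEFAULT_DT_NS  # ns per frame

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.shape[0] < 1:
            raise TopologyError("trajectory must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if not self.dt > 0:
            raise TopologyError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in ns."""
        return np.arange(self.n_frames) * self.dt


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_ATOM_CLASSES = ("CA", "heavy", "all")


@dataclass(frozen=True)
class SelectionSpec:
    """Deterministic atom selection over chain / resid range / atom class.

    ``atoms`` is ``"CA"`` (alpha carbons of standard residues), ``"heavy"``
    (non-hydrogen), ``"all"``, or an explicit tuple of atom names.
    """

    chains: tuple[str, ...] | None = None
    resid_min: int | None = None
    resid_max: int | None = None
    atoms: str | tuple[str, ...] = "CA"
    include_het: bool = False

    @classmethod
    def parse(cls, expr: str) -> "SelectionSpec":
        """Parse ``"chain:resid-range:atomclass"``, e.g. ``"A:1-166:CA"``.

        ``*`` (or empty) wildcards a field; a single resid selects that
        residue in isolation (``"A:113:CA"``).
        """
        parts = expr.split(":")
        if len(parts) != 3:
            raise SelectionError(
                f"selection {expr!r} must have three ':'-separated fields"
            )
        chain_s, resid_s, atom_s = (p.strip() for p in parts)
        chains = None if chain_s in ("", "*") else tuple(chain_s.split(","))
        lo = hi = None
        if resid_s not in ("", "*"):
            if "-" in resid_s.lstrip("-"):
                a, b = resid_s.rsplit("-", 1)
                lo, hi = int(a), int(b)
            else:
                lo = hi = int(resid_s)
        atoms: str | tuple[str, ...]
        if atom_s in ("", "*"):
            atoms = "all"
        elif atom_s in _ATOM_CLASSES:
            atoms = atom_s
        else:
            atoms = tuple(atom_s.split(","))
        return cls(chains=chains, resid_min=lo, resid_max=hi, atoms=atoms)

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.resid_min is not None and atom.resid < self.resid_min:
            return False
        if self.resid_max is not None and atom.resid > self.resid_max:
            return False
        if atom.het and not self.include_het and self.atoms in ("CA", "heavy"):
            return False
        if self.atoms == "CA":
            return atom.name == "CA" and atom.element.upper() == "C"
        if self.atoms == "heavy":
            return not atom.is_hydrogen
        if self.atoms == "all":
            return True
        return atom.name in self.atoms


def select(structure: Structure, spec: SelectionSpec | str) -> np.ndarray:
    """Resolve a selection to an ordered, deterministic atom index list.

    Ordering is by (chain, resid, insertion code, file order), so repeated
    calls on the same structure are identical.
    """
    if isinstance(spec, str):
        spec = SelectionSpec.parse(spec)
    hits = [
        (a.chain, a.resid, a.icode, i)
        for i, a in enumerate(structure.atoms)
        if spec.matches(a)
    ]
    if not hits:
        raise EmptySelectionError(f"selection {spec} matched no atoms")
    hits.sort()
    return np.array([h[3] for h in hits], dtype=int)


# ---------------------------------------------------------------------------
# structure I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _mat_to_np(m) -> np.ndarray:
    return np.array(m.tolist(), dtype=float)


def _capture_symmetry(st: gemmi.Structure) -> CrystalSymmetry | None:
    cell = st.cell
    if not cell.is_crystal():
        return None
    sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm or "P 1")
    if sg is None:
        sg = gemmi.find_spacegroup_by_name("P 1")
    orth = _mat_to_np(cell.orth.mat)
    frac = _mat_to_np(cell.frac.mat)
    ops = []
    for op in sg.operations():
        R_frac = np.array(op.rot, dtype=float) / op.DEN
        t_frac = np.array(op.tran, dtype=float) / op.DEN
        R = orth @ R_frac @ frac
        t = orth @ t_frac
        ops.append((R, t))
    return CrystalSymmetry(
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        spacegroup=st.spacegroup_hm or "P 1",
        operators=tuple(ops),
    )


def _structure_from_gemmi(st: gemmi.Structure, name: str = "") -> Structure:
    st.remove_alternative_conformations()  # keep blank/'A' conformer
    if len(st) == 0:
        raise EmptyStructureError("file contains no models")
    atoms: list[AtomRecord] = []
    model_coords = []
    for mi, model in enumerate(st):
        coords = []
        n = 0
        for chain in model:
            for res in chain:
                for atom in res:
                    if mi == 0:
                        atoms.append(AtomRecord(
                            serial=atom.serial,
                            name=atom.name,
                            resname=res.name,
                            chain=chain.name,
                            resid=res.seqid.num,
                            icode=(res.seqid.icode or "").strip(),
                            coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            element=atom.element.name,
                            occupancy=atom.occ,
                            bfactor=atom.b_iso,
                            het=res.het_flag == "H",
                        ))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    n += 1
        if n != len(atoms):
            raise TopologyError(
                f"model {mi + 1} has {n} atoms, model 1 has {len(atoms)}"
            )
        model_coords.append(coords)
    if not atoms:
        raise EmptyStructureError("file contains no atoms")
    return Structure(atoms, np.array(model_coords, dtype=float),
                     _capture_symmetry(st), name=name)


def _validate_pdb_coords(path) -> None:
    """gemmi is forgiving about unparseable coordinate fields; reject them
    explicitly, naming the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                field = line[lo:hi].strip()
                try:
                    float(field)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: malformed coordinate field "
                        f"{field!r}"
                    ) from None


def read_structure(path) -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`."""
    _validate_pdb_coords(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return _structure_from_gemmi(st, name=st.name)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.name or "netdyn"
    if structure.crystal_symmetry is not None:
        a, b, c, al, be, ga = structure.crystal_symmetry.cell
        st.cell = gemmi.UnitCell(a, b, c, al, be, ga)
        st.spacegroup_hm = structure.crystal_symmetry.spacegroup
    chain_map = _single_char_chain_map(structure)
    for mi in range(structure.n_models):
        model = gemmi.Model(str(mi + 1))
        # gemmi's add_chain/add_residue copy their argument, so assemble
        # each residue and chain completely before attaching it.
        chain = None
        res = None
        chain_key = res_key = object()
        for i, a in enumerate(structure.atoms):
            if a.chain != chain_key:
                if chain is not None:
                    if res is not None:
                        chain.add_residue(res)
                    model.add_chain(chain)
                chain = gemmi.Chain(chain_map[a.chain])
                chain_key = a.chain
                res = None
                res_key = object()
            if (a.resid, a.icode, a.resname) != res_key:
                if res is not None:
                    chain.add_residue(res)
                res = gemmi.Residue()
                res.name = a.resname
                res.seqid = gemmi.SeqId(a.resid, a.icode or " ")
                res.het_flag = "H" if a.het else "A"
                res_key = (a.resid, a.icode, a.resname)
            atom = gemmi.Atom()
            atom.name = a.name
            atom.serial = a.serial
            x, y, z = structure.model_coords[mi, i]
            atom.pos = gemmi.Position(x, y, z)
            atom.element = gemmi.Element(a.element)
            atom.occ = a.occupancy
            atom.b_iso = a.bfactor
            res.add_atom(atom)
        if chain is not None:
            if res is not None:
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    return st


def _single_char_chain_map(structure: Structure) -> dict[str, str]:
    """PDB columns allow one chain character; remap longer ids if needed."""
    chains = structure.chains
    mapping = {c: c for c in chains if len(c) == 1}
    pool = [c for c in string.ascii_uppercase + string.digits
            + string.ascii_lowercase if c not in mapping.values()]
    for c in chains:
        if len(c) != 1:
            if not pool:
                raise SelectionError("too many chains for PDB output")
            mapping[c] = pool.pop(0)
    return mapping


def write_structure(path, structure: Structure) -> None:
    """Write a structure (all models) as fixed-column PDB."""
    st = _to_gemmi(structure)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def read_trajectory(path, topology: Structure, dt: float | None = None) -> Trajectory:
    """Read DCD/XTC (via MDAnalysis) or multi-model PDB into a Trajectory.

    ``dt`` overrides any time step found in the file; when neither is
    available, :data:`DEFAULT_DT_NS` is assumed.
    """
    p = str(path)
    suffix = p.rsplit(".", 1)[-1].lower()
    if suffix in ("dcd", "xtc", "trr"):
        frames, file_dt = _read_mda(p, topology.n_atoms)
        return Trajectory(topology, frames, dt=dt or file_dt or DEFAULT_DT_NS)
    # fallback: multi-model PDB
    st = read_structure(p)
    if st.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"{path}: {st.n_atoms} atoms per frame, topology has "
            f"{topology.n_atoms}"
        )
    return Trajectory(topology, st.model_coords, dt=dt or DEFAULT_DT_NS)


def _read_mda(path: str, n_atoms: int):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms, trajectory=True)
        try:
            u.load_new(path)
        except (ValueError, OSError, EOFError) as exc:
            msg = str(exc)
            if "atoms" in msg or "natoms" in msg:
                raise TopologyError(f"{path}: {msg}") from exc
            raise ParseError(f"{path}: {msg}") from exc
        frames = []
        try:
            for ts in u.trajectory:
                frames.append(ts.positions.astype(float).copy())
        except (EOFError, OSError, ValueError) as exc:
            raise ParseError(
                f"{path}: truncated at frame {len(frames)}: {exc}"
            ) from exc
        file_dt = None
        ts = u.trajectory.ts
        if getattr(ts, "dt", None):
            file_dt = float(ts.dt) / 1000.0  # MDAnalysis ps -> ns
    return np.array(frames), file_dt


def write_trajectory(path, traj: Trajectory) -> None:
    """Write a trajectory as multi-model PDB (text) or DCD (binary)."""
    p = str(path)
    suffix = p.rsplit(".", 1)[-1].lower()
    if suffix == "dcd":
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
            with mda.Writer(p, traj.topology.n_atoms) as w:
                for f in traj.frames:
                    u.atoms.positions = f
                    w.write(u.atoms)
        return
    multi = traj.topology.with_coords(traj.frames)
    write_structure(p, multi)
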