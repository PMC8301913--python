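"""Crystallographic-dimer model construction and cross-dimer spans.

A two-protomer assembly is built either by applying an explicit symmetry
operator (rotation + translation in the orthogonal frame, e.g. one of the
operators captured from a PDB CRYST1 record) to a complex, or by Kabsch
superposition of a complex onto each protomer of a template dimer — the
route used to carry a larger complex into the dimer arrangement defined by
a smaller crystallographic template.  Spans between named atoms across the
assembly (e.g. the Cα–Cα separation of equivalent residues in the two
protomers) are plain Euclidean distances.

Full space-group assembly machinery is deliberately out of scope: a single
explicit two-fold is all that is needed, and explicit operators are
auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ClashError,
    LookupFailure,
    NamingError,
    ParameterError,
    SelectionError,
)
from .io import SelectionSpec, Structure, select
from .metrics import kabsch_superpose

__all__ = [
    "SymmetryOperator",
    "DimerModel",
    "apply_symmetry",
    "build_dimer_by_superposition",
    "find_crystal_contact_operator",
    "measure_span",
]

CLASH_ERROR_DIST = 1.5   # Å, inter-protomer heavy-atom distance -> error
CLASH_WARN_DIST = 2.5    # Å, -> warning


@dataclass(frozen=True)
class SymmetryOperator:
    """x -> R x + t in the orthogonal (Å) frame."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ParameterError("operator needs a 3x3 rotation and 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ParameterError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ParameterError("operator is a reflection (det < 0)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        return SymmetryOperator(self.rotation @ other.rotation,
                                self.rotation @ other.translation
                                + self.translation)

    def is_twofold(self, tol: float = 1e-3) -> bool:
        """True when the operator composed with itself is the identity."""
        sq = self.compose(self)
        return (np.allclose(sq.rotation, np.eye(3), atol=tol)
                and np.allclose(sq.translation, 0.0, atol=tol))


@dataclass
class DimerModel:
    """Two-protomer assembly with provenance of its construction."""

    assembly: Structure
    protomer_map: dict[str, str]          # original chain -> mate chain
    provenance: dict


def _check_clashes(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    tree = cKDTree(coords_b)
    dmin, _ = tree.query(coords_a, k=1)
    closest = float(dmin.min())
    if closest < CLASH_ERROR_DIST:
        raise ClashError(
            f"inter-protomer clash: closest approach {closest:.2f} Å "
            f"< {CLASH_ERROR_DIST} Å"
        )
    if closest < CLASH_WARN_DIST:
        warnings.warn(
            f"close inter-protomer contact: {closest:.2f} Å "
            f"< {CLASH_WARN_DIST} Å"
        )
    return closest


def _mate_chain_map(structure: Structure, suffix: str) -> dict[str, str]:
    mapping = {c: c + suffix for c in structure.chains}
    if set(mapping.values()) & set(structure.chains):
        raise NamingError(
            f"chain renaming with suffix {suffix!r} collides with existing "
            f"chains {structure.chains}"
        )
    return mapping


def apply_symmetry(
    structure: Structure,
    op: SymmetryOperator,
    chain_suffix: str = "'",
) -> DimerModel:
    """Assemble the structure with its symmetry mate.

    The transformed copy gets every chain renamed by ``chain_suffix``; a
    collision with an existing chain id is an error, as is a steric clash
    closer than 1.5 Å between the copies.
    """
    mapping = _mate_chain_map(structure, chain_suffix)
    mate = structure.transformed(op.rotation, op.translation)
    mate = mate.rename_chains(mapping)
    closest = _check_clashes(structure.coords, mate.coords)
    assembly = structure.concatenate(mate)
    return DimerModel(
        assembly=assembly,
        protomer_map=mapping,
        provenance={
            "method": "symmetry",
            "twofold": op.is_twofold(),
            "closest_approach": closest,
        },
    )


def build_dimer_by_superposition(
    complex_structure: Structure,
    template_dimer: Structure,
    anchor: SelectionSpec | str,
    template_protomers: tuple[tuple[str, ...], tuple[str, ...]],
    chain_suffix: str = "'",
) -> DimerModel:
    """Carry a complex into the dimer arrangement of a template.

    The complex is superposed (Kabsch on the ``anchor`` selection, e.g. the
    G-domain Cα trace, residues 1–166) onto each protomer of the template
    dimer; the two placed copies form the assembly.  Anchor atoms are
    matched between complex and template by (resid, insertion code, atom
    name), so the template may be a smaller construct than the complex.
    """
    if isinstance(anchor, str):
        anchor = SelectionSpec.parse(anchor)
    cx_idx = select(complex_structure, anchor)
    cx_atoms = [complex_structure.atoms[i] for i in cx_idx]
    cx_map = {(a.resid, a.icode, a.name): i for a, i in zip(cx_atoms, cx_idx)}

    placed: list[Structure] = []
    rmsds: list[float] = []
    for pi, chains in enumerate(template_protomers):
        t_anchor = SelectionSpec(
            chains=tuple(chains),
            resid_min=anchor.resid_min, resid_max=anchor.resid_max,
            atoms=anchor.atoms, include_het=anchor.include_het,
        )
        t_idx = select(template_dimer, t_anchor)
        t_atoms = [template_dimer.atoms[i] for i in t_idx]
        t_keys = [(a.resid, a.icode, a.name) for a in t_atoms]
        missing = [k for k in t_keys if k not in cx_map]
        extra = [k for k in cx_map if k not in set(t_keys)]
        if missing or extra:
            raise SelectionError(
                f"anchor mismatch on template protomer {pi}: "
                f"missing in complex: {missing[:5]}; "
                f"absent from template: {extra[:5]}"
            )
        mob = complex_structure.coords[[cx_map[k] for k in t_keys]]
        ref = template_dimer.coords[t_idx]
        sup = kabsch_superpose(mob, ref)
        placed.append(
            complex_structure.transformed(sup.rotation, sup.translation))
        rmsds.append(sup.rmsd)

    mapping = _mate_chain_map(complex_structure, chain_suffix)
    second = placed[1].rename_chains(mapping)
    closest = _check_clashes(placed[0].coords, second.coords)
    assembly = placed[0].concatenate(second)
    return DimerModel(
        assembly=assembly,
        protomer_map=mapping,
        provenance={
            "method": "superposition",
            "template": template_dimer.name,
            "anchor_rmsd": tuple(rmsds),
            "closest_approach": closest,
        },
    )


def find_crystal_contact_operator(
    structure: Structure,
    max_dist: float = 5.0,
    require_twofold: bool = True,
    max_shift: int = 1,
) -> SymmetryOperator:
    """Pick the captured crystal-symmetry operator that generates a
    contacting mate.

    Each non-identity operator from the structure's CRYST1 record, combined
    with lattice translations up to ``max_shift`` cells, is applied to the
    coordinates; the operator whose mate makes the closest (non-clashing)
    approach within ``max_dist`` is returned.  With ``require_twofold`` only
    involutive operators — the kind that generate a physical dimer — are
    considered.  This selects one explicit operator; it does not expand a
    full assembly.
    """
    sym = structure.crystal_symmetry
    if sym is None:
        raise LookupFailure("structure carries no crystal symmetry")
    orth = sym.orth_matrix
    coords = structure.coords
    tree = cKDTree(coords)
    best: tuple[float, SymmetryOperator] | None = None
    shifts = range(-max_shift, max_shift + 1)
    for R, t in sym.operators:
        for si in shifts:
            for sj in shifts:
                for sk in shifts:
                    t2 = t + orth @ np.array([si, sj, sk], dtype=float)
                    if np.allclose(R, np.eye(3), atol=1e-9) and \
                            np.allclose(t2, 0.0, atol=1e-9):
                        continue
                    op = SymmetryOperator(R, t2)
                    if require_twofold and not op.is_twofold():
                        continue
                    dmin = float(tree.query(op.apply(coords), k=1)[0].min())
                    if CLASH_ERROR_DIST <= dmin <= max_dist:
                        if best is None or dmin < best[0]:
                            best = (dmin, op)
    if best is None:
        raise LookupFailure(
            f"no crystal-symmetry mate approaches within {max_dist} Å"
        )
    return best[1]


def _find_atom(structure: Structure, spec: str) -> int:
    """Resolve ``"chain:resid:atomname"`` to an atom index."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise LookupFailure(f"atom spec {spec!r} must be chain:resid:atom")
    chain, resid_s, name = parts
    resid = int(resid_s)
    for i, a in enumerate(structure.atoms):
        if a.chain == chain and a.resid == resid and a.name == name:
            return i
    raise LookupFailure(f"atom {spec!r} not found in structure")


def measure_span(assembly: Structure, atom_a: str, atom_b: str) -> float:
    """Euclidean distance (Å) between two named atoms of the assembly."""
    ia = _find_atom(assembly, atom_a)
    ib = _find_atom(assembly, atom_b)
    return float(np.linalg.norm(assembly.coords[ia] - assembly.coords[ib]))
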