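"""Solvent-accessible surface area and interface burial.

SASA uses the Shrake–Rupley sphere-point method with a deterministic
golden-spiral point set, a 1.4 Å water probe and the Bondi van der Waals
radius table.  Buried surface area follows the crystallographic-interface
convention: the reported value is one-sided, i.e. half of the total area
lost by the two groups on complex formation (a two-sided value is also
returned).  The interface hydrophobicity statistic is a resampling analog
of interface-significance scores: it compares the mean Kyte–Doolittle
hydropathy of the interface residues against random contiguous surface
patches of the same size.

Heteroatoms (waters, ions, nucleotides) are excluded from SASA by default;
burial numbers are sensitive to this, so the flag is explicit everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    GroupingError,
    RadiusTableError,
    UndefinedStatisticError,
)
from .io import Structure

__all__ = [
    "BONDI_RADII",
    "KYTE_DOOLITTLE",
    "SASAResult",
    "InterfaceReport",
    "sasa",
    "buried_surface_area",
    "hydrophobicity_pvalue",
]

#: Bondi (1964) van der Waals radii, Å, by element symbol.
BONDI_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "MG": 1.73, "CA": 2.31, "MN": 1.97,
    "FE": 1.94, "NA": 2.27, "K": 2.75, "CU": 1.40, "NI": 1.63,
}

#: Kyte–Doolittle hydropathy by 3-letter residue code.
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

DEFAULT_PROBE = 1.4    # Å, water probe
DEFAULT_POINTS = 960   # sphere quadrature points per atom
BURIAL_MIN = 0.1       # Å², per-residue loss defining an interface residue


@dataclass(frozen=True)
class SASAResult:
    """Per-atom and total solvent-accessible surface area (Å²)."""

    per_atom: np.ndarray
    total: float
    probe_radius: float
    n_sphere_points: int


@dataclass(frozen=True)
class InterfaceReport:
    """Interface burial between two chain groups.

    ``bsa`` is one-sided (half the total SASA loss); ``bsa_two_sided`` is
    the full loss.  ``interface_residues`` maps each chain to the residues
    losing more than 0.1 Å² on complexation.
    """

    bsa: float
    bsa_two_sided: float
    interface_residues: dict[str, list[int]]
    per_residue_burial: dict[tuple[str, int, str], float]
    hydrophobicity_pvalue: float | None = None


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform points on the unit sphere
    (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ], axis=1)


def _radii(structure: Structure, table: dict[str, float]) -> np.ndarray:
    out = np.empty(structure.n_atoms)
    for k, a in enumerate(structure.atoms):
        r = table.get(a.element.upper())
        if r is None:
            raise RadiusTableError(
                f"no van der Waals radius for element {a.element!r} "
                f"(atom {a.chain}:{a.resid}:{a.name})"
            )
        out[k] = r
    return out


def _protein_indices(structure: Structure, include_het: bool,
                     include_hydrogens: bool) -> np.ndarray:
    keep = []
    for i, a in enumerate(structure.atoms):
        if a.het and not include_het:
            continue
        if a.is_hydrogen and not include_hydrogens:
            continue
        keep.append(i)
    return np.array(keep, dtype=int)


def sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    include_het: bool = False,
    include_hydrogens: bool = True,
    radii: dict[str, float] | None = None,
) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area.

    Deterministic for a given ``n_points``.  Excluded atoms (heteroatoms by
    default) carry zero area and do not occlude.
    """
    table = radii or BONDI_RADII
    idx = _protein_indices(structure, include_het, include_hydrogens)
    per_atom = np.zeros(structure.n_atoms)
    if idx.size == 0:
        return SASAResult(per_atom, 0.0, probe, n_points)
    coords = structure.coords[idx]
    r = _radii(structure.subset(idx), table) + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    r_max = r.max()
    for k in range(idx.size):
        neighbors = tree.query_ball_point(coords[k], r[k] + r_max)
        neighbors = [n for n in neighbors if n != k]
        surface = coords[k] + pts * r[k]
        if neighbors:
            nb = np.array(neighbors)
            d2 = ((surface[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (r[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[idx[k]] = frac * 4.0 * np.pi * r[k] ** 2
    return SASAResult(per_atom, float(per_atom.sum()), probe, n_points)


def _chain_indices(structure: Structure, chains) -> np.ndarray:
    chains = set(chains)
    idx = np.array([i for i, a in enumerate(structure.atoms)
                    if a.chain in chains], dtype=int)
    return idx


def _per_residue_area(structure: Structure, result: SASAResult
                      ) -> dict[tuple[str, int, str], float]:
    areas: dict[tuple[str, int, str], float] = {}
    for a, v in zip(structure.atoms, result.per_atom):
        areas[a.residue_key] = areas.get(a.residue_key, 0.0) + float(v)
    return areas


def buried_surface_area(
    structure: Structure,
    group_a,
    group_b,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    include_het: bool = False,
) -> InterfaceReport:
    """Interface area buried between two disjoint chain groups.

    BSA = (SASA(A) + SASA(B) − SASA(A∪B)) / 2 — the one-sided convention
    of crystallographic interface reports.  Interface residues are those
    losing more than 0.1 Å² of per-residue SASA on complexation.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise GroupingError("both chain groups must be non-empty")
    if group_a & group_b:
        raise GroupingError(
            f"chain groups overlap: {sorted(group_a & group_b)}"
        )
    present = set(structure.chains)
    absent = (group_a | group_b) - present
    if absent:
        raise GroupingError(f"chains not in structure: {sorted(absent)}")
    idx_a = _chain_indices(structure, group_a)
    idx_b = _chain_indices(structure, group_b)
    sub_a = structure.subset(idx_a)
    sub_b = structure.subset(idx_b)
    both = structure.subset(np.concatenate([idx_a, idx_b]))
    kw = dict(probe=probe, n_points=n_points, include_het=include_het)
    res_a = sasa(sub_a, **kw)
    res_b = sasa(sub_b, **kw)
    res_ab = sasa(both, **kw)
    loss = max(0.0, res_a.total + res_b.total - res_ab.total)
    free = {**_per_residue_area(sub_a, res_a), **_per_residue_area(sub_b, res_b)}
    bound = _per_residue_area(both, res_ab)
    burial = {k: free[k] - bound.get(k, 0.0) for k in free}
    interface: dict[str, list[int]] = {}
    for (chain, resid, _icode), lost in sorted(burial.items()):
        if lost > BURIAL_MIN:
            interface.setdefault(chain, []).append(resid)
    return InterfaceReport(
        bsa=loss / 2.0,
        bsa_two_sided=loss,
        interface_residues=interface,
        per_residue_burial=burial,
    )


def hydrophobicity_pvalue(
    structure: Structure,
    group_a,
    group_b,
    n_resamples: int = 1000,
    seed: int = 0,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    surface_min_area: float = 5.0,
    patch_link_cutoff: float = 8.0,
) -> float:
    """Resampling estimate of interface hydrophobicity significance.

    The statistic is the mean Kyte–Doolittle hydropathy of the interface
    residues.  Random contiguous patches of the same residue count are
    drawn on the surface graph (surface residues linked when their Cα
    atoms lie within 8 Å), and the mid-p fraction of patches at least as
    hydrophobic as the interface is returned: values well below 0.5 mean
    the interface is more hydrophobic than a typical surface patch of its
    size.  This is an analog of — not a reproduction of — the
    solvation-energy p-value printed by interface-assembly servers.
    """
    report = buried_surface_area(structure, group_a, group_b,
                                 probe=probe, n_points=n_points)
    iface_keys = [k for k, v in report.per_residue_burial.items()
                  if v > BURIAL_MIN]
    if not iface_keys:
        raise UndefinedStatisticError("interface is empty; hydrophobicity "
                                      "statistic undefined")
    full = sasa(structure, probe=probe, n_points=n_points)
    per_res = _per_residue_area(structure, full)
    surface_keys = sorted(k for k, v in per_res.items()
                          if v > surface_min_area and k[0] in
                          set(group_a) | set(group_b))
    # anchor each surface residue at its Cα (first atom as fallback)
    anchors = {}
    for i, a in enumerate(structure.atoms):
        k = a.residue_key
        if k in anchors and a.name != "CA":
            continue
        if k not in anchors or a.name == "CA":
            anchors[k] = structure.coords[i]
    pos = np.array([anchors[k] for k in surface_keys])
    tree = cKDTree(pos)
    neighbor_lists = tree.query_ball_point(pos, patch_link_cutoff)
    resnames = {a.residue_key: a.resname for a in structure.atoms}

    def score(keys) -> float:
        vals = [KYTE_DOOLITTLE.get(resnames.get(k, ""), 0.0) for k in keys]
        return float(np.mean(vals))

    target = score(iface_keys)
    m = min(len(iface_keys), len(surface_keys))
    rng = np.random.default_rng(seed)
    greater = equal = 0
    for _ in range(n_resamples):
        start = rng.integers(len(surface_keys))
        patch = _grow_patch(start, m, neighbor_lists, rng)
        s = score([surface_keys[i] for i in patch])
        if s > target + 1e-12:
            greater += 1
        elif abs(s - target) <= 1e-12:
            equal += 1
    return (greater + 0.5 * equal) / n_resamples


def _grow_patch(start: int, size: int, neighbor_lists, rng) -> list[int]:
    """Breadth-first contiguous patch on the surface graph; if growth
    stalls (disconnected surface) a random unused residue reseeds it."""
    patch = [start]
    seen = {start}
    frontier = [start]
    while len(patch) < size:
        candidates = sorted({n for f in frontier for n in neighbor_lists[f]}
                            - seen)
        if not candidates:
            rest = [i for i in range(len(neighbor_lists)) if i not in seen]
            if not rest:
                break
            candidates = [rest[rng.integers(len(rest))]]
        take = min(len(candidates), size - len(patch))
        chosen = rng.permutation(len(candidates))[:take]
        new = [candidates[c] for c in chosen]
        patch.extend(new)
        seen.update(new)
        frontier = new
    return patch
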