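"""Dynamical residue-interaction networks and allosteric path search.

The network has one node per residue, anchored at its Cα.  An edge joins
two residues when they stay in contact (minimum inter-residue distance
within ``contact_cutoff``) for at least ``occupancy_threshold`` of the
trajectory — the threshold is inclusive.  Edges are weighted
``w_ij = -log |C_ij|`` from the normalised Cα displacement
cross-correlation ``C_ij``, so perfectly correlated residues cost nothing
to traverse and uncorrelated ones are effectively impassable.  The optimal
source→sink path minimises the summed edge weight; suboptimal paths lie
within a user tolerance of that minimum.

Two points where the literature is loose are made explicit here:

* A 4.5 Å cutoff read as a Cα–Cα distance almost never fires; the default
  contact mode is therefore the minimum heavy-atom inter-residue distance
  (the convention of the dynamical-network methodology), with a pure-Cα
  mode available for Cα-only models.
* Sequence neighbours (|i−j| ≤ ``exclude_neighbors`` within a chain) are
  excluded from the edge set to prevent trivial backbone-only paths.

Both choices are recorded on the network and in exported tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import (
    GroupingError,
    InsufficientFramesError,
    NoPathError,
    ParameterError,
    UndefinedCorrelationError,
)
from .io import SelectionSpec, Structure, Trajectory, select
from .metrics import iterated_mean, superpose_frames

__all__ = [
    "NetworkParams",
    "ContactOccupancy",
    "CorrelationMatrix",
    "DynamicalNetwork",
    "PathQuery",
    "Path",
    "PathEnsemble",
    "WindowScheme",
    "WindowResult",
    "contact_occupancy",
    "cross_correlation",
    "build_network",
    "build_network_from_trajectory",
    "optimal_path",
    "suboptimal_paths",
    "windowed_networks",
    "interface_edge_summary",
    "to_edge_table",
]

_EPS = 1e-9


@dataclass(frozen=True)
class NetworkParams:
    """Contact and edge construction parameters."""

    contact_cutoff: float = 4.5        # Å
    occupancy_threshold: float = 0.75  # inclusive fraction of frames
    contact_mode: str = "heavy"        # "heavy" | "ca"
    exclude_neighbors: int = 1         # sequence separation excluded (same chain)

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ParameterError("contact_cutoff must be positive")
        if not 0.0 < self.occupancy_threshold <= 1.0:
            raise ParameterError("occupancy_threshold must be in (0, 1]")
        if self.contact_mode not in ("heavy", "ca"):
            raise ParameterError("contact_mode must be 'heavy' or 'ca'")


@dataclass(frozen=True)
class ContactOccupancy:
    """Symmetric matrix of contact fractions f_ij over residues."""

    fractions: np.ndarray                    # (R, R) in [0, 1], diag 1
    residues: tuple[tuple[str, int, str], ...]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Normalised Cα displacement cross-correlations C_ij in [-1, 1]."""

    values: np.ndarray                       # (R, R), diag 1
    residues: tuple[tuple[str, int, str], ...]


@dataclass
class DynamicalNetwork:
    """Residue graph with occupancy-filtered, correlation-weighted edges."""

    graph: nx.Graph                          # nodes: 0..R-1
    residues: tuple[tuple[str, int, str], ...]
    params: NetworkParams

    def node_of(self, label) -> int:
        """Resolve ``"chain:resid"`` (or a residue key tuple / int) to a node."""
        if isinstance(label, (int, np.integer)):
            return int(label)
        if isinstance(label, str):
            chain, resid = label.split(":")[:2]
            key = (chain, int(resid), "")
        else:
            key = tuple(label) if len(label) == 3 else (*label, "")
        try:
            return self.residues.index(key)
        except ValueError:
            raise NoPathError(f"residue {label!r} not in network") from None

    def label_of(self, node: int) -> str:
        chain, resid, icode = self.residues[node]
        return f"{chain}:{resid}{icode}"


@dataclass(frozen=True)
class PathQuery:
    """Source/sink pair with a suboptimal tolerance and a path cap.

    The default tolerance of 20 edge-weight units follows the established
    suboptimal-path tradition; no value is canonical, so it is exposed.
    """

    source: object
    sink: object
    tolerance: float = 20.0
    max_paths: int = 500
    hop_count: bool = False  # unweighted mode: every edge costs 1

    def __post_init__(self):
        if self.source == self.sink:
            raise ParameterError("source and sink must differ")
        if self.tolerance < 0:
            raise ParameterError("tolerance must be >= 0")
        if self.max_paths < 1:
            raise ParameterError("max_paths must be >= 1")


@dataclass(frozen=True)
class Path:
    nodes: tuple[int, ...]
    weight: float


@dataclass(frozen=True)
class PathEnsemble:
    """Optimal + suboptimal paths sorted ascending by weight, with the
    per-node usage count over the ensemble."""

    paths: tuple[Path, ...]
    node_frequency: dict[int, int]
    tolerance: float

    @property
    def optimal(self) -> Path:
        return self.paths[0]


@dataclass(frozen=True)
class WindowScheme:
    """Contiguous, non-overlapping frame ranges partitioning [0, F)."""

    ranges: tuple[tuple[int, int], ...]

    @classmethod
    def uniform(cls, n_windows: int, n_frames: int) -> "WindowScheme":
        if n_windows < 1:
            raise ParameterError("n_windows must be >= 1")
        if n_frames < n_windows:
            raise ParameterError("more windows than frames")
        edges = np.linspace(0, n_frames, n_windows + 1).astype(int)
        return cls(tuple((int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])))

    def __post_init__(self):
        prev = 0
        for a, b in self.ranges:
            if a != prev or b <= a:
                raise ParameterError(
                    f"window ranges must partition [0, F): bad range ({a}, {b})"
                )
            prev = b

    @property
    def n_windows(self) -> int:
        return len(self.ranges)


@dataclass
class WindowResult:
    window: tuple[int, int]
    network: DynamicalNetwork
    ensemble: PathEnsemble | None


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def contact_occupancy(traj: Trajectory, params: NetworkParams | None = None
                      ) -> ContactOccupancy:
    """Fraction of frames in which each residue pair is within the cutoff.

    In ``"heavy"`` mode the distance between two residues is the minimum
    over their heavy-atom pairs; in ``"ca"`` mode it is the Cα–Cα distance.
    """
    params = params or NetworkParams()
    if traj.n_frames == 0:
        raise InsufficientFramesError("empty trajectory")
    keys, atom_res = traj.topology.atom_residue_index()
    R = len(keys)
    if params.contact_mode == "ca":
        idx = select(traj.topology, SelectionSpec(atoms="CA"))
        sub_res = atom_res[idx]
        counts = np.zeros((R, R))
        for f in range(traj.n_frames):
            d = cdist(traj.frames[f, idx], traj.frames[f, idx])
            hit = d <= params.contact_cutoff
            m = np.zeros((R, R), dtype=bool)
            m[np.ix_(sub_res, sub_res)] = hit
            counts += m
    else:
        heavy = np.array([not a.is_hydrogen for a in traj.topology.atoms])
        idx = np.where(heavy)[0]
        sub_res = atom_res[idx]
        counts = np.zeros((R, R))
        for f in range(traj.n_frames):
            d = cdist(traj.frames[f, idx], traj.frames[f, idx])
            hit = d <= params.contact_cutoff
            m = np.zeros((R, R), dtype=bool)
            np.logical_or.at(m, (sub_res[:, None], sub_res[None, :]), hit)
            counts += m
    frac = counts / traj.n_frames
    frac = np.maximum(frac, frac.T)
    np.fill_diagonal(frac, 1.0)
    return ContactOccupancy(frac, tuple(keys))


def cross_correlation(traj: Trajectory, selection=None) -> CorrelationMatrix:
    """Normalised scalar cross-correlation of Cα displacements.

    Frames are superposed onto the iterated mean structure of the selected
    atoms before displacements are measured;
    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩).
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("cross-correlation needs >= 2 frames")
    if selection is None:
        selection = SelectionSpec(atoms="CA")
    if isinstance(selection, (SelectionSpec, str)):
        idx = select(traj.topology, selection)
    else:
        idx = np.asarray(selection, dtype=int)
    keys, atom_res = traj.topology.atom_residue_index()
    res_of = atom_res[idx]
    sub = traj.frames[:, idx]
    mean = iterated_mean(sub)
    aligned = superpose_frames(sub, mean)
    delta = aligned - aligned.mean(axis=0)
    inner = np.einsum("fic,fjc->ij", delta, delta) / traj.n_frames
    var = np.diag(inner)
    zero = np.where(var <= 0)[0]
    if zero.size:
        k = keys[res_of[zero[0]]]
        raise UndefinedCorrelationError(
            f"residue {k[0]}:{k[1]}{k[2]} has zero displacement variance"
        )
    denom = np.sqrt(np.outer(var, var))
    C_sel = np.clip(inner / denom, -1.0, 1.0)
    # lift onto the full residue set of the topology
    R = len(keys)
    C = np.eye(R)
    C[np.ix_(res_of, res_of)] = C_sel
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(C, tuple(keys))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(
    occ: ContactOccupancy,
    corr: CorrelationMatrix,
    params: NetworkParams | None = None,
) -> DynamicalNetwork:
    """Filter contacts by occupancy and weight edges by -log |C_ij|.

    Edges whose correlation is exactly zero would have infinite weight and
    are dropped with a warning.
    """
    params = params or NetworkParams()
    if occ.residues != corr.residues:
        raise ParameterError("occupancy and correlation matrices index "
                             "different residue sets")
    R = len(occ.residues)
    g = nx.Graph()
    g.add_nodes_from(range(R))
    dropped = 0
    for i in range(R):
        ci, ri, _ = occ.residues[i]
        for j in range(i + 1, R):
            cj, rj, _ = occ.residues[j]
            if occ.fractions[i, j] < params.occupancy_threshold:
                continue
            if ci == cj and abs(ri - rj) <= params.exclude_neighbors:
                continue
            c = abs(corr.values[i, j])
            if c <= 0.0:
                dropped += 1
                continue
            g.add_edge(i, j,
                       weight=-math.log(c),
                       occupancy=float(occ.fractions[i, j]),
                       correlation=float(corr.values[i, j]))
    if dropped:
        warnings.warn(
            f"dropped {dropped} edge(s) with zero correlation "
            "(infinite weight)"
        )
    return DynamicalNetwork(g, occ.residues, params)


def build_network_from_trajectory(
    traj: Trajectory, params: NetworkParams | None = None
) -> DynamicalNetwork:
    """Convenience: occupancy + correlation + network in one call."""
    params = params or NetworkParams()
    occ = contact_occupancy(traj, params)
    corr = cross_correlation(traj)
    return build_network(occ, corr, params)


# ---------------------------------------------------------------------------
# path search
# ---------------------------------------------------------------------------

def _resolve_query(net: DynamicalNetwork, query: PathQuery) -> tuple[int, int]:
    s = net.node_of(query.source)
    t = net.node_of(query.sink)
    if s == t:
        raise ParameterError("source and sink resolve to the same residue")
    if not nx.has_path(net.graph, s, t):
        sizes = sorted((len(c) for c in nx.connected_components(net.graph)),
                       reverse=True)
        raise NoPathError(
            f"source {net.label_of(s)} and sink {net.label_of(t)} are in "
            f"different components (component sizes: {sizes[:10]})"
        )
    return s, t


def _simple_paths_by_weight(net, s, t, bound, max_paths, hop_count=False):
    """Yen-style enumeration (networkx shortest_simple_paths) of all simple
    paths with weight <= bound, deterministically sorted."""
    out = []
    wkey = None if hop_count else "weight"
    gen = nx.shortest_simple_paths(net.graph, s, t, weight=wkey)
    for nodes in gen:
        w = _path_weight(net.graph, nodes, hop_count)
        if w > bound + _EPS:
            break
        out.append(Path(tuple(nodes), w))
        if len(out) >= max_paths:
            break
    out.sort(key=lambda p: (p.weight, p.nodes))
    return out


def _path_weight(g: nx.Graph, nodes, hop_count=False) -> float:
    if hop_count:
        return float(len(nodes) - 1)
    return float(sum(g[a][b]["weight"] for a, b in zip(nodes[:-1], nodes[1:])))


def optimal_path(net: DynamicalNetwork, query: PathQuery) -> Path:
    """Minimum-total-weight simple path from source to sink.

    Among equal-weight optima the lexicographically smallest node sequence
    is returned, so results are reproducible across runs.
    """
    s, t = _resolve_query(net, query)
    wkey = None if query.hop_count else "weight"
    w_opt = nx.dijkstra_path_length(net.graph, s, t, weight=wkey)
    ties = _simple_paths_by_weight(net, s, t, w_opt, query.max_paths,
                                   query.hop_count)
    return ties[0]


def suboptimal_paths(net: DynamicalNetwork, query: PathQuery) -> PathEnsemble:
    """All simple paths within ``query.tolerance`` of the optimal weight,
    capped at ``query.max_paths``, sorted ascending by (weight, nodes)."""
    s, t = _resolve_query(net, query)
    wkey = None if query.hop_count else "weight"
    w_opt = nx.dijkstra_path_length(net.graph, s, t, weight=wkey)
    paths = _simple_paths_by_weight(net, s, t, w_opt + query.tolerance,
                                    query.max_paths, query.hop_count)
    freq: dict[int, int] = {}
    for p in paths:
        for n in p.nodes:
            freq[n] = freq.get(n, 0) + 1
    return PathEnsemble(tuple(paths), freq, query.tolerance)


def windowed_networks(
    traj: Trajectory,
    scheme: WindowScheme | int,
    params: NetworkParams | None = None,
    query: PathQuery | None = None,
) -> list[WindowResult]:
    """Independent network (and optional path) analysis per trajectory window.

    ``scheme`` may be a :class:`WindowScheme` or a window count; a single
    window reproduces the full-trajectory analysis exactly.
    """
    params = params or NetworkParams()
    if isinstance(scheme, int):
        scheme = WindowScheme.uniform(scheme, traj.n_frames)
    if scheme.ranges[-1][1] != traj.n_frames:
        raise ParameterError("window scheme does not cover all frames")
    results = []
    for (a, b) in scheme.ranges:
        if b - a < 2:
            raise InsufficientFramesError(
                f"window ({a}, {b}) has fewer than 2 frames"
            )
        sub = Trajectory(traj.topology, traj.frames[a:b], dt=traj.dt)
        net = build_network_from_trajectory(sub, params)
        ens = suboptimal_paths(net, query) if query is not None else None
        results.append(WindowResult((a, b), net, ens))
    return results


# ---------------------------------------------------------------------------
# summaries and export
# ---------------------------------------------------------------------------

def interface_edge_summary(
    net: DynamicalNetwork, partition: dict[str, str]
) -> pd.DataFrame:
    """Edges whose endpoints fall in different chain groups.

    ``partition`` maps every chain id to a group name; an unassigned chain
    is an error.  Returns a table with residue labels, groups, occupancy,
    correlation and edge weight, sorted for reproducibility.
    """
    chains = {k[0] for k in net.residues}
    missing = chains - set(partition)
    if missing:
        raise GroupingError(f"chains with no group assignment: {sorted(missing)}")
    rows = []
    for i, j, data in net.graph.edges(data=True):
        gi = partition[net.residues[i][0]]
        gj = partition[net.residues[j][0]]
        if gi == gj:
            continue
        (i, gi), (j, gj) = sorted([(i, gi), (j, gj)])
        rows.append({
            "node_i": net.label_of(i), "node_j": net.label_of(j),
            "group_i": gi, "group_j": gj,
            "occupancy": data["occupancy"],
            "correlation": data["correlation"],
            "weight": data["weight"],
        })
    df = pd.DataFrame(
        rows, columns=["node_i", "node_j", "group_i", "group_j",
                       "occupancy", "correlation", "weight"])
    return df.sort_values(["node_i", "node_j"], ignore_index=True)


def to_edge_table(net: DynamicalNetwork) -> pd.DataFrame:
    """Full edge list (node_i, node_j, f_ij, C_ij, w_ij)."""
    rows = [{
        "node_i": net.label_of(min(i, j)), "node_j": net.label_of(max(i, j)),
        "occupancy": d["occupancy"], "correlation": d["correlation"],
        "weight": d["weight"],
    } for i, j, d in net.graph.edges(data=True)]
    df = pd.DataFrame(rows, columns=["node_i", "node_j", "occupancy",
                                     "correlation", "weight"])
    return df.sort_values(["node_i", "node_j"], ignore_index=True)
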