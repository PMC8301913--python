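"""Superposition, RMSD/RMSF and distance time series.

The rotational fit is the Kabsch solution (reflections excluded), obtained
through :func:`scipy.spatial.transform.Rotation.align_vectors`.  RMSF uses
an iterated mean structure as reference by default (two superposition
passes), configurable to the first frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    InsufficientFramesError,
)
from .io import SelectionSpec, Structure, Trajectory, select

__all__ = [
    "SuperpositionResult",
    "FluctuationProfile",
    "kabsch_superpose",
    "superpose_frames",
    "iterated_mean",
    "rmsd_series",
    "rmsf",
    "distance_series",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform x -> R x + t minimising (weighted) RMSD."""

    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float              # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class FluctuationProfile:
    """Per-residue RMSF (Å) over a selection, with its reference coords."""

    values: np.ndarray
    reference: np.ndarray  # (N, 3) coordinates fluctuations are about


def _check_nondegenerate(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError(
            f"superposition needs >= 3 points, got {coords.shape[0]}"
        )
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(1.0, s[0]):
        raise DegenerateGeometryError("points are collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DegenerateGeometryError(
            f"point counts differ: {mobile.shape} vs {reference.shape}"
        )
    _check_nondegenerate(mobile)
    _check_nondegenerate(reference)
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_c = (w[:, None] * reference).sum(axis=0) / wsum
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c,
                                        weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt((w[:, None] * (moved - reference) ** 2).sum()
                         / wsum))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _resolve_selection(topology: Structure, selection) -> np.ndarray:
    if selection is None:
        selection = SelectionSpec(atoms="all")
    if isinstance(selection, (SelectionSpec, str)):
        return select(topology, selection)
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise EmptySelectionError("empty selection")
    return idx


def superpose_frames(
    frames: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray | None = None
) -> np.ndarray:
    """Superpose every frame onto ``reference`` (fitting on ``fit_idx``)."""
    frames = np.asarray(frames, dtype=float)
    if fit_idx is None:
        fit_idx = np.arange(frames.shape[1])
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        sup = kabsch_superpose(frames[f, fit_idx], reference[fit_idx])
        out[f] = sup.apply(frames[f])
    return out


def iterated_mean(frames: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Mean structure refined by alternating mean/superposition passes."""
    mean = frames.mean(axis=0)
    for _ in range(n_iter):
        aligned = superpose_frames(frames, mean)
        mean = aligned.mean(axis=0)
    return mean


def rmsd_series(
    traj: Trajectory,
    reference: Structure | np.ndarray | None = None,
    selection=None,
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference after superposing on the selection.

    ``reference`` defaults to the topology coordinates.
    """
    idx = _resolve_selection(traj.topology, selection)
    if reference is None:
        ref = traj.topology.coords
    elif isinstance(reference, Structure):
        ref = reference.coords
    else:
        ref = np.asarray(reference, dtype=float)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = kabsch_superpose(traj.frames[f, idx], ref[idx]).rmsd
    return out


def rmsf(
    traj: Trajectory,
    selection=None,
    reference: str = "mean",
    n_iter: int = 2,
) -> FluctuationProfile:
    """Per-atom RMSF (Å) over the selection.

    ``reference="mean"`` (default) superposes the frames onto the iterated
    mean structure before measuring fluctuations; ``reference="first"``
    uses frame 0 as the alignment target, with fluctuations still measured
    about the aligned-ensemble mean.
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    idx = _resolve_selection(traj.topology, selection)
    sub = traj.frames[:, idx]
    if reference == "mean":
        target = iterated_mean(sub, n_iter=n_iter)
    elif reference == "first":
        target = sub[0]
    else:
        raise ValueError("reference must be 'mean' or 'first'")
    aligned = superpose_frames(sub, target)
    mean = aligned.mean(axis=0)
    dev = aligned - mean
    values = np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))
    return FluctuationProfile(values=values, reference=mean)


def distance_series(traj: Trajectory, atom_i: int, atom_j: int) -> np.ndarray:
    """Euclidean distance between two atoms per frame (no superposition)."""
    if atom_i == atom_j:
        warnings.warn("distance_series called with i == j; returning zeros")
        return np.zeros(traj.n_frames)
    d = traj.frames[:, atom_i] - traj.frames[:, atom_j]
    return np.linalg.norm(d, axis=1)
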