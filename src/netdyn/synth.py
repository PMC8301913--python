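"""Synthetic Cα trajectories with planted statistical structure.

Real MD ensembles of the Ras–Raf dimer are too expensive to regenerate and
are not redistributable, so this module provides a Gaussian elastic
generator whose output carries exactly the statistics the downstream
analysis consumes: per-residue fluctuation amplitudes, a residue–residue
displacement cross-correlation structure (including a plantable
high-correlation chain between two terminal residues), and residue contacts
with prescribed occupancies.

Frames are sampled independently (no temporal autocorrelation): contact
occupancies, cross-correlations and fluctuation profiles — everything the
network and metrics stages measure — are single-frame statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    LookupFailure,
    NotPositiveSemidefiniteError,
    ParameterError,
)
from .io import AtomRecord, Structure, Trajectory

__all__ = [
    "GeneratorConfig",
    "PlantedContact",
    "ElasticModel",
    "make_toy_fold",
    "isotropic_model",
    "plant_correlated_path",
    "plant_contact",
    "sample_trajectory",
]

CA_SPACING = 3.8  # Å, consecutive Cα distance in extended geometry

# ideal alpha-helix Calpha parameters
_HELIX_RADIUS = 2.3   # Å
_HELIX_RISE = 1.5     # Å per residue
_HELIX_TURN = 100.0   # degrees per residue


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling configuration; the same seed gives a bit-identical trajectory."""

    n_frames: int = 1000
    seed: int = 0
    dt: float = 0.1            # ns per frame
    displacement_scale: float = 1.0  # multiplies the model's sigma

    def __post_init__(self):
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")


@dataclass(frozen=True)
class PlantedContact:
    """A residue pair toggled inside/outside the contact cutoff.

    In a Bernoulli(``occupancy``) fraction of frames the pair separation is
    set to ``d_in`` (inside the 4.5 Å cutoff), otherwise to ``d_out``.  Only
    the second residue of the pair is moved, along the instantaneous
    pair axis, so all other pair distances are preserved to first order.
    """

    i: int
    j: int
    occupancy: float
    d_in: float = 4.0
    d_out: float = 6.0

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ParameterError("occupancy must be in [0, 1]")
        if self.i == self.j:
            raise ParameterError("contact endpoints must differ")


@dataclass
class ElasticModel:
    """Gaussian elastic model over the Cα atoms of a reference structure.

    The residue-level correlation matrix ``corr`` (N×N) is applied
    identically and independently to the x, y and z displacement
    components, so the full 3N×3N covariance is
    ``kron(diag(sigma) @ corr @ diag(sigma), I3)`` and the scalar
    displacement cross-correlation of residues i, j equals ``corr[i, j]``.
    """

    reference: Structure
    sigma: np.ndarray = None          # (N,) Å per-component std dev
    corr: np.ndarray = None           # (N, N) residue correlation
    planted_path: list[int] | None = None
    planted_contacts: list[PlantedContact] = field(default_factory=list)

    def __post_init__(self):
        n = self.reference.n_atoms
        if self.sigma is None:
            self.sigma = np.full(n, 0.5)
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.sigma.size == 1:
            self.sigma = np.full(n, float(self.sigma[0]))
        if self.sigma.shape != (n,):
            raise ParameterError(f"sigma must have length {n}")
        if np.any(self.sigma < 0):
            raise ParameterError("sigma must be non-negative")
        if self.corr is None:
            self.corr = np.eye(n)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (n, n):
            raise ParameterError(f"corr must be {n}x{n}")

    @property
    def n_residues(self) -> int:
        return self.reference.n_atoms

    @property
    def covariance(self) -> np.ndarray:
        """Residue-level displacement covariance per component (N×N, Å²)."""
        return self.corr * np.outer(self.sigma, self.sigma)


def make_toy_fold(n_residues: int, geometry: str = "chain") -> Structure:
    """Build a Cα-only toy fold.

    geometry:
      - ``"chain"``: straight chain, consecutive spacing 3.8 Å.
      - ``"helix"``: ideal alpha-helix (radius 2.3 Å, rise 1.5 Å/res,
        100°/res), so residues i and i±3/i±4 are spatial neighbours.
      - ``"two_chain"``: two parallel straight chains A and B separated by
        5.4 Å, giving a contiguous inter-chain interface.
    """
    if n_residues < 3:
        raise ParameterError("a toy fold needs at least 3 residues")
    if geometry == "chain":
        coords = np.zeros((n_residues, 3))
        coords[:, 0] = np.arange(n_residues) * CA_SPACING
        chains = ["A"] * n_residues
        resids = list(range(1, n_residues + 1))
    elif geometry == "helix":
        i = np.arange(n_residues)
        theta = np.deg2rad(_HELIX_TURN) * i
        coords = np.stack([
            _HELIX_RADIUS * np.cos(theta),
            _HELIX_RADIUS * np.sin(theta),
            _HELIX_RISE * i,
        ], axis=1)
        chains = ["A"] * n_residues
        resids = list(range(1, n_residues + 1))
    elif geometry == "two_chain":
        na = n_residues // 2
        nb = n_residues - na
        coords = np.zeros((n_residues, 3))
        coords[:na, 0] = np.arange(na) * CA_SPACING
        coords[na:, 0] = np.arange(nb) * CA_SPACING
        coords[na:, 1] = 5.4
        chains = ["A"] * na + ["B"] * nb
        resids = list(range(1, na + 1)) + list(range(1, nb + 1))
    else:
        raise ParameterError(f"unknown geometry {geometry!r}")
    atoms = [
        AtomRecord(serial=k + 1, name="CA", resname="ALA", chain=chains[k],
                   resid=resids[k], coord=coords[k].copy(), element="C")
        for k in range(n_residues)
    ]
    return Structure(atoms, coords[None].copy(), name=f"toy-{geometry}")


def isotropic_model(reference: Structure, sigma: float = 0.5) -> ElasticModel:
    """Independent isotropic Gaussian displacements of std ``sigma`` Å
    per Cartesian component (so per-residue RMSF is √3·sigma)."""
    return ElasticModel(reference, sigma=np.full(reference.n_atoms, sigma))


def _nearest_psd(corr: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone by clipping eigenvalues,
    then restore a unit diagonal."""
    sym = (corr + corr.T) / 2
    w, v = np.linalg.eigh(sym)
    if w.min() >= 0:
        return sym
    w = np.clip(w, 0.0, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    return fixed / np.outer(d, d)


def plant_correlated_path(
    model: ElasticModel,
    path: list[int],
    rho: float,
    max_gap: float = 8.0,
) -> ElasticModel:
    """Plant a first-order correlation chain along ``path``.

    Consecutive path residues receive displacement correlation ``rho``;
    path residues ``d`` steps apart receive ``rho**d`` (the AR(1) chain
    correlation, which is positive semidefinite by construction).  Pairs
    not involving path residues are untouched.  The combined matrix is
    re-projected to the nearest PSD correlation matrix, since stacking
    plants can break positive semidefiniteness.

    ``max_gap`` guards the geometric precondition that consecutive path
    residues are close enough in the reference to be (or be planted as)
    contacts.
    """
    if not 0.0 < rho < 1.0:
        raise ParameterError("rho must be in the open interval (0, 1)")
    if len(path) < 2:
        raise ParameterError("a path needs at least two residues")
    n = model.n_residues
    for r in path:
        if not 0 <= r < n:
            raise LookupFailure(f"path residue index {r} not in model (N={n})")
    if len(set(path)) != len(path):
        raise ParameterError("path residues must be distinct")
    ref = model.reference.coords
    for a, b in zip(path[:-1], path[1:]):
        d = float(np.linalg.norm(ref[a] - ref[b]))
        if d > max_gap:
            raise ParameterError(
                f"path step {a}->{b} spans {d:.1f} Å in the reference "
                f"(> {max_gap} Å); not a plausible contact"
            )
    corr = model.corr.copy()
    for ai, a in enumerate(path):
        for bi, b in enumerate(path):
            if a != b:
                corr[a, b] = rho ** abs(ai - bi)
    corr = _nearest_psd(corr)
    return replace(model, corr=corr, planted_path=list(path))


def plant_contact(
    model: ElasticModel,
    i: int,
    j: int,
    occupancy: float,
    d_in: float = 4.0,
    d_out: float = 6.0,
) -> ElasticModel:
    """Register a contact to be realised at the given frame occupancy.

    The pair should already sit near contact distance in the reference:
    planting then only adjusts the radial separation.  Planting a pair that
    is far apart relocates the second residue wholesale, which makes it
    co-move with the first (correlation near 1) — almost never what a
    planted *contact* is meant to model, hence the warning.
    """
    n = model.n_residues
    for r in (i, j):
        if not 0 <= r < n:
            raise LookupFailure(f"residue index {r} not in model (N={n})")
    ref_d = float(np.linalg.norm(model.reference.coords[i]
                                 - model.reference.coords[j]))
    if ref_d > d_out + 2.0:
        import warnings

        warnings.warn(
            f"planted contact {i}-{j}: reference separation {ref_d:.1f} Å is "
            f"far from the target range [{d_in}, {d_out}] Å; the moved "
            "residue will co-move with its anchor"
        )
    contact = PlantedContact(i, j, occupancy, d_in, d_out)
    return replace(model,
                   planted_contacts=model.planted_contacts + [contact])


def planted_path_benchmark(
    n_residues: int = 28,
    hop: int = 3,
    rho: float = 0.9,
    sigma: float = 0.4,
) -> tuple[ElasticModel, list[int]]:
    """Canonical parameter-recovery scenario for the full pipeline.

    A helical toy fold carries a planted correlation-``rho`` chain from the
    first to the last residue in hops of ``hop`` (sequence separation > 1,
    so the neighbour-exclusion rule does not delete it), with occupancy-1.0
    contacts along the chain.  A parallel decoy chain over the interleaved
    residues has the same occupancy-1.0 contacts but no planted
    correlation, so its edges are heavy; the planted chain must come back
    as the optimal path between its endpoints.
    """
    ref = make_toy_fold(n_residues, "helix")
    path = list(range(0, n_residues - 1, hop)) + [n_residues - 1]
    model = isotropic_model(ref, sigma)
    model = plant_correlated_path(model, path, rho)
    for a, b in zip(path[:-1], path[1:]):
        model = plant_contact(model, a, b, occupancy=1.0)
    for a in range(1, n_residues - hop, hop):
        model = plant_contact(model, a, a + hop, occupancy=1.0)
    return model, path


def sample_trajectory(model: ElasticModel, config: GeneratorConfig) -> Trajectory:
    """Draw independent Gaussian frames from the elastic model.

    Planted contacts are applied in listed order after Gaussian sampling:
    for each contact, the second residue is moved along the instantaneous
    pair axis to the target separation.  A chain of contacts listed head to
    tail (i0–i1, i1–i2, …) therefore stays exactly consistent, because each
    residue is repositioned only after its predecessor has settled.
    """
    n = model.n_residues
    cov = model.covariance
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise NotPositiveSemidefiniteError(float(w.min()))
    factor = v * np.sqrt(np.clip(w, 0.0, None))  # (N, N), factor @ factor.T = cov
    rng = np.random.default_rng(config.seed)
    F = config.n_frames
    # one independent Gaussian field per Cartesian component
    z = rng.standard_normal((3, F, n))
    disp = np.einsum("cfk,nk->fnc", z, factor) * config.displacement_scale
    frames = model.reference.coords[None] + disp
    for contact in model.planted_contacts:
        on = rng.random(F) < contact.occupancy
        target = np.where(on, contact.d_in, contact.d_out)
        vec = frames[:, contact.j] - frames[:, contact.i]
        dist = np.linalg.norm(vec, axis=1)
        dist = np.where(dist < 1e-9, 1e-9, dist)
        frames[:, contact.j] = (
            frames[:, contact.i] + vec / dist[:, None] * target[:, None]
        )
    return Trajectory(model.reference, frames, dt=config.dt)
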