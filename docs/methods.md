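# Methods

This note records the models and conventions implemented in `netdyn`, the
places where the underlying methodology is under-specified and a concrete
choice had to be made, and what the synthetic validation does and does not
demonstrate.

## Dynamical network model

Every residue is a node anchored at its Cα atom. Two residues are
connected when their distance stays within the contact cutoff (default
4.5 Å) for at least the occupancy threshold (default 75 %, **inclusive**:
a contact present in exactly 75 % of frames forms an edge) of the frames
analysed. Edge weights are `w_ij = −log |C_ij|`, with `C_ij` the
normalised scalar cross-correlation of Cα displacement vectors measured
after superposing all frames onto the iterated mean structure. This is
the standard functional form of the dynamical-network methodology: a
perfectly correlated pair costs nothing to traverse, an uncorrelated pair
is effectively impassable, and path costs are additive in
−log-probability style. Edges whose correlation is exactly zero would
have infinite weight and are dropped with a warning.

Two conventions deserve emphasis because the usual one-line description
("nodes within 4.5 Å for 75 % of the trajectory") leaves them open:

* **Contact distance definition.** Read literally as a Cα–Cα distance,
  4.5 Å contacts essentially never occur between non-bonded residues. The
  default contact mode is therefore the *minimum heavy-atom inter-residue
  distance* (the convention of the network methodology in common use); a
  pure Cα mode (`contact_mode="ca"`) is provided and is the natural mode
  for Cα-only synthetic models. The mode is recorded on the network and
  in exported headers.
* **Sequence-neighbour exclusion.** Directly bonded neighbours are always
  in contact and perfectly correlated, so they would provide trivial
  backbone-only shortcuts. Residues with sequence separation
  ≤ `exclude_neighbors` (default 1) within a chain carry no edge;
  cross-chain pairs are never excluded. Configurable and disclosed in
  outputs.

### Path search

The optimal path minimises summed edge weight (Dijkstra); suboptimal
paths are enumerated Yen-style (`networkx.shortest_simple_paths`) up to a
weight bound of optimal + tolerance, capped at `max_paths` (default 500)
to bound runtime. All results are deterministically ordered by
(weight, node sequence), so equal-weight ties resolve to the
lexicographically smallest path. The tolerance default of 20 edge-weight
units follows the suboptimal-path tradition of the field; no canonical
value exists, so it is an explicit parameter. Two definitions of
"optimal" circulate — fewest edges versus smallest summed weight; the
weighted-sum definition is primary (it subsumes the hop count when
weights are uniform), and `PathQuery(hop_count=True)` switches to the
unweighted fewest-edges mode.

Correlations are scalar projections (the `C_ij` above), not 3×3 tensor
correlations, and each trajectory (or trajectory window, or replicate) is
analysed independently; nothing is pooled across replicates.

### Windowed analysis

A `WindowScheme` partitions `[0, F)` into contiguous, non-overlapping
ranges (`WindowScheme.uniform(7, 3500)` gives seven 500-frame segments —
50 ns each at 0.1 ns/frame). Each window is analysed completely
independently (occupancy, correlation, network, paths); a single window
reproduces the full-trajectory analysis bit-identically because it runs
the same code on the same frames.

## Superposition metrics

Superposition is the Kabsch least-squares fit with reflections excluded
(via `scipy.spatial.transform.Rotation.align_vectors`); degenerate inputs
(< 3 points, collinear sets) are rejected rather than silently fitted.
RMSD series superpose each frame onto the reference over the chosen
selection. RMSF uses an *iterated mean* reference: the frame mean is
computed, frames are superposed onto it, and the mean is recomputed (two
passes), after which `RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩)`. The reference is
configurable to the first frame. Mass weighting is off by default — the
analyses here are Cα-level, where it is a no-op in practice. The default
RMSD selection in the CLI is Cα; heavy-atom RMSD is available through
selections.

A finite-size caveat that the tests make explicit: superposition absorbs
roughly six rigid-body degrees of freedom out of 3N, so measured
quantities on small systems sit slightly below their no-superposition
closed forms. Mean RMSD under isotropic per-component noise σ is close to
`√3·σ·√((N−3.5)/N)`, and planted pair correlations of 0.9 are recovered
at ≈0.88 on a 100-residue system (the common-mode removal subtracts a
shared component of order 1/N). Validation tolerances of 5 % are applied
at N = 100 where these effects are ≈1 %.

## Synthetic trajectory generator

The generator is a Gaussian elastic model over the Cα atoms of a
reference structure: displacements are zero-mean Gaussians with a
residue-level correlation matrix applied identically and independently to
x, y and z (full covariance `kron(D K D, I₃)` with `D = diag(σ_i)`), so
the scalar displacement cross-correlation of residues i, j equals
`K_ij` by construction. Frames are sampled independently — no temporal
autocorrelation — because every quantity the downstream stages consume
(occupancy fractions, cross-correlations, fluctuation profiles) is a
single-frame statistic. Sampling is fully seeded: the same model and seed
give bit-identical trajectories.

* **Planted correlation paths** set `K = rho^d` between path residues `d`
  steps apart along the chain (the AR(1) structure, PSD by construction);
  residues off the path are untouched. After planting, the matrix is
  re-projected onto the PSD cone by eigenvalue clipping (with diagonal
  renormalisation), since stacking multiple plants can break positive
  semidefiniteness.
* **Planted contacts** realise a prescribed occupancy exactly: in a
  Bernoulli(occupancy) fraction of frames the pair separation is set to
  `d_in` (default 4.0 Å, inside the cutoff), otherwise `d_out` (6.0 Å),
  by moving the second residue along the instantaneous pair axis. A chain
  of contacts listed head-to-tail stays exactly consistent because each
  residue is only repositioned after its predecessor has settled.
  Planting a pair that is *far* apart in the reference relocates the
  second residue wholesale and makes it co-move with its anchor
  (correlation → 1); the generator warns in that case, and the intended
  use — pairs already near contact distance — only pins the radial
  component, which biases the pair correlation towards (2·K_ij + 1)/3.
* **Toy folds**: straight chain (3.8 Å Cα spacing), ideal α-helix
  (radius 2.3 Å, rise 1.5 Å, 100°/residue — giving i, i±3 spatial
  neighbours at ≈5 Å, convenient for planting), and a two-chain
  interface model (parallel chains 5.4 Å apart).

`planted_path_benchmark()` is the canonical recovery scenario: a
28-residue helix, a planted correlation-0.9 chain with occupancy-1.0
contacts in hops of 3 from the first to the last residue, and a decoy
chain over the interleaved residues with the same occupancy-1.0 contacts
but no planted correlation. Decoy edges carry |C| of roughly 1/3
(radial-pinning bias) to 0.8 (chained satellites), i.e. weights ≥ 0.19,
while planted edges cost ≈ 0.05 — so replacing even one planted edge with
any detour is more expensive than the whole planted path, and recovery is
stable across seeds. Problem sizes used in validation (5000-frame
trajectories, 5 seeds; 10⁴ frames for closed-form checks; 100 random
graphs for the enumeration oracle) were chosen to put Monte-Carlo noise
an order of magnitude below the tested tolerances.

**What passing these tests shows — and does not.** They show the analysis
chain is correct: planted statistical structure propagates through
occupancy, correlation, weighting and search, and comes back intact. They
do not show anything about real MD ensembles, which have temporal
autocorrelation (effective sample sizes far below the frame count),
anharmonic and multi-basin dynamics, and side-chain-mediated contacts
that a Cα elastic model does not represent.

## SASA, interface burial and hydrophobicity

SASA is Shrake–Rupley with a deterministic golden-spiral quadrature
(default 960 points/atom, probe 1.4 Å) and the Bondi (1964) van der Waals
radius set, named in output headers because buried-area figures move by
several percent between published radius tables. Heteroatoms (waters,
ions, nucleotide analogues, Zn²⁺) are excluded by default and togglable —
burial numbers are sensitive to this, so the flag is logged.

Buried surface area between chain groups A and B is
`(SASA(A) + SASA(B) − SASA(A∪B))/2` — the **one-sided** convention of
crystallographic interface reports; the two-sided value is also returned.
Interface residues are those losing > 0.1 Å² of per-residue SASA on
complexation.

The hydrophobicity statistic is a resampling *analog* of the
interface-significance p-values printed by interface-analysis servers,
not a reproduction of any solvation free-energy model: the score of a
residue set is its mean Kyte–Doolittle hydropathy; random contiguous
patches of the interface's residue count are grown by seeded BFS on the
surface graph (surface residues linked at Cα distance < 8 Å); the mid-p
fraction of patches scoring at least as hydrophobic as the interface is
returned. Mid-p handles the all-ties degenerate case (uniform
composition) by returning 0.5, i.e. "indistinguishable from a random
patch".

## Dimer construction

Symmetry operators are explicit rotation + translation pairs in the
orthogonal frame. When a structure carries CRYST1 information, its
space-group operators are captured (via gemmi) and
`find_crystal_contact_operator` selects the involutive operator (plus
lattice shift, ±1 cell) whose mate makes the closest non-clashing
approach — the operator that generates the physical crystallographic
dimer. Full space-group assembly expansion is deliberately not
implemented: one explicit two-fold is all these analyses need, and
explicit operators are auditable.

`build_dimer_by_superposition` carries a larger complex into the dimer
arrangement of a template: the complex is Kabsch-superposed onto each
template protomer over an anchor selection (for Ras–Raf work, the
G-domain Cα trace, residues 1–166), anchors being matched by
(resid, insertion code, atom name) so the template may be a smaller
construct. Per-protomer anchor RMSDs are reported as provenance. Clash
policy for assembled models: inter-protomer contacts closer than 1.5 Å
are an error, closer than 2.5 Å a warning — thresholds meant to catch
gross construction errors, not to validate packing.

## Numerical choices and limitations

* PDB I/O preserves author residue numbering verbatim; altloc handling
  keeps the blank/'A' conformer; insertion codes are part of residue
  identity. Coordinates round-trip at the format's 3-decimal precision.
* Trajectory time steps default to 0.1 ns/frame when a file carries no
  time information, and are always overridable; windowing logic is
  frame-based with time derived from `dt`.
* PSD repair clips eigenvalues at zero; sampling rejects covariance with
  eigenvalues below −1e−8 (relative), naming the offending eigenvalue.
* Zero-variance residues make correlations undefined and raise an error
  naming the residue rather than propagating NaNs.
* The SASA quadrature converges at the < 0.5 % level on smooth protein
  surfaces when the point count doubles; sharp Cα-only toy geometries
  converge more slowly, which the tests account for explicitly.
* The path enumeration cap (`max_paths`) bounds worst-case Yen runtime on
  dense graphs; hitting the cap truncates the suboptimal ensemble, which
  is reported by its size.
* Two published structural measurements (the ≈1005 Å² interface of the
  KRas–CRaf-RBD_CRD crystallographic dimer, PDB 6XI7, checked at ±10 %
  for radius-table dependence; the ≈85 Å D113–D113′ Cα span of the
  4G0N dimer, checked at ±5 Å since the printed value's atom pair is not
  stated) are implemented end-to-end but require the deposited
  coordinates, which this package does not redistribute; the
  corresponding tests fail with an explanatory message when the files are
  absent.
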