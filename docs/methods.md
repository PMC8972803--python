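# Methods

This note records the models implemented in `globaldyn`, the
assumptions behind them, the defaults that matter, and the numerical
choices made where the design was genuinely open.

## Elastic network models

Both network models treat the experimentally resolved structure as an
energy minimum and connect coarse-grained nodes (one per residue, at
the C-alpha) by harmonic springs with a uniform force constant γ inside
a distance cutoff.

**ANM.** The potential is V = (γ/2) Σ (r_ij − r_ij⁰)² over pairs with
r_ij⁰ ≤ r_cut. Its analytical Hessian is assembled from 3×3
super-elements H_ij = −(γ/r_ij⁰²) x_ij⁰ x_ij⁰ᵀ with diagonal blocks
H_ii = −Σ_j H_ij, which makes H symmetric, positive semi-definite and
translation-invariant by construction; a unit test checks it against
central finite differences of the potential. **GNM** uses the N×N
Kirchhoff matrix Γ_ij = −γ for contacts, Γ_ii = degree·γ.

Defaults: γ = 1 (reduced units; all fluctuations come out in k_BT/γ),
r_cut = 15 Å (ANM) and 10 Å (GNM) — the standard residue-level values
in the elastic-network literature. Both are exposed everywhere.

**Modes and zero-mode bookkeeping.** Eigenvalues below 1e−6 × λ_max
are treated as rigid-body modes, removed and counted; the count is
sanity-checked against the expectation (6 for a connected,
non-collinear ANM; 1 for a connected GNM; scaled by the number of
contact-graph components, which is detected and warned about).
Collinear or disconnected geometries legitimately violate the 3N−6
rule — they produce a warning, never silent truncation. Retained modes
are sorted softest-first ("mode 1" is the lowest nonzero mode) and
given a deterministic sign (largest-magnitude component positive) so
outputs are identical across eigensolvers. Dense symmetric
eigendecomposition is used throughout; the structures this package
targets (≤ a few thousand nodes) do not need sparse solvers.

**Fluctuations.** MSF_i = Σ_k λ_k⁻¹ ‖p_k at node i‖² for ANM;
3·Σ_k λ_k⁻¹ p_{k,i}² for GNM. The factor of 3 converts the GNM's
per-coordinate isotropic fluctuation into a per-node value and is a
convention choice, documented here because other codes report Γ⁺_ii
without it. Mode covariances C = Σ var_k p_k p_kᵀ reduce to the
Moore–Penrose pseudo-inverse of the model matrix when all nonzero
modes are retained.

**VSA.** The reduction onto a subsystem is the Schur complement
H_eff = H_ss − H_se H_ee⁺ H_es (pseudo-inverse so that singular
environment blocks are tolerated). One subtlety is deliberate: for an
unanchored network, pinv(H_eff) and the subsystem block of pinv(H)
differ by rigid-body terms, because the two pseudo-inverses fix
different gauges — pinv(H) is orthogonal to whole-system rigid
motions, pinv(H_eff) to subsystem rigid motions. On the nonrigid
subspace of H_eff the two covariances agree to machine precision, and
that is the form the tests assert. Physical observables built from
internal coordinates are gauge-independent either way.

## Superposition and ensembles

Pairwise fits use the weighted Kabsch algorithm (SVD of the weighted
cross-covariance; reflections corrected by flipping the smallest
singular vector, so rotations are always proper). Near-collinear node
sets give a warning — the optimal rotation is then not unique — but a
valid solution is still returned.

Ensembles are aligned by iterative superposition: every member is
fitted to the running mean, the mean recomputed, until the mean moves
by less than 1e−5 Å RMSD (well below PDB coordinate precision) or 50
iterations. The initial reference is the ensemble's reference member
(member 0 by default) for determinism. Each iteration is a descent
step on the total variance about the mean, so the recorded variance
history is non-increasing; non-convergence is flagged on the result,
not raised. Nodes absent from a member (alignment gaps) carry zero
weight in fits and means, and columns absent from any member are
excluded from covariance analysis (common-core analysis). Trimming of
flexible termini/loops is a plain column filter applied consistently
to coordinates, labels and mask.

## Ensemble PCA

The covariance is normalised by 1/M (the plain average of deviation
outer products), switchable to 1/(M−1); with the 1/M convention the
noise-free two-state fixture has PC1 eigenvalue exactly a²/4. PCA is
always about the ensemble mean. Components with σ below 1e−12 × σ_max
are dropped (these include the rigid-body directions removed by
superposition); at most min(3N, M−1) PCs can be nonzero. Projections
are reported in Å along unit modes; dividing by √N turns a projection
into the RMSD it contributes per node — the same 1/√N factor relates a
conformer-generation coefficient c to its RMSD from the reference.

Adding a PC "with fraction f of its variance" means amplitude
c = sqrt(f·σ): the generated conformer sits at f times the mode's
variance from the mean. This r.m.s.-amplitude reading is a convention
choice; raw-amplitude coefficients are the default interface.

Landscape densities over 2D projections use 25×25 histograms
(normalised to sum to 1) or a Gaussian KDE with Scott's-rule bandwidth
(normalised to integrate to 1 on the evaluation grid); free energy is
G = −ln(ρ/ρ_max) in k_BT, +∞ on empty bins. These are first
estimates: they assume the ensemble samples the accessible states with
meaningful occupancies.

## Signature dynamics

Mode similarity uses the correlation cosine with absolute value (an
eigenvector's sign is arbitrary). Sets of modes are compared by the
Hess covariance overlap; numerically it is evaluated as
Ω = 1 − sqrt(‖C_A^½ − C_B^½‖_F² / (tr C_A + tr C_B)) with the matrix
square roots expressed in an orthonormal basis of the joint mode
subspace. This is algebraically identical to the familiar
variance-weighted squared-dot-product expression but cancellation-free:
the naive form loses half the working precision when A ≈ B, which
matters because Ω(A,A) = 1 is a property tests rely on exactly.

Family comparisons default to the 20 softest modes — the global end of
the spectrum, where dynamics is most conserved across homologs — and
the dissimilarity is d = 1 − Ω, the simplest monotone transform; both
are exposed parameters. Mode matching is greedy on the overlap matrix
(global maximum first, ties to the lowest row then column index).
Ragged member sizes are refused: members must come through the
alignment/common-core path first, so profiles stay in column
correspondence.

Trees are UPGMA (size-weighted average linkage), chosen over
neighbour-joining for determinism and an ultrametric output that is
directly comparable across families; ties in the minimum distance
break on the lexicographically smallest pair of cluster labels.
Output is Newick with branch lengths.

## Pseudoatoms from density maps

Maps are voxel grids in Å with a voxel-center origin convention,
read/written as MRC2014 (modes 0/1/2) through gemmi with axis order
normalised to x, y, z. Synthetic maps place an isotropic Gaussian of
σ = resolution/(2√(2 ln 2)) (FWHM = resolution) on each node,
normalised to the node weight.

Neural-gas fitting draws training points from the above-threshold
voxels with probability proportional to density (uniform jitter inside
the voxel avoids lattice-locked codebooks), ranks all K codebook
vectors by distance and updates each by ε(t)·exp(−rank/λ(t))·(x − w),
with ε annealed 0.5 → 0.005 and λ annealed K/3 → 0.01 exponentially —
the schedule of the original neural-gas literature. The step count
defaults to max(20000, 200K), and the returned positions are the
Polyak average of the iterates over the final 25% of the schedule.
The averaging matters: with a fixed final step ε_f, each codebook
jitters around its target with per-axis standard deviation
≈ sqrt(ε_f/2)·σ of its cell, which for a small K on a wide map is
several ångströms; averaging over many correlation times of the tail
removes it (K = 1 recovers the density-weighted centroid of a 40 Å
four-blob map to ~0.3 Å). Weights are assigned post hoc as the density
mass of each codebook's nearest-neighbour cell, so they conserve the
total above-threshold mass exactly; the stored quantization error is
the density-weighted mean squared distance of voxel centers to their
nearest codebook. Identical seeds give bit-identical models.

Atom↔pseudoatom mapping is brute-force nearest neighbour (ties to the
lowest pseudoatom index). Pseudoatom ANM reuses the elastic-model
machinery with a cutoff of 2.0 × the mean nearest-neighbour codebook
distance by default — elastic-network cutoffs must scale with the
coarse-graining level — and is exposed for override.

## Synthetic fixtures

The generators exist so every pipeline is testable against planted
ground truth without downloads, and they define what the tests do and
do not show.

- `make_lattice_structure`: n³ nodes on a cubic lattice, 3.8 Å spacing
  (the C-alpha virtual bond length). Compact and non-collinear, so ANM
  zero-mode counting behaves as for a globular protein; it has none of
  a real fold's contact anisotropy.
- `make_two_state_ensemble`: members alternate between
  base ± (a/2)·d for a planted unit 3N direction d, plus isotropic
  Gaussian noise. The noise scale is the r.m.s. magnitude of each
  member's total 3N noise displacement (per-coordinate std
  = noise_sigma/√(3N)), so amplitude and noise are on the same
  collective scale and "amplitude = 10 × noise" means the planted
  motion truly dominates the variance (fraction a²/4 / (a²/4 + σ²)).
  Members are generated in a common frame — no rigid motion is applied
  — so the ensemble is already aligned and PCA can be applied directly;
  superposing first would remove the planted direction's rigid-subspace
  component (about 3% of a random direction's squared norm) and cap
  the recoverable overlap accordingly. Defaults: amplitude 4 Å, noise
  0.4 Å, M = 50.
- `make_blob_map`: well-separated isotropic Gaussian blobs with known
  centers and weights.

Passing tests on these fixtures demonstrate correctness of the
machinery (recovery of planted signals, analytic identities, oracle
agreement), not performance on real data: real ensembles have
correlated, anisotropic noise, alignment gaps and multiple motions;
real maps have noise, B-factor blurring and non-Gaussian features.

## Degenerate inputs and determinism

Coincident nodes are a hard error (the ANM super-element is undefined).
Collinear geometries warn and proceed. All randomized procedures take
explicit seeds (never global state) and are bit-reproducible;
eigenvector signs, greedy tie-breaks and UPGMA tie-breaks are all
deterministic. PDB B-factors written by the tools are clamped to
[0, 999.99] as the fixed-width format requires; altloc records resolve
to the highest occupancy with the first record winning ties.

## Problem sizes

Tests and the acceptance script run on 8–192-node structures, 50-member
ensembles and ~30³-voxel maps — sizes at which every quantity checked
(eigenstructure, recovery overlaps, oracle agreement) is already fully
expressed, while the whole suite stays fast. Nothing in the
implementation is specific to these sizes; dense eigendecomposition is
the only super-linear step.
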