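# globaldyn

Coarse-grained analysis of protein **global dynamics**: elastic-network
normal mode analysis (ANM/GNM), essential-dynamics PCA of structural
ensembles, comparative "signature dynamics" across protein families,
vibrational subsystem analysis (VSA), and neural-gas pseudoatom fitting
of cryoEM-style density maps with downstream pseudoatom NMA.

It is written for structural biologists and biophysicists who want the
collective, low-frequency motions of a protein or complex — the motions
that carry function — from nothing more than one structure (NMA), a set
of related structures (PCA), or a density map (pseudoatoms), without
running molecular dynamics.

## The models

A structure is reduced to one node per residue (the C-alpha), giving the
3N-dimensional coordinate vector **q** = (x₁, y₁, z₁, …, x_N, y_N, z_N).

**ANM.** Nodes closer than a cutoff r_cut (default 15 Å) are connected
by springs with uniform force constant γ (reduced units, γ = 1):

    V = (γ/2) Σ_{r⁰ᵢⱼ ≤ r_cut} (rᵢⱼ − r⁰ᵢⱼ)²

The analytical Hessian **H** has 3×3 super-elements
Hᵢⱼ = −(γ/r⁰ᵢⱼ²)·x⁰ᵢⱼ x⁰ᵢⱼᵀ off the diagonal and Hᵢᵢ = −Σⱼ Hᵢⱼ.
Eigendecomposition yields 3N−6 nonzero normal modes (six rigid-body
modes have eigenvalue zero); eigenvectors are the directions of
collective motion, eigenvalues the squared frequencies, and 1/λₖ the
per-mode variance. The **GNM** is the isotropic N×N counterpart built
on the Kirchhoff (connectivity) matrix (cutoff default 10 Å), with one
zero mode.

**Ensemble PCA (essential dynamics).** For M superposed conformations,
the positional covariance **C** = (1/M) Σₘ Δ**q**ₘ Δ**q**ₘᵀ is
decomposed into principal components **p**ₖ with variances σₖ; the top
PCs capture the dominant conformational changes, members project onto
them as Δ**q**ₘ·**p**ₖ (Å), and densities over 2D projections give a
first estimate of the conformational free-energy landscape,
G = −ln(ρ/ρ_max) in k_BT.

**Signature dynamics.** Per-member modes are compared by the
correlation cosine |**v**·**w**|/(‖v‖‖w‖) and by the Hess covariance
overlap Ω ∈ [0, 1] over mode sets; families are summarised as
mean ± std fluctuation profiles and clustered into dynamics-based trees
(UPGMA on d = 1 − Ω).

**Pseudoatoms.** A density map is coarse-grained into K pseudoatoms by
neural-gas vector quantization (rank-annealed codebook updates on
density-weighted samples); pseudoatoms carry their Voronoi density
mass, map back to atoms by nearest neighbour, and feed the ANM with a
cutoff rescaled to the coarse spacing.

## Worked example

Generate a synthetic two-state ensemble with one planted collective
motion (64 nodes, amplitude 4 Å against noise 0.4 Å, 50 members) and
recover it by PCA:

```python
import globaldyn as gd
from globaldyn.pca import variance_fractions

base = gd.make_lattice_structure(4)                    # 64-node lattice
gen  = gd.make_two_state_ensemble(base, amplitude=4.0,
                                  noise_sigma=0.4, m=50, seed=11)
cov  = gd.ensemble_covariance(gen.ensemble)
pcs  = gd.pca_modes(cov)
print(f"PC1 variance fraction: {variance_fractions(pcs)[0]:.3f}")
print(f"PC1 . planted direction: {gd.mode_overlap(pcs.mode(0), gen.direction):.4f}")
print(f"PC1 eigenvalue: {pcs.variances[0]:.3f}")
```

prints

```
PC1 variance fraction: 0.963
PC1 . planted direction: 0.9996
PC1 eigenvalue: 4.033
```

— PC1 carries 96% of the total variance, points within 1.6° of the
planted direction, and its eigenvalue matches the planted two-state
variance a²/4 = 4.0 Å². Normal modes of the same lattice:

```python
modes = gd.compute_modes(gd.build_anm_hessian(base), 10)
print(modes.n_zero, modes.eigenvalues[:3].round(3), gd.msf(modes).max().round(4))
# 6 [6.375 6.375 8.764] 0.1304
```

— exactly six rigid-body modes are removed and the two softest internal
modes are a degenerate pair (the lattice's symmetry), with mean-square
fluctuations in units of k_BT/γ.

The same pipelines run from the shell:

```sh
globaldyn synth two-state --n 64 --amplitude 4 --noise 0.4 --m 50 \
    --seed 11 --out ens.pdb --truth truth.json
globaldyn pca --in ens.pdb --nmodes 3 --out pcs.json --proj proj.tsv
# globaldyn: PCA variance fractions: 0.963, 0.002, 0.002
```

and a density-map pipeline fits pseudoatoms (here 4 planted Gaussian
blobs are each recovered to within 0.2 Å):

```sh
globaldyn synthmap --in nodes.pdb --res 8 --voxel 2 --out map.mrc
globaldyn fitpseudo --map map.mrc --k 4 --seed 7 --out pseudo.pdb
```

Subcommands: `convert`, `superpose`, `anm`, `gnm`, `pca`, `morph`,
`signdy`, `fitpseudo`, `synthmap`, `synth`. Every run logs its full
parameter set (and seed) to stderr; `--manifest run.json` records it as
JSON for exact reproduction.

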