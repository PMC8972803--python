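"""Synthetic fixtures with planted ground truth.

Every generator is deterministic under an explicit seed and returns the
planted truth next to the data, so tests (and users exploring the
methods) never have to re-derive what was put in.  The geometry is
deliberately idealized — cubic lattices rather than protein folds, a
single dominant motion plus isotropic Gaussian coordinate noise, and
well-separated Gaussian blobs for density maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError
from .pseudoatoms import DensityGrid, synth_density
from .structures import Ensemble, NodeSet

__all__ = [
    "make_lattice_structure",
    "make_two_state_ensemble",
    "make_blob_map",
    "TwoStateEnsemble",
    "BlobMap",
]


def make_lattice_structure(n_side: int, spacing: float = 3.8) -> NodeSet:
    """n_side³ nodes on a cubic lattice (chain A, sequential numbering).

    The default spacing of 3.8 Å matches the C-alpha virtual bond length
    so the lattice behaves like a generic compact protein-scale object.
    """
    if n_side < 2:
        raise ValueError("n_side must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    axes = spacing * np.arange(n_side)
    gx, gy, gz = np.meshgrid(axes, axes, axes, indexing="ij")
    coords = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    labels = [("A", str(i + 1), "GLY") for i in range(coords.shape[0])]
    return NodeSet(labels, coords)


@dataclass
class TwoStateEnsemble:
    """A generated ensemble plus its planted ground truth."""

    ensemble: Ensemble
    direction: np.ndarray  # planted unit 3N vector
    amplitude: float
    noise_sigma: float
    seed: int | None
    base: NodeSet

    def truth(self) -> dict:
        return {
            "direction": self.direction.tolist(),
            "amplitude": self.amplitude,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "planted_pc1_variance": self.amplitude ** 2 / 4.0,
        }


def make_two_state_ensemble(
    base: NodeSet,
    direction: np.ndarray | None = None,
    amplitude: float = 4.0,
    noise_sigma: float = 0.4,
    m: int = 50,
    seed: int | None = None,
) -> TwoStateEnsemble:
    """Ensemble hopping between base ± (amplitude/2)·direction plus noise.

    Half the members sit at each endpoint of a single planted collective
    motion, with isotropic Gaussian noise on top — the simplest ensemble
    with one dominant principal component (whose noise-free variance
    under the 1/M convention is amplitude²/4).  ``amplitude`` and
    ``noise_sigma`` live on the same collective scale: noise_sigma is
    the r.m.s. magnitude of each member's total 3N noise displacement
    (per-coordinate std = noise_sigma / sqrt(3N)), so the planted
    motion truly dominates whenever amplitude >> noise_sigma.  Members
    are generated in a common frame — no rigid motion is applied — so
    the ensemble is already aligned for covariance analysis.  When
    ``direction`` is omitted a random unit vector is drawn from the
    same seed.
    """
    if m < 2:
        raise ShapeError("need M >= 2 members")
    rng = np.random.default_rng(seed)
    n3 = 3 * base.n_nodes
    if direction is None:
        direction = rng.standard_normal(n3)
    direction = np.asarray(direction, dtype=float).ravel()
    if direction.size != n3:
        raise ShapeError(f"direction must have length 3N = {n3}")
    direction = direction / np.linalg.norm(direction)
    signs = np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
    disp = (amplitude / 2.0) * direction.reshape(-1, 3)
    members = base.coords[None, :, :] + signs[:, None, None] * disp[None, :, :]
    members = members + rng.normal(
        0.0, noise_sigma / np.sqrt(n3), size=members.shape
    )
    ens = Ensemble(list(base.labels), members)
    return TwoStateEnsemble(ens, direction, amplitude, noise_sigma, seed, base)


@dataclass
class BlobMap:
    """A generated blob map plus its planted ground truth."""

    grid: DensityGrid
    centers: np.ndarray
    weights: np.ndarray
    sigma: float

    def truth(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "sigma": self.sigma,
        }


def make_blob_map(
    centers,
    weights=None,
    sigma: float = 4.0,
    voxel: float = 2.0,
    pad: float | None = None,
) -> BlobMap:
    """Density map of isotropic Gaussian blobs at planted centers."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 1 or centers.shape[1] != 3:
        raise ShapeError("centers must be (n, 3) with n >= 1")
    w = np.ones(centers.shape[0]) if weights is None else np.asarray(
        weights, dtype=float
    ).ravel()
    if w.shape != (centers.shape[0],):
        raise ShapeError("one weight per blob required")
    grid = synth_density(centers, sigma=sigma, voxel=voxel, pad=pad, weights=w)
    return BlobMap(grid, centers, w, sigma)
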