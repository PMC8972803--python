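"""Pseudoatom coarse-graining of density maps and downstream ENM handoff.

A cryoEM-style map is represented as a voxel grid (Å units, voxel-center
origin).  Neural-gas vector quantization (the topology-representing
network, TRN) places K codebook vectors — pseudoatoms — to represent
the above-threshold density: at every step a point is drawn from the
density, all codebook vectors are ranked by distance to it, and each is
pulled towards the point by ε(t)·exp(−rank/λ(t)), with ε and λ annealed
exponentially.  Pseudoatoms then carry the density mass of their
nearest-neighbour (Voronoi) cells as weights, map back to atoms by
nearest neighbour, and feed the anisotropic network model with a cutoff
rescaled to the coarser spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .elastic import ENMParameters, HessianMatrix, ModeSet, build_anm_hessian, compute_modes
from .errors import DensityFormatError, ShapeError
from .structures import NodeSet

__all__ = [
    "DensityGrid",
    "PseudoatomModel",
    "NeuralGasSchedule",
    "read_density",
    "write_density",
    "synth_density",
    "trn_fit",
    "map_pseudoatoms_to_atoms",
    "pseudoatom_anm",
    "pseudoatoms_to_nodes",
]

_SIGMA_PER_RESOLUTION = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # FWHM = resolution


@dataclass
class DensityGrid:
    """3D voxel map: values[ix, iy, iz], voxel size and origin in Å.

    ``origin`` is the Cartesian position of the *center* of voxel
    (0, 0, 0); axis order is (x, y, z) with x fastest in file storage.
    """

    values: np.ndarray
    voxel: np.ndarray  # (3,) Å per axis
    origin: np.ndarray  # (3,) Å
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError("density values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise DensityFormatError("density contains non-finite values")
        self.voxel = np.broadcast_to(
            np.asarray(self.voxel, dtype=float).ravel(), (3,)
        ).copy()
        if np.any(self.voxel <= 0):
            raise ValueError("voxel size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).ravel().copy()
        if self.origin.shape != (3,):
            raise ShapeError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) Cartesian centers, C-order matching values.ravel()."""
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
        return self.origin + idx * self.voxel

    def above_threshold(self, threshold: float | None = None):
        """(centers, masses) of voxels strictly above the threshold."""
        thr = self.threshold if threshold is None else threshold
        flat = self.values.ravel()
        keep = flat > thr
        return self.voxel_centers()[keep], flat[keep]

    def total_mass(self, threshold: float | None = None) -> float:
        _, masses = self.above_threshold(threshold)
        return float(masses.sum())


@dataclass
class NeuralGasSchedule:
    """Annealing schedule for the neural-gas updates.

    ``eps`` is the learning step, ``lam`` the neighbourhood range in
    rank units; both decay exponentially from initial to final over
    ``steps`` samples.  Defaults follow the original neural-gas
    literature (ε: 0.5 → 0.005), with λ_i scaling with K and a floor on
    the step count so that the stationary jitter of each codebook,
    ~sqrt(ε_f/2)·σ of its cell, is averaged down by the tail averaging
    in :func:`trn_fit` even for small K.
    """

    eps_i: float = 0.5
    eps_f: float = 0.005
    lam_i: float | None = None  # default K / 3
    lam_f: float = 0.01
    steps: int | None = None  # default max(20000, 200 * K)

    def resolve(self, k: int) -> tuple[float, float, float, float, int]:
        lam_i = self.lam_i if self.lam_i is not None else max(k / 3.0, 0.01)
        steps = self.steps if self.steps is not None else max(20000, 200 * k)
        if steps < 1:
            raise ValueError("schedule needs steps >= 1")
        return self.eps_i, self.eps_f, lam_i, self.lam_f, int(steps)


@dataclass
class PseudoatomModel:
    """Fitted codebook vectors with density-mass weights."""

    positions: np.ndarray  # (K, 3) Å
    weights: np.ndarray  # (K,) density mass of each Voronoi cell
    seed: int | None = None
    schedule: NeuralGasSchedule | None = None
    quantization_error: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.weights = np.asarray(self.weights, float).ravel()
        if self.positions.shape[0] < 1 or self.positions.shape[1] != 3:
            raise ShapeError("positions must be (K, 3) with K >= 1")
        if self.weights.shape != (self.positions.shape[0],):
            raise ShapeError("one weight per pseudoatom required")

    @property
    def k(self) -> int:
        return self.positions.shape[0]


# ---------------------------------------------------------------------------
# MRC2014 I/O (via gemmi)

def read_density(path) -> DensityGrid:
    """Read an MRC2014 map (modes 0/1/2); axes normalized to (x, y, z)."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise DensityFormatError(f"cannot read MRC map {path}: {exc}") from exc
    mode = ccp4.header_i32(4)
    if mode not in (0, 1, 2):
        raise DensityFormatError(
            f"unsupported MRC MODE field: {mode} (only 0/1/2 accepted)"
        )
    ccp4.setup(float("nan"))
    values = np.array(ccp4.grid, copy=True, dtype=float)
    if np.any(~np.isfinite(values)):
        raise DensityFormatError("map has unfilled or non-finite voxels")
    cell = ccp4.grid.unit_cell
    shape = values.shape
    voxel = np.array([cell.a / shape[0], cell.b / shape[1], cell.c / shape[2]])
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    if np.allclose(origin, 0.0):
        nstart = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * voxel
    return DensityGrid(values, voxel, origin)


def write_density(grid: DensityGrid, path) -> None:
    """Write a DensityGrid as MRC2014 (mode 2, float32, ORIGIN header)."""
    data = np.ascontiguousarray(grid.values, dtype=np.float32)
    g = gemmi.FloatGrid(data)
    nx, ny, nz = grid.shape
    g.set_unit_cell(gemmi.UnitCell(
        nx * grid.voxel[0], ny * grid.voxel[1], nz * grid.voxel[2],
        90.0, 90.0, 90.0,
    ))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# synthetic maps

def synth_density(
    nodes: NodeSet | np.ndarray,
    resolution: float | None = None,
    voxel: float = 2.0,
    pad: float | None = None,
    weights=None,
    sigma: float | None = None,
) -> DensityGrid:
    """Gaussian-smeared density from point coordinates.

    Each node contributes an isotropic 3D Gaussian of width
    σ = resolution / (2 sqrt(2 ln 2)) (so FWHM = resolution), normalized
    to its weight (default 1), sampled at voxel centers.  ``pad``
    (default 3σ) extends the box beyond the coordinate extrema.
    """
    coords = nodes.coords if isinstance(nodes, NodeSet) else np.atleast_2d(
        np.asarray(nodes, float)
    )
    if sigma is None:
        if resolution is None or resolution <= 0:
            raise ValueError("give a positive resolution (or an explicit sigma)")
        sigma = resolution * _SIGMA_PER_RESOLUTION
        if voxel > resolution / 2.0:
            raise ValueError(
                f"voxel {voxel} A too coarse for resolution {resolution} A "
                "(need voxel <= resolution / 2)"
            )
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if pad is None:
        pad = 3.0 * sigma
    w = np.ones(len(coords)) if weights is None else np.asarray(weights, float)
    if w.shape != (len(coords),):
        raise ShapeError("one weight per node required")
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    n_vox = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    axes = [lo[d] + voxel * np.arange(n_vox[d]) for d in range(3)]
    values = np.zeros(tuple(n_vox))
    norm = (2.0 * math.pi * sigma ** 2) ** 1.5
    for c, wi in zip(coords, w):
        if wi == 0:
            continue
        gx = np.exp(-((axes[0] - c[0]) ** 2) / (2 * sigma ** 2))
        gy = np.exp(-((axes[1] - c[1]) ** 2) / (2 * sigma ** 2))
        gz = np.exp(-((axes[2] - c[2]) ** 2) / (2 * sigma ** 2))
        values += (wi / norm) * np.einsum("i,j,k->ijk", gx, gy, gz)
    return DensityGrid(values, np.full(3, float(voxel)), lo)


# ---------------------------------------------------------------------------
# neural-gas fitting

def trn_fit(
    grid: DensityGrid,
    k: int,
    schedule: NeuralGasSchedule | None = None,
    seed: int | None = None,
    threshold: float | None = None,
    jitter: bool = True,
    tail_average: float = 0.25,
) -> PseudoatomModel:
    """Fit K pseudoatoms to a density map by neural-gas vector quantization.

    Training points are voxel centers drawn with probability proportional
    to their above-threshold density, with uniform jitter inside the
    voxel (on by default) to avoid lattice-locked codebooks.  The
    returned positions are the Polyak average of the iterates over the
    final ``tail_average`` fraction of the schedule (0 disables), which
    removes the residual stochastic jitter of the final learning step.
    The run is fully reproducible from ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    schedule = schedule or NeuralGasSchedule()
    centers, masses = grid.above_threshold(threshold)
    if masses.size == 0:
        raise ValueError("no voxels above threshold: cannot fit pseudoatoms")
    if masses.size < k:
        raise ValueError(
            f"K={k} exceeds the {masses.size} voxels above threshold"
        )
    eps_i, eps_f, lam_i, lam_f, steps = schedule.resolve(k)
    rng = np.random.default_rng(seed)
    prob = masses / masses.sum()
    # init: codebooks at K distinct density-weighted voxel draws
    init_idx = rng.choice(masses.size, size=k, replace=False, p=prob)
    w = centers[init_idx].astype(float).copy()
    samples_idx = rng.choice(masses.size, size=steps, p=prob)
    offsets = (
        rng.uniform(-0.5, 0.5, size=(steps, 3)) * grid.voxel
        if jitter
        else np.zeros((steps, 3))
    )
    eps_ratio = eps_f / eps_i
    lam_ratio = lam_f / lam_i
    denom = max(steps - 1, 1)
    tail_start = steps - max(int(round(tail_average * steps)), 1) \
        if tail_average > 0 else steps
    tail_sum = np.zeros_like(w)
    tail_n = 0
    for t in range(steps):
        x = centers[samples_idx[t]] + offsets[t]
        frac = t / denom
        eps = eps_i * eps_ratio ** frac
        lam = lam_i * lam_ratio ** frac
        dist2 = np.sum((w - x) ** 2, axis=1)
        ranks = np.argsort(np.argsort(dist2, kind="stable"), kind="stable")
        w += (eps * np.exp(-ranks / lam))[:, None] * (x - w)
        if t >= tail_start:
            tail_sum += w
            tail_n += 1
    if tail_n > 0:
        w = tail_sum / tail_n
    # Voronoi mass assignment and quantization error on voxel centers
    d = cdist(centers, w)
    nearest = np.argmin(d, axis=1)
    weights = np.bincount(nearest, weights=masses, minlength=k)
    qerr = float(np.sum(masses * np.min(d, axis=1) ** 2) / masses.sum())
    return PseudoatomModel(
        positions=w,
        weights=weights,
        seed=seed,
        schedule=schedule,
        quantization_error=qerr,
        metadata={"threshold": grid.threshold if threshold is None else threshold,
                  "steps": steps},
    )


def map_pseudoatoms_to_atoms(
    model: PseudoatomModel, nodes: NodeSet
) -> tuple[np.ndarray, list[list[int]]]:
    """Nearest-neighbour atom → pseudoatom assignment.

    Returns ``(assignment, members)``: assignment[i] is the pseudoatom
    index of atom i (ties to the lowest index); members[p] lists the
    atoms assigned to pseudoatom p.
    """
    if model.k < 1 or nodes.n_nodes < 1:
        raise ShapeError("need at least one pseudoatom and one atom")
    d = cdist(nodes.coords, model.positions)
    assignment = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    members: list[list[int]] = [[] for _ in range(model.k)]
    for atom, p in enumerate(assignment):
        members[p].append(atom)
    return assignment, members


def pseudoatoms_to_nodes(model: PseudoatomModel) -> NodeSet:
    """Represent pseudoatoms as a NodeSet (chain P, sequential numbering)."""
    labels = [("P", str(i + 1), "PSD") for i in range(model.k)]
    return NodeSet(labels, model.positions.copy())


def pseudoatom_anm(
    model: PseudoatomModel,
    params: ENMParameters | None = None,
    cutoff_scale: float = 2.0,
    n_modes: int | None = None,
) -> ModeSet:
    """ANM normal modes of the pseudoatom model.

    With no explicit cutoff the ENM cutoff adapts to the coarse-graining
    level: ``cutoff_scale`` × the mean nearest-neighbour codebook
    distance (coarser models need proportionally longer springs).
    """
    if model.k < 2:
        raise ShapeError("pseudoatom ANM needs K >= 2")
    nodes = pseudoatoms_to_nodes(model)
    if params is None or params.cutoff is None:
        d = cdist(model.positions, model.positions)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        cutoff = cutoff_scale * float(nn.mean())
        gamma = params.gamma if params is not None else 1.0
        params = ENMParameters(gamma=gamma, cutoff=cutoff, model="ANM")
    hessian = build_anm_hessian(nodes, params)
    return compute_modes(hessian, n_modes)
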