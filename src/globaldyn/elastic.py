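"""Elastic network models: ANM/GNM matrices, normal modes, fluctuations, VSA.

The anisotropic network model (ANM) connects every pair of nodes closer
than a cutoff r_cut with a harmonic spring of uniform force constant γ,

    V = (γ/2) Σ_{r_ij⁰ ≤ r_cut} (r_ij − r_ij⁰)²,

whose analytical Hessian has 3x3 super-elements

    H_ij = −(γ / r_ij⁰²) · x_ij⁰ x_ij⁰ᵀ        (i ≠ j, within cutoff)
    H_ii = −Σ_{j≠i} H_ij,

with x_ij⁰ the equilibrium inter-node vector.  Its eigendecomposition
yields the 3N−6 nonzero normal modes (six rigid-body modes have zero
eigenvalue; "mode 1" here is the lowest nonzero mode, sometimes called
mode 7 elsewhere).  The Gaussian network model (GNM) is the isotropic
N x N counterpart built on the Kirchhoff (connectivity) matrix, with a
single zero mode for a connected network.

Units are reduced throughout: γ = 1 and k_B T = 1, so mode variances
are 1/λ and mean-square fluctuations come out in units of k_B T / γ.

Vibrational subsystem analysis (VSA) reduces the Hessian onto a chosen
subsystem by integrating out the environment through the Schur
complement H_ss − H_se H_ee⁺ H_es, the standard remedy for "tip
effects" from floppy termini and loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .errors import (
    ShapeError,
    SingularGeometryError,
    UnsupportedKindError,
    ZeroModeCountWarning,
)
from .structures import NodeSet

__all__ = [
    "ENMParameters",
    "HessianMatrix",
    "KirchhoffMatrix",
    "ModeSet",
    "build_anm_hessian",
    "build_gnm_kirchhoff",
    "compute_modes",
    "msf",
    "rmsf",
    "covariance_from_modes",
    "anm_potential",
    "vsa_reduce",
]

ANM_DEFAULT_CUTOFF = 15.0  # Angstrom, standard residue-level ANM value
GNM_DEFAULT_CUTOFF = 10.0
ZERO_MODE_RTOL = 1e-6  # λ < rtol * λ_max counts as a rigid-body mode
MIN_PAIR_DISTANCE = 1e-6


@dataclass(frozen=True)
class ENMParameters:
    """Uniform-spring network parameters (γ in reduced units, r_cut in Å)."""

    gamma: float = 1.0
    cutoff: float | None = None
    model: Literal["ANM", "GNM"] = "ANM"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def effective_cutoff(self) -> float:
        if self.cutoff is not None:
            return self.cutoff
        return ANM_DEFAULT_CUTOFF if self.model == "ANM" else GNM_DEFAULT_CUTOFF


@dataclass
class HessianMatrix:
    matrix: np.ndarray  # (3N, 3N)
    params: ENMParameters
    labels: list = field(default_factory=list)
    n_components: int = 1  # connected components of the contact graph

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class KirchhoffMatrix:
    matrix: np.ndarray  # (N, N)
    params: ENMParameters
    labels: list = field(default_factory=list)
    n_components: int = 1

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ModeSet:
    """Eigenvectors/eigenvalues from ANM, GNM or PCA with zero-mode bookkeeping.

    ``vectors`` holds orthonormal columns (3N- or N-dimensional);
    ``eigenvalues`` are the retained (nonzero) eigenvalues, ascending for
    ENMs, and ``variances`` the per-mode variance (1/λ for ENMs, the
    covariance eigenvalue σ_k for PCA, descending).
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    variances: np.ndarray
    n_zero: int
    kind: Literal["ANM", "GNM", "PCA"]
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.vectors.ndim != 2:
            raise ShapeError("mode vectors must form a (dim, k) matrix")
        k = self.vectors.shape[1]
        if self.eigenvalues.shape != (k,) or self.variances.shape != (k,):
            raise ShapeError("one eigenvalue and one variance per mode required")
        if not np.all(np.isfinite(self.variances)):
            raise ShapeError("mode variances must be finite")

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    @property
    def dim(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.dim // 3 if self.kind in ("ANM", "PCA") else self.dim

    def mode(self, k: int) -> np.ndarray:
        return self.vectors[:, k]


def _pair_distances(nodes: NodeSet) -> np.ndarray:
    d = squareform(pdist(nodes.coords))
    off = d[np.triu_indices_from(d, k=1)]
    if off.size and off.min() < MIN_PAIR_DISTANCE:
        i, j = np.unravel_index(
            np.argmin(d + np.eye(len(d)) * 1e9), d.shape
        )
        raise SingularGeometryError(
            f"nodes {i} and {j} are coincident (r = {d[i, j]:.2e} A)"
        )
    return d


def _contact_components(adjacency: np.ndarray) -> int:
    n_comp, _ = connected_components(adjacency, directed=False)
    return int(n_comp)


def build_anm_hessian(
    nodes: NodeSet, params: ENMParameters | None = None
) -> HessianMatrix:
    """Analytical ANM Hessian (3N x 3N) from equilibrium coordinates."""
    if params is None:
        params = ENMParameters(model="ANM")
    n = nodes.n_nodes
    if n < 2:
        raise ShapeError("ANM needs at least 2 nodes")
    dist = _pair_distances(nodes)
    cutoff = params.effective_cutoff
    gamma = params.gamma
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    h = np.zeros((3 * n, 3 * n))
    coords = nodes.coords
    for i in range(n):
        for j in np.flatnonzero(contact[i]):
            if j <= i:
                continue
            xij = coords[j] - coords[i]
            block = -(gamma / dist[i, j] ** 2) * np.outer(xij, xij)
            h[3 * i: 3 * i + 3, 3 * j: 3 * j + 3] = block
            h[3 * j: 3 * j + 3, 3 * i: 3 * i + 3] = block
    for i in range(n):
        diag = -sum(
            h[3 * i: 3 * i + 3, 3 * j: 3 * j + 3]
            for j in np.flatnonzero(contact[i])
        )
        if np.isscalar(diag):  # isolated node: zero block
            diag = np.zeros((3, 3))
        h[3 * i: 3 * i + 3, 3 * i: 3 * i + 3] = diag
    n_comp = _contact_components(contact.astype(int))
    if n_comp > 1:
        warnings.warn(
            f"contact graph has {n_comp} components at cutoff {cutoff} A; "
            "zero-mode count will exceed 6",
            ZeroModeCountWarning,
            stacklevel=2,
        )
    return HessianMatrix(h, params, list(nodes.labels), n_comp)


def build_gnm_kirchhoff(
    nodes: NodeSet, params: ENMParameters | None = None
) -> KirchhoffMatrix:
    """GNM Kirchhoff (connectivity) matrix: Γ_ij = −γ inside the cutoff."""
    if params is None:
        params = ENMParameters(model="GNM")
    n = nodes.n_nodes
    if n < 2:
        raise ShapeError("GNM needs at least 2 nodes")
    dist = _pair_distances(nodes)
    contact = (dist <= params.effective_cutoff) & ~np.eye(n, dtype=bool)
    gamma = params.gamma
    k = np.where(contact, -gamma, 0.0)
    np.fill_diagonal(k, gamma * contact.sum(axis=1))
    n_comp = _contact_components(contact.astype(int))
    if n_comp > 1:
        warnings.warn(
            f"contact graph has {n_comp} components; zero-mode count will "
            "exceed 1",
            ZeroModeCountWarning,
            stacklevel=2,
        )
    return KirchhoffMatrix(k, params, list(nodes.labels), n_comp)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| made positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def compute_modes(
    matrix: HessianMatrix | KirchhoffMatrix, n_modes: int | None = None
) -> ModeSet:
    """Normal modes of an ENM matrix, zero modes removed and counted.

    Eigenvalues below ``ZERO_MODE_RTOL * λ_max`` are treated as
    rigid-body modes; the expected count (6 for ANM, 1 for GNM, scaled
    by connected components) is sanity-checked with a warning on
    mismatch.  Retained modes are sorted ascending — softest first.
    """
    if isinstance(matrix, HessianMatrix):
        kind = "ANM"
        expected_zero = 6 * matrix.n_components if matrix.n_nodes > 2 else None
    elif isinstance(matrix, KirchhoffMatrix):
        kind = "GNM"
        expected_zero = 1 * matrix.n_components
    else:
        raise TypeError("expected a HessianMatrix or KirchhoffMatrix")
    evals, evecs = scipy.linalg.eigh(matrix.matrix)
    lam_max = float(evals[-1]) if evals.size else 0.0
    if lam_max <= 0:
        raise SingularGeometryError("matrix has no positive eigenvalues")
    zero = evals < ZERO_MODE_RTOL * lam_max
    n_zero = int(zero.sum())
    if expected_zero is not None and n_zero != expected_zero:
        warnings.warn(
            f"{kind}: found {n_zero} zero modes, expected {expected_zero} "
            "(collinear or otherwise degenerate geometry?)",
            ZeroModeCountWarning,
            stacklevel=2,
        )
    evals = evals[~zero]
    evecs = evecs[:, ~zero]
    avail = evals.size
    if n_modes is not None and n_modes > avail:
        warnings.warn(
            f"requested {n_modes} modes but only {avail} nonzero modes exist",
            UserWarning,
            stacklevel=2,
        )
    if n_modes is not None:
        evals = evals[:n_modes]
        evecs = evecs[:, :n_modes]
    evecs = _fix_signs(evecs)
    return ModeSet(
        vectors=evecs,
        eigenvalues=evals,
        variances=1.0 / evals,
        n_zero=n_zero,
        kind=kind,
        labels=list(matrix.labels),
    )


def msf(modes: ModeSet) -> np.ndarray:
    """Mean-square fluctuation per node in reduced units (k_B T / γ = 1).

    ANM:  MSF_i = Σ_k (1/λ_k) ‖p_k at node i‖²
    GNM:  MSF_i = 3 Σ_k (1/λ_k) p_{k,i}²   (per-node, 3 isotropic d.o.f.)
    """
    if modes.kind == "ANM":
        per_coord = (modes.vectors ** 2) @ modes.variances
        return per_coord.reshape(-1, 3).sum(axis=1)
    if modes.kind == "GNM":
        return 3.0 * (modes.vectors ** 2) @ modes.variances
    raise UnsupportedKindError(
        "msf is defined for ENM modes; use the ensemble variance for PCA"
    )


def rmsf(modes: ModeSet) -> np.ndarray:
    """Root-mean-square fluctuation per node, sqrt of :func:`msf`."""
    return np.sqrt(msf(modes))


def covariance_from_modes(modes: ModeSet) -> np.ndarray:
    """Covariance C = Σ_k var_k p_k p_kᵀ over the retained modes.

    With all nonzero ENM modes retained this is the Moore-Penrose
    pseudo-inverse of the Hessian/Kirchhoff matrix.
    """
    return (modes.vectors * modes.variances) @ modes.vectors.T


def anm_potential(
    reference: NodeSet, conformation: NodeSet, params: ENMParameters | None = None
) -> float:
    """ANM spring energy of ``conformation`` with contacts from ``reference``."""
    if params is None:
        params = ENMParameters(model="ANM")
    if reference.n_nodes != conformation.n_nodes:
        raise ShapeError(
            f"node counts differ: {reference.n_nodes} vs {conformation.n_nodes}"
        )
    d0 = _pair_distances(reference)
    iu = np.triu_indices(reference.n_nodes, k=1)
    contact = d0[iu] <= params.effective_cutoff
    d1 = squareform(pdist(conformation.coords))[iu]
    delta = d1[contact] - d0[iu][contact]
    return float(0.5 * params.gamma * np.sum(delta ** 2))


def vsa_reduce(hessian: HessianMatrix, subsystem) -> HessianMatrix:
    """Schur-complement reduction of the Hessian onto a node subsystem.

    H_eff = H_ss − H_se H_ee⁺ H_es, with the pseudo-inverse so that
    singular environment blocks (isolated or floppy environment
    pieces) are handled gracefully.

    Note on rigid-body gauge: pinv(H_eff) reproduces the subsystem
    block of pinv(H) on the nonrigid subspace of H_eff (to round-off).
    The raw blocks differ by rigid-mode terms, because pinv(H) is
    orthogonal to whole-system rigid motions while pinv(H_eff) is
    orthogonal to subsystem rigid motions.
    """
    sub = np.asarray(sorted(set(int(i) for i in np.atleast_1d(subsystem))))
    n = hessian.n_nodes
    if sub.size == 0:
        raise ShapeError("subsystem must be non-empty")
    if sub.min() < 0 or sub.max() >= n:
        raise ShapeError(f"subsystem indices must lie in [0, {n})")
    env = np.setdiff1d(np.arange(n), sub)
    sub_dof = (3 * sub[:, None] + np.arange(3)).ravel()
    if env.size == 0:
        return HessianMatrix(
            hessian.matrix.copy(), hessian.params,
            [hessian.labels[i] for i in sub] if hessian.labels else [],
            hessian.n_components,
        )
    env_dof = (3 * env[:, None] + np.arange(3)).ravel()
    h = hessian.matrix
    h_ss = h[np.ix_(sub_dof, sub_dof)]
    h_se = h[np.ix_(sub_dof, env_dof)]
    h_ee = h[np.ix_(env_dof, env_dof)]
    h_eff = h_ss - h_se @ np.linalg.pinv(h_ee, hermitian=True) @ h_se.T
    h_eff = 0.5 * (h_eff + h_eff.T)
    return HessianMatrix(
        h_eff, hessian.params,
        [hessian.labels[i] for i in sub] if hessian.labels else [],
        hessian.n_components,
    )
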