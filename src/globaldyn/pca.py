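"""Essential dynamics of structural ensembles.

Given M superposed conformations, the positional covariance

    C = (1/M) Σ_m Δq_m Δq_mᵀ,      Δq_m = q_m − <q>,

is eigendecomposed into principal components p_k with variances σ_k.
The top few PCs capture the dominant conformational changes; members
project onto them as Δq_m · p_k (in Å, since the PCs are unit vectors),
and new conformers can be generated by adding linear combinations of
PCs to the mean.  Projections onto two PCs, binned or smoothed with a
kernel density estimate, give a first estimate of the conformational
(free-)energy landscape, G = −ln(ρ/ρ_max) in k_B T.

The 1/M normalisation (covariance as the plain average of outer
products) is the default; pass ``ddof=1`` for the 1/(M−1) sample
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.stats import gaussian_kde

from .errors import ShapeError
from .structures import DeformationVector, Ensemble, NodeSet, to_coordinate_vector
from .superpose import kabsch_superpose
from .elastic import ModeSet

__all__ = [
    "CovarianceMatrix",
    "ProjectionSet",
    "LandscapeDensity",
    "deformation_vector",
    "morph",
    "ensemble_covariance",
    "pca_modes",
    "project",
    "generate_conformer",
    "landscape_density",
]


@dataclass
class CovarianceMatrix:
    """3N' x 3N' positional covariance over the ensemble's common core."""

    matrix: np.ndarray
    mean: NodeSet
    n_members: int
    core_columns: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ShapeError("covariance must be square")

    @property
    def total_variance(self) -> float:
        return float(np.trace(self.matrix))


@dataclass
class ProjectionSet:
    """Per-member coordinates along unit mode vectors (Å)."""

    coordinates: np.ndarray  # (M, k)
    modes: ModeSet
    member_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, float))
        if not self.member_labels:
            self.member_labels = [
                f"member{i}" for i in range(self.coordinates.shape[0])
            ]


@dataclass
class LandscapeDensity:
    """Gridded density over a 2D projection, with optional free energy."""

    density: np.ndarray  # (nx, ny)
    x_centers: np.ndarray
    y_centers: np.ndarray
    method: str
    free_energy: np.ndarray | None = None  # −ln(ρ/ρ_max), k_B T; +inf off-support


def deformation_vector(
    a: NodeSet, b: NodeSet, superpose: bool = True
) -> DeformationVector:
    """Δq = q_b − q_a, after optionally superposing b onto a."""
    if a.n_nodes != b.n_nodes:
        raise ShapeError(f"node counts differ: {a.n_nodes} vs {b.n_nodes}")
    if superpose:
        b, *_ = kabsch_superpose(b, a)
    values = to_coordinate_vector(b) - to_coordinate_vector(a)
    return DeformationVector(values, source="a", target="b")


def morph(
    a: NodeSet, b: NodeSet, n_frames: int, superpose: bool = True
) -> Ensemble:
    """Linear interpolation along the deformation vector from a to b.

    Frame 0 equals ``a`` and the last frame equals ``b`` (after the
    optional superposition of b onto a).
    """
    if n_frames < 2:
        raise ValueError("a morph needs at least 2 frames")
    delta = deformation_vector(a, b, superpose=superpose).as_matrix()
    ts = np.linspace(0.0, 1.0, n_frames)
    members = a.coords[None, :, :] + ts[:, None, None] * delta[None, :, :]
    return Ensemble(
        list(a.labels), members,
        member_labels=[f"frame{t}" for t in range(n_frames)],
    )


def ensemble_covariance(ensemble: Ensemble, ddof: int = 0) -> CovarianceMatrix:
    """Positional covariance about the ensemble mean over the common core.

    The caller is responsible for superposing the ensemble first (the
    CLI runs iterative superposition before this).  Columns absent from
    any member are excluded.
    """
    m = ensemble.n_members
    if m < 2:
        raise ShapeError("covariance needs M >= 2 members")
    core = ensemble.core_columns()
    if core.size < 1:
        raise ShapeError("no columns are present in every member")
    coords = ensemble.members[:, core, :]
    mean = coords.mean(axis=0)
    dev = (coords - mean).reshape(m, -1)
    cov = dev.T @ dev / (m - ddof)
    mean_nodes = NodeSet([ensemble.labels[i] for i in core], mean)
    return CovarianceMatrix(cov, mean_nodes, m, core)


def pca_modes(cov: CovarianceMatrix, n: int | None = None) -> ModeSet:
    """Principal components of the covariance, descending variance σ_k.

    At most min(3N, M−1) PCs carry nonzero variance; components with
    σ below 1e−12 × σ_max are dropped and counted as zero modes (these
    include the rigid-body directions removed by superposition).
    """
    if n is not None and n < 1:
        raise ValueError("n must be >= 1")
    sigma, vecs = scipy.linalg.eigh(cov.matrix)
    sigma = sigma[::-1]
    vecs = vecs[:, ::-1]
    sigma = np.clip(sigma, 0.0, None)
    s_max = sigma[0] if sigma.size else 0.0
    nonzero = sigma > max(s_max, 1.0) * 1e-12
    n_zero = int((~nonzero).sum())
    sigma = sigma[nonzero]
    vecs = vecs[:, nonzero]
    if n is not None:
        sigma = sigma[:n]
        vecs = vecs[:, :n]
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1
    vecs = vecs * signs
    return ModeSet(
        vectors=vecs,
        eigenvalues=sigma,
        variances=sigma,
        n_zero=n_zero,
        kind="PCA",
        labels=list(cov.mean.labels),
    )


def variance_fractions(modes: ModeSet, total: float | None = None) -> np.ndarray:
    """σ_k / Σσ for PCA modes.

    With ``total`` (e.g. the covariance trace) the fractions are of the
    ensemble's total variance even when only some modes were retained;
    otherwise they are fractions of the retained variance.
    """
    denom = modes.variances.sum() if total is None else float(total)
    return modes.variances / denom


def project(
    ensemble: Ensemble, modes: ModeSet, k: int | None = None,
    mean: NodeSet | None = None,
) -> ProjectionSet:
    """Dot products of member deviations with the first k mode vectors.

    Deviations are taken about ``mean`` (default: the ensemble mean over
    the same columns the modes were built on).
    """
    k = modes.n_modes if k is None else min(k, modes.n_modes)
    core = ensemble.core_columns()
    coords = ensemble.members[:, core, :]
    if 3 * coords.shape[1] != modes.dim:
        raise ShapeError(
            f"modes are {modes.dim}-dimensional but the ensemble core has "
            f"{coords.shape[1]} nodes"
        )
    mu = coords.mean(axis=0) if mean is None else mean.coords
    dev = (coords - mu).reshape(ensemble.n_members, -1)
    return ProjectionSet(
        dev @ modes.vectors[:, :k], modes, list(ensemble.member_labels)
    )


def generate_conformer(
    reference: NodeSet,
    modes: ModeSet,
    coefficients,
    variance_fraction: bool = False,
) -> NodeSet:
    """q_new = q_ref + Σ_j c_j p_j.

    With ``variance_fraction=True`` each coefficient is read as a
    fraction f of that mode's variance and converted to the amplitude
    c_j = sign(f)·sqrt(|f|·σ_j) — e.g. adding a PC "with 1/8 of its
    variance" uses f = 1/8.
    """
    c = np.asarray(coefficients, dtype=float).ravel()
    if c.size > modes.n_modes:
        raise ShapeError(
            f"{c.size} coefficients for {modes.n_modes} retained modes"
        )
    if 3 * reference.n_nodes != modes.dim:
        raise ShapeError("reference and modes disagree on node count")
    if variance_fraction:
        c = np.sign(c) * np.sqrt(np.abs(c) * modes.variances[: c.size])
    disp = modes.vectors[:, : c.size] @ c
    return reference.copy(reference.coords + disp.reshape(-1, 3))


def landscape_density(
    proj: ProjectionSet,
    method: str = "histogram",
    bins: int = 25,
    bandwidth=None,
    free_energy: bool = True,
    allow_any_k: bool = False,
) -> LandscapeDensity:
    """Density estimate of a 2D projection (the conformational landscape).

    ``histogram`` normalises bin masses to sum to 1; ``kde`` (Gaussian,
    Scott's-rule bandwidth by default) integrates to 1 over the grid.
    The free-energy surface is G = −ln(ρ/ρ_max) in k_B T, +inf where the
    density is zero.
    """
    pts = proj.coordinates
    if pts.shape[1] != 2 and not allow_any_k:
        raise ShapeError(
            f"landscape expects k=2 projections, got k={pts.shape[1]} "
            "(pass allow_any_k=True to override)"
        )
    pts = pts[:, :2]
    x, y = pts[:, 0], pts[:, 1]
    span_x = (x.max() - x.min()) or 1.0
    span_y = (y.max() - y.min()) or 1.0
    lo_x, hi_x = x.min() - 0.05 * span_x, x.max() + 0.05 * span_x
    lo_y, hi_y = y.min() - 0.05 * span_y, y.max() + 0.05 * span_y
    if method == "histogram":
        h, xe, ye = np.histogram2d(x, y, bins=bins, range=[[lo_x, hi_x], [lo_y, hi_y]])
        density = h / h.sum()
        xc = 0.5 * (xe[:-1] + xe[1:])
        yc = 0.5 * (ye[:-1] + ye[1:])
    elif method == "kde":
        if pts.shape[0] < 10:
            raise ShapeError("kde landscape needs M >= 10 members")
        kde = gaussian_kde(pts.T, bw_method=bandwidth)
        xc = np.linspace(lo_x, hi_x, bins)
        yc = np.linspace(lo_y, hi_y, bins)
        gx, gy = np.meshgrid(xc, yc, indexing="ij")
        density = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(bins, bins)
        cell = (xc[1] - xc[0]) * (yc[1] - yc[0])
        density = density / (density.sum() * cell)
    else:
        raise ValueError("method must be 'histogram' or 'kde'")
    g = None
    if free_energy:
        with np.errstate(divide="ignore"):
            g = -np.log(density / density.max())
    return LandscapeDensity(density, xc, yc, method, g)
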