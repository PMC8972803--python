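"""Rigid-body superposition and ensemble trimming.

Pairwise fits use the Kabsch algorithm (weighted least squares over
proper rotations, reflections corrected through the sign of the smallest
singular vector).  Ensembles are superposed iteratively: every member is
fitted onto the running mean and the mean recomputed, until the mean
moves by less than a tolerance — the standard construction of an aligned
ensemble before covariance analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryWarning, ShapeError
from .structures import Ensemble, NodeSet

__all__ = [
    "kabsch_superpose",
    "rmsd",
    "iterative_superpose",
    "trim",
    "SuperpositionResult",
]


def _coords(x) -> np.ndarray:
    return x.coords if isinstance(x, NodeSet) else np.asarray(x, dtype=float)


def rmsd(a, b) -> float:
    """Root-mean-square deviation between paired nodes, no superposition."""
    ca, cb = _coords(a), _coords(b)
    if ca.shape != cb.shape:
        raise ShapeError(f"node counts differ: {ca.shape} vs {cb.shape}")
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def _kabsch(mobile: np.ndarray, target: np.ndarray, weights: np.ndarray):
    """Weighted Kabsch: returns (R, t) with transformed = mobile @ R.T + t."""
    w = weights / weights.sum()
    mu_m = w @ mobile
    mu_t = w @ target
    a = (mobile - mu_m) * w[:, None]
    cov = a.T @ (target - mu_t)
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-12 * max(s[0], 1.0):
        warnings.warn(
            "(near-)collinear node set: rotation is not unique",
            DegenerateGeometryWarning,
            stacklevel=3,
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_t - rot @ mu_m
    return rot, trans


def kabsch_superpose(
    mobile: NodeSet, target: NodeSet, weights=None
) -> tuple[NodeSet, np.ndarray, np.ndarray, float]:
    """Least-squares fit of ``mobile`` onto ``target``.

    Returns ``(transformed, rotation, translation, rmsd)`` where
    ``rotation`` is a proper 3x3 matrix (det +1) and the RMSD is the
    weighted least-squares minimum.
    """
    cm, ct = _coords(mobile), _coords(target)
    if cm.shape != ct.shape:
        raise ShapeError(f"node counts differ: {cm.shape[0]} vs {ct.shape[0]}")
    n = cm.shape[0]
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ShapeError("weights must have one value per node")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    rot, trans = _kabsch(cm, ct, weights)
    moved = cm @ rot.T + trans
    w = weights / weights.sum()
    fit_rmsd = float(np.sqrt(np.sum(w * np.sum((moved - ct) ** 2, axis=1))))
    transformed = mobile.copy(moved) if isinstance(mobile, NodeSet) else moved
    return transformed, rot, trans, fit_rmsd


@dataclass
class SuperpositionResult:
    ensemble: Ensemble
    mean: NodeSet
    n_iter: int
    converged: bool
    #: total ensemble variance about the mean after each iteration
    variance_history: list[float] = None


def iterative_superpose(
    ensemble: Ensemble, tol: float = 1e-5, max_iter: int = 50
) -> SuperpositionResult:
    """Superpose every member onto the running mean until it converges.

    Masked (absent) nodes get zero weight in the fits and are left out
    of the mean.  Non-convergence within ``max_iter`` is flagged on the
    result, not raised.
    """
    if ensemble.n_members < 2:
        raise ShapeError("iterative superposition needs M >= 2 members")
    if tol <= 0:
        raise ValueError("tol must be positive")
    mask = ensemble.full_mask().astype(float)
    coords = ensemble.members.copy()
    mean = coords[ensemble.reference_index].copy()
    n_iter = 0
    converged = False
    history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        for m in range(coords.shape[0]):
            w = mask[m]
            rot, trans = _kabsch(coords[m], mean, w)
            coords[m] = coords[m] @ rot.T + trans
        counts = mask.sum(axis=0)[:, None]
        new_mean = (coords * mask[:, :, None]).sum(axis=0) / np.maximum(counts, 1)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        history.append(float(np.sum(
            mask[:, :, None] * (coords - mean) ** 2
        )))
        if shift < tol:
            converged = True
            break
    out = ensemble.copy()
    out.members = coords
    mean_nodes = NodeSet(list(ensemble.labels), mean)
    return SuperpositionResult(out, mean_nodes, n_iter, converged, history)


def trim(
    ensemble: Ensemble,
    keep: np.ndarray | None = None,
    drop_termini: int | None = None,
) -> Ensemble:
    """Remove columns (nodes) consistently from every member.

    ``keep`` is a boolean per column; ``drop_termini=k`` removes the k
    first and k last columns.  Fewer than 3 surviving columns is an
    error because superposition is then undefined.
    """
    n = ensemble.n_nodes
    if keep is None and drop_termini is None:
        raise ValueError("give either keep or drop_termini")
    if keep is None:
        k = int(drop_termini)
        keep = np.zeros(n, dtype=bool)
        if k < 0:
            raise ValueError("drop_termini must be >= 0")
        keep[k: n - k if k > 0 else n] = True
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (n,):
        raise ShapeError(f"keep mask must have length N={n}")
    if keep.sum() < 3:
        raise ShapeError(
            f"only {int(keep.sum())} columns would survive; need >= 3"
        )
    return Ensemble(
        [lab for lab, k in zip(ensemble.labels, keep) if k],
        ensemble.members[:, keep],
        None if ensemble.mask is None else ensemble.mask[:, keep],
        ensemble.reference_index,
        list(ensemble.member_labels),
    )
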