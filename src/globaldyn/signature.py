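"""Comparative ("signature") dynamics across a protein family.

Per-member normal modes are compared through the correlation cosine of
individual mode vectors and through Hess's covariance overlap over sets
of modes,

    Ω(A, B) = 1 − sqrt[ (Σ v_iᴬ + Σ v_jᴮ − 2 Σ_ij (v_iᴬ v_jᴮ)^½ (p_iᴬ·p_jᴮ)²)
                        / (Σ v_iᴬ + Σ v_jᴮ) ],

with v the per-mode variances (1/λ for ENMs, σ for PCA).  Ω = 1 means
identical dynamics subspaces.  Family members can then be summarised as
mean ± std fluctuation profiles on a common core, placed in a distance
matrix d = 1 − Ω, and clustered into a dynamics-based tree (UPGMA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .elastic import ModeSet
from .errors import ShapeError

__all__ = [
    "SignatureProfile",
    "DynamicsDistanceMatrix",
    "mode_overlap",
    "overlap_matrix",
    "match_modes",
    "covariance_overlap",
    "signature_profile",
    "dynamics_distance_matrix",
    "upgma_tree",
    "UPGMANode",
]

DEFAULT_N_MODES = 20  # soft-mode emphasis for family comparisons


@dataclass
class SignatureProfile:
    """Mean ± std of a per-node scalar (e.g. MSF) across family members."""

    mean: np.ndarray
    std: np.ndarray
    n_members: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.std = np.asarray(self.std, float)
        if self.mean.shape != self.std.shape:
            raise ShapeError("mean and std profiles must match in length")


@dataclass
class DynamicsDistanceMatrix:
    """Symmetric, zero-diagonal dissimilarities d = 1 − Ω between members."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        f = self.matrix.shape[0]
        if self.matrix.shape != (f, f):
            raise ShapeError("distance matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ShapeError("distance matrix must be symmetric")
        if not self.labels:
            self.labels = [f"member{i}" for i in range(f)]


def mode_overlap(v: np.ndarray, w: np.ndarray) -> float:
    """Correlation cosine |v·w| / (‖v‖‖w‖); sign of a mode is arbitrary."""
    v = np.asarray(v, float).ravel()
    w = np.asarray(w, float).ravel()
    if v.shape != w.shape:
        raise ShapeError(f"vector lengths differ: {v.size} vs {w.size}")
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("mode overlap undefined for a zero vector")
    return float(abs(v @ w) / (nv * nw))


def overlap_matrix(a: ModeSet, b: ModeSet, k: int | None = None) -> np.ndarray:
    """Pairwise correlation cosines between the first k modes of each set."""
    if a.dim != b.dim:
        raise ShapeError(f"mode dimensions differ: {a.dim} vs {b.dim}")
    ka = a.n_modes if k is None else min(k, a.n_modes)
    kb = b.n_modes if k is None else min(k, b.n_modes)
    va = a.vectors[:, :ka] / np.linalg.norm(a.vectors[:, :ka], axis=0)
    vb = b.vectors[:, :kb] / np.linalg.norm(b.vectors[:, :kb], axis=0)
    return np.abs(va.T @ vb)


def match_modes(overlaps: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy mode pairing from an overlap matrix.

    Repeatedly takes the global maximum among unmatched rows/columns;
    ties break on the lowest row index, then the lowest column index.
    Returns ``[(i, j, overlap), ...]`` sorted by row index i.
    """
    m = np.asarray(overlaps, dtype=float)
    if m.ndim != 2:
        raise ShapeError("overlap matrix must be 2D")
    free_i = set(range(m.shape[0]))
    free_j = set(range(m.shape[1]))
    pairs: list[tuple[int, int, float]] = []
    while free_i and free_j:
        best = None
        for i in sorted(free_i):
            for j in sorted(free_j):
                if best is None or m[i, j] > best[2]:
                    best = (i, j, m[i, j])
        i, j, val = best
        pairs.append((i, j, float(val)))
        free_i.remove(i)
        free_j.remove(j)
    return sorted(pairs)


def covariance_overlap(a: ModeSet, b: ModeSet, k: int | None = DEFAULT_N_MODES) -> float:
    """Hess covariance overlap Ω ∈ [0, 1] over the first k modes of each set.

    Evaluated as Ω = 1 − sqrt(‖C_A^½ − C_B^½‖_F² / (tr C_A + tr C_B))
    with the matrix square roots expressed in an orthonormal basis of
    the joint mode subspace.  This is algebraically identical to the
    variance-weighted squared-dot-product form but free of the
    catastrophic cancellation that form suffers when A ≈ B (where the
    naive expression loses half the working precision under the
    square root).
    """
    if a.dim != b.dim:
        raise ShapeError(f"mode dimensions differ: {a.dim} vs {b.dim}")
    ka = a.n_modes if k is None else min(k, a.n_modes)
    kb = b.n_modes if k is None else min(k, b.n_modes)
    va = a.variances[:ka]
    vb = b.variances[:kb]
    total = va.sum() + vb.sum()
    if total <= 0:
        raise ValueError("covariance overlap undefined for zero total variance")
    pa = a.vectors[:, :ka]
    pb = b.vectors[:, :kb]
    joint, _ = np.linalg.qr(np.hstack([pa, pb]))
    qa = joint.T @ pa  # (ka+kb, ka)
    qb = joint.T @ pb
    half_a = (qa * np.sqrt(va)) @ qa.T
    half_b = (qb * np.sqrt(vb)) @ qb.T
    diff_sq = float(np.sum((half_a - half_b) ** 2))
    return float(1.0 - np.sqrt(diff_sq / total))


def signature_profile(profiles: Sequence[np.ndarray]) -> SignatureProfile:
    """Element-wise mean and population std of per-node profiles."""
    arrays = [np.asarray(p, float).ravel() for p in profiles]
    if not arrays:
        raise ShapeError("need at least one profile")
    n = arrays[0].size
    for i, p in enumerate(arrays):
        if p.size != n:
            raise ShapeError(
                f"profile {i} has length {p.size}, expected {n}"
            )
    stack = np.vstack(arrays)
    return SignatureProfile(stack.mean(axis=0), stack.std(axis=0), len(arrays))


def dynamics_distance_matrix(
    members: Sequence[ModeSet],
    k: int | None = DEFAULT_N_MODES,
    labels: Sequence[str] | None = None,
) -> DynamicsDistanceMatrix:
    """Pairwise d(i, j) = 1 − Ω(i, j) over family members on a common core."""
    members = list(members)
    f = len(members)
    if f < 2:
        raise ShapeError("need at least 2 members")
    dim = members[0].dim
    for i, m in enumerate(members):
        if m.dim != dim:
            raise ShapeError(
                f"member {i} lives on a different core (dim {m.dim} != {dim})"
            )
    d = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            d[i, j] = d[j, i] = 1.0 - covariance_overlap(members[i], members[j], k)
    return DynamicsDistanceMatrix(
        d, list(labels) if labels is not None else []
    )


@dataclass
class UPGMANode:
    """Node of a rooted ultrametric tree; ``height`` is distance/2 to leaves."""

    label: str
    height: float = 0.0
    children: list["UPGMANode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.label
        else:
            body = "(" + ",".join(
                c._newick(self.height) for c in self.children
            ) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:g}"


def upgma_tree(dist: DynamicsDistanceMatrix | np.ndarray,
               labels: Sequence[str] | None = None) -> UPGMANode:
    """UPGMA agglomeration (size-weighted average linkage), ultrametric.

    Ties in the minimum distance break on the lexicographically smallest
    pair of cluster labels (a cluster is labelled by its smallest leaf
    label), so the topology is deterministic.  Branch lengths follow
    from cluster heights = d/2.
    """
    if isinstance(dist, DynamicsDistanceMatrix):
        d = dist.matrix.copy()
        labels = list(dist.labels)
    else:
        d = np.asarray(dist, dtype=float).copy()
        if not np.allclose(d, d.T, atol=1e-10):
            raise ShapeError("distance matrix must be symmetric")
        labels = list(labels) if labels is not None else [
            f"member{i}" for i in range(d.shape[0])
        ]
    f = d.shape[0]
    if f < 2:
        raise ShapeError("need at least 2 taxa")
    clusters: dict[int, UPGMANode] = {
        i: UPGMANode(labels[i]) for i in range(f)
    }
    sizes = {i: 1 for i in range(f)}
    names = {i: labels[i] for i in range(f)}  # smallest leaf label per cluster
    active = list(range(f))
    dmat = {(i, j): d[i, j] for i in range(f) for j in range(f) if i < j}
    next_id = f
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                val = dmat[key]
                pair = tuple(sorted((names[i], names[j])))
                if best is None or val < best[0] - 1e-15 or (
                    abs(val - best[0]) <= 1e-15 and pair < best[1]
                ):
                    best = (val, pair, i, j)
        val, _, i, j = best
        ci, cj = clusters[i], clusters[j]
        if names[j] < names[i]:
            ci, cj = cj, ci
        node = UPGMANode(label="", height=val / 2.0, children=[ci, cj])
        new = next_id
        next_id += 1
        si, sj = sizes[i], sizes[j]
        for other in active:
            if other in (i, j):
                continue
            dio = dmat[(min(i, other), max(i, other))]
            djo = dmat[(min(j, other), max(j, other))]
            dmat[(min(new, other), max(new, other))] = (
                si * dio + sj * djo
            ) / (si + sj)
        clusters[new] = node
        sizes[new] = si + sj
        names[new] = min(names[i], names[j])
        active = [x for x in active if x not in (i, j)] + [new]
    return clusters[active[0]]
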