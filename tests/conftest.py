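import numpy as np
import pytest

from globaldyn import NodeSet


def truncated_pinv(matrix: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Pseudo-inverse with an explicit relative eigenvalue cut.

    Keeps the rigid-mode truncation consistent between the quantities a
    test compares (numpy's default rcond is far below the zero-mode
    noise floor of an ENM Hessian).
    """
    w, v = np.linalg.eigh(matrix)
    keep = w > rtol * w.max()
    return (v[:, keep] / w[keep]) @ v[:, keep].T


def rigid_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of translations + infinitesimal rotations."""
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    vecs = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        vecs.append(t.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        vecs.append(np.cross(e, centered).ravel())
    q, _ = np.linalg.qr(np.array(vecs).T)
    return q


def random_nodeset(rng: np.random.Generator, n: int, box: float = 10.0) -> NodeSet:
    labels = [("A", str(i + 1), "GLY") for i in range(n)]
    return NodeSet(labels, rng.uniform(0.0, box, size=(n, 3)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_modeset(rng: np.random.Generator, dim: int, k: int, kind: str = "ANM"):
    from globaldyn import ModeSet

    q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
    eigenvalues = np.sort(rng.uniform(0.5, 5.0, size=k))
    if kind == "PCA":
        variances = np.sort(rng.uniform(0.1, 2.0, size=k))[::-1]
        return ModeSet(q, variances, variances, 0, "PCA")
    return ModeSet(q, eigenvalues, 1.0 / eigenvalues, 6, kind)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      -0.500   0.200   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.000   0.500   0.100  1.00  0.00           C
ATOM      4  O   ALA A   1       1.500   1.000   0.500  1.00  0.00           O
ATOM      5  N   GLY A   2       3.000   0.100   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       4.600   0.300   0.200  1.00  0.00           C
ATOM      8  O   GLY A   2       5.100   0.900   0.600  1.00  0.00           O
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
HETATM    2  O   HOH A 102      12.000  10.000  10.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""
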