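"""Coarse-grained structure containers and fixed-width PDB I/O.

A structure is reduced to one node per selected atom (by default the
C-alpha of each residue), giving the 3N-dimensional coordinate vector
q = (x1, y1, z1, ..., xN, yN, zN) that all downstream normal-mode and
essential-dynamics machinery operates on.  An :class:`Ensemble` stacks M
such conformations over a shared node set, optionally with a presence
mask so that members missing residues (insertions/deletions relative to
the family core) can still be analysed over the common core.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentKeyError,
    EmptySelectionError,
    PDBParseError,
    ShapeError,
)

__all__ = [
    "NodeSet",
    "Ensemble",
    "DeformationVector",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "to_coordinate_vector",
    "from_coordinate_vector",
    "build_ensemble",
]

#: label of one node: (chain id, residue number incl. insertion code, name)
Label = tuple[str, str, str]


@dataclass
class NodeSet:
    """One coarse-grained node per residue (or per atom).

    Parameters
    ----------
    labels
        One ``(chain, residue number, name)`` tuple per node.  Residue
        numbers are strings so PDB insertion codes survive ("52A").  For
        all-atom selections the name field is ``"RES:ATOM"`` so labels
        stay unique.
    coords
        ``(N, 3)`` Cartesian coordinates in Angstrom.
    """

    labels: list[Label]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ShapeError("a NodeSet needs at least one node")
        if len(self.labels) != self.coords.shape[0]:
            raise ShapeError(
                f"{len(self.labels)} labels for {self.coords.shape[0]} nodes"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError("coordinates must be finite")
        if len(set(self.labels)) != len(self.labels):
            raise ShapeError("node labels must be unique")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def copy(self, coords: np.ndarray | None = None) -> "NodeSet":
        return NodeSet(
            list(self.labels),
            self.coords.copy() if coords is None else np.asarray(coords, float),
        )

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_nodes


@dataclass
class Ensemble:
    """M aligned conformations over a common set of N nodes.

    ``mask[m, i]`` is False when node ``i`` is absent from member ``m``
    (e.g. a residue missing from that structure's alignment row); such
    nodes carry placeholder coordinates and zero weight in fits.
    """

    labels: list[Label]
    members: np.ndarray  # (M, N, 3)
    mask: np.ndarray | None = None  # (M, N) bool
    reference_index: int = 0
    member_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=float)
        if self.members.ndim != 3 or self.members.shape[2] != 3:
            raise ShapeError(f"members must be (M, N, 3), got {self.members.shape}")
        m, n, _ = self.members.shape
        if m < 1 or n < 1:
            raise ShapeError("ensemble needs M >= 1 members and N >= 1 nodes")
        if len(self.labels) != n:
            raise ShapeError(f"{len(self.labels)} labels for N={n}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (m, n):
                raise ShapeError(f"mask must be (M, N)={m, n}, got {self.mask.shape}")
        if not self.member_labels:
            self.member_labels = [f"member{i}" for i in range(m)]
        if len(self.member_labels) != m:
            raise ShapeError("member_labels length must equal M")

    @property
    def n_members(self) -> int:
        return self.members.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.members.shape[1]

    def full_mask(self) -> np.ndarray:
        """Boolean (M, N) mask; all-True when no mask was given."""
        if self.mask is None:
            return np.ones(self.members.shape[:2], dtype=bool)
        return self.mask

    def core_columns(self) -> np.ndarray:
        """Indices of columns present in every member (the common core)."""
        return np.flatnonzero(self.full_mask().all(axis=0))

    def member(self, m: int) -> NodeSet:
        return NodeSet(list(self.labels), self.members[m].copy())

    def copy(self) -> "Ensemble":
        return Ensemble(
            list(self.labels),
            self.members.copy(),
            None if self.mask is None else self.mask.copy(),
            self.reference_index,
            list(self.member_labels),
        )


@dataclass
class DeformationVector:
    """3N displacement between two superposed conformations (Angstrom)."""

    values: np.ndarray
    source: str = ""
    target: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size % 3 != 0:
            raise ShapeError("deformation vector length must be divisible by 3")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("deformation vector must be finite")

    @property
    def rmsd(self) -> float:
        """RMS displacement per node implied by this vector."""
        n = self.values.size // 3
        return float(np.linalg.norm(self.values) / np.sqrt(n))

    def as_matrix(self) -> np.ndarray:
        return self.values.reshape(-1, 3)


# ---------------------------------------------------------------------------
# coordinate flattening (interleaved per node: x1, y1, z1, x2, ...)

def to_coordinate_vector(nodes: NodeSet | np.ndarray) -> np.ndarray:
    """Flatten N x 3 coordinates to the 3N vector q."""
    coords = nodes.coords if isinstance(nodes, NodeSet) else np.asarray(nodes, float)
    return coords.reshape(-1).copy()


def from_coordinate_vector(q: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_coordinate_vector`; returns the N x 3 matrix."""
    q = np.asarray(q, dtype=float).ravel()
    if q.size % 3 != 0:
        raise ShapeError("coordinate vector length must be divisible by 3")
    return q.reshape(-1, 3)


# ---------------------------------------------------------------------------
# PDB parsing (fixed-width ATOM/HETATM records)

def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        return {
            "record": line[0:6].strip(),
            "name": line[12:16].strip(),
            "altloc": line[16:17].strip(),
            "resname": line[17:20].strip(),
            "chain": line[21:22].strip() or " ",
            "resseq": int(line[22:26]),
            "icode": line[26:27].strip(),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "occupancy": float(line[54:60]) if line[54:60].strip() else 1.0,
        }
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"malformed fixed-width PDB record at line {lineno}: {line.rstrip()!r}"
        ) from exc


def _select_atoms(atoms: list[dict], selection: str) -> list[dict]:
    if selection == "calpha":
        picked = [a for a in atoms if a["name"] == "CA" and a["resname"] != "HOH"]
    elif selection == "all-atom":
        picked = list(atoms)
    else:
        raise ValueError(f"unknown selection {selection!r} (use 'calpha' or 'all-atom')")
    # altloc resolution: highest occupancy wins, first record on ties
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for a in picked:
        key = (a["chain"], a["resseq"], a["icode"], a["name"])
        if key not in best:
            best[key] = a
            order.append(key)
        elif a["occupancy"] > best[key]["occupancy"]:
            best[key] = a
    return [best[k] for k in order]


def _atoms_to_nodeset(atoms: list[dict], selection: str) -> NodeSet:
    labels: list[Label] = []
    coords = np.empty((len(atoms), 3))
    for i, a in enumerate(atoms):
        resnum = f"{a['resseq']}{a['icode']}"
        name = a["resname"] if selection == "calpha" else f"{a['resname']}:{a['name']}"
        labels.append((a["chain"], resnum, name))
        coords[i] = (a["x"], a["y"], a["z"])
    return NodeSet(labels, coords)


def _parse_pdb_models(text: str, selection: str) -> list[NodeSet]:
    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                models.append(current)
            current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
    if current or not models:
        models.append(current)
    node_models = []
    for atoms in models:
        sel = _select_atoms(atoms, selection)
        if not sel:
            raise EmptySelectionError(
                f"selection {selection!r} matched no atoms"
            )
        node_models.append(_atoms_to_nodeset(sel, selection))
    return node_models


def _read_text(source) -> str:
    if isinstance(source, io.IOBase):
        return source.read()
    text = str(source)
    if "\n" in text or text.lstrip()[:6].split()[0:1] in (["ATOM"], ["HETATM"], ["MODEL"]):
        return text
    with open(text) as fh:
        return fh.read()


def read_structure(source, selection: str = "calpha") -> NodeSet:
    """Read one structure (first MODEL of a multi-model file) from PDB.

    ``source`` may be a path, an open text file, or the PDB text itself.
    """
    return _parse_pdb_models(_read_text(source), selection)[0]


def read_ensemble(source, selection: str = "calpha") -> Ensemble:
    """Read a multi-MODEL PDB file; each MODEL becomes one member."""
    models = _parse_pdb_models(_read_text(source), selection)
    return build_ensemble(models)


# ---------------------------------------------------------------------------
# PDB writing

def _format_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: str,
    xyz: np.ndarray, bfactor: float, hetatm: bool,
) -> str:
    icode = ""
    digits = resnum
    while digits and not digits[-1].isdigit():
        icode = digits[-1] + icode
        digits = digits[:-1]
    resseq = int(digits) if digits else 0
    b = min(max(bfactor, 0.0), 999.99)
    rec = "HETATM" if hetatm else "ATOM  "
    padded = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{rec}{serial:5d} {padded}{'':1s}{resname[:3]:>3s} {chain[:1]}"
        f"{resseq:4d}{icode[:1]:1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{b:6.2f}"
        f"          {'':>2s}\n"
    )


def _nodeset_lines(nodes: NodeSet, bfactors=None, hetatm: bool = False) -> list[str]:
    if bfactors is None:
        bfactors = np.zeros(nodes.n_nodes)
    bfactors = np.asarray(bfactors, dtype=float)
    if bfactors.shape != (nodes.n_nodes,):
        raise ShapeError("bfactors must have one value per node")
    lines = []
    for i, (chain, resnum, name) in enumerate(nodes.labels):
        if ":" in name:
            resname, atname = name.split(":", 1)
        else:
            resname, atname = name, "CA"
        lines.append(
            _format_atom_line(i + 1, atname, resname, chain, resnum,
                              nodes.coords[i], bfactors[i], hetatm)
        )
    return lines


def write_structure(nodes: NodeSet, path, bfactors=None, hetatm: bool = False) -> None:
    """Write a NodeSet as fixed-width PDB ATOM (or HETATM) records.

    ``bfactors`` rides in the B-factor column (clamped to [0, 999.99]),
    the conventional way to carry a per-node scalar such as an MSF.
    """
    lines = _nodeset_lines(nodes, bfactors, hetatm) + ["END\n"]
    _write_lines(path, lines)


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write an Ensemble as a multi-MODEL PDB file."""
    lines: list[str] = []
    for m in range(ensemble.n_members):
        lines.append(f"MODEL     {m + 1:4d}\n")
        lines.extend(_nodeset_lines(ensemble.member(m)))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    _write_lines(path, lines)


def _write_lines(path, lines: list[str]) -> None:
    if isinstance(path, io.IOBase):
        path.write("".join(lines))
    else:
        with open(path, "w") as fh:
            fh.write("".join(lines))


# ---------------------------------------------------------------------------
# ensemble construction

def build_ensemble(
    structures: Sequence[NodeSet],
    alignment: pd.DataFrame | None = None,
    member_labels: Iterable[str] | None = None,
) -> Ensemble:
    """Stack structures into an Ensemble, optionally through an alignment.

    Without an alignment every member must carry the identical label
    sequence.  With one, ``alignment`` is a table with one row per core
    column and one column per member, each cell holding that member's
    node label for the column (as a ``(chain, resnum, name)`` tuple or a
    ``"chain:resnum"`` string) or None/NaN where the member lacks the
    column.  Columns absent from any member are flagged in the mask and
    excluded from downstream covariance analysis.
    """
    structures = list(structures)
    if not structures:
        raise ShapeError("need at least one structure")
    names = list(member_labels) if member_labels is not None else [
        f"member{i}" for i in range(len(structures))
    ]
    if alignment is None:
        ref = structures[0]
        for k, s in enumerate(structures[1:], start=1):
            if s.labels != ref.labels:
                raise ShapeError(
                    f"member {k} labels differ from member 0 "
                    f"(N={s.n_nodes} vs {ref.n_nodes}); provide an alignment table"
                )
        members = np.stack([s.coords for s in structures])
        return Ensemble(list(ref.labels), members,
                        np.ones((len(structures), ref.n_nodes), bool),
                        member_labels=names)

    if alignment.shape[1] != len(structures):
        raise ShapeError(
            f"alignment has {alignment.shape[1]} member columns for "
            f"{len(structures)} structures"
        )
    n_core = alignment.shape[0]
    m = len(structures)
    members = np.zeros((m, n_core, 3))
    mask = np.zeros((m, n_core), dtype=bool)
    core_labels: list[Label] = [("A", str(i + 1), "COR") for i in range(n_core)]
    for j, struct in enumerate(structures):
        index = _label_index(struct)
        for i in range(n_core):
            cell = alignment.iloc[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            try:
                row = index[_normalize_key(cell)]
            except KeyError:
                raise AlignmentKeyError(
                    f"alignment references residue {cell!r} absent from "
                    f"member {j} ({names[j]})"
                ) from None
            members[j, i] = struct.coords[row]
            mask[j, i] = True
            core_labels[i] = struct.labels[row]
    return Ensemble(core_labels, members, mask, member_labels=names)


def _normalize_key(cell) -> tuple[str, str]:
    if isinstance(cell, tuple):
        return (str(cell[0]), str(cell[1]))
    text = str(cell)
    if ":" in text:
        chain, resnum = text.split(":", 1)
        return (chain, resnum)
    return (" ", text)


def _label_index(struct: NodeSet) -> dict[tuple[str, str], int]:
    return {(c, r): i for i, (c, r, _) in enumerate(struct.labels)}
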