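"""Graph-theoretic and geometric views of a molecule.

A :class:`MolecularGraph` is the per-molecule substrate of the product-graph
construction: the kept heavy atoms (hydrogens and dummy atoms are dropped by
default), their bond adjacency, the all-pairs topological distance matrix in
covalent-bond counts, and the Euclidean distance matrix in Å.  Graphs are
computed once per molecule and treated as immutable — the screening loop
reuses the reference graph across an entire library.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .mol2 import Atom, Molecule

__all__ = ["MolecularGraph", "DegenerateMoleculeError", "build_graph",
           "rigid_transform", "random_rotation"]


class DegenerateMoleculeError(ValueError):
    """The hydrogen/dummy policy left no atoms to build a graph from."""


class MolecularGraph:
    """Adjacency, topological and geometric distances over kept atoms.

    Attributes
    ----------
    source : Molecule
        The molecule the graph was built from.
    kept : tuple[int, ...]
        Indices into ``source.atoms`` surviving the hydrogen policy.
    n : int
        Number of kept atoms.
    adjacency : (n, n) bool ndarray
    topo_dist : (n, n) float ndarray
        Shortest-path lengths in bond counts; ``inf`` for atom pairs in
        different connected fragments.
    geo_dist : (n, n) float ndarray
        Euclidean distances in Å.
    """

    __slots__ = ("source", "kept", "n", "adjacency", "topo_dist", "geo_dist",
                 "sybyl", "serials")

    def __init__(self, source: Molecule, kept: tuple[int, ...],
                 adjacency: np.ndarray, topo_dist: np.ndarray,
                 geo_dist: np.ndarray):
        self.source = source
        self.kept = kept
        self.n = len(kept)
        self.adjacency = adjacency
        self.topo_dist = topo_dist
        self.geo_dist = geo_dist
        self.sybyl = tuple(source.atoms[i].sybyl_type for i in kept)
        self.serials = tuple(source.atoms[i].serial for i in kept)
        for m in (self.adjacency, self.topo_dist, self.geo_dist):
            m.setflags(write=False)

    def atom(self, kept_index: int) -> Atom:
        return self.source.atoms[self.kept[kept_index]]


def build_graph(mol: Molecule, include_h: bool = False) -> MolecularGraph:
    """Build the :class:`MolecularGraph` of ``mol``.

    With ``include_h`` false (the default, matching the screening default of
    ignoring hydrogens for speed) atoms whose element is ``H`` are dropped,
    as are dummy atoms (``Du``, ``LP``) always; bonds incident to dropped
    atoms are dropped with them.  Topological distances are breadth-first
    shortest paths over the remaining bonds; pairs in different fragments
    get ``inf``.
    """
    kept = tuple(
        i for i, a in enumerate(mol.atoms)
        if not a.is_dummy and (include_h or not a.is_hydrogen)
    )
    if not kept:
        raise DegenerateMoleculeError(
            f"molecule {mol.name!r} has no atoms left after the "
            f"hydrogen/dummy policy")
    n = len(kept)
    serial_to_local = {mol.atoms[i].serial: k for k, i in enumerate(kept)}

    adjacency = np.zeros((n, n), dtype=bool)
    for b in mol.bonds:
        u = serial_to_local.get(b.a_serial)
        v = serial_to_local.get(b.b_serial)
        if u is None or v is None:
            continue  # bond touched a dropped atom
        adjacency[u, v] = adjacency[v, u] = True

    topo = shortest_path(csr_matrix(adjacency), method="D", unweighted=True,
                         directed=False)

    coords = np.array([mol.atoms[i].coords for i in kept], dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    geo = np.sqrt((diff * diff).sum(axis=-1))

    return MolecularGraph(mol, kept, adjacency, topo, geo)


def rigid_transform(mol: Molecule, rotation: np.ndarray,
                    translation: np.ndarray) -> Molecule:
    """Return a copy of ``mol`` with every coordinate mapped x → R·x + t.

    ``rotation`` must be a proper rotation (orthonormal, det +1); anything
    else is a contract error.  Connectivity, serials, names are untouched.
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float).reshape(3)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("rotation matrix is not proper (det != +1)")

    atoms = tuple(
        Atom(serial=a.serial, name=a.name, sybyl_type=a.sybyl_type,
             coords=tuple((R @ np.asarray(a.coords) + t).tolist()))
        for a in mol.atoms
    )
    return Molecule(name=mol.name, atoms=atoms, bonds=mol.bonds,
                    record_index=mol.record_index)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det-fixed)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
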