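"""Product graphs and exact maximum-clique search.

The common substructure of two molecules is found as a maximum clique of
their *product graph*: one vertex per type-compatible atom pair (one atom
from the reference, one from the target), one edge per pair of vertices
whose internal relations agree.  Two relation rules are supported:

* dimension 2 (topological): the shortest-path bond counts between the two
  reference atoms and between the two target atoms may differ by at most the
  threshold (an integer number of bonds);
* dimension 3 (geometric): the Euclidean distances may differ by at most the
  threshold in Å.

Atom compatibility is exact SYBYL-type string equality, so ``C.ar`` never
matches ``C.3``.  A clique then corresponds to an injective atom-to-atom
mapping whose internal distances are mutually consistent; the maximum clique
is the largest such common substructure (not required to be connected).

The solver is an exact branch-and-bound in the Tomita/MaxCliqueDyn family:
vertices are pre-ordered by descending degree, each search node greedily
colours the candidate set and prunes branches whose colour bound cannot beat
the incumbent.  The search order is fully deterministic, so the same input
always yields the same member set.  A brute-force enumerator (guarded to 24
vertices) is provided purely as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .graph import MolecularGraph

__all__ = [
    "ProductVertex", "ProductGraph", "Clique",
    "build_product_graph", "max_clique", "brute_force_clique",
    "maximum_clique_indices", "brute_force_clique_indices",
]

BRUTE_FORCE_MAX_VERTICES = 24


class ProductVertex(NamedTuple):
    """A type-compatible atom pair: kept-atom indices (reference, target)."""

    r: int
    t: int


@dataclass(frozen=True)
class ProductGraph:
    """The clique substrate for one reference/target comparison."""

    vertices: tuple[ProductVertex, ...]
    adjacency: np.ndarray  # symmetric bool, no self-loops
    dimension: int         # 2 or 3
    threshold: float       # bonds (2D) or Å (3D)

    @property
    def n(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class Clique:
    """A set of pairwise-adjacent product vertices = one consistent mapping."""

    members: tuple[ProductVertex, ...]

    @property
    def size(self) -> int:
        return len(self.members)


def build_product_graph(ref: MolecularGraph, tgt: MolecularGraph,
                        dimension: int, threshold: float) -> ProductGraph:
    """Construct the 2D or 3D product graph between two molecular graphs.

    Vertices enumerate every pair of atoms with identical SYBYL type
    (reference-major order).  The edge rule for vertices (i, i') and (j, j')
    requires i ≠ j, i' ≠ j' (injectivity) and, for 2D, both topological
    distances finite with ``|d_ref(i,j) - d_tgt(i',j')| <= threshold``; for
    3D, ``|g_ref(i,j) - g_tgt(i',j')| <= threshold``.  Any comparison that
    involves an infinite topological distance fails, including inf vs inf —
    no consistency is asserted across disconnected fragments.

    A molecule pair sharing no SYBYL type yields an empty product graph
    (similarity 0); that is legal, not an error.
    """
    if dimension not in (2, 3):
        raise ValueError(f"dimension must be 2 or 3, got {dimension}")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")

    verts = [ProductVertex(i, t)
             for i in range(ref.n) for t in range(tgt.n)
             if ref.sybyl[i] == tgt.sybyl[t]]
    nv = len(verts)
    if nv == 0:
        return ProductGraph((), np.zeros((0, 0), dtype=bool),
                            dimension, threshold)

    ri = np.fromiter((v.r for v in verts), dtype=np.intp, count=nv)
    ti = np.fromiter((v.t for v in verts), dtype=np.intp, count=nv)

    if dimension == 2:
        dr = ref.topo_dist[ri[:, None], ri[None, :]]
        dt = tgt.topo_dist[ti[:, None], ti[None, :]]
        finite = np.isfinite(dr) & np.isfinite(dt)
        with np.errstate(invalid="ignore"):
            ok = finite & (np.abs(dr - dt) <= threshold)
    else:
        dr = ref.geo_dist[ri[:, None], ri[None, :]]
        dt = tgt.geo_dist[ti[:, None], ti[None, :]]
        ok = np.abs(dr - dt) <= threshold

    inj = (ri[:, None] != ri[None, :]) & (ti[:, None] != ti[None, :])
    adjacency = ok & inj
    np.fill_diagonal(adjacency, False)
    return ProductGraph(tuple(verts), adjacency, dimension, threshold)


# ---------------------------------------------------------------------------
# exact solver (bitset branch-and-bound with greedy-colouring bound)
# ---------------------------------------------------------------------------

def _adjacency_to_masks(adjacency: np.ndarray) -> list[int]:
    """Rows of a boolean adjacency matrix as python-int bitsets."""
    n = adjacency.shape[0]
    masks = []
    for i in range(n):
        row = 0
        for j in np.flatnonzero(adjacency[i]):
            row |= 1 << int(j)
        masks.append(row)
    return masks


def _colour_sort(P: int, adj: list[int]) -> tuple[list[int], list[int]]:
    """Greedy sequential colouring of the candidate set ``P``.

    Returns vertices in colour order together with their colour numbers
    (non-decreasing); the colour of a vertex is an upper bound on the size
    of any clique inside ``P`` that contains it and its predecessors.
    """
    order: list[int] = []
    colours: list[int] = []
    uncoloured = P
    colour = 0
    while uncoloured:
        colour += 1
        Q = uncoloured
        while Q:
            v = (Q & -Q).bit_length() - 1
            vb = 1 << v
            order.append(v)
            colours.append(colour)
            uncoloured &= ~vb
            Q &= ~(adj[v] | vb)
    return order, colours


def maximum_clique_indices(adjacency: np.ndarray) -> list[int]:
    """Exact maximum clique of an arbitrary undirected boolean adjacency.

    Deterministic: vertices are pre-ordered by descending degree (ties by
    original index) and the branch-and-bound expansion order is fixed, so
    the same matrix always returns the same vertex list (sorted ascending).
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    n = adjacency.shape[0]
    if n == 0:
        return []
    degrees = adjacency.sum(axis=1)
    # descending degree, stable on index
    perm = sorted(range(n), key=lambda v: (-int(degrees[v]), v))
    inv = {orig: new for new, orig in enumerate(perm)}
    reordered = adjacency[np.ix_(perm, perm)]
    adj = _adjacency_to_masks(reordered)

    best: list[int] = []
    best_size = 0

    def expand(R: list[int], P: int) -> None:
        nonlocal best, best_size
        order, colours = _colour_sort(P, adj)
        for i in range(len(order) - 1, -1, -1):
            if len(R) + colours[i] <= best_size:
                return
            v = order[i]
            vb = 1 << v
            R.append(v)
            new_P = P & adj[v]
            if new_P:
                expand(R, new_P)
            elif len(R) > best_size:
                best_size = len(R)
                best = R.copy()
            R.pop()
            P &= ~vb

    expand([], (1 << n) - 1)
    return sorted(perm[v] for v in best)


def brute_force_clique_indices(adjacency: np.ndarray) -> list[int]:
    """Exhaustive maximum clique (test oracle), limited to 24 vertices.

    Plain Bron–Kerbosch enumeration of all maximal cliques, no pivoting and
    no bounding — deliberately independent of the branch-and-bound path.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    n = adjacency.shape[0]
    if n > BRUTE_FORCE_MAX_VERTICES:
        raise ValueError(
            f"brute-force oracle is guarded to {BRUTE_FORCE_MAX_VERTICES} "
            f"vertices, got {n}")
    if n == 0:
        return []
    adj = _adjacency_to_masks(adjacency)
    best: list[int] = []

    def enumerate_cliques(R: list[int], P: int, X: int) -> None:
        if not P and not X:
            if len(R) > len(best):
                best[:] = R
            return
        Q = P
        while Q:
            v = (Q & -Q).bit_length() - 1
            vb = 1 << v
            enumerate_cliques(R + [v], P & adj[v], X & adj[v])
            P &= ~vb
            X |= vb
            Q &= ~vb

    enumerate_cliques([], (1 << n) - 1, 0)
    return sorted(best)


def max_clique(g: ProductGraph) -> Clique:
    """Exact maximum clique of a product graph (empty graph → empty clique)."""
    idx = maximum_clique_indices(g.adjacency) if g.n else []
    return Clique(tuple(g.vertices[i] for i in idx))


def brute_force_clique(g: ProductGraph) -> Clique:
    """Exhaustive-search clique oracle for product graphs (≤ 24 vertices)."""
    idx = brute_force_clique_indices(g.adjacency) if g.n else []
    return Clique(tuple(g.vertices[i] for i in idx))
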