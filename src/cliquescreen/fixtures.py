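"""Synthetic molecule generation for tests, examples and benchmarks.

Generated molecules are chemically naive on purpose — random connected
topologies (chains, trees, rings, decorated rings) over a SYBYL-type
alphabet, with bond-length-scaled 3D coordinates plus Gaussian jitter —
but they are structurally valid MOL2 citizens: unique serials, consistent
bonds, finite coordinates rounded to the 4-decimal write precision so the
read/write round trip is exact.

Generation is a pure function of the :class:`FixtureSpec` (same seed, same
molecule), which is what makes planted-truth tests and byte-identical
determinism checks possible.  :func:`make_known_mcs_pair` plants a common
substructure whose size is provable, not probabilistic: the decoration
atoms of each molecule use SYBYL types absent from the partner, so they can
never enter the product graph, and decorations only hang off existing atoms,
so they never shorten a path between core atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .graph import random_rotation
from .mol2 import Atom, Bond, Molecule

__all__ = ["FixtureSpec", "make_molecule", "make_library",
           "make_known_mcs_pair", "benzene", "toluene", "propane"]

BOND_LENGTH = 1.54  # Å, generic single-bond scale

# types used for planted cores vs. per-side decorations; the three sets are
# pairwise disjoint so decoration atoms cannot pair with anything across
# molecules at any threshold
CORE_TYPES = ("C.3", "C.ar", "N.ar")
DECOR_TYPES_A = ("P.3", "F")
DECOR_TYPES_B = ("O.3", "Cl")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic molecule or library.

    n_heavy is an inclusive (lo, hi) range; topology is one of ``chain``,
    ``tree``, ``ring``, ``ring+substituent``; jitter_sigma is the Gaussian
    coordinate noise in Å; conformers is how many geometries per compound a
    library carries (same topology, re-randomised pose and jitter).
    """

    seed: int = 0
    n_heavy: tuple[int, int] = (4, 10)
    topology: str = "chain"
    type_alphabet: tuple[str, ...] = ("C.3", "C.ar", "N.3", "O.3", "S.3")
    jitter_sigma: float = 0.05
    conformers: int = 1

    def __post_init__(self):
        if self.topology not in ("chain", "tree", "ring", "ring+substituent"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_heavy[0] < 1 or self.n_heavy[0] > self.n_heavy[1]:
            raise ValueError(f"bad n_heavy range {self.n_heavy}")
        if self.conformers < 1:
            raise ValueError("conformers must be >= 1")


def _round4(x: float) -> float:
    return float(f"{x:.4f}")


def _assemble(name: str, types: list[str], coords: np.ndarray,
              edges: list[tuple[int, int]], record_index: int = 0) -> Molecule:
    atoms = tuple(
        Atom(serial=i + 1, name=f"{t.split('.')[0]}{i + 1}", sybyl_type=t,
             coords=(_round4(coords[i, 0]), _round4(coords[i, 1]),
                     _round4(coords[i, 2])))
        for i, t in enumerate(types)
    )
    bonds = tuple(Bond(a + 1, b + 1, "1") for a, b in edges)
    return Molecule(name=name, atoms=atoms, bonds=bonds,
                    record_index=record_index)


def _topology_edges(rng: np.random.Generator, n: int,
                    topology: str) -> list[tuple[int, int]]:
    if topology == "chain":
        return [(i, i + 1) for i in range(n - 1)]
    if topology == "tree":
        return [(int(rng.integers(0, i)), i) for i in range(1, n)]
    if topology == "ring":
        if n < 3:
            raise ValueError(f"ring topology needs >= 3 atoms, got {n}")
        return [(i, (i + 1) % n) for i in range(n)]
    # ring+substituent: a ring of ceil(n/2)>=3 atoms, rest hang off it
    ring_n = max(3, (n + 1) // 2)
    if ring_n > n:
        raise ValueError(f"ring+substituent topology needs >= 3 atoms, got {n}")
    edges = [(i, (i + 1) % ring_n) for i in range(ring_n)]
    for i in range(ring_n, n):
        edges.append((int(rng.integers(0, i)), i))
    return edges


def _embed(rng: np.random.Generator, n: int, edges: list[tuple[int, int]],
           topology: str, jitter_sigma: float) -> np.ndarray:
    coords = np.zeros((n, 3))
    if topology in ("ring", "ring+substituent"):
        ring_n = n if topology == "ring" else max(3, (n + 1) // 2)
        radius = BOND_LENGTH / (2.0 * math.sin(math.pi / ring_n))
        for i in range(ring_n):
            ang = 2.0 * math.pi * i / ring_n
            coords[i] = (radius * math.cos(ang), radius * math.sin(ang), 0.0)
        for parent, child in edges:
            if child >= ring_n:
                step = rng.standard_normal(3)
                step *= BOND_LENGTH / np.linalg.norm(step)
                coords[child] = coords[parent] + step
    else:
        # grow along the tree/chain with unit-bond random steps
        for parent, child in edges:
            step = rng.standard_normal(3)
            step *= BOND_LENGTH / np.linalg.norm(step)
            coords[child] = coords[parent] + step
    if jitter_sigma > 0:
        coords = coords + rng.normal(0.0, jitter_sigma, size=coords.shape)
    return coords


def make_molecule(spec: FixtureSpec, name: str | None = None,
                  record_index: int = 0) -> Molecule:
    """Generate one molecule deterministically from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = int(rng.integers(spec.n_heavy[0], spec.n_heavy[1] + 1))
    edges = _topology_edges(rng, n, spec.topology)
    types = [str(rng.choice(spec.type_alphabet)) for _ in range(n)]
    coords = _embed(rng, n, edges, spec.topology, spec.jitter_sigma)
    return _assemble(name or f"MOL{spec.seed:06d}", types, coords, edges,
                     record_index)


def make_library(spec: FixtureSpec, n_molecules: int) -> list[Molecule]:
    """Generate a library of ``n_molecules`` compounds.

    Compound ``k`` is generated from ``spec`` reseeded with ``seed + k``.
    With ``spec.conformers > 1`` each compound contributes that many
    consecutive records sharing its name, each a re-posed (randomly rotated
    and re-jittered) geometry of the same topology — what a conformer
    ensemble looks like to a rigid 3D comparison.
    """
    library: list[Molecule] = []
    rec = 0
    for k in range(n_molecules):
        sub = replace(spec, seed=spec.seed + k)
        base = make_molecule(sub, name=f"MOL{k:05d}", record_index=rec)
        library.append(base)
        rec += 1
        pose_rng = np.random.default_rng(100_000 + spec.seed + k)
        for _c in range(spec.conformers - 1):
            R = random_rotation(pose_rng)
            t = pose_rng.uniform(-5, 5, size=3)
            coords = np.array([a.coords for a in base.atoms])
            coords = coords @ R.T + t
            coords += pose_rng.normal(0.0, spec.jitter_sigma, coords.shape)
            conf = _assemble(base.name,
                             [a.sybyl_type for a in base.atoms], coords,
                             [(b.a_serial - 1, b.b_serial - 1)
                              for b in base.bonds],
                             record_index=rec)
            library.append(conf)
            rec += 1
    return library


def make_known_mcs_pair(spec: FixtureSpec,
                        core_size: int) -> tuple[Molecule, Molecule, int]:
    """Two molecules with a planted common substructure of known size.

    Both molecules contain an identical ``core_size``-atom chain (same SYBYL
    types, same bond topology, rigidly transformed copies of the same
    geometry).  Each is decorated with 1–3 pendant atoms whose types are
    disjoint between the two molecules and from the core, so at threshold 0
    (2D) the product graph spans only core×core pairs and the planted core
    is the maximum common substructure: the returned expected clique size is
    exactly ``core_size``.
    """
    if core_size < 1:
        raise ValueError("core_size must be >= 1")
    lo, hi = spec.n_heavy
    if core_size > hi:
        raise ValueError(
            f"core_size {core_size} exceeds the heavy-atom cap {hi}")
    rng = np.random.default_rng(spec.seed)

    core_types = [str(rng.choice(CORE_TYPES)) for _ in range(core_size)]
    core_edges = [(i, i + 1) for i in range(core_size - 1)]
    core_coords = _embed(rng, core_size, core_edges, "chain",
                         jitter_sigma=0.0)

    def decorated(decor_types: tuple[str, ...], pose_seed: int,
                  name: str) -> Molecule:
        sub = np.random.default_rng(pose_seed)
        n_dec = int(sub.integers(1, 4))
        types = list(core_types)
        edges = list(core_edges)
        R = random_rotation(sub)
        t = sub.uniform(-3, 3, size=3)
        coords = [core_coords @ R.T + t]
        flat = coords[0].tolist()
        for j in range(n_dec):
            parent = int(sub.integers(0, core_size + j))
            types.append(str(sub.choice(decor_types)))
            edges.append((parent, core_size + j))
            step = sub.standard_normal(3)
            step *= BOND_LENGTH / np.linalg.norm(step)
            flat.append((np.asarray(flat[parent]) + step).tolist())
        return _assemble(name, types, np.asarray(flat), edges)

    ref = decorated(DECOR_TYPES_A, spec.seed * 2 + 1, "PLANT_REF")
    tgt = decorated(DECOR_TYPES_B, spec.seed * 2 + 2, "PLANT_TGT")
    return ref, tgt, core_size


# ---------------------------------------------------------------------------
# small named molecules used in examples and regression tests
# ---------------------------------------------------------------------------

def _hexagon(radius: float) -> list[tuple[float, float, float]]:
    return [(_round4(radius * math.cos(math.pi * i / 3)),
             _round4(radius * math.sin(math.pi * i / 3)), 0.0)
            for i in range(6)]


def benzene() -> Molecule:
    """Benzene: 6 aromatic carbons in a regular hexagon plus 6 hydrogens."""
    ring = _hexagon(1.39)
    outer = _hexagon(1.39 + 1.09)
    atoms = []
    for i, (x, y, z) in enumerate(ring):
        atoms.append(Atom(i + 1, f"C{i + 1}", "C.ar", (x, y, z)))
    for i, (x, y, z) in enumerate(outer):
        atoms.append(Atom(7 + i, f"H{i + 1}", "H", (x, y, z)))
    bonds = [Bond(i + 1, (i + 1) % 6 + 1, "ar") for i in range(6)]
    bonds += [Bond(i + 1, 7 + i, "1") for i in range(6)]
    return Molecule("BENZENE", tuple(atoms), tuple(bonds))


def toluene() -> Molecule:
    """Toluene: the benzene ring with a methyl carbon replacing one hydrogen."""
    base = benzene()
    ring = [a for a in base.atoms if a.sybyl_type == "C.ar"]
    hydrogens = [a for a in base.atoms if a.sybyl_type == "H"][1:]  # drop H on C1
    methyl_x = 1.39 + 1.52
    atoms = list(ring)
    atoms.append(Atom(7, "C7", "C.3", (_round4(methyl_x), 0.0, 0.0)))
    for j, h in enumerate(hydrogens):
        atoms.append(Atom(8 + j, h.name, "H", h.coords))
    # methyl hydrogens
    for j in range(3):
        ang = 2.0 * math.pi * j / 3
        atoms.append(Atom(13 + j, f"HM{j + 1}", "H",
                          (_round4(methyl_x + 0.51),
                           _round4(0.9 * math.cos(ang)),
                           _round4(0.9 * math.sin(ang)))))
    bonds = [Bond(i + 1, (i + 1) % 6 + 1, "ar") for i in range(6)]
    bonds.append(Bond(1, 7, "1"))
    for j in range(5):
        bonds.append(Bond(2 + j, 8 + j, "1"))
    for j in range(3):
        bonds.append(Bond(7, 13 + j, "1"))
    return Molecule("TOLUENE", tuple(atoms), tuple(bonds))


def propane() -> Molecule:
    """Propane heavy-atom chain C1-C2-C3 with its 8 hydrogens."""
    positions = [(0.0, 0.0, 0.0), (1.26, 0.89, 0.0), (2.52, 0.0, 0.0)]
    atoms = [Atom(i + 1, f"C{i + 1}", "C.3", p)
             for i, p in enumerate(positions)]
    h_serial = 4
    bonds = [Bond(1, 2, "1"), Bond(2, 3, "1")]
    for carbon, count in ((1, 3), (2, 2), (3, 3)):
        cx, cy, cz = positions[carbon - 1]
        for j in range(count):
            ang = 2.0 * math.pi * j / count
            atoms.append(Atom(h_serial, f"H{h_serial - 3}", "H",
                              (_round4(cx + 0.7 * math.cos(ang)),
                               _round4(cy - 0.9),
                               _round4(cz + 0.7 * math.sin(ang)))))
            bonds.append(Bond(carbon, h_serial, "1"))
            h_serial += 1
    return Molecule("PROPANE", tuple(atoms), tuple(bonds))
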