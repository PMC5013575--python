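"""Library screening: score, group conformers, rank by Tanimoto.

A screening run compares one reference ligand against every record of a
target library.  Each comparison finds the maximum common substructure via
the product-graph maximum clique and scores it with the graph-matching
Tanimoto coefficient

    Tc = c / (n_ref + n_tgt - c)

where ``c`` is the clique (common substructure) size and ``n_ref``,
``n_tgt`` the kept-atom counts of the two molecules.  Tc is 1 exactly when
the mapping covers both molecules completely, 0 when no atom pair matches.

Records sharing a molecule name are treated as conformers of one compound.
In 3D screening a compound's score is its best conformer's score and up to
``conformers_per_molecule`` best conformers are retained per compound; 2D
scores are conformation-independent, so one entry per compound is kept.
Ranking is by decreasing Tanimoto, ties broken by ascending record index;
the output is identical for any worker count.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

from joblib import Parallel, delayed

from .clique import build_product_graph, max_clique
from .graph import DegenerateMoleculeError, MolecularGraph, build_graph
from .mol2 import Molecule

__all__ = ["ScreenConfig", "MatchResult", "Hit", "ScreenReport",
           "score_pair", "screen_library", "tanimoto"]

logger = logging.getLogger(__name__)


def tanimoto(c: int, n_ref: int, n_tgt: int) -> float:
    """Graph-matching Tanimoto coefficient c / (n_ref + n_tgt - c)."""
    denom = n_ref + n_tgt - c
    return c / denom if denom else 0.0


@dataclass(frozen=True)
class ScreenConfig:
    """Options of one screening run.

    dimension : 2 for topological, 3 for geometric comparison.
    threshold_2d : max allowed shortest-path difference, in bonds (2D rule).
    threshold_3d : max allowed spatial distance difference, in Å (3D rule).
    top_k : number of highest-ranking compounds reported.
    conformers_per_molecule : best conformers kept per compound (3D only).
    include_h : include hydrogens in the molecular and product graphs
        (off by default — the customary speed/size trade-off).
    workers : parallel worker count (None → all available cores).
    """

    dimension: int = 2
    threshold_2d: int = 1
    threshold_3d: float = 1.0
    top_k: int = 100
    conformers_per_molecule: int = 1
    include_h: bool = False
    workers: int | None = None

    def __post_init__(self):
        if self.dimension not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {self.dimension}")
        if self.threshold_2d < 0 or self.threshold_3d < 0:
            raise ValueError("thresholds must be non-negative")
        if self.top_k < 1:
            raise ValueError("top_k must be positive")
        if self.conformers_per_molecule < 1:
            raise ValueError("conformers_per_molecule must be positive")
        if self.workers is not None and self.workers < 1:
            raise ValueError("workers must be positive")

    @property
    def threshold(self) -> float:
        """The active threshold for the configured dimension."""
        return self.threshold_2d if self.dimension == 2 else self.threshold_3d

    @property
    def effective_workers(self) -> int:
        return self.workers if self.workers is not None else (os.cpu_count() or 1)


@dataclass(frozen=True)
class MatchResult:
    """One reference-vs-target comparison.

    ``pairs`` lists the matched atoms in clique order as
    (reference serial, reference SYBYL type, target serial, target SYBYL
    type); serials are the ones printed in the source mol2 files.
    """

    pairs: tuple[tuple[int, str, int, str], ...]
    c: int
    n_ref: int
    n_tgt: int
    tanimoto: float

    @classmethod
    def from_clique(cls, pairs: Sequence[tuple[int, str, int, str]],
                    n_ref: int, n_tgt: int) -> "MatchResult":
        c = len(pairs)
        return cls(pairs=tuple(pairs), c=c, n_ref=n_ref, n_tgt=n_tgt,
                   tanimoto=tanimoto(c, n_ref, n_tgt))

    def serial_pairs(self) -> tuple[tuple[int, int], ...]:
        """(reference serial, target serial) pairs, for superposition."""
        return tuple((p[0], p[2]) for p in self.pairs)


@dataclass(frozen=True)
class Hit:
    """One ranked entry: a compound (or one retained conformer of it)."""

    rank: int
    name: str
    record_index: int
    result: MatchResult


@dataclass(frozen=True)
class ScreenReport:
    """Ranked outcome of one screening run."""

    reference_name: str
    config: ScreenConfig
    hits: tuple[Hit, ...]
    skipped_records: int = 0

    def ranked_names(self) -> list[tuple[str, float]]:
        return [(h.name, h.result.tanimoto) for h in self.hits]


def score_pair(ref: MolecularGraph, tgt: MolecularGraph,
               config: ScreenConfig) -> MatchResult:
    """Score one reference/target graph pair under ``config``.

    Both graphs must have been built under the same hydrogen policy.  An
    empty product graph is legal and scores 0.
    """
    pg = build_product_graph(ref, tgt, config.dimension, config.threshold)
    clique = max_clique(pg)
    pairs = [
        (ref.serials[v.r], ref.sybyl[v.r], tgt.serials[v.t], tgt.sybyl[v.t])
        for v in clique.members
    ]
    return MatchResult.from_clique(pairs, ref.n, tgt.n)


def _score_record(ref: MolecularGraph, mol: Molecule,
                  config: ScreenConfig):
    """Worker body: returns (record_index, name, MatchResult) or None (skip)."""
    try:
        tg = build_graph(mol, include_h=config.include_h)
    except DegenerateMoleculeError:
        return None
    return (mol.record_index, mol.name, score_pair(ref, tg, config))


def screen_library(ref: Molecule, library: Sequence[Molecule],
                   config: ScreenConfig | None = None) -> ScreenReport:
    """Screen ``library`` against ``ref`` and return the ranked report.

    Every record is scored independently (in parallel across
    ``config.workers`` processes when > 1); records are then grouped by
    molecule name, ranked by decreasing best Tanimoto (ties by ascending
    record index) and truncated to ``top_k`` compounds.  Work scheduling
    never affects the output: results are merged in record order before
    ranking, so any worker count produces the identical report.

    Records whose graph degenerates (e.g. hydrogen-only under the default
    policy) are skipped with a warning and counted in ``skipped_records``.
    """
    if config is None:
        config = ScreenConfig()
    if not library:
        raise ValueError("library must contain at least one molecule")

    ref_graph = build_graph(ref, include_h=config.include_h)

    n_jobs = config.effective_workers
    if n_jobs > 1 and len(library) > 1:
        raw = Parallel(n_jobs=n_jobs)(
            delayed(_score_record)(ref_graph, m, config) for m in library)
    else:
        raw = [_score_record(ref_graph, m, config) for m in library]

    scored: list[tuple[int, str, MatchResult]] = []
    skipped = 0
    for mol, res in zip(library, raw):
        if res is None:
            skipped += 1
            logger.warning("skipping degenerate record %d (%r)",
                           mol.record_index, mol.name)
        else:
            scored.append(res)

    # group records by compound name (conformers share a name)
    groups: dict[str, list[tuple[int, str, MatchResult]]] = {}
    for entry in sorted(scored, key=lambda e: e[0]):
        groups.setdefault(entry[1], []).append(entry)

    per_conformer = config.conformers_per_molecule if config.dimension == 3 else 1
    ranked_groups = []
    for name, entries in groups.items():
        entries = sorted(entries, key=lambda e: (-e[2].tanimoto, e[0]))
        best = entries[0]
        ranked_groups.append((name, best[2].tanimoto, best[0],
                              entries[:per_conformer]))
    ranked_groups.sort(key=lambda g: (-g[1], g[2]))

    hits: list[Hit] = []
    for rank, (name, _score, _first, entries) in enumerate(
            ranked_groups[:config.top_k], start=1):
        for rec_idx, _name, result in entries:
            hits.append(Hit(rank=rank, name=name, record_index=rec_idx,
                            result=result))

    return ScreenReport(reference_name=ref.name, config=config,
                        hits=tuple(hits), skipped_records=skipped)
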