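"""Matched-atom superposition and the run's two output artifacts.

After a 3D screen each hit is superimposed onto the reference over its
matched atom pairs with a least-squares rigid fit (Kabsch: SVD of the
cross-covariance with a reflection guard), the pair-fitting operation a
molecular viewer performs.  The matched-atom RMSD after the fit quantifies
how well the common substructure overlays.

Two files per run are written: a ranked list (one line per hit, molecule ID
and Tanimoto, tab-separated, 4 decimals) and one aligned mol2 per hit whose
comment header records the run metadata and one matched pair per line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph import rigid_transform
from .mol2 import Molecule, write_mol2
from .screen import Hit, ScreenReport

__all__ = ["Superposition", "superpose_matched", "apply_superposition",
           "pair_rmsd", "write_ranked_list", "read_ranked_list",
           "write_aligned_mol2", "RANKED_LIST_NAME"]

RANKED_LIST_NAME = "lisica_results.txt"


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map x → R·x + t of target onto reference, with RMSD (Å)."""

    rotation: np.ndarray     # 3x3, orthonormal, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float              # over matched pairs, after the transform

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _paired_coords(ref: Molecule, tgt: Molecule,
                   pairs: Sequence[tuple[int, int]]):
    P = np.array([tgt.atom_by_serial(t).coords for _r, t in pairs], float)
    Q = np.array([ref.atom_by_serial(r).coords for r, _t in pairs], float)
    return P, Q


def pair_rmsd(ref: Molecule, tgt: Molecule,
              pairs: Sequence[tuple[int, int]]) -> float:
    """RMSD over the matched pairs with coordinates as given (no fit)."""
    P, Q = _paired_coords(ref, tgt, pairs)
    return float(np.sqrt(((P - Q) ** 2).sum(axis=1).mean()))


def superpose_matched(ref: Molecule, tgt: Molecule,
                      pairs: Sequence[tuple[int, int]]) -> Superposition:
    """Least-squares rigid fit of the target onto the reference.

    ``pairs`` are (reference serial, target serial) matched atom pairs.
    With ≥ 3 pairs the rotation comes from the Kabsch construction —
    SVD of the centred cross-covariance, with the smallest singular
    direction flipped when the raw optimum would be a reflection.  With 1
    or 2 pairs the rotation is not determined, so the fit degrades to the
    documented translation-only mode (identity rotation, centroid match).
    Zero pairs is a contract error.
    """
    if not pairs:
        raise ValueError("superpose_matched requires at least one matched pair")
    P, Q = _paired_coords(ref, tgt, pairs)  # P: target (moving), Q: reference
    cp, cq = P.mean(axis=0), Q.mean(axis=0)

    if len(pairs) < 3:
        R = np.eye(3)
    else:
        H = (P - cp).T @ (Q - cq)
        U, _s, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T

    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(mol: Molecule, sup: Superposition) -> Molecule:
    """Move the *whole* molecule (not only matched atoms) by the fit."""
    return rigid_transform(mol, sup.rotation, sup.translation)


def write_ranked_list(report: ScreenReport, path: str | Path) -> Path:
    """Write the ranked text file: ``<molecule ID>\\t<Tanimoto %.4f>`` lines.

    One line per hit, decreasing Tanimoto, nothing else on the line.
    """
    if not report.hits:
        raise ValueError("report has no hits to write")
    lines = [f"{h.name}\t{h.result.tanimoto:.4f}" for h in report.hits]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_ranked_list(path: str | Path) -> list[tuple[str, float]]:
    """Parse a ranked list back into (name, tanimoto) rows."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, value = line.rsplit("\t", 1)
        rows.append((name, float(value)))
    return rows


def match_comment_lines(hit: Hit, hit_index: int) -> list[str]:
    """Comment header for one aligned mol2: metadata plus one pair per line."""
    r = hit.result
    lines = [
        f"# name: {hit.name}",
        f"# rank: {hit.rank}",
        f"# record_index: {hit.record_index}",
        f"# hit_index: {hit_index}",
        f"# n_ref: {r.n_ref}",
        f"# n_tgt: {r.n_tgt}",
    ]
    for ref_serial, ref_type, tgt_serial, tgt_type in r.pairs:
        lines.append(f"# pair {ref_serial} {ref_type} {tgt_serial} {tgt_type}")
    return lines


_PAIR_RE = re.compile(r"^#\s*pair\s+(\d+)\s+(\S+)\s+(\d+)\s+(\S+)\s*$")
_META_RE = re.compile(r"^#\s*(\w+):\s*(.*)$")


def parse_match_comments(comments: Sequence[str]):
    """Inverse of :func:`match_comment_lines`: (metadata dict, pair tuples)."""
    meta: dict[str, str] = {}
    pairs: list[tuple[int, str, int, str]] = []
    for line in comments:
        m = _PAIR_RE.match(line)
        if m:
            pairs.append((int(m.group(1)), m.group(2),
                          int(m.group(3)), m.group(4)))
            continue
        m = _META_RE.match(line)
        if m:
            meta[m.group(1)] = m.group(2)
    return meta, pairs


def write_aligned_mol2(ref: Molecule, hit_tgt: Molecule, hit: Hit,
                       superposition: Superposition | None,
                       path: str | Path, hit_index: int = 0) -> Path:
    """Write one aligned-structures file for a hit.

    The file holds the reference record first and the target second.  For a
    3D hit the supplied superposition is applied to the whole target; for a
    2D hit the target coordinates pass through unchanged.  The comment
    section before the first record lists run metadata and the matched pairs
    in clique order.
    """
    tgt_out = (apply_superposition(hit_tgt, superposition)
               if superposition is not None else hit_tgt)
    doc = write_mol2([ref, tgt_out],
                     comment_lines=match_comment_lines(hit, hit_index))
    path = Path(path)
    path.write_text(doc)
    return path
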