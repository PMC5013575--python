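"""Tripos MOL2 reading and writing.

Only the ``MOLECULE``, ``ATOM`` and ``BOND`` record types are interpreted;
any other ``@<TRIPOS>`` section (``SUBSTRUCTURE``, ``CRYSIN``, ...) is
skipped without error.  Atom serial numbers and SYBYL atom-type strings are
preserved verbatim from the file — no operation in this package ever
renumbers atoms, because downstream output (matched-pair listings, aligned
structures) refers to atoms by the serial printed in the source file.

Multi-record files are the normal case: a screening library is one MOL2
document holding many ``@<TRIPOS>MOLECULE`` records, optionally with several
conformers of the same compound identified by a shared molecule name.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "Mol2Error",
    "Mol2ParseError",
    "read_mol2",
    "read_mol2_comments",
    "write_mol2",
]

# SYBYL types whose atoms carry no chemistry: kept on read, always excluded
# from molecular graphs (see graph.build_graph).
DUMMY_ELEMENTS = frozenset({"Du", "LP"})


class Mol2Error(ValueError):
    """Base class for MOL2 format problems."""


class Mol2ParseError(Mol2Error):
    """A malformed line or an internally inconsistent record.

    Carries the 0-based record index and the 1-based line number within the
    document so the offending record can be located in a large library file.
    """

    def __init__(self, message: str, record_index: int | None = None,
                 line_no: int | None = None):
        loc = []
        if record_index is not None:
            loc.append(f"record {record_index}")
        if line_no is not None:
            loc.append(f"line {line_no}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.record_index = record_index
        self.line_no = line_no


@dataclass(frozen=True)
class Atom:
    """One ATOM record line.

    ``serial`` is the 1-based identifier printed in the file; ``sybyl_type``
    is the raw SYBYL string (e.g. ``"C.ar"``, ``"N.3"``, ``"Br"``); the
    element is the text before the first ``"."``.
    """

    serial: int
    name: str
    sybyl_type: str
    coords: tuple[float, float, float]

    @property
    def element(self) -> str:
        return self.sybyl_type.split(".", 1)[0]

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_dummy(self) -> bool:
        return self.element in DUMMY_ELEMENTS


@dataclass(frozen=True)
class Bond:
    """One undirected covalent bond between two atom serials."""

    a_serial: int
    b_serial: int
    order_label: str = "1"

    def key(self) -> tuple[int, int]:
        """Canonical undirected key."""
        a, b = self.a_serial, self.b_serial
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Molecule:
    """One parsed ``@<TRIPOS>MOLECULE`` record.

    ``record_index`` is the 0-based position of the record in its source
    document; conformer handling and tie-breaking in the screening module
    rely on it.
    """

    name: str
    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    record_index: int = 0

    def atom_by_serial(self, serial: int) -> Atom:
        atom = self._serial_map().get(serial)
        if atom is None:
            raise KeyError(f"no atom with serial {serial} in {self.name!r}")
        return atom

    def _serial_map(self) -> dict[int, Atom]:
        # cached lazily on the instance; frozen dataclass, so go via __dict__
        cached = self.__dict__.get("_serials")
        if cached is None:
            cached = {a.serial: a for a in self.atoms}
            self.__dict__["_serials"] = cached
        return cached


def _looks_like_document(source: str) -> bool:
    return "@<TRIPOS>" in source or "\n" in source


def _read_text(path_or_text: str | os.PathLike) -> str:
    if isinstance(path_or_text, str) and _looks_like_document(path_or_text):
        return path_or_text
    return Path(path_or_text).read_text()


def read_mol2(path_or_text: str | os.PathLike) -> list[Molecule]:
    """Parse a MOL2 document into an ordered list of :class:`Molecule`.

    ``path_or_text`` may be a filesystem path or the document text itself
    (recognised by containing ``@<TRIPOS>`` or a newline).  Records appear in
    file order with ``record_index`` 0, 1, 2, ...; atom serials are taken from
    the file, not renumbered.  Line endings (LF/CRLF) and trailing blank
    lines are irrelevant.

    Raises
    ------
    Mol2ParseError
        On a malformed ATOM/BOND line, an atom/bond count that disagrees with
        the record's counts line, a bond referencing a missing serial, a
        duplicate serial or duplicate undirected bond, or a document with no
        ``@<TRIPOS>MOLECULE`` record at all.
    """
    text = _read_text(path_or_text)
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")

    # locate record starts
    starts = [i for i, ln in enumerate(lines)
              if ln.strip() == "@<TRIPOS>MOLECULE"]
    if not starts:
        raise Mol2ParseError("document contains no @<TRIPOS>MOLECULE record")

    molecules: list[Molecule] = []
    for rec_idx, start in enumerate(starts):
        end = starts[rec_idx + 1] if rec_idx + 1 < len(starts) else len(lines)
        molecules.append(_parse_record(lines, start, end, rec_idx))
    return molecules


def _parse_record(lines: list[str], start: int, end: int,
                  rec_idx: int) -> Molecule:
    # sections: map section name -> list of (line_no, text)
    section = "MOLECULE"
    body: dict[str, list[tuple[int, str]]] = {"MOLECULE": []}
    for i in range(start + 1, end):
        raw = lines[i]
        stripped = raw.strip()
        if stripped.startswith("@<TRIPOS>"):
            section = stripped[len("@<TRIPOS>"):]
            body.setdefault(section, [])
            continue
        if stripped.startswith("#"):
            continue
        body.setdefault(section, []).append((i + 1, raw))

    mol_lines = [(n, ln) for n, ln in body["MOLECULE"]]
    # first line: name (verbatim, minus trailing whitespace); second: counts
    meaningful = [(n, ln) for n, ln in mol_lines if ln.strip() != ""] or mol_lines
    if not meaningful:
        raise Mol2ParseError("MOLECULE record has no name line", rec_idx)
    name = meaningful[0][1].strip()
    if len(meaningful) < 2:
        raise Mol2ParseError("MOLECULE record has no counts line", rec_idx,
                             meaningful[0][0])
    counts_no, counts_line = meaningful[1]
    try:
        counts = [int(tok) for tok in counts_line.split()[:2]]
        n_atoms, n_bonds = counts[0], counts[1] if len(counts) > 1 else 0
    except (ValueError, IndexError):
        raise Mol2ParseError(f"unreadable counts line {counts_line!r}",
                             rec_idx, counts_no) from None

    atoms: list[Atom] = []
    seen_serials: set[int] = set()
    for line_no, raw in body.get("ATOM", []):
        if not raw.strip():
            continue
        tok = raw.split()
        if len(tok) < 6:
            raise Mol2ParseError(f"malformed ATOM line {raw!r}", rec_idx, line_no)
        try:
            serial = int(tok[0])
            x, y, z = float(tok[2]), float(tok[3]), float(tok[4])
        except ValueError:
            raise Mol2ParseError(f"malformed ATOM line {raw!r}", rec_idx,
                                 line_no) from None
        sybyl = tok[5]
        if not sybyl:
            raise Mol2ParseError("empty SYBYL type", rec_idx, line_no)
        if serial in seen_serials:
            raise Mol2ParseError(f"duplicate atom serial {serial}", rec_idx,
                                 line_no)
        if not all(math.isfinite(v) for v in (x, y, z)):
            raise Mol2ParseError(f"non-finite coordinates in {raw!r}", rec_idx,
                                 line_no)
        seen_serials.add(serial)
        atoms.append(Atom(serial=serial, name=tok[1], sybyl_type=sybyl,
                          coords=(x, y, z)))

    bonds: list[Bond] = []
    seen_bonds: set[tuple[int, int]] = set()
    for line_no, raw in body.get("BOND", []):
        if not raw.strip():
            continue
        tok = raw.split()
        if len(tok) < 4:
            raise Mol2ParseError(f"malformed BOND line {raw!r}", rec_idx, line_no)
        try:
            a, b = int(tok[1]), int(tok[2])
        except ValueError:
            raise Mol2ParseError(f"malformed BOND line {raw!r}", rec_idx,
                                 line_no) from None
        if a == b:
            raise Mol2ParseError(f"self-bond on serial {a}", rec_idx, line_no)
        for s in (a, b):
            if s not in seen_serials:
                raise Mol2ParseError(
                    f"bond references missing atom serial {s}", rec_idx, line_no)
        bond = Bond(a_serial=a, b_serial=b, order_label=tok[3])
        if bond.key() in seen_bonds:
            raise Mol2ParseError(
                f"duplicate bond {a}-{b}", rec_idx, line_no)
        seen_bonds.add(bond.key())
        bonds.append(bond)

    if len(atoms) != n_atoms:
        raise Mol2ParseError(
            f"counts line declares {n_atoms} atoms but {len(atoms)} were read",
            rec_idx, counts_no)
    if len(bonds) != n_bonds:
        raise Mol2ParseError(
            f"counts line declares {n_bonds} bonds but {len(bonds)} were read",
            rec_idx, counts_no)

    return Molecule(name=name, atoms=tuple(atoms), bonds=tuple(bonds),
                    record_index=rec_idx)


def read_mol2_comments(path_or_text: str | os.PathLike) -> list[str]:
    """Return the ``#``-prefixed comment lines preceding the first record."""
    text = _read_text(path_or_text)
    out = []
    for raw in text.replace("\r\n", "\n").split("\n"):
        stripped = raw.strip()
        if stripped == "@<TRIPOS>MOLECULE" or stripped.startswith("@<TRIPOS>"):
            break
        if stripped.startswith("#"):
            out.append(stripped)
    return out


def write_mol2(molecules: Sequence[Molecule],
               comment_lines: Iterable[str] | None = None) -> str:
    """Serialize molecules to one MOL2 document.

    ``comment_lines`` (already ``#``-prefixed, or prefixed here if not) are
    emitted before the first ``@<TRIPOS>MOLECULE`` record.  Coordinates are
    written with 4 decimal places; the round trip
    ``read_mol2(write_mol2(ms)) == ms`` holds exactly for molecules whose
    coordinates are representable at that precision (everything the fixture
    generator produces).
    """
    if not molecules:
        raise ValueError("write_mol2 requires at least one molecule")
    chunks: list[str] = []
    if comment_lines:
        for c in comment_lines:
            c = c if c.startswith("#") else "# " + c
            chunks.append(c)
        chunks.append("")
    for mol in molecules:
        chunks.append("@<TRIPOS>MOLECULE")
        chunks.append(mol.name)
        chunks.append(f"{len(mol.atoms):>5d} {len(mol.bonds):>5d}     0     0     0")
        chunks.append("SMALL")
        chunks.append("NO_CHARGES")
        chunks.append("")
        chunks.append("@<TRIPOS>ATOM")
        for a in mol.atoms:
            x, y, z = a.coords
            chunks.append(
                f"{a.serial:>7d} {a.name:<8s} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
                f"{a.sybyl_type:<9s} 1 LIG1 0.0000")
        chunks.append("@<TRIPOS>BOND")
        for i, b in enumerate(mol.bonds, start=1):
            chunks.append(f"{i:>6d} {b.a_serial:>5d} {b.b_serial:>5d} {b.order_label}")
        chunks.append("")
    return "\n".join(chunks) + "\n"
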