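"""MDL molfile (V2000/V3000) and XYZ input/output.

Molfile bond type 4 ("aromatic") maps to the :data:`~kekulize.molgraph.UNRESOLVED`
sentinel, types 1-3 to resolved orders.  Explicit hydrogen atoms are
collapsed into implicit counts on their heavy neighbor when reading; for
heavy atoms without aromatic bonds any remaining valence deficit is also
read as implicit hydrogen (the explicit valence field, when present,
overrides the element default).  Atoms with aromatic bonds carry only
the hydrogens that are explicit in the file -- their bond orders, and
hence any valence deficit, are not yet defined.

Writing auto-selects V3000 whenever the 999 atom/bond fields of V2000
would overflow.  Implicit hydrogens are expanded to explicit atoms when
the graph still contains unresolved bonds (otherwise the counts could
not be recovered); fully kekulized graphs are written compactly, with
hydrogens implicit.  Line endings are normalized on read and written
platform-independently.

The .cc1 dialect is not supported; the loader raises an informative
error for it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .molgraph import (
    UNRESOLVED,
    Atom,
    Bond,
    DEFAULT_VALENCES,
    KekulizeError,
    MolecularGraph,
    build_molecule,
)

__all__ = [
    "FileDialect",
    "MolfileError",
    "UnsupportedFormatError",
    "XYZRecord",
    "read_molfile",
    "write_molfile",
    "read_xyz",
    "write_xyz",
    "load",
]


class MolfileError(KekulizeError):
    """Malformed or out-of-range molfile content."""


class UnsupportedFormatError(KekulizeError):
    """A file format this package does not read or write."""


@dataclass(slots=True)
class FileDialect:
    """Output dialect selector.

    ``format`` is ``"molfile_v2000"``, ``"molfile_v3000"`` or ``"xyz"``;
    ``kekulized=True`` forbids unresolved bonds on write.  V2000 cannot
    hold more than 999 atoms or bonds.
    """

    format: str = "molfile_v2000"
    kekulized: bool = False

    def __post_init__(self) -> None:
        if self.format not in ("molfile_v2000", "molfile_v3000", "xyz"):
            raise UnsupportedFormatError(f"unknown format {self.format!r}")


@dataclass(slots=True)
class XYZRecord:
    """Coordinates-only record: parallel element and position lists."""

    elements: List[str]
    coords: np.ndarray  # (n, 3) Angstrom
    comment: str = ""


def _text(source: Union[str, io.TextIOBase]) -> str:
    if hasattr(source, "read"):
        source = source.read()  # type: ignore[union-attr]
    return str(source).replace("\r\n", "\n").replace("\r", "\n")


# ---------------------------------------------------------------------------
# reading


def read_molfile(source: Union[str, io.TextIOBase]) -> MolecularGraph:
    """Parse a V2000 or V3000 molfile (text or stream) into a graph."""
    lines = _text(source).split("\n")
    if len(lines) < 4:
        raise MolfileError("molfile too short: no counts line")
    counts = lines[3]
    if "V3000" in counts:
        elements, coords, valences, bonds = _parse_v3000(lines)
    elif "V2000" in counts or len(counts) >= 6:
        elements, coords, valences, bonds = _parse_v2000(lines)
    else:
        raise MolfileError(f"malformed counts line: {counts!r}")
    return _assemble(elements, coords, valences, bonds)


def _parse_v2000(lines: List[str]):
    counts = lines[3]
    try:
        na = int(counts[0:3])
        nb = int(counts[3:6])
    except ValueError as exc:
        raise MolfileError(f"malformed counts line: {counts!r}") from exc
    if na > 999 or nb > 999:
        raise MolfileError(
            f"{na} atoms / {nb} bonds exceed the V2000 999 limit; "
            "this structure requires the V3000 dialect"
        )
    elements, coords, valences = [], [], []
    for line in lines[4 : 4 + na]:
        try:
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            el = line[31:34].strip()
        except (ValueError, IndexError) as exc:
            raise MolfileError(f"malformed atom line: {line!r}") from exc
        vvv = 0
        if len(line) >= 51:
            try:
                vvv = int(line[48:51])
            except ValueError:
                vvv = 0
        elements.append(el)
        coords.append((x, y, z))
        valences.append(0 if vvv == 0 else (0 if vvv == 15 else vvv))
    bonds = []
    for line in lines[4 + na : 4 + na + nb]:
        try:
            u, v, t = int(line[0:3]), int(line[3:6]), int(line[6:9])
        except (ValueError, IndexError) as exc:
            raise MolfileError(f"malformed bond line: {line!r}") from exc
        bonds.append((u, v, t))
    return elements, coords, valences, bonds


def _parse_v3000(lines: List[str]):
    elements, coords, valences, bonds = [], [], [], []
    section = None
    for raw in lines:
        if not raw.startswith("M  V30"):
            continue
        body = raw[6:].strip()
        if body.startswith("BEGIN"):
            section = body.split()[1]
            continue
        if body.startswith("END"):
            section = None
            continue
        if section == "ATOM":
            parts = body.split()
            try:
                el = parts[1]
                x, y, z = (float(parts[2]), float(parts[3]), float(parts[4]))
            except (ValueError, IndexError) as exc:
                raise MolfileError(f"malformed V3000 atom line: {raw!r}") from exc
            vvv = 0
            for p in parts[6:]:
                if p.startswith("VAL="):
                    vvv = int(p[4:])
            elements.append(el)
            coords.append((x, y, z))
            valences.append(0 if vvv in (0, -1) else vvv)
        elif section == "BOND":
            parts = body.split()
            try:
                t, u, v = int(parts[1]), int(parts[2]), int(parts[3])
            except (ValueError, IndexError) as exc:
                raise MolfileError(f"malformed V3000 bond line: {raw!r}") from exc
            bonds.append((u, v, t))
    if not elements:
        raise MolfileError("V3000 block contains no atoms")
    return elements, coords, valences, bonds


def _assemble(elements, coords, valences, bonds) -> MolecularGraph:
    n = len(elements)
    order_map = {1: 1, 2: 2, 3: 3, 4: UNRESOLVED}
    parsed: List[Tuple[int, int, int]] = []
    for u, v, t in bonds:
        if t not in order_map:
            raise MolfileError(f"unsupported bond type {t}")
        if not (1 <= u <= n and 1 <= v <= n):
            raise MolfileError(f"bond ({u}, {v}) index out of range 1..{n}")
        parsed.append((u - 1, v - 1, order_map[t]))

    # collapse explicit hydrogens bonded singly to one heavy atom
    nbrs: List[List[Tuple[int, int]]] = [[] for _ in range(n)]
    for u, v, o in parsed:
        nbrs[u].append((v, o))
        nbrs[v].append((u, o))
    collapse = set()
    extra_h = [0] * n
    for i, el in enumerate(elements):
        if el == "H" and len(nbrs[i]) == 1 and nbrs[i][0][1] == 1:
            j = nbrs[i][0][0]
            if elements[j] != "H":
                collapse.add(i)
                extra_h[j] += 1

    keep = [i for i in range(n) if i not in collapse]
    remap = {old: new for new, old in enumerate(keep)}
    atoms: List[Atom] = []
    for old in keep:
        el = elements[old]
        val = valences[old] or DEFAULT_VALENCES.get(el)
        if val is None:
            raise MolfileError(f"no default valence for element {el!r}")
        atoms.append(
            Atom(
                remap[old],
                element=el,
                valence=val,
                implicit_h=extra_h[old],
                coords=coords[old],
            )
        )
    blist = [
        Bond(remap[u], remap[v], o)
        for u, v, o in parsed
        if u not in collapse and v not in collapse
    ]
    graph = build_molecule(atoms, blist)
    # valence-deficit hydrogens for atoms outside the pi system
    for atom in graph.atoms:
        incident = graph.adjacency[atom.index]
        if any(graph.bonds[bi].order == UNRESOLVED for _, bi in incident):
            continue
        occupied = atom.implicit_h + sum(
            graph.bonds[bi].order for _, bi in incident
        )
        if occupied < atom.valence:
            atom.implicit_h += atom.valence - occupied
    return graph


# ---------------------------------------------------------------------------
# writing


def _expanded(graph: MolecularGraph) -> MolecularGraph:
    """Copy of ``graph`` with implicit hydrogens as explicit atoms."""
    atoms = []
    bonds = []
    for a in graph.atoms:
        atoms.append(
            Atom(a.index, a.element, a.valence, implicit_h=0, coords=a.coords)
        )
    for b in graph.bonds:
        bonds.append(Bond(b.u, b.v, b.order))
    for a in graph.atoms:
        for _ in range(a.implicit_h):
            h = Atom(len(atoms), "H", 1, 0, coords=None)
            atoms.append(h)
            bonds.append(Bond(a.index, h.index, 1))
    return build_molecule(atoms, bonds)


def write_molfile(
    graph: MolecularGraph,
    dialect: Optional[FileDialect] = None,
    title: str = "",
    expand_hydrogens: Optional[bool] = None,
) -> str:
    """Serialize ``graph`` as a molfile.

    With no ``dialect``, V3000 is selected automatically when atom or
    bond counts exceed 999.  ``dialect.kekulized=True`` raises if any
    bond is still unresolved.  ``expand_hydrogens`` defaults to True
    exactly when unresolved bonds are present (see module docstring).
    """
    has_unresolved = any(b.order == UNRESOLVED for b in graph.bonds)
    if dialect is not None and dialect.kekulized and has_unresolved:
        raise KekulizeError(
            "kekulized output requested but unresolved bonds remain; "
            "run kekulize() first"
        )
    if expand_hydrogens is None:
        expand_hydrogens = has_unresolved
    g = _expanded(graph) if expand_hydrogens else graph
    na, nb = len(g.atoms), len(g.bonds)
    fmt = dialect.format if dialect is not None else None
    if fmt is None:
        fmt = "molfile_v3000" if (na > 999 or nb > 999) else "molfile_v2000"
    if fmt == "molfile_v2000" and (na > 999 or nb > 999):
        raise MolfileError(
            f"{na} atoms / {nb} bonds exceed the V2000 999 limit; "
            "use the molfile_v3000 dialect"
        )
    if fmt == "xyz":
        raise UnsupportedFormatError("use write_xyz for XYZ output")

    type_of = {1: 1, 2: 2, 3: 3, UNRESOLVED: 4}
    out: List[str] = [title, "  kekulize", ""]
    if fmt == "molfile_v2000":
        out.append(f"{na:3d}{nb:3d}  0  0  0  0  0  0  0  0999 V2000")
        for a in g.atoms:
            x, y, z = a.coords if a.coords is not None else (0.0, 0.0, 0.0)
            out.append(
                f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0"
                "  0  0  0  0  0  0  0"
            )
        for b in g.bonds:
            out.append(f"{b.u + 1:3d}{b.v + 1:3d}{type_of[b.order]:3d}  0")
    else:
        out.append("  0  0  0     0  0            999 V3000")
        out.append("M  V30 BEGIN CTAB")
        out.append(f"M  V30 COUNTS {na} {nb} 0 0 0")
        out.append("M  V30 BEGIN ATOM")
        for a in g.atoms:
            x, y, z = a.coords if a.coords is not None else (0.0, 0.0, 0.0)
            out.append(f"M  V30 {a.index + 1} {a.element} {x:.4f} {y:.4f} {z:.4f} 0")
        out.append("M  V30 END ATOM")
        out.append("M  V30 BEGIN BOND")
        for i, b in enumerate(g.bonds):
            out.append(f"M  V30 {i + 1} {type_of[b.order]} {b.u + 1} {b.v + 1}")
        out.append("M  V30 END BOND")
        out.append("M  V30 END CTAB")
    out.append("M  END")
    return "\n".join(out) + "\n"


def write_xyz(graph: MolecularGraph, comment: str = "") -> str:
    """XYZ text (count line, comment, ``element x y z`` rows).

    Export-only for structures carrying coordinates; implicit hydrogens
    have none and are omitted.  Raises if any heavy atom lacks
    coordinates.
    """
    missing = [a.index for a in graph.atoms if a.coords is None]
    if missing:
        raise KekulizeError(
            f"{len(missing)} atoms have no coordinates (first: atom "
            f"{missing[0]}); XYZ export needs a geometry"
        )
    rows = [str(len(graph.atoms)), comment]
    for a in graph.atoms:
        x, y, z = a.coords  # type: ignore[misc]
        rows.append(f"{a.element:<3s}{x:15.4f}{y:15.4f}{z:15.4f}")
    return "\n".join(rows) + "\n"


def read_xyz(source: Union[str, io.TextIOBase]) -> XYZRecord:
    """Parse XYZ text into a coordinates-only record (no bonds)."""
    lines = _text(source).split("\n")
    try:
        n = int(lines[0].strip())
    except (ValueError, IndexError) as exc:
        raise MolfileError(f"malformed XYZ count line: {lines[:1]!r}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    elements: List[str] = []
    coords: List[Tuple[float, float, float]] = []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        if len(parts) < 4:
            raise MolfileError(f"malformed XYZ row: {line!r}")
        elements.append(parts[0])
        coords.append((float(parts[1]), float(parts[2]), float(parts[3])))
    if len(elements) != n:
        raise MolfileError(f"XYZ declares {n} atoms, found {len(elements)}")
    return XYZRecord(elements, np.asarray(coords, dtype=float), comment)


def load(path: str) -> Union[MolecularGraph, XYZRecord]:
    """Read a structure file, dispatching on the extension."""
    lower = path.lower()
    if lower.endswith(".cc1"):
        raise UnsupportedFormatError(
            ".cc1 files are not supported; convert to MDL molfile "
            "(V2000/V3000) or XYZ first"
        )
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if lower.endswith(".xyz"):
        return read_xyz(text)
    if lower.endswith((".mol", ".sdf", ".mdl")):
        return read_molfile(text)
    raise UnsupportedFormatError(f"unrecognized structure file: {path!r}")
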