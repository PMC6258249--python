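"""Valence-annotated molecular graph model and the pi-assignment problem.

A molecule is a simple graph of heavy atoms (hydrogens are stored as
implicit counts).  Bonds carry either a resolved integer order (1, 2, 3)
or the sentinel :data:`UNRESOLVED`, meaning the bond belongs to a
conjugated system whose orders are yet to be determined.

The kekulization problem is stated through the *pi-deficiency* of each
atom::

    d(a) = valence(a) - implicit_h(a) - (number of incident bonds)

with resolved bonds contributing their full order and unresolved bonds
contributing 1 (their sigma component).  An atom with d = 1 demands one
extra bond-order unit (aromatic carbon), d = 2 demands two (acetylenic or
cumulenic carbon).  A Kekule structure is an assignment of pi-orders
x(e) in {0, 1, 2} to the unresolved bonds such that every atom's incident
pi-orders sum exactly to its deficiency; the final bond order is then
1 + x(e).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "UNRESOLVED",
    "DEFAULT_VALENCES",
    "KekulizeError",
    "StructureError",
    "ValenceError",
    "HybridizationError",
    "Atom",
    "Bond",
    "MolecularGraph",
    "PiSystem",
    "build_molecule",
    "pi_deficiency",
    "extract_pi_system",
    "validate_assignment",
    "apply_assignment",
]

#: Sentinel bond order for a conjugated ("aromatic") bond whose final order
#: is not yet known.  The value 4 matches the MDL molfile aromatic bond type.
UNRESOLVED = 4

#: Fixed element -> default valence mapping.  Extensible, but only C, N and
#: (implicit) H occur in the benchmark families.
DEFAULT_VALENCES = {"C": 4, "N": 3, "H": 1}


class KekulizeError(Exception):
    """Base class for errors raised by this package."""


class StructureError(KekulizeError):
    """Malformed connectivity: bad indices, duplicate bonds, loops."""


class ValenceError(KekulizeError):
    """An atom's bonds and hydrogens exceed or contradict its valence."""


class HybridizationError(ValenceError):
    """Pi-deficiency outside the supported range {0, 1, 2}."""


@dataclass(slots=True)
class Atom:
    """A heavy atom.

    Parameters
    ----------
    index : int
        0-based position in the owning graph.
    element : str
        Element symbol; must have an entry in :data:`DEFAULT_VALENCES`
        (or ``valence`` must be given explicitly).
    valence : int
        Total bonding capacity (C=4, N=3, H=1 by default).
    implicit_h : int
        Hydrogens attached to this atom but not stored as graph nodes.
    coords : tuple of float, optional
        Cartesian coordinates in Angstrom.  Generators may emit none.
    """

    index: int
    element: str = "C"
    valence: int = 4
    implicit_h: int = 0
    coords: Optional[Tuple[float, float, float]] = None


@dataclass(slots=True)
class Bond:
    """An undirected bond between two atom indices.

    ``order`` is 1, 2, 3 or :data:`UNRESOLVED`.
    """

    u: int
    v: int
    order: int = UNRESOLVED

    def other(self, a: int) -> int:
        return self.v if a == self.u else self.u


@dataclass
class MolecularGraph:
    """Atoms, bonds and an adjacency index.

    ``adjacency[a]`` is a list of ``(neighbor, bond_index)`` pairs.
    """

    atoms: List[Atom]
    bonds: List[Bond]
    adjacency: List[List[Tuple[int, int]]] = field(repr=False)

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def degree(self, a: int) -> int:
        return len(self.adjacency[a])

    def formula(self) -> Dict[str, int]:
        """Element counts including implicit hydrogens."""
        counts: Dict[str, int] = {}
        h = 0
        for atom in self.atoms:
            counts[atom.element] = counts.get(atom.element, 0) + 1
            h += atom.implicit_h
        if h:
            counts["H"] = counts.get("H", 0) + h
        return counts

    def formula_string(self) -> str:
        """Hill-style formula, e.g. ``C144H48`` or ``C18N2``."""
        counts = dict(self.formula())
        parts = []
        for el in ("C", "H"):
            n = counts.pop(el, 0)
            if n:
                parts.append(f"{el}{n}" if n > 1 else el)
        for el in sorted(counts):
            n = counts[el]
            parts.append(f"{el}{n}" if n > 1 else el)
        return "".join(parts)

    def copy(self) -> "MolecularGraph":
        atoms = [replace(a) for a in self.atoms]
        bonds = [replace(b) for b in self.bonds]
        adjacency = [list(nbrs) for nbrs in self.adjacency]
        return MolecularGraph(atoms, bonds, adjacency)


def build_molecule(atoms: Sequence[Atom], bonds: Sequence[Bond]) -> MolecularGraph:
    """Assemble a :class:`MolecularGraph`, checking structural sanity.

    Raises
    ------
    StructureError
        On inconsistent indices, self-loops or duplicate bonds.
    ValenceError
        If an atom's incident bond count plus implicit hydrogens exceeds
        its valence (each bond contributes at least order 1).
    """
    n = len(atoms)
    atoms = list(atoms)
    for pos, atom in enumerate(atoms):
        if atom.index != pos:
            raise StructureError(
                f"atom at position {pos} carries index {atom.index}"
            )
        if atom.valence < 1:
            raise ValenceError(f"atom {pos}: non-positive valence {atom.valence}")
        if atom.implicit_h < 0:
            raise ValenceError(f"atom {pos}: negative implicit H count")
    adjacency: List[List[Tuple[int, int]]] = [[] for _ in range(n)]
    seen = set()
    blist: List[Bond] = []
    for bond in bonds:
        u, v = bond.u, bond.v
        if not (0 <= u < n and 0 <= v < n):
            raise StructureError(f"bond ({u}, {v}) references a missing atom")
        if u == v:
            raise StructureError(f"self-bond on atom {u}")
        key = (u, v) if u < v else (v, u)
        if key in seen:
            raise StructureError(f"duplicate bond between atoms {u} and {v}")
        if bond.order not in (1, 2, 3, UNRESOLVED):
            raise StructureError(f"unsupported bond order {bond.order}")
        seen.add(key)
        bi = len(blist)
        blist.append(bond)
        adjacency[u].append((v, bi))
        adjacency[v].append((u, bi))
    graph = MolecularGraph(atoms, blist, adjacency)
    # minimum-order occupancy must fit into the valence
    for atom in atoms:
        occupied = atom.implicit_h
        for _, bi in adjacency[atom.index]:
            order = blist[bi].order
            occupied += 1 if order == UNRESOLVED else order
        if occupied > atom.valence:
            raise ValenceError(
                f"atom {atom.index} ({atom.element}): bonds + hydrogens "
                f"occupy {occupied} > valence {atom.valence}"
            )
    return graph


def pi_deficiency(graph: MolecularGraph) -> Dict[int, int]:
    """Per-atom pi-deficiency d(a) = valence - implicit_h - sigma occupancy.

    Resolved bonds contribute their full order; unresolved bonds count 1.
    Raises :class:`HybridizationError` if any d(a) falls outside {0, 1, 2}.
    """
    d: Dict[int, int] = {}
    for atom in graph.atoms:
        occ = atom.implicit_h
        for _, bi in graph.adjacency[atom.index]:
            order = graph.bonds[bi].order
            occ += 1 if order == UNRESOLVED else order
        da = atom.valence - occ
        if da < 0 or da > 2:
            raise HybridizationError(
                f"atom {atom.index} ({atom.element}): pi-deficiency {da} "
                "outside the supported range 0..2"
            )
        d[atom.index] = da
    return d


@dataclass
class PiSystem:
    """The unresolved sub-problem extracted from a molecule.

    ``members`` are the atoms with deficiency > 0, ``demand`` maps each
    member to its deficiency (1 or 2), and ``edges`` lists the unresolved
    bonds between members as ``(u, v, bond_index)`` triples.  Every edge
    has pi-capacity 2.
    """

    members: List[int]
    demand: Dict[int, int]
    edges: List[Tuple[int, int, int]]
    #: member atom -> list of positions into ``edges``
    incidence: Dict[int, List[int]] = field(repr=False)

    def __len__(self) -> int:
        return len(self.members)

    def total_deficiency(self) -> int:
        return sum(self.demand.values())

    def components(self) -> List[List[int]]:
        """Connected components of the member/edge subgraph."""
        seen = set()
        comps = []
        for start in self.members:
            if start in seen:
                continue
            comp = [start]
            seen.add(start)
            stack = [start]
            while stack:
                a = stack.pop()
                for ei in self.incidence[a]:
                    u, v, _ = self.edges[ei]
                    b = v if a == u else u
                    if b not in seen:
                        seen.add(b)
                        comp.append(b)
                        stack.append(b)
            comps.append(comp)
        return comps


def extract_pi_system(graph: MolecularGraph) -> PiSystem:
    """Collect the atoms and unresolved bonds that form the pi problem.

    Atoms with deficiency 0 are excluded.  An unresolved bond incident to
    a deficiency-0 atom is an inconsistency (it could never receive any
    pi-order) and raises :class:`ValenceError`.
    """
    d = pi_deficiency(graph)
    members = [a for a in d if d[a] > 0]
    member_set = set(members)
    demand = {a: d[a] for a in members}
    edges: List[Tuple[int, int, int]] = []
    incidence: Dict[int, List[int]] = {a: [] for a in members}
    for bi, bond in enumerate(graph.bonds):
        if bond.order != UNRESOLVED:
            continue
        u, v = bond.u, bond.v
        if u not in member_set or v not in member_set:
            raise ValenceError(
                f"unresolved bond ({u}, {v}) incident to a fully "
                "saturated atom"
            )
        ei = len(edges)
        edges.append((u, v, bi))
        incidence[u].append(ei)
        incidence[v].append(ei)
    return PiSystem(members, demand, edges, incidence)


def validate_assignment(
    graph: MolecularGraph, assignment: Mapping[int, int]
) -> bool:
    """True iff ``assignment`` (bond index -> pi-order in {0,1,2}) satisfies
    every member atom's deficiency exactly.

    Applying the assignment (final order = 1 + pi-order) then fills all
    valences.  Returns False, never raises, on an arithmetic violation;
    raises :class:`KekulizeError` only if the assignment misses a pi edge.
    """
    pis = extract_pi_system(graph)
    for _, _, bi in pis.edges:
        if bi not in assignment:
            raise KekulizeError(f"assignment missing pi bond {bi}")
    received = {a: 0 for a in pis.members}
    for u, v, bi in pis.edges:
        x = assignment[bi]
        if x not in (0, 1, 2):
            return False
        received[u] += x
        received[v] += x
    return all(received[a] == pis.demand[a] for a in pis.members)


def apply_assignment(
    graph: MolecularGraph, assignment: Mapping[int, int]
) -> MolecularGraph:
    """Return a copy of ``graph`` with unresolved bonds resolved to
    order ``1 + pi``.  The atom set, and hence the formula, is unchanged."""
    out = graph.copy()
    for bi, bond in enumerate(out.bonds):
        if bond.order == UNRESOLVED:
            bond.order = 1 + assignment[bi]
    return out
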