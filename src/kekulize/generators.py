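"""Parametric generators for the benchmark structure families.

Each family is built as a repeating *block* of atoms with a fixed internal
topology, assembled into a polymer by joining designated attachment ports
of consecutive blocks with unresolved ("aromatic") bonds, exactly because
the order of a bond created by joining two attachment points is not known
until kekulization.  Port valences left unused at the chain termini are
capped with implicit hydrogens.

Hydrogen counts are never set by hand: every atom receives

    implicit_h = valence - pi_demand - degree

once the full polymer connectivity is in place, so the molecular formula
is a pure function of the assembled topology.  The composition laws this
yields (per chain length n):

    ==================  ==========  =================
    family              carbons     hydrogens
    ==================  ==========  =================
    nanotube C[12,12]   144 n       48
    graphene sheet      144 n       12 n + 26
    graphyne GY1        136 n       8 n + 66
    graphyne GY7        188 n       4 n + 82
    graphyne nanotube   192 n       72
    polycyclopentadiene 150 n       50 n + 4 (linear)
                                    50 n     (cyclic, Moebius)
    ==================  ==========  =================

The figures defining the historical patterns fix these compositions, the
ring content (hexagons for nanotube/graphene, hexagons plus acetylenic
linkers for the graphynes, pentagons for polycyclopentadiene) and the
existence of Kekule structures; the explicit unit cells constructed here
are this package's own realizations of those constraints.  Kekulization
is purely topological, so no coordinates are generated except for the
fullerene polyhedra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .molgraph import (
    UNRESOLVED,
    Atom,
    Bond,
    DEFAULT_VALENCES,
    MolecularGraph,
    StructureError,
    build_molecule,
)

__all__ = [
    "GeneratorSpec",
    "FAMILIES",
    "generate",
    "generate_nanotube",
    "generate_graphene",
    "generate_gy1",
    "generate_gy7",
    "generate_graphyne_tube",
    "generate_polycyclopentadiene",
    "generate_fullerene",
    "substitute_aza",
    "porphine",
]

FAMILIES = (
    "nanotube",
    "graphene",
    "gy1",
    "gy7",
    "graphyne_tube",
    "polycyclopentadiene",
    "fullerene",
    "porphine",
)


@dataclass(slots=True)
class GeneratorSpec:
    """Declarative request for one benchmark structure.

    ``aza_count`` carbons are substituted by nitrogen after generation;
    an odd count makes kekulization impossible (the total pi-deficiency
    becomes odd) and is rejected unless ``allow_odd_aza`` is set for
    deliberately infeasible test cases.
    """

    family: str
    n: int = 1
    topology: str = "linear"
    fullerene_name: str = "C60"
    aza_count: int = 0
    seed: int = 0
    allow_odd_aza: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("chain length n must be >= 1")
        if self.topology not in ("linear", "cyclic", "moebius"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.aza_count < 0:
            raise ValueError("aza_count must be >= 0")
        if self.aza_count % 2 == 1 and not self.allow_odd_aza:
            raise ValueError(
                "aza_count must be even (bonds cannot be alternated for an "
                "odd substitution count); pass allow_odd_aza=True to build "
                "a deliberately infeasible structure"
            )


def generate(spec: GeneratorSpec) -> MolecularGraph:
    """Build the structure described by ``spec`` (deterministic)."""
    if spec.family == "nanotube":
        g = generate_nanotube(spec.n)
    elif spec.family == "graphene":
        g = generate_graphene(spec.n)
    elif spec.family == "gy1":
        g = generate_gy1(spec.n)
    elif spec.family == "gy7":
        g = generate_gy7(spec.n)
    elif spec.family == "graphyne_tube":
        g = generate_graphyne_tube(spec.n)
    elif spec.family == "polycyclopentadiene":
        g = generate_polycyclopentadiene(spec.n, spec.topology)
    elif spec.family == "fullerene":
        g = generate_fullerene(spec.fullerene_name)
    else:
        g = porphine()
    if spec.aza_count:
        g = substitute_aza(g, spec.aza_count, spec.seed)
    return g


# ---------------------------------------------------------------------------
# assembly helper


class _Builder:
    """Accumulates atoms (with target pi-demand) and skeleton bonds.

    ``finalize`` fills implicit hydrogens from the valence bookkeeping and
    marks every bond between two demanding atoms as unresolved; bonds
    touching a saturated (demand-0) atom are plain single bonds.
    """

    def __init__(self) -> None:
        self.elements: List[str] = []
        self.demands: List[int] = []
        self.coords: List[Optional[Tuple[float, float, float]]] = []
        self.bonds: List[Tuple[int, int]] = []
        self.degree: List[int] = []

    def add_atom(
        self,
        element: str = "C",
        demand: int = 1,
        coords: Optional[Tuple[float, float, float]] = None,
    ) -> int:
        self.elements.append(element)
        self.demands.append(demand)
        self.coords.append(coords)
        self.degree.append(0)
        return len(self.elements) - 1

    def add_bond(self, u: int, v: int) -> None:
        self.bonds.append((u, v))
        self.degree[u] += 1
        self.degree[v] += 1

    def free_valences(self, a: int) -> int:
        val = DEFAULT_VALENCES[self.elements[a]]
        return val - self.demands[a] - self.degree[a]

    def finalize(self) -> MolecularGraph:
        atoms = []
        for i, el in enumerate(self.elements):
            val = DEFAULT_VALENCES[el]
            h = val - self.demands[i] - self.degree[i]
            if h < 0:
                raise StructureError(
                    f"builder atom {i}: degree {self.degree[i]} plus demand "
                    f"{self.demands[i]} exceeds valence {val}"
                )
            atoms.append(
                Atom(i, element=el, valence=val, implicit_h=h, coords=self.coords[i])
            )
        bonds = []
        for u, v in self.bonds:
            order = (
                UNRESOLVED
                if self.demands[u] > 0 and self.demands[v] > 0
                else 1
            )
            bonds.append(Bond(u, v, order))
        return build_molecule(atoms, bonds)


def _check_n(n: int) -> None:
    if n < 1:
        raise ValueError("chain length n must be >= 1")


# ---------------------------------------------------------------------------
# honeycomb families


def generate_nanotube(n: int) -> MolecularGraph:
    """Armchair C[12,12] nanotube of ``n`` repeat units (144 C each).

    A honeycomb cylinder, 24 atoms around the circumference and 6 atom
    rows per unit; consecutive units are joined by the 24 axial bonds of
    the lattice (the attachment points), and the 24 rim valences at each
    end are hydrogen capped.  Formula C(144n)H48.
    """
    _check_n(n)
    b = _Builder()
    rows = 6 * n
    cols = 24
    idx = {}
    for i in range(rows):
        for j in range(cols):
            idx[i, j] = b.add_atom()
    for i in range(rows):
        for j in range(cols):
            if i < rows - 1:
                b.add_bond(idx[i, j], idx[i + 1, j])
            if (i + j) % 2 == 0:
                b.add_bond(idx[i, j], idx[i, (j + 1) % cols])
    return b.finalize()


def _graphene_block(b: _Builder) -> Tuple[List[int], List[int]]:
    """One 144-carbon graphene block; returns (right ports, left ports).

    A brick-wall honeycomb patch of 8 rows x 18 columns with two rim
    atoms removed and two pendant methylene-type carbons added (the
    acyclic carbons of the pattern); 13 attachment valences on each side.
    """
    rows, cols = 8, 18
    removed = {(0, 0), (7, 0)}
    idx: Dict[Tuple[int, int], int] = {}
    for i in range(rows):
        for j in range(cols):
            if (i, j) not in removed:
                idx[i, j] = b.add_atom()
    for i in range(rows):
        for j in range(cols):
            if (i, j) not in idx:
                continue
            if j + 1 < cols and (i, j + 1) in idx:
                b.add_bond(idx[i, j], idx[i, j + 1])
            if i + 1 < rows and (i + j) % 2 == 0 and (i + 1, j) in idx:
                b.add_bond(idx[i, j], idx[i + 1, j])
    # pendant acyclic carbons (methylene groups at the chain termini)
    for host in ((0, 1), (7, 1)):
        p = b.add_atom()
        b.add_bond(idx[host], p)
    # attachment valences, pendants excluded
    block_atoms = sorted(idx.values())
    slots: List[int] = []
    for a in block_atoms:
        slots.extend([a] * b.free_valences(a))
    left = slots[:13]
    right = slots[-13:]
    return right, left


def generate_graphene(n: int) -> MolecularGraph:
    """Graphene sheet of ``n`` 144-carbon blocks; formula C(144n)H(12n+26).

    Blocks are joined by 13 unresolved bonds between the attachment
    valences of consecutive blocks; terminal attachment valences and the
    two pendant acyclic carbons per block are hydrogen capped (each
    pendant becomes a =CH2 methylene group).
    """
    _check_n(n)
    b = _Builder()
    prev_right: Optional[List[int]] = None
    for _ in range(n):
        right, left = _graphene_block(b)
        if prev_right is not None:
            for u, v in zip(prev_right, left):
                b.add_bond(u, v)
        prev_right = right
    return b.finalize()


# ---------------------------------------------------------------------------
# graphyne families (hexagons + acetylenic -C#C- linkers)


class _RingKit:
    """Hexagon rings plus acetylene bridges with slot bookkeeping."""

    def __init__(self, b: _Builder):
        self.b = b
        self.rings: List[List[int]] = []
        self.next_slot: List[int] = []

    def ring(self) -> int:
        ids = [self.b.add_atom() for _ in range(6)]
        for k in range(6):
            self.b.add_bond(ids[k], ids[(k + 1) % 6])
        self.rings.append(ids)
        self.next_slot.append(0)
        return len(self.rings) - 1

    def _take(self, r: int) -> int:
        ids = self.rings[r]
        k = self.next_slot[r]
        if k >= 6:
            raise StructureError(f"ring {r}: more than 6 external connections")
        self.next_slot[r] = k + 1
        return ids[k]

    def direct(self, r1: int, r2: int) -> None:
        self.b.add_bond(self._take(r1), self._take(r2))

    def bridge(self, r1: int, r2: Optional[int]) -> int:
        """-C#C- linker from ring r1 to ring r2 (or dangling if None).

        Returns the terminal sp carbon (useful as a port).  sp carbons
        carry pi-demand 2 (triple-bond / cumulene capable).
        """
        sp1 = self.b.add_atom(demand=2)
        sp2 = self.b.add_atom(demand=2)
        self.b.add_bond(self._take(r1), sp1)
        self.b.add_bond(sp1, sp2)
        if r2 is not None:
            self.b.add_bond(sp2, self._take(r2))
        return sp2

    def free_ring_slots(self) -> List[int]:
        """Ring atoms still carrying a free valence, in atom-id order."""
        out = []
        for ids in self.rings:
            for a in ids:
                if self.b.free_valences(a) > 0:
                    out.append(a)
        return sorted(out)


def _assemble_graphyne(
    n: int,
    block_fn,
    n_ports: int,
) -> MolecularGraph:
    """Generic graphyne polymer: n blocks, ``n_ports`` junction bonds."""
    b = _Builder()
    prev_right: Optional[List[int]] = None
    for _ in range(n):
        slots = block_fn(b)
        left = slots[:n_ports]
        right = slots[-n_ports:]
        if prev_right is not None:
            for u, v in zip(prev_right, left):
                b.add_bond(u, v)
        prev_right = right
    return b.finalize()


def _gy1_block(b: _Builder) -> List[int]:
    """136 C: 20 hexagons, 8 acetylene linkers, 15 direct ring-ring bonds."""
    kit = _RingKit(b)
    r = [kit.ring() for _ in range(20)]
    for i in range(15):
        kit.direct(r[i], r[i + 1])
    for a, c in [(15, 16), (16, 17), (17, 18), (18, 19), (19, 0), (2, 7), (4, 12), (9, 17)]:
        kit.bridge(r[a], r[c])
    return kit.free_ring_slots()


def generate_gy1(n: int) -> MolecularGraph:
    """Graphyne GY1, 136 C per monomer unit; formula C(136n)H(8n+66).

    Hexagonal rings joined by single acetylenic linkers; consecutive
    units are joined by 33 unresolved attachment bonds.
    """
    _check_n(n)
    return _assemble_graphyne(n, _gy1_block, 33)


def _gy7_block(b: _Builder) -> List[int]:
    """188 C: 22 hexagons, 28 acetylene linkers (5 hydrogen-terminated)."""
    kit = _RingKit(b)
    r = [kit.ring() for _ in range(22)]
    for i in range(21):
        kit.bridge(r[i], r[i + 1])
    kit.bridge(r[21], r[0])
    kit.bridge(r[5], r[16])
    dangling = [kit.bridge(r[i], None) for i in range(5)]
    slots = kit.free_ring_slots()
    # terminal sp carbons take part in the attachment surface
    return slots[:41] + dangling[:1] + slots[41:] + dangling[1:]


def generate_gy7(n: int) -> MolecularGraph:
    """Graphyne GY7, 188 C per monomer unit; formula C(188n)H(4n+82).

    Denser acetylenic linking than GY1; 41 unresolved attachment bonds
    join consecutive units, one of them through a terminal sp carbon.
    """
    _check_n(n)
    return _assemble_graphyne(n, _gy7_block, 41)


def _graphyne_tube_block(b: _Builder) -> List[int]:
    """192 C: 22 hexagons, 30 acetylene linkers, all ring-attached."""
    kit = _RingKit(b)
    r = [kit.ring() for _ in range(22)]
    for i in range(21):
        kit.bridge(r[i], r[i + 1])
    extra = [
        (21, 0), (0, 11), (2, 13), (4, 15), (6, 17),
        (8, 19), (10, 21), (1, 12), (3, 14),
    ]
    for a, c in extra:
        kit.bridge(r[a], r[c])
    return kit.free_ring_slots()


def generate_graphyne_tube(n: int) -> MolecularGraph:
    """Graphyne nanotube, 192 C per unit; formula C(192n)H72.

    The GY7 sheet closed onto itself: every hydrogen position of the
    interior becomes a carbon-carbon attachment, so the hydrogen count
    (the two open ends) is independent of the chain length.  36 unresolved
    bonds join consecutive units.
    """
    _check_n(n)
    return _assemble_graphyne(n, _graphyne_tube_block, 36)


# ---------------------------------------------------------------------------
# polycyclopentadienes (odd-sized rings)


def generate_polycyclopentadiene(n: int, topology: str = "linear") -> MolecularGraph:
    """Polycyclopentadiene of ``n`` 150-carbon units.

    Each unit is a chain of 30 five-membered rings (cross-linked into a
    polycyclic band) and contributes 150 carbons; consecutive units are
    joined by two unresolved bonds.  ``linear`` caps the four terminal
    attachment valences with hydrogens (methylene-type end groups, +4 H);
    ``cyclic`` joins the last unit back to the first straight;
    ``moebius`` joins them crisscross, giving the same formula and degree
    sequence but a different edge set.

    Formulas: C(150n)H(50n+4) linear, C(150n)H(50n) cyclic and Moebius.
    """
    _check_n(n)
    if topology not in ("linear", "cyclic", "moebius"):
        raise ValueError(f"unknown topology {topology!r}")
    b = _Builder()
    first_left: Optional[List[int]] = None
    prev_right: Optional[List[int]] = None
    for _ in range(n):
        rings: List[List[int]] = []
        for _r in range(30):
            ids = [b.add_atom() for _ in range(5)]
            for k in range(5):
                b.add_bond(ids[k], ids[(k + 1) % 5])
            rings.append(ids)
        for i in range(29):
            b.add_bond(rings[i][0], rings[i + 1][2])
        for i in range(19):
            b.add_bond(rings[i][4], rings[i + 10][1])
        left = [rings[0][1], rings[0][2]]
        right = [rings[29][0], rings[29][4]]
        if prev_right is not None:
            b.add_bond(prev_right[0], left[0])
            b.add_bond(prev_right[1], left[1])
        else:
            first_left = left
        prev_right = right
    assert prev_right is not None and first_left is not None
    if topology == "cyclic":
        b.add_bond(prev_right[0], first_left[0])
        b.add_bond(prev_right[1], first_left[1])
    elif topology == "moebius":
        b.add_bond(prev_right[0], first_left[1])
        b.add_bond(prev_right[1], first_left[0])
    return b.finalize()


# ---------------------------------------------------------------------------
# fullerenes and porphine


_PHI = (1.0 + math.sqrt(5.0)) / 2.0


def _dodecahedron_vertices() -> List[Tuple[float, float, float]]:
    pts = []
    for sx in (1, -1):
        for sy in (1, -1):
            for sz in (1, -1):
                pts.append((sx * 1.0, sy * 1.0, sz * 1.0))
    for s1 in (1, -1):
        for s2 in (1, -1):
            pts.append((0.0, s1 / _PHI, s2 * _PHI))
            pts.append((s1 / _PHI, s2 * _PHI, 0.0))
            pts.append((s1 * _PHI, 0.0, s2 / _PHI))
    return pts


def _icosahedron_vertices() -> List[Tuple[float, float, float]]:
    pts = []
    for s1 in (1, -1):
        for s2 in (1, -1):
            pts.append((0.0, s1 * 1.0, s2 * _PHI))
            pts.append((s1 * 1.0, s2 * _PHI, 0.0))
            pts.append((s2 * _PHI, 0.0, s1 * 1.0))
    return pts


def _edges_at_min_distance(pts: Sequence[Tuple[float, float, float]]) -> List[Tuple[int, int]]:
    arr = np.asarray(pts)
    d2 = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    cutoff = d2.min() * 1.01
    edges = [
        (i, j)
        for i in range(len(pts))
        for j in range(i + 1, len(pts))
        if d2[i, j] <= cutoff
    ]
    return edges

def generate_fullerene(name: str) -> MolecularGraph:
    """C20 (dodecahedron) or C60 (truncated icosahedron).

    Every atom has pi-deficiency 1 and no hydrogens.  Idealized cartesian
    coordinates (bond length scaled to 1.42 A) are attached for export.
    Other cages (C70, C80, C82) have unspecified isomers and must be
    loaded from a molfile instead.
    """
    if name == "C20":
        pts = _dodecahedron_vertices()
        edges = _edges_at_min_distance(pts)
    elif name == "C60":
        ico = _icosahedron_vertices()
        ico_edges = _edges_at_min_distance(ico)
        nbrs: Dict[int, List[int]] = {i: [] for i in range(12)}
        for i, j in ico_edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        arr = np.asarray(ico)

        def cyclic(v: int) -> List[int]:
            # order neighbors by angle in the plane normal to v
            axis = arr[v] / np.linalg.norm(arr[v])
            ref = arr[nbrs[v][0]] - arr[v]
            ref = ref - axis * (ref @ axis)
            ref = ref / np.linalg.norm(ref)
            perp = np.cross(axis, ref)
            ang = []
            for u in nbrs[v]:
                w = arr[u] - arr[v]
                w = w - axis * (w @ axis)
                ang.append(math.atan2(w @ perp, w @ ref))
            return [u for _, u in sorted(zip(ang, nbrs[v]))]

        index: Dict[Tuple[int, int], int] = {}
        pts = []
        for v in range(12):
            for u in nbrs[v]:
                index[v, u] = len(pts)
                p = arr[v] + (arr[u] - arr[v]) / 3.0
                pts.append(tuple(p))
        edges = []
        for v in range(12):
            ring = cyclic(v)
            for k in range(5):
                edges.append((index[v, ring[k]], index[v, ring[(k + 1) % 5]]))
        for v, u in ico_edges:
            edges.append((index[v, u], index[u, v]))
    else:
        raise ValueError(
            f"unsupported fullerene {name!r}: only C20 and C60 are "
            "generated; load other cages from a molfile"
        )
    # scale coordinates so the shortest bond is 1.42 A
    arr = np.asarray(pts)
    dmin = min(np.linalg.norm(arr[i] - arr[j]) for i, j in edges)
    arr = arr * (1.42 / dmin)
    b = _Builder()
    for p in arr:
        b.add_atom(coords=tuple(round(float(c), 4) for c in p))
    for u, v in edges:
        b.add_bond(u, v)
    return b.finalize()


def substitute_aza(graph: MolecularGraph, k: int, seed: int = 0) -> MolecularGraph:
    """Replace ``k`` random carbons by trivalent nitrogen (aza analog).

    Nitrogen has valence 3 and three single converging bonds, so each
    substitution lowers the local pi-deficiency by one; eligible sites
    are therefore the carbons with deficiency >= 1 (hydrogen counts are
    unchanged).  Deterministic for a given seed.  An odd ``k`` makes the
    total deficiency odd, hence unkekulizable; a warning is emitted.
    """
    from .molgraph import pi_deficiency  # local import to avoid cycle at top

    if k == 0:
        return graph.copy()
    d = pi_deficiency(graph)
    eligible = [
        a.index
        for a in graph.atoms
        if a.element == "C" and d[a.index] >= 1
    ]
    if k > len(eligible):
        raise ValueError(
            f"cannot substitute {k} carbons: only {len(eligible)} eligible"
        )
    if k % 2 == 1:
        warnings.warn(
            "odd aza substitution count: bonds cannot be alternated and "
            "the number of unmatched atoms will be odd",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=k, replace=False)
    out = graph.copy()
    for c in sorted(int(i) for i in chosen):
        atom = out.atoms[eligible[c]]
        atom.element = "N"
        atom.valence = 3
        # a nitrogen whose deficiency dropped to zero keeps only single
        # converging bonds: release its unresolved bonds from the pi system
        occ = atom.implicit_h
        for _, bi in out.adjacency[atom.index]:
            order = out.bonds[bi].order
            occ += 1 if order == UNRESOLVED else order
        if atom.valence - occ == 0:
            for _, bi in out.adjacency[atom.index]:
                if out.bonds[bi].order == UNRESOLVED:
                    out.bonds[bi].order = 1
    return out


def porphine() -> MolecularGraph:
    """The porphine macrocycle, C20H14N4.

    Four five-membered nitrogen rings bridged by methine carbons; two
    nitrogens are pyrrole-type (N-H, deficiency 0, single converging
    bonds) and two are pyridine-type (deficiency 1).
    """
    b = _Builder()
    alpha1, alpha2, nitro = [], [], []
    for ring in range(4):
        pyrrole = ring % 2 == 0
        nn = b.add_atom("N", demand=0 if pyrrole else 1)
        a1 = b.add_atom()
        b1 = b.add_atom()
        b2 = b.add_atom()
        a2 = b.add_atom()
        b.add_bond(nn, a1)
        b.add_bond(a1, b1)
        b.add_bond(b1, b2)
        b.add_bond(b2, a2)
        b.add_bond(a2, nn)
        alpha1.append(a1)
        alpha2.append(a2)
        nitro.append(nn)
    for ring in range(4):
        meso = b.add_atom()
        b.add_bond(alpha2[ring], meso)
        b.add_bond(meso, alpha1[(ring + 1) % 4])
    return b.finalize()
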