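"""Benchmark family generators: composition laws, topology, determinism."""

import networkx as nx
import numpy as np
import pytest

from kekulize import (
    GeneratorSpec,
    KekulizeConfig,
    backtrack_exact,
    extract_pi_system,
    generate,
    generate_fullerene,
    generate_graphene,
    generate_graphyne_tube,
    generate_gy1,
    generate_gy7,
    generate_nanotube,
    generate_polycyclopentadiene,
    kekulize,
    pi_deficiency,
    porphine,
    substitute_aza,
    validate_assignment,
)

SIZES = [1, 2, 3, 10, 100]

#: family -> (builder, C per unit, H slope, H intercept)
LAWS = {
    "nanotube": (generate_nanotube, 144, 0, 48),
    "graphene": (generate_graphene, 144, 12, 26),
    "gy1": (generate_gy1, 136, 8, 66),
    "gy7": (generate_gy7, 188, 4, 82),
    "graphyne_tube": (generate_graphyne_tube, 192, 0, 72),
    "pcp_linear": (
        lambda n: generate_polycyclopentadiene(n, "linear"), 150, 50, 4),
    "pcp_cyclic": (
        lambda n: generate_polycyclopentadiene(n, "cyclic"), 150, 50, 0),
    "pcp_moebius": (
        lambda n: generate_polycyclopentadiene(n, "moebius"), 150, 50, 0),
}


class TestCompositionLaws:
    @pytest.mark.parametrize("family", sorted(LAWS))
    @pytest.mark.parametrize("n", SIZES)
    def test_formula_law(self, family, n):
        fn, c_unit, h_slope, h_icept = LAWS[family]
        counts = fn(n).formula()
        assert counts["C"] == c_unit * n
        assert counts.get("H", 0) == h_slope * n + h_icept
        assert "N" not in counts

    def test_chain_length_must_be_positive(self):
        for fn, _, _, _ in LAWS.values():
            with pytest.raises(ValueError):
                fn(0)


class TestRingContent:
    @staticmethod
    def _nx(graph):
        G = nx.Graph()
        G.add_nodes_from(a.index for a in graph.atoms)
        G.add_edges_from((b.u, b.v) for b in graph.bonds)
        return G

    def test_nanotube_is_cubic_with_hexagons(self):
        g = generate_nanotube(1)
        G = self._nx(g)
        assert sorted(d for _, d in G.degree()).count(3) == 96  # interior
        assert min(len(c) for c in nx.minimum_cycle_basis(G)) == 6

    def test_graphene_contains_hexagons(self):
        G = self._nx(generate_graphene(1))
        assert 6 in {len(c) for c in nx.minimum_cycle_basis(G)}

    def test_polycyclopentadiene_contains_pentagons(self):
        G = self._nx(generate_polycyclopentadiene(1, "linear"))
        sizes = [len(c) for c in nx.minimum_cycle_basis(G)]
        assert sizes.count(5) >= 30

    def test_graphynes_have_sp_carbons(self):
        for fn, n_sp in ((generate_gy1, 16), (generate_gy7, 56),
                         (generate_graphyne_tube, 60)):
            d = pi_deficiency(fn(1))
            assert sum(1 for v in d.values() if v == 2) == n_sp

    def test_generated_graphs_are_connected(self):
        for family, (fn, *_rest) in sorted(LAWS.items()):
            G = self._nx(fn(2))
            assert nx.is_connected(G), family


class TestFullerenes:
    def test_c20_dodecahedron(self):
        g = generate_fullerene("C20")
        assert len(g.atoms) == 20 and len(g.bonds) == 30
        assert all(g.degree(a.index) == 3 for a in g.atoms)
        assert g.formula_string() == "C20"
        G = nx.Graph((b.u, b.v) for b in g.bonds)
        assert all(len(c) == 5 for c in nx.minimum_cycle_basis(G))

    def test_c60_truncated_icosahedron(self):
        g = generate_fullerene("C60")
        assert len(g.atoms) == 60 and len(g.bonds) == 90
        assert all(g.degree(a.index) == 3 for a in g.atoms)
        G = nx.Graph((b.u, b.v) for b in g.bonds)
        assert nx.is_connected(G)
        # 12 pentagonal and 20 hexagonal faces; girth 5
        basis = nx.minimum_cycle_basis(G)
        sizes = sorted(len(c) for c in basis)
        assert sizes.count(5) == 12
        assert all(s in (5, 6) for s in sizes)

    def test_unsupported_cage_rejected(self):
        with pytest.raises(ValueError, match="molfile"):
            generate_fullerene("C70")

    def test_all_atoms_deficiency_one(self):
        for name in ("C20", "C60"):
            d = pi_deficiency(generate_fullerene(name))
            assert set(d.values()) == {1}


class TestAza:
    def test_zero_substitution_is_identity(self):
        g = generate_fullerene("C20")
        g0 = substitute_aza(g, 0, seed=5)
        assert g0.formula() == g.formula()
        assert [(b.u, b.v, b.order) for b in g0.bonds] == [
            (b.u, b.v, b.order) for b in g.bonds
        ]

    @pytest.mark.parametrize(
        "name,k,expected",
        [("C20", 2, "C18N2"), ("C20", 8, "C12N8"), ("C60", 8, "C52N8")],
    )
    def test_formulas(self, name, k, expected):
        g = substitute_aza(generate_fullerene(name), k, seed=7)
        assert g.formula_string() == expected

    def test_deterministic_per_seed(self):
        g = generate_fullerene("C60")
        a = substitute_aza(g, 4, seed=3)
        b = substitute_aza(g, 4, seed=3)
        c = substitute_aza(g, 4, seed=4)
        n_at = lambda m: {x.index for x in m.atoms if x.element == "N"}
        assert n_at(a) == n_at(b)
        assert n_at(a) != n_at(c)

    def test_nitrogen_gets_single_converging_bonds(self):
        g = substitute_aza(generate_fullerene("C20"), 2, seed=1)
        d = pi_deficiency(g)
        for atom in g.atoms:
            if atom.element == "N":
                assert d[atom.index] == 0
                orders = [g.bonds[bi].order for _, bi in g.adjacency[atom.index]]
                assert orders == [1, 1, 1]

    def test_too_many_rejected(self):
        with pytest.raises(ValueError):
            substitute_aza(generate_fullerene("C20"), 21, seed=0)

    def test_odd_count_warns(self):
        with pytest.warns(UserWarning, match="odd"):
            substitute_aza(generate_fullerene("C20"), 1, seed=0)

    def test_spec_rejects_odd_without_override(self):
        with pytest.raises(ValueError):
            GeneratorSpec("fullerene", fullerene_name="C20", aza_count=3)
        spec = GeneratorSpec(
            "fullerene", fullerene_name="C20", aza_count=3, allow_odd_aza=True
        )
        with pytest.warns(UserWarning):
            g = generate(spec)
        assert g.formula_string() == "C17N3"


class TestPorphine:
    def test_formula_and_heavy_atoms(self):
        g = porphine()
        assert g.formula_string() == "C20H14N4"
        assert len(g.atoms) == 24  # 20 C + 4 N, hydrogens implicit

    def test_two_pyrrole_and_two_pyridine_nitrogens(self):
        g = porphine()
        d = pi_deficiency(g)
        nh = [a for a in g.atoms if a.element == "N" and a.implicit_h == 1]
        bare = [a for a in g.atoms if a.element == "N" and a.implicit_h == 0]
        assert len(nh) == 2 and len(bare) == 2
        assert all(d[a.index] == 0 for a in nh)
        assert all(d[a.index] == 1 for a in bare)

    def test_kekulizable(self):
        g = porphine()
        result = kekulize(g, KekulizeConfig(seed=1))
        assert result.success
        assert validate_assignment(g, result.assignment)


class TestTopologies:
    def test_cyclic_and_moebius_same_formula_and_degrees(self):
        cyc = generate_polycyclopentadiene(2, "cyclic")
        moe = generate_polycyclopentadiene(2, "moebius")
        assert cyc.formula() == moe.formula()
        deg = lambda g: sorted(g.degree(a.index) for a in g.atoms)
        assert deg(cyc) == deg(moe)
        edges = lambda g: {frozenset((b.u, b.v)) for b in g.bonds}
        assert edges(cyc) != edges(moe)

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError):
            generate_polycyclopentadiene(1, "trefoil")


class TestDeterminismAndKekulizability:
    def test_generators_are_deterministic(self):
        for family, (fn, *_rest) in sorted(LAWS.items()):
            a, b = fn(2), fn(2)
            assert [(x.element, x.implicit_h) for x in a.atoms] == [
                (x.element, x.implicit_h) for x in b.atoms
            ], family
            assert [(x.u, x.v, x.order) for x in a.bonds] == [
                (x.u, x.v, x.order) for x in b.bonds
            ], family

    @pytest.mark.parametrize("family", sorted(LAWS))
    def test_small_structures_kekulizable_by_backtrack(self, family):
        """Spot-check: the exact search finds a Kekule structure for
        every generated family at small chain length."""
        fn = LAWS[family][0]
        for n in (1, 3):
            g = fn(n)
            pis = extract_pi_system(g)
            assert pis.total_deficiency() % 2 == 0
            exists, assignment = backtrack_exact(pis)
            assert exists, (family, n)
            assert validate_assignment(g, assignment)
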