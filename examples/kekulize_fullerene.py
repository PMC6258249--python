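"""Kekulize a fullerene and inspect the result.

Builds the C60 truncated icosahedron (60 carbons, each demanding one
extra bond-order unit), runs the randomized kekulizer and verifies the
assignment.  The 30 pi-order-1 edges it prints are the 30 double bonds
of a Kekule structure of C60; `iterations` is the number of random
shuffles the search consumed.
"""

from kekulize import (
    KekulizeConfig,
    generate_fullerene,
    kekulize,
    validate_assignment,
)

graph = generate_fullerene("C60")
print(f"structure: {graph.formula_string()}, "
      f"{len(graph.atoms)} atoms, {len(graph.bonds)} bonds")

result = kekulize(graph, KekulizeConfig(seed=1))
double_bonds = sum(1 for v in result.assignment.values() if v == 1)
print(f"success={result.success} after {result.iterations} shuffle(s); "
      f"{result.unmatched_first_pass} atoms unmatched on the first pass")
print(f"double bonds in the Kekule structure: {double_bonds}")
print(f"assignment validates: {validate_assignment(graph, result.assignment)}")
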