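# kekulize

Fast approximate kekulization of large conjugated polycyclic structures
— nanotubes, graphenes, graphynes, fullerenes and their aza-analogs —
with triple-bond and cumulene handling, plus parametric generators for
the benchmark structure families these methods are profiled on.

## The problem

Chemical file formats and structure generators often record conjugated
bonds only as "aromatic": the connectivity is known but the alternating
single/double (or triple/cumulated-double) pattern is not.  Assigning
explicit bond orders so that every atom's orders sum exactly to its
valence — finding a *Kekulé structure* — is required before force
fields, molfile consumers or depiction tools can use the structure.  For
nanomaterials the inputs reach 10⁶–10⁷ atoms, far beyond what exact
matching algorithms are usually run on.

Formally, each atom demands

```
d(a) = valence(a) − implicit_H(a) − (number of incident bonds)
```

extra bond-order units (π-deficiency): `d = 1` for an aromatic carbon,
`d = 2` for an acetylenic/cumulenic carbon, and trivalent nitrogen with
three single converging bonds demands none.  A Kekulé structure is an
assignment of π-orders `x(e) ∈ {0, 1, 2}` to the unresolved bonds with
`Σ_{e∋a} x(e) = d(a)` for every atom — a degree-constrained subgraph
(perfect *b*-matching) problem.

## The algorithm

A greedy **alternation pass** visits atoms in random order, spending
each atom's remaining demand on a bond whose partner also has remaining
demand (two demand-2 atoms preferentially share a π-order-2 edge — a
triple bond), with forced-move propagation in between.  Atoms left
unsatisfied are *unmatched*.  The pass is repeated under fresh random
shuffles until no atom is unmatched; after 300 fruitless shuffles the
structure is presumed to have no Kekulé structure, unless the **exact
backtrack fallback** (depth-first search with forward pruning) is
enabled to decide the question rigorously.  An optional
**alternating-path augmentation** flag repairs the handful of unmatched
atoms a single pass leaves on very large lattices instead of restarting.

Random restarts also expose the statistics the benchmark tables report:
the distribution of unmatched atoms after the first pass, the average
and maximum number of shuffles, and the number of trials in which no
Kekulé structure was found.

## Worked example

```python
from kekulize import KekulizeConfig, generate_fullerene, kekulize, validate_assignment

graph = generate_fullerene("C60")
result = kekulize(graph, KekulizeConfig(seed=1))
print(result.success, result.iterations, result.unmatched_first_pass)
print(sum(1 for v in result.assignment.values() if v == 1))
print(validate_assignment(graph, result.assignment))
```

prints

```
True 2 2
30
True
```

— the first shuffle left 2 unmatched atoms, the second found a Kekulé
structure; its 30 π-order-1 edges are the 30 double bonds of C60, and
the assignment satisfies all 60 valences exactly
(`examples/kekulize_fullerene.py`).

Generators cover every benchmark family, with compositions that are
exact linear laws in the chain length `n`:

| family                         | formula                          |
|--------------------------------|----------------------------------|
| `generate_nanotube(n)`         | C(144n) H48                      |
| `generate_graphene(n)`         | C(144n) H(12n+26)                |
| `generate_gy1(n)`              | C(136n) H(8n+66)                 |
| `generate_gy7(n)`              | C(188n) H(4n+82)                 |
| `generate_graphyne_tube(n)`    | C(192n) H72                      |
| `generate_polycyclopentadiene` | C(150n) H(50n+4) linear, H(50n) cyclic/Möbius |
| `generate_fullerene("C20"/"C60")`, `porphine()`, `substitute_aza(g, k, seed)` | C20, C60, C20H14N4, aza-analogs |

The command line mirrors the library:

```sh
kekulize run --generate fullerene --fullerene C60 --aza 4 --trials 1000 --seed 0
kekulize gen --family nanotube --n 10 --out tube.mol
```

`examples/` contains one short narrative script per capability
(generation, kekulization, trial statistics, molfile/XYZ round-trips).

## Scope

Charges, radicals, isotopes and elements beyond C/N/H are outside the
data model; `.cc1` files are not read; C70/C80/C82 cages have
unspecified isomers and are loaded from molfiles rather than generated.
See `docs/methods.md` for the model, the design decisions and the
limitations.
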