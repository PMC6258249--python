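# Methods

## Model

A molecule is a simple graph of heavy atoms (C, N; hydrogens are
implicit counts) with bonds that are either resolved (order 1, 2, 3) or
*unresolved* — conjugated bonds whose order is unknown.  Each atom's
π-deficiency

```
d(a) = valence(a) − implicit_H(a) − #incident bonds
```

(resolved bonds counted at full order, unresolved at 1) states how many
extra bond-order units it must receive: 1 for aromatic carbon or
pyridine-type nitrogen, 2 for acetylenic/cumulenic carbon, 0 for sp³
carbon or pyrrole-type N–H nitrogen.  Deficiencies outside {0, 1, 2}
are rejected rather than guessed: a terminal alkyne written with all
bonds unresolved would demand 3, which the model deliberately does not
cover.  Charges, radicals and isotopes are out of the data model — none
occur in the benchmark families.

Kekulization is feasibility of the *b*-matching `x(e) ∈ {0,1,2}` on the
unresolved edges with `Σ_{e∋a} x(e) = d(a)`.  A connected π-component
with odd total deficiency is infeasible outright (every edge changes
the satisfied total by an even amount); this parity test short-circuits
the search.  Final orders are `1 + x(e)`, so atom counts — and hence
molecular formulas — are conserved by construction.

## The randomized search

One **alternation pass** is a greedy maximal assignment guided by two
seeded permutations (atom order and edge priority, Fisher–Yates via
NumPy's PCG64), interleaved with forced-move propagation: whenever an
atom's remaining demand equals the total remaining capacity of its
undecided edges, those edges are assigned immediately, and a saturated
atom releases its undecided edges to order 1.  Propagation makes the
pass equivalent to a Karp–Sipser-style greedy and is what keeps the
unmatched count low (tens of atoms on 10⁵-atom lattices, ~1 % of
atoms).  The pass touches each edge a bounded number of times, so its
cost is linear in the structure size; `count_pass_operations` exposes
an instruction-count proxy used by the scaling tests.

The driver repeats the pass under fresh shuffles until no atom is
unmatched, up to `max_iterations` (default 300, the benchmark cutoff).
Two escalations exist:

- **Augmentation (`augment=True`, off by default).**  Leftover
  unmatched atoms are repaired by alternating-path augmentation
  (breadth-first search over (atom, parity) states that alternately
  increases and decreases π-orders; the net per-edge delta is clamped
  to the 0–2 capacity, and a full demand check guards the result).  The
  BFS does not handle blossom-type configurations, so a repair may
  fail; the restart loop covers those cases.  Restart-only is the
  default because the iteration statistics of the benchmark protocol
  measure plain restarts; augmentation is the practical choice for
  lattices beyond ~10⁴ atoms, where the probability that a single pass
  leaves zero unmatched atoms is effectively nil.
- **Exact backtrack (`exact_fallback=True`, on by default).**  After
  exhaustion, depth-first search decides feasibility exactly: branch on
  an undecided edge of the most constrained atom (minimum slack),
  larger π-orders first, with unit-propagation of forced assignments
  and pruning when any atom's remaining demand exceeds the capacity of
  its undecided edges.  Worst-case exponential; on the generated
  families it terminates quickly because valid assignments are dense.

Determinism: identical (graph, config) gives identical results.  On a
parity violation the result reports `iterations = 0` (no shuffles are
consumed deciding it) but one diagnostic pass is still run so that the
unmatched-atom statistic is populated; trial aggregation counts such
trials as one nominal iteration.

"Removing" unmatched atoms always means restarting or repairing — atoms
are never deleted, so formulas are conserved across Tables-style runs.

## Generators: what they emulate

Each family is a repeating block joined to the next by unresolved
attachment bonds, with hydrogens computed as
`implicit_H = valence − demand − degree` after assembly — the formula
laws are consequences of the block topology, not hand-set counts.  The
historical patterns are defined pictorially; this package constructs
explicit unit cells that satisfy the constraints those patterns pin
down: per-unit composition, ring content, attachment-point counts and
kekulizability.  The intra-block atom numbering and the port placement
are this package's own choices; per-pass unmatched-atom histograms
therefore match the benchmark tables only qualitatively (they are
properties of the specific shuffle and layout), while formulas,
existence verdicts and iteration behavior are reproduced exactly.

- **Nanotube C[12,12]** — honeycomb cylinder, 24 atoms per ring row, 6
  rows (144 C) per unit; all 24 axial bonds between units are the
  attachment bonds; each open end carries 24 rim hydrogens: C(144n)H48.
  A perfect matching always exists (pair adjacent rows by axial bonds).
- **Graphene** — 8×18 brick-wall honeycomb patch with two rim atoms
  removed and two pendant methylene-type carbons added (the acyclic
  carbons of the pattern), 144 C per block, 13 attachment bonds per
  junction: C(144n)H(12n+26).
- **Graphynes GY1/GY7/tube** — hexagons plus −C≡C− linkers whose sp
  carbons carry deficiency 2 (triple-bond or cumulene capable).  GY1:
  20 hexagons + 8 linkers + 15 direct ring–ring bonds, 33 junction
  bonds.  GY7: 22 hexagons + 28 linkers, 5 of them hydrogen-terminated,
  41 junction bonds.  Graphyne tube: 22 hexagons + 30 linkers, every
  interior hydrogen position replaced by a carbon–carbon attachment, 36
  junction bonds, hence H = 72 independent of n.  Each hexagon can
  alternate internally and each linker take a triple bond, so all sizes
  are kekulizable.
- **Polycyclopentadiene** — 30 five-membered rings per 150-C unit,
  chained and cross-linked; two junction bonds per unit.  `linear` caps
  the four terminal port valences with hydrogens (methylene-type end
  groups), `cyclic` closes the chain straight, `moebius` closes it
  crisscross — same formula and degree sequence, different edge set.
  The odd ring size is the stress test: single rings cannot alternate
  internally, so matchings must run through the inter-ring bonds.
- **Fullerenes** — C20 dodecahedron from its canonical coordinates, C60
  truncated icosahedron by vertex truncation of the icosahedron
  (idealized geometry, bonds scaled to 1.42 Å, retained for XYZ
  export).  C70/C80/C82 isomers are unspecified in the benchmark set
  and are loaded from molfiles instead of generated.
- **Aza substitution** — k uniformly chosen distinct carbons of
  deficiency ≥ 1 become trivalent nitrogen; a nitrogen whose deficiency
  reaches 0 keeps three single converging bonds (its unresolved bonds
  leave the π-system).  Hydrogen counts are untouched, matching the
  benchmark compositions (e.g. C1498H504N2).  Odd k gives odd total
  deficiency — generation refuses it unless explicitly overridden, and
  the substitution emits a warning.
- **Porphine** — hardcoded C20H14N4 macrocycle: four five-membered
  N-rings bridged by methine carbons, two pyrrole-type (N–H, d = 0) and
  two pyridine-type (d = 1) nitrogens.

What the generators do **not** emulate: realistic geometry (except the
fullerene polyhedra, coordinates are absent and kekulization is purely
topological), arbitrary nanotube chiralities, edge reconstructions or
defects.  Passing tests show the algorithm handles the *topological*
features of these materials — fused hexagons, sp linkers, odd rings,
heteroatoms — not that it has been validated against experimentally
derived structures.

## I/O conventions

Molfile bond type 4 ↔ unresolved; types 1–3 ↔ resolved orders.  On
read, explicit hydrogens are collapsed into implicit counts; heavy
atoms without aromatic bonds additionally absorb their valence deficit
as implicit hydrogen (the explicit valence field overrides the element
default when present).  Atoms *with* aromatic bonds keep only
file-explicit hydrogens, since their deficit is undefined until
kekulization — consequently, writing expands implicit hydrogens to
explicit atoms whenever unresolved bonds are present, and writes
compact implicit-hydrogen files otherwise.  V3000 is auto-selected
above 999 atoms or bonds; requesting V2000 beyond that limit is an
error that names the fix.  A dialect with `kekulized=True` refuses to
write unresolved bonds.  `.cc1` is not supported (niche dialect); the
loader raises an informative error.  XYZ is export-only for structures
with coordinates and carries no bonds.

## Trial statistics

`run_trials` derives per-trial seeds from the master seed with a
counter-based seed sequence (seeds stay below 2³¹), so trials are
independent and order-insensitive.  For aza specs the default
re-randomizes the nitrogen placement every trial — the benchmark's
"random aza-analogs" — and `fixed_placement=True` freezes one
placement; both modes are provided because the historical protocol does
not fully specify which was used.  Three counters are kept separate
rather than folded into one column: trials with no Kekulé structure
found, trials rescued by the backtrack after exhaustion, and the
first-pass unmatched histogram.  Wall-clock time is reported for
information only and never asserted — it is hardware-dependent.

## Problem sizes used in the checks

The test suite asserts printed formula cells at chain lengths 1–1000
and exact linearity of each composition law (the laws then pin the
printed 10⁴–10⁵ cells); existence is checked for all families at n ≤ 10
plus a 144 000-atom nanotube run; the exact-oracle comparison uses 500
random instances of ≤ 14 π-atoms and ≤ 12 edges against exhaustive
enumeration of all 3^m π-order vectors; scaling is asserted as
operation counts per atom across nanotube n ∈ {1, 10, 100, 1000}.  The
acceptance script generates every structure it reports on directly, up
to the 1.88-million-atom GY7 sheet, and runs the full 1000-trial
protocol for C60 and porphine.  These sizes keep the whole suite within
minutes on one CPU while still exercising every regime the method is
meant for.

## Known limitations

- The augmentation repair is not a complete matching algorithm (no
  blossom handling); completeness comes from restarts plus the exact
  backtrack.
- The backtrack has no polynomial guarantee; a pathological input could
  make the fallback slow.  Blossom-based exact b-matching is a
  non-goal here.
- With `exact_fallback=False`, a failure after N shuffles is "presumed
  non-existent", never a proof.
- Unmatched-atom histograms depend on the shuffle stream and unit-cell
  layout; only their parity and qualitative shape are stable.
- Elements beyond C/N/H pass through the valence table untested;
  aromaticity perception from geometry, tautomers and resonance
  counting are out of scope.
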