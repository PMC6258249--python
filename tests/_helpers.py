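"""Shared test utilities: tiny molecule builders and independent oracles."""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from kekulize import Atom, Bond, MolecularGraph, PiSystem, UNRESOLVED, build_molecule


def ring_molecule(n: int, demand: int = 1) -> MolecularGraph:
    """n-cycle of carbons, each with the given pi-demand (1 by default).

    Benzene is ``ring_molecule(6)``; the all-aromatic 5-cycle used for
    parity tests is ``ring_molecule(5)``.
    """
    atoms = [Atom(i, "C", 4, 4 - demand - 2) for i in range(n)]
    bonds = [Bond(i, (i + 1) % n, UNRESOLVED) for i in range(n)]
    return build_molecule(atoms, bonds)


def chain_molecule(demands: List[int]) -> MolecularGraph:
    """Open chain of carbons with prescribed per-atom pi-demands."""
    n = len(demands)
    atoms = []
    for i, d in enumerate(demands):
        deg = (1 if i in (0, n - 1) else 2) if n > 1 else 0
        atoms.append(Atom(i, "C", 4, 4 - d - deg))
    bonds = [Bond(i, i + 1, UNRESOLVED) for i in range(n - 1)]
    return build_molecule(atoms, bonds)


def random_pi_molecule(
    rng: np.random.Generator,
    max_atoms: int = 14,
    max_edges: int = 12,
) -> MolecularGraph:
    """Random connected-ish test instance with demands in {1, 2}.

    Degrees are capped so that implicit hydrogen counts stay
    non-negative; feasible and infeasible instances both occur.
    """
    n = int(rng.integers(4, max_atoms + 1))
    demands = rng.integers(1, 3, size=n)
    max_deg = [4 - int(d) for d in demands]  # keep implicit_h >= 0
    deg = [0] * n
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rng.shuffle(pairs)
    edges = []
    for i, j in pairs:
        if len(edges) >= max_edges:
            break
        if deg[i] < max_deg[i] and deg[j] < max_deg[j] and rng.random() < 0.7:
            edges.append((i, j))
            deg[i] += 1
            deg[j] += 1
    atoms = [
        Atom(i, "C", 4, 4 - int(demands[i]) - deg[i]) for i in range(n)
    ]
    bonds = [Bond(i, j, UNRESOLVED) for i, j in edges]
    return build_molecule(atoms, bonds)


def brute_force_feasible(pis: PiSystem) -> bool:
    """Exhaustive enumeration of all pi-order vectors in {0,1,2}^m.

    Completely independent of the package's search code: a vectorized
    scan of every assignment, feasible iff some vector meets every
    member's demand exactly.  Only usable for small edge counts.
    """
    m = len(pis.edges)
    n = len(pis.members)
    demand = np.array([pis.demand[a] for a in pis.members], dtype=np.int64)
    if m == 0:
        return bool((demand == 0).all()) if n else True
    if m > 13:
        raise ValueError("brute force capped at 13 edges")
    local = {a: i for i, a in enumerate(pis.members)}
    incidence = np.zeros((n, m), dtype=np.int8)
    for ei, (u, v, _) in enumerate(pis.edges):
        incidence[local[u], ei] = 1
        incidence[local[v], ei] = 1
    codes = np.arange(3**m, dtype=np.int64)
    powers = 3 ** np.arange(m, dtype=np.int64)
    digits = ((codes[None, :] // powers[:, None]) % 3).astype(np.int8)
    sums = incidence @ digits  # (n, 3**m); max value 2m <= 26, fits int8
    return bool((sums == demand[:, None].astype(np.int8)).all(axis=0).any())
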