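"""Write and re-read structures in MDL molfile and XYZ formats.

An aromatic (unresolved) nanotube is written with bond type 4 and
explicit hydrogens; after kekulization the same structure is written
compactly with resolved orders 1/2.  V3000 is selected automatically
once the V2000 999-atom field would overflow.
"""

from kekulize import (
    KekulizeConfig,
    apply_assignment,
    generate_fullerene,
    generate_nanotube,
    kekulize,
    read_molfile,
    read_xyz,
    write_molfile,
    write_xyz,
)

tube = generate_nanotube(1)
text = write_molfile(tube)
back = read_molfile(text)
print(f"nanotube n=1: wrote {text.count(chr(10))} lines "
      f"({'V3000' if 'V3000' in text else 'V2000'}); "
      f"round-trip formula {back.formula_string()}")

big = generate_nanotube(10)
print(f"nanotube n=10 ({len(big.atoms)} atoms) selects "
      f"{'V3000' if 'V3000' in write_molfile(big) else 'V2000'}")

c60 = generate_fullerene("C60")
result = kekulize(c60, KekulizeConfig(seed=1))
resolved = apply_assignment(c60, result.assignment)
orders = sorted(set(b.order for b in resolved.bonds))
print(f"kekulized C60 bond orders: {orders}")

rec = read_xyz(write_xyz(c60, comment="C60"))
print(f"XYZ round-trip: {len(rec.elements)} atoms, "
      f"first coordinate {tuple(float(c) for c in rec.coords[0])}")
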