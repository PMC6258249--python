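"""Generate each benchmark family and print its molecular formula.

The formulas follow exact linear composition laws in the chain length n
(e.g. the nanotube is always C(144n)H48: hydrogens only cap the two open
ends).  Every structure below is kekulizable; the graphynes contain
sp carbons (pi-deficiency 2) that end up in triple or cumulated double
bonds.
"""

from kekulize import (
    generate_graphene,
    generate_graphyne_tube,
    generate_gy1,
    generate_gy7,
    generate_nanotube,
    generate_polycyclopentadiene,
    porphine,
)

for n in (1, 10, 100):
    print(f"chain length {n}:")
    print(f"  nanotube C[12,12]     {generate_nanotube(n).formula_string()}")
    print(f"  graphene sheet        {generate_graphene(n).formula_string()}")
    print(f"  graphyne GY1          {generate_gy1(n).formula_string()}")
    print(f"  graphyne GY7          {generate_gy7(n).formula_string()}")
    print(f"  graphyne nanotube     {generate_graphyne_tube(n).formula_string()}")
    lin = generate_polycyclopentadiene(n, 'linear').formula_string()
    cyc = generate_polycyclopentadiene(n, 'cyclic').formula_string()
    print(f"  polycyclopentadiene   {lin} (linear) / {cyc} (cyclic)")
print(f"porphine                {porphine().formula_string()}")
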