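"""Repeated-trial statistics for aza-fullerenes.

Runs 1000 kekulization trials of tetraaza-C60 (four random carbons
replaced by nitrogen, fresh placement each trial).  The histogram counts
trials by the number of unmatched atoms after the first alternation
pass; `No. non-existent` counts placements for which no Kekule structure
was found within 300 shuffles and the exact backtrack confirmed
non-existence; `Backtrack rescued` counts placements where the backtrack
overturned an exhausted random search.
"""

from kekulize import GeneratorSpec, KekulizeConfig, report, run_trials

spec = GeneratorSpec("fullerene", fullerene_name="C60", aza_count=4)
config = KekulizeConfig(max_iterations=300, exact_fallback=True)
stats = run_trials(spec, n_trials=1000, config=config, master_seed=0)
print(report(stats, "table"))
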