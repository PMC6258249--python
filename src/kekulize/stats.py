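"""Repeated-trial statistics for the randomized kekulizer.

A *trial* is one full :func:`~kekulize.kekulizer.kekulize` call under a
fresh per-trial seed.  Over many trials this estimates the distribution
of unmatched atoms after the first alternation pass, the fraction of
runs in which no Kekule structure was found within the shuffle budget,
and the shuffle counts -- the quantities the benchmark tables report.

Per-trial seeds are derived from the master seed with a counter-based
seed sequence, so trials are independent and order-insensitive.  For
aza-substituted generator specs the nitrogen placement is re-randomized
every trial by default (each trial sees a fresh random aza analog);
``fixed_placement=True`` freezes one placement for all trials.
"""

from __future__ import annotations

import csv
import io
import json
import time
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Union

import numpy as np

from .generators import GeneratorSpec, generate, substitute_aza
from .kekulizer import KekulizeConfig, kekulize
from .molgraph import MolecularGraph

__all__ = ["TrialStatistics", "run_trials", "report", "derive_seed"]


def derive_seed(master_seed: int, counter: int) -> int:
    """Counter-based per-trial seed (stable, below 2**31)."""
    ss = np.random.SeedSequence((int(master_seed), int(counter)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class TrialStatistics:
    """Aggregate outcome of ``n_trials`` kekulization attempts.

    ``histogram`` maps unmatched-atom counts after the first pass to the
    number of trials that produced them; its values sum to ``n_trials``
    and, for a fixed structure, its keys share the parity of the total
    pi-deficiency.  ``n_non_existent`` counts trials in which no Kekule
    structure was found; ``n_backtrack_rescued`` counts trials in which
    shuffle exhaustion was overturned by the exact backtrack.
    ``avg_iterations`` includes the full shuffle budget spent by
    unsuccessful trials.  ``max_iterations_seen`` is over successful
    trials only.
    """

    n_trials: int
    histogram: Dict[int, int]
    n_non_existent: int
    n_backtrack_rescued: int
    avg_iterations: float
    max_iterations_seen: int
    formula: str = ""
    wall_time_s: float = 0.0  # informational only, hardware dependent

    def validate(self) -> None:
        if sum(self.histogram.values()) != self.n_trials:
            raise ValueError("histogram does not sum to n_trials")
        parities = {k % 2 for k in self.histogram}
        if len(parities) > 1:
            raise ValueError("histogram keys mix parities")

    def to_json(self) -> str:
        d = {
            "n_trials": self.n_trials,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "n_non_existent": self.n_non_existent,
            "n_backtrack_rescued": self.n_backtrack_rescued,
            "avg_iterations": self.avg_iterations,
            "max_iterations_seen": self.max_iterations_seen,
            "formula": self.formula,
            "wall_time_s": self.wall_time_s,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrialStatistics":
        d = json.loads(text)
        return cls(
            n_trials=d["n_trials"],
            histogram={int(k): v for k, v in d["histogram"].items()},
            n_non_existent=d["n_non_existent"],
            n_backtrack_rescued=d["n_backtrack_rescued"],
            avg_iterations=d["avg_iterations"],
            max_iterations_seen=d["max_iterations_seen"],
            formula=d.get("formula", ""),
            wall_time_s=d.get("wall_time_s", 0.0),
        )


def run_trials(
    source: Union[GeneratorSpec, MolecularGraph],
    n_trials: int,
    config: Optional[KekulizeConfig] = None,
    master_seed: int = 0,
    fixed_placement: bool = False,
    progress=None,
) -> TrialStatistics:
    """Kekulize ``source`` ``n_trials`` times and aggregate statistics.

    ``source`` is a molecular graph or a generator spec; specs with
    ``aza_count > 0`` get a fresh random nitrogen placement per trial
    unless ``fixed_placement``.  ``progress`` may be a callable
    ``(trial_index, result)`` for logging.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    base_config = config if config is not None else KekulizeConfig()

    per_trial_aza = False
    if isinstance(source, GeneratorSpec):
        if source.aza_count and not fixed_placement:
            base_graph = generate(replace(source, aza_count=0))
            per_trial_aza = True
            # composition is independent of the nitrogen placement
            formula = substitute_aza(
                base_graph, source.aza_count, seed=0
            ).formula_string()
        else:
            base_graph = generate(source)
            formula = base_graph.formula_string()
    else:
        base_graph = source
        formula = base_graph.formula_string()

    histogram: Dict[int, int] = {}
    n_non = 0
    n_rescued = 0
    iter_sum = 0
    max_ok = 0
    t0 = time.perf_counter()
    for t in range(n_trials):
        seed = derive_seed(master_seed, 2 * t)
        if per_trial_aza:
            assert isinstance(source, GeneratorSpec)
            graph = substitute_aza(
                base_graph, source.aza_count,
                seed=derive_seed(master_seed, 2 * t + 1),
            )
        else:
            graph = base_graph
        result = kekulize(graph, replace(base_config, seed=seed))
        histogram[result.unmatched_first_pass] = (
            histogram.get(result.unmatched_first_pass, 0) + 1
        )
        iter_sum += result.iterations if result.iterations else 1
        if result.success:
            if result.used_backtrack:
                n_rescued += 1
            else:
                max_ok = max(max_ok, result.iterations)
        else:
            n_non += 1
        if progress is not None:
            progress(t, result)
    stats = TrialStatistics(
        n_trials=n_trials,
        histogram=histogram,
        n_non_existent=n_non,
        n_backtrack_rescued=n_rescued,
        avg_iterations=iter_sum / n_trials,
        max_iterations_seen=max_ok,
        formula=formula,
        wall_time_s=time.perf_counter() - t0,
    )
    stats.validate()
    return stats


def report(stats: TrialStatistics, format: str = "table") -> str:
    """Render ``stats`` as a text table, CSV, or JSON."""
    if format == "json":
        return stats.to_json()
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(
            [
                "formula",
                "n_trials",
                "n_non_existent",
                "n_backtrack_rescued",
                "avg_iterations",
                "max_iterations_seen",
                "histogram",
            ]
        )
        hist = ";".join(f"{k}:{v}" for k, v in sorted(stats.histogram.items()))
        writer.writerow(
            [
                stats.formula,
                stats.n_trials,
                stats.n_non_existent,
                stats.n_backtrack_rescued,
                f"{stats.avg_iterations:.3f}",
                stats.max_iterations_seen,
                hist,
            ]
        )
        return buf.getvalue()
    if format == "table":
        lines = [
            f"Formula              {stats.formula}",
            f"Trials               {stats.n_trials}",
            f"No. non-existent     {stats.n_non_existent}",
            f"Backtrack rescued    {stats.n_backtrack_rescued}",
            f"Avg. no. iterations  {stats.avg_iterations:.3f}",
            f"Max. no. iterations  {stats.max_iterations_seen}",
            "Unmatched atoms statistic (first pass):",
        ]
        for k in sorted(stats.histogram):
            lines.append(f"  {k:6d}  {stats.histogram[k]}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")
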