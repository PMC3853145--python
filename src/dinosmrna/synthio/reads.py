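"""Simulation of per-condition small-RNA read pileups.

Reads are drawn from the guide, star, and loop regions of every
planted hairpin with Poisson counts around ``read_depth`` times the
arm weight, templated terminal jitter (up to 1 nt at the 5' end, up to
3 nt at the 3' end), a constant Phred-40 quality string, and the 3'
sequencing adapter appended. Alongside the FASTQ records the simulator
emits the corresponding genome alignments (the reads originate from
known loci, so mapping is resolved by construction) and the table of
expected arm counts (depth x weight) for conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..discovery import ReadAlignment
from ..io import FastqRead
from .config import PlantedTruth, SimulationConfig


@dataclass
class ReadSimResult:
    fastq: dict[str, list[FastqRead]] = field(default_factory=dict)
    alignments: list[ReadAlignment] = field(default_factory=list)
    expected_counts: pd.DataFrame | None = None


def _jitter_probs(j5: dict[int, float], j3: dict[int, float]) -> list[tuple[int, int, float]]:
    combos = [(d5, d3, p5 * p3) for d5, p5 in j5.items() for d3, p3 in j3.items()]
    total = sum(p for _, _, p in combos)
    return [(d5, d3, p / total) for d5, d3, p in combos]


def simulate_smrna_reads(
    truth: PlantedTruth,
    config: SimulationConfig,
    genome: dict[str, str],
) -> ReadSimResult:
    """Draw reads for every planted arm; returns FASTQ records per
    condition, aggregated alignments, and the expected-count table."""
    rng = config.rng("reads")
    result = ReadSimResult(fastq={c: [] for c in config.conditions})
    aln_index: dict[tuple[str, int, int, str], ReadAlignment] = {}
    expected_rows = []

    for pid, planted in truth.precursors.items():
        contig, lo, _, strand = planted.locus
        contig_seq = genome[contig]
        spec = planted.spec
        j5 = spec.jitter5 if spec.jitter5 is not None else config.terminal_jitter5
        j3 = spec.jitter3 if spec.jitter3 is not None else config.terminal_jitter3
        combos = _jitter_probs(j5, j3)
        probs = np.array([p for _, _, p in combos])
        guide_conds = (set(spec.guide_conditions) if spec.guide_conditions is not None
                       else set(config.conditions))
        star_conds = (set(spec.star_conditions) if spec.star_conditions is not None
                      else set(config.conditions))
        arms = {
            "guide": (planted.guide_arm, guide_conds, 1.0),
            "star": (planted.star_arm, star_conds, config.star_weight),
            "loop": (planted.loop, set(config.conditions), config.loop_weight),
        }
        expected = {"id": pid}
        for arm_name, (interval, conds, weight) in arms.items():
            for cond in config.conditions:
                mean = config.read_depth * weight * (cond in conds)
                expected[f"{arm_name}:{cond}"] = mean
                if mean <= 0:
                    continue
                n = int(rng.poisson(mean))
                if n == 0:
                    continue
                per_combo = rng.multinomial(n, probs)
                for (d5, d3, _), k in zip(combos, per_combo):
                    if k == 0:
                        continue
                    a_lo = lo + interval[0] - d5
                    a_hi = lo + interval[1] + d3
                    insert = contig_seq[a_lo:a_hi]
                    key = (contig, a_lo, a_hi, strand)
                    aln = aln_index.get(key)
                    if aln is None:
                        aln = ReadAlignment(contig, a_lo, a_hi, strand, insert)
                        aln_index[key] = aln
                    aln.counts[cond] = aln.counts.get(cond, 0) + int(k)
                    seq = insert + config.adapter
                    qual = [40] * len(seq)
                    for i in range(int(k)):
                        result.fastq[cond].append(
                            FastqRead(f"{pid}:{arm_name}:{cond}:{a_lo}:{i}", seq, qual))
        expected_rows.append(expected)

    result.alignments = list(aln_index.values())
    result.expected_counts = pd.DataFrame(expected_rows).set_index("id") \
        if expected_rows else pd.DataFrame()
    truth.expected_arm_counts = result.expected_counts
    return result
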