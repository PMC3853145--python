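"""Plant-like target prediction: near-perfect full-length
complementarity over CDS and 3'UTR sequences, with a randomized-cohort
false-positive estimator used to choose the mismatch cutoff.

Every ungapped window whose reverse complement differs from the smRNA
at no more than ``max_mm`` positions is a hit; only antisense
(reverse-complement) windows count, G:U wobbles count as mismatches by
default. False positives are estimated by scanning cohorts of random
sequences with the native set's length multiset and pooled
mononucleotide composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from ._seq import DNA, encode, revcomp, to_dna


@dataclass
class PlantSite:
    smrna_id: str
    gene_id: str
    region: str      # "CDS" | "UTR3"
    position: int    # 0-based window start on the gene sequence
    mismatches: int


def _scan_one(query_rc: np.ndarray, target: np.ndarray, max_mm: int) -> np.ndarray:
    """Mismatch count of ``query_rc`` against every window of ``target``;
    returns the window starts with count <= max_mm."""
    L = len(query_rc)
    if len(target) < L:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(target, L)
    mm = (windows != query_rc).sum(axis=1)
    return np.nonzero(mm <= max_mm)[0]


def _window_mismatches(query_rc: np.ndarray, target: np.ndarray) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(target, len(query_rc))
    return (windows != query_rc).sum(axis=1)


def align_plant_targets(
    smrnas: dict[str, str],
    genes: dict[tuple[str, str], str],
    max_mm: int = 3,
) -> list[PlantSite]:
    """Scan smRNAs against region-labelled gene sequences.

    ``genes`` maps (gene_id, region) -> sequence with region "CDS" or
    "UTR3". Hits are deduplicated by (smrna, gene, region, position).
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    encoded = {key: encode(seq) for key, seq in genes.items()}
    sites: list[PlantSite] = []
    seen: set[tuple] = set()
    for sid, smrna in smrnas.items():
        qrc = encode(revcomp(to_dna(smrna)))
        for (gid, region), target in encoded.items():
            if len(target) < len(qrc):
                continue
            mm = _window_mismatches(qrc, target)
            for pos in np.nonzero(mm <= max_mm)[0]:
                key = (sid, gid, region, int(pos))
                if key not in seen:
                    seen.add(key)
                    sites.append(PlantSite(sid, gid, region, int(pos), int(mm[pos])))
    return sites


def base_composition(seqs: list[str]) -> dict[str, float]:
    pooled = "".join(to_dna(s) for s in seqs)
    n = len(pooled)
    return {b: pooled.count(b) / n for b in DNA}


def random_cohorts(
    native: list[str],
    n_cohorts: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> list[list[str]]:
    """Random smRNA cohorts with the native cardinality, length
    multiset, and pooled mononucleotide composition."""
    if not native:
        raise ValueError("native smRNA set is empty")
    rng = np.random.default_rng(rng)
    comp = base_composition(native)
    bases = list(DNA)
    probs = np.array([comp[b] for b in bases])
    lengths = [len(to_dna(s)) for s in native]
    cohorts = []
    for _ in range(n_cohorts):
        cohort = ["".join(rng.choice(bases, size=ln, p=probs)) for ln in lengths]
        cohorts.append(cohort)
    return cohorts


def dinucleotide_shuffled_cohorts(
    native: list[str],
    n_cohorts: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> list[list[str]]:
    """Optional null: per-sequence dinucleotide-preserving shuffles
    (Euler-walk approximation via repeated doublet swaps)."""
    rng = np.random.default_rng(rng)
    cohorts = []
    for _ in range(n_cohorts):
        cohort = []
        for seq in native:
            chars = list(to_dna(seq))
            # Swap interior positions that preserve flanking doublets.
            for _ in range(10 * len(chars)):
                i, j = sorted(rng.integers(1, len(chars) - 1, size=2))
                if i == j:
                    continue
                if (chars[i - 1] == chars[j - 1] and chars[i + 1] == chars[j + 1]):
                    chars[i], chars[j] = chars[j], chars[i]
            cohort.append("".join(chars))
        cohorts.append(cohort)
    return cohorts


def expected_random_hits(
    query_lengths: list[int], n_windows_per_length: dict[int, int], max_mm: int
) -> float:
    """Closed-form expectation for i.i.d. uniform targets: per window,
    P(<= max_mm mismatches) = sum_j C(L,j) (3/4)^j (1/4)^(L-j)."""
    total = 0.0
    for L in query_lengths:
        p = sum(comb(L, j) * (3 / 4) ** j * (1 / 4) ** (L - j)
                for j in range(max_mm + 1))
        total += n_windows_per_length.get(L, 0) * p
    return total


def estimate_fp(
    cohorts: list[list[str]],
    genes: dict[tuple[str, str], str],
    mm_range: range = range(0, 5),
    native: list[str] | None = None,
) -> pd.DataFrame:
    """Mean random hits per cohort (and real:random ratio) per mismatch
    cutoff, with the analytic i.i.d.-uniform expectation as cross-check.

    Returns one row per cutoff with columns mismatch_cutoff,
    real_hits (when ``native`` given), mean_random_hits, ratio
    (real:random, NaN when the denominator is 0), expected_uniform.
    """
    if not genes:
        raise ValueError("empty gene set")
    max_mm = max(mm_range)
    encoded = [encode(seq) for seq in genes.values()
               if len(seq) >= min(len(q) for c in cohorts for q in c)]

    def hits_by_cutoff(queries: list[str]) -> np.ndarray:
        counts = np.zeros(max_mm + 1, dtype=np.int64)
        for q in queries:
            qrc = encode(revcomp(to_dna(q)))
            for target in encoded:
                if len(target) < len(qrc):
                    continue
                mm = _window_mismatches(qrc, target)
                mm = mm[mm <= max_mm]
                if len(mm):
                    counts += np.bincount(mm, minlength=max_mm + 1)
        return np.cumsum(counts)  # hits at cutoff k = hits with mm <= k

    random_hits = np.zeros(max_mm + 1, dtype=float)
    for cohort in cohorts:
        random_hits += hits_by_cutoff(cohort)
    random_hits /= len(cohorts)

    real_hits = hits_by_cutoff(native) if native is not None else None

    lengths0 = [len(q) for q in cohorts[0]]
    windows_per_length = {
        L: sum(max(0, len(t) - L + 1) for t in encoded) for L in set(lengths0)
    }
    rows = []
    for mm in mm_range:
        row = {
            "mismatch_cutoff": mm,
            "mean_random_hits": float(random_hits[mm]),
            "expected_uniform": expected_random_hits(
                lengths0, windows_per_length, mm),
        }
        if real_hits is not None:
            row["real_hits"] = int(real_hits[mm])
            row["ratio"] = (
                float(real_hits[mm] / random_hits[mm])
                if random_hits[mm] > 0 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
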