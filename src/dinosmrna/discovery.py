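"""Small-RNA discovery: read preprocessing, collapsing, hairpin
candidate excision, and validation of miRNA/siRNA precursors.

The validation criteria follow the conserved plant/bilaterian miRNA
annotation rules: a homogeneous 5' terminus on both duplex strands, a
2-nt 3' overhang on both ends of the guide/star duplex, a fold-back
with MFE < -25 kcal/mol, and cross-condition support (guide detected in
>= 7 of 9 conditions, star in >= 2). Candidates whose guide/star duplex
is perfectly Watson-Crick complementary are classified as siRNAs,
everything else as miRNAs.

Coordinates are 0-based half-open throughout; sequences are handled on
the DNA alphabet internally and exposed as RNA at the record level.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import hamming, revcomp, to_dna, to_rna
from .fold import (
    FoldingEngine,
    default_engine,
    duplex_mismatch_count,
    duplex_overhangs,
    pair_table,
)
from .io import FastqRead


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class CollapsedRead:
    """A distinct small-RNA sequence with per-condition read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def first_nt(self) -> str:
        return to_rna(self.sequence[0]) if self.sequence else ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ReadAlignment:
    """Ungapped, stranded placement of a collapsed read on the genome."""

    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Precursor:
    """A hairpin candidate: sequence, fold, and duplex geometry."""

    sequence: str
    structure: str | None = None
    mfe: float | None = None
    locus: tuple[str, int, int, str] | None = None
    guide_arm: tuple[int, int] | None = None
    star_arm: tuple[int, int] | None = None
    loop: tuple[int, int] | None = None
    duplex_mismatches: int | None = None

    def __post_init__(self) -> None:
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise ValueError("structure length must equal sequence length")
        if self.mfe is not None and self.mfe > 0:
            raise ValueError("mfe must be <= 0")

    @property
    def rna(self) -> str:
        return to_rna(self.sequence)

    def arm_seq(self, arm: tuple[int, int]) -> str:
        return self.sequence[arm[0]:arm[1]]


@dataclass
class Thresholds:
    """Tunable validation thresholds."""

    mfe_max: float = -25.0                 # kcal/mol, criterion is mfe < mfe_max
    min_guide_conditions: int = 7
    min_star_conditions: int = 2
    five_prime_homogeneity: float = 0.9    # modal 5'-position weight fraction
    overhang: int = 2                      # nt, required on both duplex ends


@dataclass
class CriteriaReport:
    five_prime_homogeneity: bool
    overhang: bool
    mfe: bool
    guide_conditions: bool
    star_conditions: bool
    guide_modal_fraction: float = float("nan")
    star_modal_fraction: float = float("nan")
    overhang_lengths: tuple[int, int] | None = None
    n_conditions_guide: int = 0
    n_conditions_star: int = 0
    loop_read_total: int = 0   # reported, never thresholded

    @property
    def passed(self) -> bool:
        return (self.five_prime_homogeneity and self.overhang and self.mfe
                and self.guide_conditions and self.star_conditions)

    def as_dict(self) -> dict:
        return {
            "five_prime_homogeneity": self.five_prime_homogeneity,
            "overhang": self.overhang,
            "mfe": self.mfe,
            "guide_conditions": self.guide_conditions,
            "star_conditions": self.star_conditions,
            "passed": self.passed,
            "guide_modal_fraction": self.guide_modal_fraction,
            "star_modal_fraction": self.star_modal_fraction,
            "overhang_lengths": self.overhang_lengths,
            "n_conditions_guide": self.n_conditions_guide,
            "n_conditions_star": self.n_conditions_star,
            "loop_read_total": self.loop_read_total,
        }


@dataclass
class SmRNARecord:
    """A validated smRNA with its per-condition support."""

    id: str
    mature_seq: str          # RNA alphabet
    star_seq: str
    smrna_class: str         # "miRNA" | "siRNA"
    guide_counts: dict[str, int]
    star_counts: dict[str, int]
    criteria: CriteriaReport
    precursor: Precursor

    @property
    def n_conditions_guide(self) -> int:
        return sum(1 for v in self.guide_counts.values() if v >= 1)

    @property
    def n_conditions_star(self) -> int:
        return sum(1 for v in self.star_counts.values() if v >= 1)


# --------------------------------------------------------------------------
# Read preprocessing
# --------------------------------------------------------------------------

def _find_adapter(seq: str, adapter: str, min_overlap: int, max_error: float) -> int:
    """Leftmost start of a 3' adapter occurrence, or -1.

    The adapter is matched as a prefix against every suffix of the read,
    allowing ``max_error`` mismatches per matched base (>= ``min_overlap``
    bases must overlap).
    """
    n = len(seq)
    for i in range(n - min_overlap + 1):
        overlap = min(len(adapter), n - i)
        if overlap < min_overlap:
            break
        if hamming(seq[i:i + overlap], adapter[:overlap]) <= int(max_error * overlap):
            return i
    return -1


def preprocess_reads(
    reads: list[FastqRead],
    adapter: str,
    min_len: int = 18,
    qual_threshold: int = 20,
    min_overlap: int = 5,
    max_error: float = 0.1,
    discard_unmatched: bool = False,
) -> list[FastqRead]:
    """Quality-trim 3' ends, drop low-quality reads, remove the 3' adapter.

    3' bases are trimmed until the terminal Phred score exceeds
    ``qual_threshold``; reads whose mean Phred is <= the threshold are
    discarded; the 3' adapter is removed by prefix matching with up to
    10% mismatches; inserts shorter than ``min_len`` are discarded.
    """
    adapter = to_dna(adapter)
    out: list[FastqRead] = []
    for read in reads:
        seq, qual = to_dna(read.sequence), list(read.quality)
        while qual and qual[-1] <= qual_threshold:
            seq, qual = seq[:-1], qual[:-1]
        if not qual or float(np.mean(qual)) <= qual_threshold:
            continue
        cut = _find_adapter(seq, adapter, min_overlap, max_error)
        if cut >= 0:
            seq, qual = seq[:cut], qual[:cut]
        elif discard_unmatched:
            continue
        if len(seq) < min_len:
            continue
        out.append(FastqRead(read.id, seq, qual))
    return out


def collapse_and_filter(
    reads_by_condition: dict[str, list[str]],
    blacklist: dict[str, str] | None = None,
) -> tuple[list[CollapsedRead], list[CollapsedRead]]:
    """Collapse identical sequences and drop known-ncRNA matches.

    A collapsed sequence is removed when it is an exact substring (on
    either strand) of any blacklist entry (rRNA/tRNA/snoRNA or mRNA
    contigs). Returns (kept, removed); per-condition counts are
    conserved across the two lists.
    """
    merged: dict[str, CollapsedRead] = {}
    for cond, seqs in reads_by_condition.items():
        for s in seqs:
            s = to_dna(s)
            rec = merged.setdefault(s, CollapsedRead(s))
            rec.counts[cond] = rec.counts.get(cond, 0) + 1
    blob = "$".join(to_dna(s) for s in (blacklist or {}).values())
    kept, removed = [], []
    for rec in merged.values():
        if blob and (rec.sequence in blob or revcomp(rec.sequence) in blob):
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


# --------------------------------------------------------------------------
# Hairpin candidate excision
# --------------------------------------------------------------------------

def excise_candidates(
    alignments: list[ReadAlignment],
    genome: dict[str, str],
    max_precursor: int = 90,
    flank: int = 10,
    engine: FoldingEngine | None = None,
) -> list[Precursor]:
    """Excise and fold hairpin candidate windows from read clusters.

    Alignments on the same strand within ``flank`` nt of each other are
    clustered; for each cluster two ``max_precursor``-nt windows are
    anchored at the dominant (highest-count) read's 5' end — one with
    the read as prospective 5' arm, one as prospective 3' arm — then
    deduplicated and folded.
    """
    engine = engine or default_engine()
    for aln in alignments:
        if aln.contig not in genome:
            raise ValueError(f"alignment on unknown contig {aln.contig!r}")
        if aln.start < 0 or aln.end > len(genome[aln.contig]):
            raise ValueError(
                f"alignment {aln.contig}:{aln.start}-{aln.end} beyond contig bounds")

    clusters: list[list[ReadAlignment]] = []
    for key in sorted({(a.contig, a.strand) for a in alignments}):
        group = sorted(
            (a for a in alignments if (a.contig, a.strand) == key),
            key=lambda a: a.start,
        )
        current: list[ReadAlignment] = []
        current_end = -1
        for aln in group:
            if current and aln.start > current_end + flank:
                clusters.append(current)
                current = []
            current.append(aln)
            current_end = max(current_end, aln.end)
        if current:
            clusters.append(current)

    seen: set[tuple[str, int, int, str]] = set()
    candidates: list[Precursor] = []
    for cluster in clusters:
        dom = max(cluster, key=lambda a: a.total)
        contig_len = len(genome[dom.contig])
        if dom.strand == "+":
            windows = [
                (dom.start, dom.start + max_precursor),
                (dom.end - max_precursor, dom.end),
            ]
        else:
            windows = [
                (dom.end - max_precursor, dom.end),
                (dom.start, dom.start + max_precursor),
            ]
        for lo, hi in windows:
            lo, hi = max(0, lo), min(contig_len, hi)
            locus = (dom.contig, lo, hi, dom.strand)
            if hi - lo < 2 * len(dom.sequence) or locus in seen:
                continue
            seen.add(locus)
            seq = genome[dom.contig][lo:hi]
            if dom.strand == "-":
                seq = revcomp(seq)
            structure, mfe = engine.fold(seq)
            candidates.append(
                Precursor(sequence=seq, structure=structure,
                          mfe=min(mfe, 0.0), locus=locus)
            )
    return candidates


def map_reads_to_precursor(
    precursor: Precursor, alignments: list[ReadAlignment]
) -> dict[str, list[tuple[int, int, int]]]:
    """Per-condition (start_on_precursor, length, count) for reads fully
    inside the candidate window, in precursor (5'->3') orientation."""
    contig, lo, hi, strand = precursor.locus
    out: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for aln in alignments:
        if aln.contig != contig or aln.strand != strand:
            continue
        if aln.start < lo or aln.end > hi:
            continue
        if strand == "+":
            start = aln.start - lo
        else:
            start = hi - aln.end
        for cond, count in aln.counts.items():
            if count > 0:
                out[cond].append((start, aln.end - aln.start, count))
    return dict(out)


def assign_arms(
    precursor: Precursor,
    reads_by_condition: dict[str, list[tuple[int, int, int]]],
    min_gap: int = 3,
) -> bool:
    """Set guide/star arm intervals from the read pileup.

    The guide arm is the modal (start, length) read weighted by total
    count; the star arm is the strongest non-overlapping read at least
    ``min_gap`` nt away. Returns False when no two-arm geometry exists.
    """
    tally: Counter[tuple[int, int]] = Counter()
    for reads in reads_by_condition.values():
        for start, length, count in reads:
            tally[(start, length)] += count
    if not tally:
        return False
    (g_start, g_len), _ = tally.most_common(1)[0]
    precursor.guide_arm = (g_start, g_start + g_len)
    star = None
    for (s, ln), cnt in tally.most_common():
        if s + ln + min_gap <= g_start or s >= g_start + g_len + min_gap:
            star = (s, s + ln)
            break
    if star is None:
        return False
    precursor.star_arm = star
    a, b = sorted([precursor.guide_arm, precursor.star_arm])
    precursor.loop = (a[1], b[0])
    return True


def _arm_stats(
    arm: tuple[int, int],
    reads_by_condition: dict[str, list[tuple[int, int, int]]],
    slack: int = 4,
) -> tuple[dict[str, int], float, dict[tuple[int, int], int]]:
    """Per-condition counts, modal-5'-position fraction, and the pooled
    (start, length) tally for reads attributable to one arm.

    A read belongs to the arm when its 5' end lies within ``slack`` nt
    of the arm start (terminal processing jitter).
    """
    counts: dict[str, int] = {}
    tally: Counter[tuple[int, int]] = Counter()
    start_tally: Counter[int] = Counter()
    for cond, reads in reads_by_condition.items():
        for start, length, count in reads:
            if abs(start - arm[0]) <= slack:
                counts[cond] = counts.get(cond, 0) + count
                tally[(start, length)] += count
                start_tally[start] += count
    total = sum(start_tally.values())
    modal = max(start_tally.values()) / total if total else float("nan")
    return counts, modal, dict(tally)


def evaluate_candidate(
    precursor: Precursor,
    reads_by_condition: dict[str, list[tuple[int, int, int]]],
    thresholds: Thresholds | None = None,
) -> CriteriaReport:
    """Score a folded, arm-assigned candidate against the five criteria.

    (a) >= 90% of each arm's reads share one 5' position, (b) the
    guide/star duplex carries a 2-nt 3' overhang on both ends (read from
    the fold), (c) MFE < -25 kcal/mol, (d) guide detected in >= 7
    conditions, (e) star detected in >= 2 conditions.
    """
    th = thresholds or Thresholds()
    if precursor.guide_arm is None or precursor.star_arm is None:
        raise ValueError("arm intervals undefined; run assign_arms first")
    if precursor.structure is None or precursor.mfe is None:
        raise ValueError("candidate must be folded before evaluation")

    guide_counts, guide_modal, _ = _arm_stats(precursor.guide_arm, reads_by_condition)
    star_counts, star_modal, _ = _arm_stats(precursor.star_arm, reads_by_condition)
    loop_total = 0
    if precursor.loop is not None:
        lo, hi = precursor.loop
        for reads in reads_by_condition.values():
            for start, length, count in reads:
                if lo <= start and start + length <= hi:
                    loop_total += count

    overhangs = duplex_overhangs(
        precursor.structure, precursor.guide_arm, precursor.star_arm)
    overhang_ok = overhangs is not None and all(o == th.overhang for o in overhangs)

    n_guide = sum(1 for v in guide_counts.values() if v >= 1)
    n_star = sum(1 for v in star_counts.values() if v >= 1)
    homogeneous = (
        not np.isnan(guide_modal) and guide_modal >= th.five_prime_homogeneity
        and not np.isnan(star_modal) and star_modal >= th.five_prime_homogeneity
    )
    return CriteriaReport(
        five_prime_homogeneity=homogeneous,
        overhang=overhang_ok,
        mfe=precursor.mfe < th.mfe_max,
        guide_conditions=n_guide >= th.min_guide_conditions,
        star_conditions=n_star >= th.min_star_conditions,
        guide_modal_fraction=guide_modal,
        star_modal_fraction=star_modal,
        overhang_lengths=overhangs,
        n_conditions_guide=n_guide,
        n_conditions_star=n_star,
        loop_read_total=loop_total,
    )


def classify_duplex(precursor: Precursor, overhang: int = 2) -> str:
    """siRNA iff every guide-arm position outside the 2-nt 3' overhang is
    Watson-Crick paired into the star arm; miRNA otherwise."""
    if precursor.guide_arm is None or precursor.star_arm is None:
        raise ValueError("arm intervals undefined")
    mm = duplex_mismatch_count(
        precursor.sequence, precursor.structure,
        precursor.guide_arm, precursor.star_arm, overhang=overhang,
    )
    precursor.duplex_mismatches = mm
    return "siRNA" if mm == 0 else "miRNA"


def discover_smrnas(
    alignments: list[ReadAlignment],
    genome: dict[str, str],
    thresholds: Thresholds | None = None,
    max_precursor: int = 90,
    flank: int = 10,
    engine: FoldingEngine | None = None,
    keep_failed: bool = False,
) -> list[SmRNARecord]:
    """End-to-end candidate excision, validation, and classification."""
    th = thresholds or Thresholds()
    candidates = excise_candidates(
        alignments, genome, max_precursor=max_precursor, flank=flank, engine=engine)
    # Guide and star pileups cluster separately (the loop exceeds the
    # clustering gap), so one locus can surface as two shifted windows;
    # validated records are deduplicated on the genomic guide interval.
    by_guide_locus: dict[tuple, SmRNARecord] = {}
    records: list[SmRNARecord] = []
    for idx, cand in enumerate(candidates):
        reads = map_reads_to_precursor(cand, alignments)
        if not assign_arms(cand, reads):
            continue
        report = evaluate_candidate(cand, reads, th)
        if not (report.passed or keep_failed):
            continue
        smrna_class = classify_duplex(cand, overhang=th.overhang)
        guide_counts, _, _ = _arm_stats(cand.guide_arm, reads)
        star_counts, _, _ = _arm_stats(cand.star_arm, reads)
        contig, lo, _, strand = cand.locus
        record = SmRNARecord(
            id=f"cand-{contig}-{lo}-{strand}-{idx}",
            mature_seq=to_rna(cand.arm_seq(cand.guide_arm)),
            star_seq=to_rna(cand.arm_seq(cand.star_arm)),
            smrna_class=smrna_class,
            guide_counts=guide_counts,
            star_counts=star_counts,
            criteria=report,
            precursor=cand,
        )
        if strand == "+":
            guide_locus = (contig, strand, lo + cand.guide_arm[0], lo + cand.guide_arm[1])
        else:
            hi = cand.locus[2]
            guide_locus = (contig, strand, hi - cand.guide_arm[1], hi - cand.guide_arm[0])
        best = by_guide_locus.get(guide_locus)
        if best is None or (record.criteria.passed and not best.criteria.passed) or (
            record.criteria.passed == best.criteria.passed
            and record.precursor.mfe < best.precursor.mfe
        ):
            by_guide_locus[guide_locus] = record
    records = list(by_guide_locus.values())
    return records


# --------------------------------------------------------------------------
# Catalog summary & genomic context
# --------------------------------------------------------------------------

def records_to_frame(records: list[SmRNARecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "smrna_class": r.smrna_class,
            "sequence": r.mature_seq,
            "length": len(r.mature_seq),
            "stemloop_len": len(r.precursor.sequence),
            "mfe_kcal_mol": r.precursor.mfe,
            "mature_reads": sum(r.guide_counts.values()),
            "star_reads": sum(r.star_counts.values()),
            "star_conditions": r.n_conditions_star,
        })
    return pd.DataFrame(rows)


def summarize_catalog(catalog: pd.DataFrame) -> dict:
    """Summary statistics for an smRNA catalog table.

    Expects the catalog schema (id, smrna_class, sequence, length,
    stemloop_len, mfe_kcal_mol, ..., star_conditions); returns length
    histogram, 5'-nucleotide composition, MFE and stem-loop ranges,
    per-class counts, and the star-strand condition tally.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    seqs = catalog["sequence"].map(to_rna)
    summary = {
        "n": int(len(catalog)),
        "length_histogram": seqs.str.len().value_counts().sort_index().to_dict(),
        "first_nt_composition": seqs.str[0].value_counts().to_dict(),
        "mfe_min": float(catalog["mfe_kcal_mol"].min()),
        "mfe_mean": float(catalog["mfe_kcal_mol"].mean()),
        "mfe_max": float(catalog["mfe_kcal_mol"].max()),
        "stemloop_min": int(catalog["stemloop_len"].min()),
        "stemloop_max": int(catalog["stemloop_len"].max()),
        "class_counts": catalog["smrna_class"].value_counts().to_dict(),
    }
    if "star_conditions" in catalog:
        sc = catalog["star_conditions"]
        summary["star_condition_tally"] = sc.value_counts().sort_index().to_dict()
        summary["n_star_in_7plus_conditions"] = int((sc >= 7).sum())
    return summary


_CONTEXT_CATEGORIES = [
    "exon_sense", "exon_antisense", "intron_sense",
    "intron_antisense", "repeat", "other",
]


def classify_genomic_context(
    alignments: list[ReadAlignment], annotation: pd.DataFrame
) -> pd.Series:
    """Fraction of read counts per genomic context category.

    Precedence exon > intron > repeat > other; within a feature type a
    sense overlap outranks an antisense one. ``annotation`` is a GFF3
    table (1-based inclusive) with exon/intron/repeat feature rows.
    """
    feats: dict[str, list[tuple[int, int, str, str]]] = defaultdict(list)
    for row in annotation.itertuples():
        ftype = row.type.lower()
        if ftype in ("exon", "intron") or "repeat" in ftype:
            kind = "repeat" if "repeat" in ftype else ftype
            if row.strand not in ("+", "-", "."):
                raise ValueError(f"unknown strand symbol {row.strand!r}")
            feats[row.seqid].append((int(row.start) - 1, int(row.end), kind, row.strand))

    weights: Counter[str] = Counter()
    for aln in alignments:
        if aln.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {aln.strand!r}")
        hits = set()
        for lo, hi, kind, strand in feats.get(aln.contig, ()):
            if aln.start < hi and aln.end > lo:
                if kind == "repeat":
                    hits.add("repeat")
                else:
                    rel = "sense" if strand == aln.strand else "antisense"
                    hits.add(f"{kind}_{rel}")
        for cat in _CONTEXT_CATEGORIES:
            if cat in hits:
                weights[cat] += aln.total
                break
        else:
            weights["other"] += aln.total

    total = sum(weights.values())
    if total == 0:
        raise ValueError("no aligned reads to classify")
    return pd.Series(
        {cat: weights.get(cat, 0) / total for cat in _CONTEXT_CATEGORIES},
        name="fraction",
    )
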