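"""Discovery stage: preprocessing, collapsing, excision, validation."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from conftest import build_discovery_scenario
from dinosmrna.discovery import (
    CollapsedRead,
    Precursor,
    ReadAlignment,
    Thresholds,
    classify_duplex,
    classify_genomic_context,
    collapse_and_filter,
    discover_smrnas,
    evaluate_candidate,
    excise_candidates,
    preprocess_reads,
    records_to_frame,
    summarize_catalog,
)
from dinosmrna.io import FastqRead


# ------------------------------------------------------------- preprocessing

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _read(seq, qual=40):
    return FastqRead("r", seq, [qual] * len(seq))


def test_low_quality_tail_is_trimmed():
    body = "ACGTACGTACGTACGTACGTACGT"
    read = FastqRead("r", body + "AAAA", [40] * len(body) + [2, 2, 2, 2])
    out = preprocess_reads([read], ADAPTER)
    assert out[0].sequence == body


def test_short_insert_discarded_after_adapter_removal():
    insert17 = "ACGTACGTACGTACGTA"
    insert18 = "ACGTACGTACGTACGTAC"
    out = preprocess_reads([_read(insert17 + ADAPTER), _read(insert18 + ADAPTER)],
                           ADAPTER)
    assert [r.sequence for r in out] == [insert18]


def test_read_without_adapter_passes_through_by_default():
    seq = "ACGTACGTACGTACGTACGTAC"
    assert preprocess_reads([_read(seq)], ADAPTER)[0].sequence == seq
    assert preprocess_reads([_read(seq)], ADAPTER, discard_unmatched=True) == []


def test_low_mean_quality_read_discarded():
    seq = "ACGTACGTACGTACGTACGTAC"
    read = FastqRead("r", seq, [15] * (len(seq) - 1) + [40])
    assert preprocess_reads([read], ADAPTER) == []


def test_malformed_fastq_reports_record_index(tmp_path):
    from dinosmrna.io import read_fastq

    path = tmp_path / "bad.fastq"
    path.write_text("@ok\nACGT\n+\nIIII\n@bad\nACGTACGT\n+\nII\n")
    with pytest.raises(ValueError, match="index 1"):
        read_fastq(path)


# ---------------------------------------------------------------- collapsing

def test_collapse_merges_and_conserves_counts():
    reads = {
        "c1": ["ACGTACGTACGTACGTACGTAC"] * 2 + ["TTTTACGTACGTACGTACGTAC"],
        "c2": ["ACGTACGTACGTACGTACGTAC"],
    }
    blacklist = {"rRNA-1": "GGG" + "TTTTACGTACGTACGTACGTAC" + "CCC"}
    kept, removed = collapse_and_filter(reads, blacklist)
    total_in = sum(len(v) for v in reads.values())
    assert sum(r.total for r in kept) + sum(r.total for r in removed) == total_in
    [k] = kept
    assert k.counts == {"c1": 2, "c2": 1}
    assert [r.sequence for r in removed] == ["TTTTACGTACGTACGTACGTAC"]


def test_blacklist_matches_either_strand():
    from dinosmrna._seq import revcomp

    seq = "ACGTACGTACGTACGTACGTAC"
    kept, removed = collapse_and_filter({"c": [seq]}, {"b": "AA" + revcomp(seq)})
    assert kept == [] and len(removed) == 1


def test_empty_input_collapses_to_empty():
    assert collapse_and_filter({}, {}) == ([], [])


# ------------------------------------------------------------------ excision

def test_empty_alignments_give_no_candidates():
    assert excise_candidates([], {"chr1": "ACGT" * 100}) == []


def test_out_of_bounds_alignment_rejected():
    aln = ReadAlignment("chr1", 390, 412, "+", "A" * 22, {"c": 1})
    with pytest.raises(ValueError, match="bounds"):
        excise_candidates([aln], {"chr1": "ACGT" * 100})


def test_planted_cluster_yields_window_spanning_both_arms(base_scenario, base_records):
    _, genome_res, _ = base_scenario
    by_guide = {r.mature_seq: r for r in base_records}
    for planted in genome_res.truth.precursors.values():
        from dinosmrna._seq import to_rna

        rec = by_guide[to_rna(planted.guide_seq)]
        _, lo, hi, _ = rec.precursor.locus
        p_lo = planted.locus[1]
        assert lo <= p_lo and p_lo + len(planted.sequence) <= hi


# ---------------------------------------------------------------- validation

def _synthetic_candidate(mfe=-40.0, overhang=2):
    """A precursor with designed structure and pileups matching its arms."""
    from dinosmrna.synthio import build_precursor

    kind = "siRNA"
    p = build_precursor("ACGUACGUACGUACGUACGUAC", kind, 43, 0, rng=2,
                        overhang=overhang)
    p.mfe = mfe
    reads = {
        f"c{i}": [(p.guide_arm[0], 22, 100), (p.star_arm[0], 22, 25)]
        for i in range(9)
    }
    return p, reads


def test_mfe_threshold_is_strict():
    p, reads = _synthetic_candidate(mfe=-24.9)
    assert not evaluate_candidate(p, reads).mfe
    p, reads = _synthetic_candidate(mfe=-25.1)
    report = evaluate_candidate(p, reads)
    assert report.mfe and report.passed


def test_condition_minima():
    p, reads = _synthetic_candidate()
    limited = {}
    for i, (cond, rl) in enumerate(sorted(reads.items())):
        guide = [r for r in rl if r[0] == p.guide_arm[0]]
        star = [r for r in rl if r[0] == p.star_arm[0]]
        limited[cond] = (guide if i < 7 else []) + (star if i < 2 else [])
    report = evaluate_candidate(p, limited)
    assert report.guide_conditions and report.star_conditions
    assert report.n_conditions_guide == 7 and report.n_conditions_star == 2
    limited[sorted(limited)[0]] = [r for r in limited[sorted(limited)[0]]
                                   if r[0] != p.guide_arm[0]]
    assert not evaluate_candidate(p, limited).guide_conditions


def test_blunt_duplex_fails_overhang_criterion():
    p, reads = _synthetic_candidate(overhang=0)
    report = evaluate_candidate(p, reads)
    assert not report.overhang
    assert report.overhang_lengths == (0, 0)


def test_heterogeneous_five_prime_fails():
    p, reads = _synthetic_candidate()
    smeared = {cond: [(p.guide_arm[0], 22, 50), (p.guide_arm[0] + 1, 21, 50),
                      (p.star_arm[0], 22, 25)]
               for cond in reads}
    assert not evaluate_candidate(p, smeared).five_prime_homogeneity


def test_unassigned_arms_raise():
    p, reads = _synthetic_candidate()
    p.guide_arm = None
    with pytest.raises(ValueError, match="arm"):
        evaluate_candidate(p, reads)


def test_duplex_classification():
    from dinosmrna.synthio import build_precursor

    perfect = build_precursor("ACGUACGUACGUACGUACGUAC", "siRNA", 43, 0, rng=3)
    assert classify_duplex(perfect) == "siRNA"
    assert perfect.duplex_mismatches == 0
    one_off = build_precursor("ACGUACGUACGUACGUACGUAC", "miRNA", 43, 1, rng=3)
    assert classify_duplex(one_off) == "miRNA"
    assert one_off.duplex_mismatches == 1


# ------------------------------------------------------------------ roundtrip

def test_planted_catalog_recovered_and_classified(base_scenario, base_records):
    config, genome_res, _ = base_scenario
    assert len(base_records) == 21
    assert Counter(r.smrna_class for r in base_records) == {
        "siRNA": 13, "miRNA": 8}
    truth_guides = {p.guide_seq for p in genome_res.truth.precursors.values()}
    from dinosmrna._seq import to_dna

    assert {to_dna(r.mature_seq) for r in base_records} == truth_guides


@pytest.mark.parametrize("degrade", [
    lambda s: setattr(s, "jitter5", {0: 0.5, 1: 0.5}),
    lambda s: setattr(s, "overhang", 0),
    lambda s: setattr(s, "weak_fold", True),
    lambda s: setattr(s, "guide_conditions",
                      ["noon", "4C", "16C", "34C", "36C", "20g"]),
    lambda s: setattr(s, "star_conditions", ["noon"]),
], ids=["five-prime", "overhang", "mfe", "guide-conditions", "star-conditions"])
def test_single_criterion_degradation_removes_one_record(degrade):
    _, genome_res, reads = build_discovery_scenario(seed=3, modify=degrade)
    records = discover_smrnas(reads.alignments, genome_res.genome)
    assert len(records) == 20


def test_mfe_threshold_monotonicity(base_scenario, base_records):
    _, genome_res, reads = base_scenario
    strict = discover_smrnas(reads.alignments, genome_res.genome,
                             thresholds=Thresholds(mfe_max=-60.0))
    assert len(strict) <= len(base_records)


# ------------------------------------------------------------------- summary

def test_reference_catalog_summary_matches_published_statistics(reference_catalog):
    summary = summarize_catalog(reference_catalog)
    assert summary["n"] == 21
    assert round(summary["mfe_mean"], 1) == -68.2
    assert summary["mfe_min"] == -83.1 and summary["mfe_max"] == -40.6
    assert summary["length_histogram"] == {21: 2, 22: 19}
    assert summary["first_nt_composition"]["U"] == 9
    assert summary["stemloop_min"] == 84 and summary["stemloop_max"] == 90
    assert summary["class_counts"] == {"siRNA": 13, "miRNA": 8}
    assert summary["n_star_in_7plus_conditions"] == 19


def test_summary_requires_records():
    import pandas as pd

    with pytest.raises(ValueError):
        summarize_catalog(pd.DataFrame(columns=["sequence"]))


def test_records_to_frame_summary(base_records):
    frame = records_to_frame(base_records)
    summary = summarize_catalog(frame)
    assert summary["class_counts"] == {"siRNA": 13, "miRNA": 8}
    assert summary["mfe_max"] < -25.0
    assert set(summary["length_histogram"]) <= {21, 22}


# ------------------------------------------------------------------- context

def test_genomic_context_classification():
    import pandas as pd

    gff = pd.DataFrame([
        {"seqid": "chr1", "source": "t", "type": "gene", "start": 1, "end": 400,
         "score": ".", "strand": "+", "phase": ".", "attributes": "ID=g"},
        {"seqid": "chr1", "source": "t", "type": "exon", "start": 1, "end": 100,
         "score": ".", "strand": "+", "phase": ".", "attributes": "."},
        {"seqid": "chr1", "source": "t", "type": "intron", "start": 101, "end": 300,
         "score": ".", "strand": "+", "phase": ".", "attributes": "."},
        {"seqid": "chr1", "source": "t", "type": "repeat_region", "start": 500,
         "end": 600, "score": ".", "strand": "+", "phase": ".", "attributes": "."},
    ])
    alns = [
        ReadAlignment("chr1", 10, 32, "+", "A" * 22, {"c": 2}),   # exon sense
        ReadAlignment("chr1", 120, 142, "-", "A" * 22, {"c": 1}),  # intron anti
        ReadAlignment("chr1", 520, 542, "+", "A" * 22, {"c": 1}),  # repeat
        ReadAlignment("chr1", 800, 822, "-", "A" * 22, {"c": 4}),  # other
    ]
    fractions = classify_genomic_context(alns, gff)
    assert fractions["exon_sense"] == pytest.approx(2 / 8)
    assert fractions["intron_antisense"] == pytest.approx(1 / 8)
    assert fractions["repeat"] == pytest.approx(1 / 8)
    assert fractions["other"] == pytest.approx(4 / 8)
    assert fractions.sum() == pytest.approx(1.0, abs=1e-9)


def test_unknown_strand_rejected():
    import pandas as pd

    gff = pd.DataFrame([{"seqid": "chr1", "source": "t", "type": "exon",
                         "start": 1, "end": 100, "score": ".", "strand": "+",
                         "phase": ".", "attributes": "."}])
    with pytest.raises(ValueError, match="strand"):
        classify_genomic_context(
            [ReadAlignment("chr1", 1, 23, "*", "A" * 22, {"c": 1})], gff)
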