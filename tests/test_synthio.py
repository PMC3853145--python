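"""Synthetic-data generator: planted truth must be exact and seeded."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

from dinosmrna._seq import hamming, revcomp
from dinosmrna.discovery import preprocess_reads
from dinosmrna.io import FastqRead
from dinosmrna.synthio import (
    CorrelationSpec,
    PlantedSiteSpec,
    SimulationConfig,
    build_precursor,
    generate_go_fixture,
    plant_genome,
    plant_target_sites,
    simulate_expression,
    simulate_smrna_reads,
)
from dinosmrna.target_animal import find_seed_sites
from dinosmrna.target_plant import align_plant_targets


# ------------------------------------------------------------------ hairpins

def test_precursor_length_arithmetic():
    p = build_precursor("ACGU" * 5 + "AC", "siRNA", loop_len=43,
                        duplex_mismatches=0, rng=0)
    assert len(p.sequence) == 22 + 43 + 22


@pytest.mark.parametrize("kind,mm", [("siRNA", 0), ("miRNA", 3)])
def test_duplex_mismatch_construction(kind, mm):
    p = build_precursor("ACGUACGUACGUACGUACGUAC", kind, 43, mm, rng=1)
    guide = p.arm_seq(p.guide_arm)
    star = p.arm_seq(p.star_arm)
    # Overhang-aligned comparison: paired regions exclude each 3' dinucleotide.
    assert hamming(guide[:-2], revcomp(star[:-2])) == mm


def test_precursor_rejects_inconsistent_kind():
    with pytest.raises(ValueError):
        build_precursor("ACGUACGUACGUACGUACGUAC", "siRNA", 43, 2, rng=0)
    with pytest.raises(ValueError):
        build_precursor("ACGUACGUACGUACGUACGUAC", "miRNA", 43, 0, rng=0)
    with pytest.raises(ValueError):  # 22+100+22 nt is outside 84-90
        build_precursor("ACGUACGUACGUACGUACGUAC", "siRNA", 100, 0, rng=0)


# ------------------------------------------------------------------ genome

def test_planted_loci_roundtrip_and_determinism():
    config = SimulationConfig(rng_seed=11, n_precursors=6, n_mirna=2, n_genes=8)
    config.precursor_specs = config.default_precursor_specs()
    res1 = plant_genome(config)
    assert len(res1.truth.precursors) == 6
    for planted in res1.truth.precursors.values():
        contig, lo, hi, strand = planted.locus
        assert res1.genome[contig][lo:hi] == planted.sequence
        assert strand == "+"
    res2 = plant_genome(config)
    assert res1.genome == res2.genome


def test_empty_simulation_emits_genome():
    config = SimulationConfig(rng_seed=0, n_precursors=0, n_genes=2)
    config.precursor_specs = []
    res = plant_genome(config)
    assert len(res.genome["chr1"]) == config.genome_len
    assert res.truth.precursors == {}


def test_genome_too_short_raises():
    config = SimulationConfig(rng_seed=0, genome_len=2000)
    with pytest.raises(ValueError, match="too short"):
        plant_genome(config)


# ------------------------------------------------------------------ reads

@pytest.fixture(scope="module")
def small_scenario():
    config = SimulationConfig(rng_seed=7, n_precursors=4, n_mirna=2, n_genes=6)
    config.precursor_specs = config.default_precursor_specs()
    res = plant_genome(config)
    reads = simulate_smrna_reads(res.truth, config, res.genome)
    return config, res, reads


def test_zero_star_weight_yields_no_star_reads():
    config = SimulationConfig(rng_seed=7, n_precursors=2, n_mirna=1,
                              n_genes=4, star_weight=0.0)
    config.precursor_specs = config.default_precursor_specs()
    res = plant_genome(config)
    reads = simulate_smrna_reads(res.truth, config, res.genome)
    for planted in res.truth.precursors.values():
        _, lo, _, _ = planted.locus
        star_lo = lo + planted.star_arm[0]
        star_alns = [a for a in reads.alignments
                     if abs(a.start - star_lo) <= 4]
        assert star_alns == []


def test_read_counts_near_poisson_mean(small_scenario):
    config, res, reads = small_scenario
    depth = config.read_depth
    for pid, planted in res.truth.precursors.items():
        _, lo, _, _ = planted.locus
        guide_lo = lo + planted.guide_arm[0]
        for cond in config.conditions:
            observed = sum(a.counts.get(cond, 0) for a in reads.alignments
                           if abs(a.start - guide_lo) <= 4)
            assert abs(observed - depth) <= 4 * np.sqrt(depth)


def test_expected_count_conservation(small_scenario):
    config, res, reads = small_scenario
    table = reads.expected_counts
    guide_cols = [c for c in table.columns if c.startswith("guide:")]
    star_cols = [c for c in table.columns if c.startswith("star:")]
    assert np.allclose(table[guide_cols].to_numpy(), config.read_depth)
    assert np.allclose(table[star_cols].to_numpy(),
                       config.read_depth * config.star_weight)


def test_adapter_roundtrip_recovers_insert(small_scenario):
    config, _, reads = small_scenario
    raw = reads.fastq[config.conditions[0]][:50]
    trimmed = preprocess_reads(raw, config.adapter)
    inserts = {a.sequence for a in reads.alignments}
    assert len(trimmed) == len(raw)
    for t in trimmed:
        assert t.sequence in inserts


# ------------------------------------------------------------------ targets

def test_planted_sites_roundtrip():
    smrnas = {"s1": "UCAGAGACCAGACGCAGAGGCU", "s2": "ACUUAGAACUCUCCUACGAGGG"}
    config = SimulationConfig(rng_seed=13, n_genes=6, planted_sites=[
        PlantedSiteSpec("s1", "gene-001", "UTR3", site_class="8mer"),
        PlantedSiteSpec("s2", "gene-002", "CDS", mismatch_count=3),
    ])
    fx = plant_target_sites(config, smrnas)
    animal, plant = fx.registry
    found = find_seed_sites(smrnas["s1"], fx.utrs["gene-001"])
    assert [(s.utr_position, s.site_class) for s in found] == [
        (animal.position, "8mer")]
    hits3 = align_plant_targets(smrnas, fx.genes(), max_mm=3)
    assert [(h.smrna_id, h.gene_id, h.region, h.position, h.mismatches)
            for h in hits3] == [("s2", "gene-002", "CDS", plant.position, 3)]
    assert align_plant_targets(smrnas, fx.genes(), max_mm=2) == []


def test_scrubbed_background_has_no_accidental_sites():
    smrnas = {"s1": "UCAGAGACCAGACGCAGAGGCU", "s2": "AAUUUGAACGUUGCCAUCUAUC"}
    config = SimulationConfig(rng_seed=17, n_genes=8)
    fx = plant_target_sites(config, smrnas, specs=[])
    for sid, smrna in smrnas.items():
        for seq in list(fx.utrs.values()) + list(fx.cds.values()):
            assert find_seed_sites(smrna, seq) == []
    assert align_plant_targets(smrnas, fx.genes(), max_mm=4) == []


def test_boundary_site_position_rejected():
    smrnas = {"s1": "UCAGAGACCAGACGCAGAGGCU"}
    config = SimulationConfig(rng_seed=1, n_genes=2, planted_sites=[
        PlantedSiteSpec("s1", "gene-001", "UTR3", site_class="8mer", position=0)])
    with pytest.raises(ValueError, match="truncate"):
        plant_target_sites(config, smrnas)


# ------------------------------------------------------------------ expression

def test_perfect_monotone_pairs_have_exact_spearman():
    config = SimulationConfig(rng_seed=23, n_genes=5, correlation_plan=[
        CorrelationSpec("pre-001", "gene-001", 1.0),
        CorrelationSpec("pre-002", "gene-002", -1.0),
    ])
    smrna, mrna, registry = simulate_expression(config)
    rho_pos = spearmanr(smrna.loc["pre-001"], mrna.loc["gene-001"]).statistic
    rho_neg = spearmanr(smrna.loc["pre-002"], mrna.loc["gene-002"]).statistic
    assert rho_pos == 1.0
    assert rho_neg == -1.0
    assert set(registry["sign"]) == {"positive", "negative"}


def test_copula_hits_target_rho_on_average():
    """Mean sample Spearman at rho=0.9, n=9 vs a Monte-Carlo oracle
    built on an independent rank routine (scipy.stats.spearmanr)."""
    rng = np.random.default_rng(5)
    r = 2 * np.sin(np.pi * 0.9 / 6)
    oracle = []
    for _ in range(500):
        z1 = rng.standard_normal(9)
        z2 = r * z1 + np.sqrt(1 - r * r) * rng.standard_normal(9)
        oracle.append(spearmanr(z1, z2).statistic)
    sampled = []
    for seed in range(500):
        config = SimulationConfig(rng_seed=seed, n_genes=1, correlation_plan=[
            CorrelationSpec("pre-001", "gene-001", 0.9)])
        smrna, mrna, _ = simulate_expression(config)
        sampled.append(
            spearmanr(smrna.loc["pre-001"], mrna.loc["gene-001"]).statistic)
    assert abs(np.mean(sampled) - np.mean(oracle)) < 0.05


def test_size_factor_plan_scales_columns():
    plan = [1.0, 2.0, 0.5, 1.0, 1.0, 1.5, 1.0, 1.0, 1.0]
    config = SimulationConfig(rng_seed=3, n_genes=50, size_factor_plan=plan)
    _, mrna, _ = simulate_expression(config)
    config0 = SimulationConfig(rng_seed=3, n_genes=50)
    _, mrna0, _ = simulate_expression(config0)
    ratio = mrna.sum(axis=0) / mrna0.sum(axis=0)
    assert np.allclose(ratio.to_numpy(), plan, rtol=0.05)


def test_invalid_rho_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(correlation_plan=[CorrelationSpec("a", "b", 1.2)])


# ------------------------------------------------------------------ GO fixture

def test_go_fixture_cycle_detection():
    config = SimulationConfig(rng_seed=1)
    with pytest.raises(ValueError, match="cycle"):
        generate_go_fixture(config, edges=[("GO:1", "GO:2"), ("GO:2", "GO:1")])


def test_planted_enrichment_is_detectable(tmp_path):
    from dinosmrna.go_enrichment import fisher_term, load_and_propagate

    significant = 0
    n_rep = 50
    for seed in range(n_rep):
        config = SimulationConfig(rng_seed=seed)
        fx = generate_go_fixture(config, n_population=1000, study_size=50,
                                 odds_ratio=10.0)
        obo = tmp_path / f"o{seed}.obo"
        ann = tmp_path / f"a{seed}.tsv"
        obo.write_text(fx.obo_text)
        fx.annotations.to_csv(ann, sep="\t", index=False, header=False)
        dag = load_and_propagate(str(obo), str(ann))
        res = fisher_term(fx.enriched_term, dag.term_genes[fx.enriched_term],
                          fx.study, fx.population)
        significant += res.p_value < 0.05
    assert significant / n_rep >= 0.9
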