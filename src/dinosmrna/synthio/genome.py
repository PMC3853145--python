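"""Embedding of planted hairpins in a synthetic genome with gene models.

Precursors are placed at non-overlapping loci on an i.i.d. random
background, either inside the intron of an annotated two-exon gene or
intergenically. Every planted hairpin is validated exactly as the
discovery stage will see it — both 90-nt candidate windows anchored at
the guide read are folded with the reference engine and checked
against the duplex-geometry, MFE, and classification criteria — and
resampled until the planted truth's contract holds (for ``weak_fold``
specs the contract is inverted: the fold must *fail* the MFE
criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._seq import random_seq
from ..fold import FoldingEngine, default_engine, duplex_overhangs, duplex_mismatch_count
from ..io import GFF3_COLUMNS
from .config import PlantedPrecursor, PlantedTruth, PrecursorSpec, SimulationConfig
from .precursor import build_precursor

_MAX_ATTEMPTS = 400
_FLANK = 10   # nt kept on each side of a planted hairpin inside its block


@dataclass
class GenomeResult:
    genome: dict[str, str]
    annotation: pd.DataFrame   # GFF3 table, 1-based inclusive
    truth: PlantedTruth


def _window_report(
    window: str,
    guide_off: int,
    spec: PrecursorSpec,
    loop_len: int,
    engine: FoldingEngine,
) -> tuple[bool, bool, int, float, str]:
    """Fold one candidate window and read off (overhang_ok, mfe_ok,
    duplex_mismatches, mfe, structure) at the planted arm intervals."""
    L = spec.guide_len
    guide = (guide_off, guide_off + L)
    star = (guide_off + L + loop_len, guide_off + 2 * L + loop_len)
    structure, mfe = engine.fold(window)
    overhangs = duplex_overhangs(structure, guide, star)
    overhang_ok = overhangs is not None and all(o == 2 for o in overhangs)
    mm = duplex_mismatch_count(window, structure, guide, star, overhang=spec.overhang)
    return overhang_ok, mfe < -25.0, mm, mfe, structure


def _try_build_block(
    spec: PrecursorSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    engine: FoldingEngine,
    max_precursor: int = 90,
) -> tuple[str, PlantedPrecursor] | None:
    """One attempt at flank + hairpin + flank; None when the folded
    windows do not honour the spec's contract."""
    loop_len = (
        spec.loop_len
        if spec.loop_len is not None
        else int(rng.integers(config.loop_len_range[0], config.loop_len_range[1] + 1))
    )
    gc = 0.15 if spec.weak_fold else spec.gc
    mismatches = 6 if spec.weak_fold else spec.duplex_mismatches
    kind = "miRNA" if spec.weak_fold else spec.kind
    guide = random_seq(rng, spec.guide_len, gc=gc)
    try:
        hairpin = build_precursor(
            guide, kind, loop_len, mismatches, rng=rng,
            overhang=spec.overhang, length_range=config.precursor_len_range,
        )
    except ValueError:
        return None
    plen = len(hairpin.sequence)
    pre = random_seq(rng, _FLANK + (max_precursor - plen), gc=config.background_gc)
    post = random_seq(rng, _FLANK + (max_precursor - plen), gc=config.background_gc)
    block = pre + hairpin.sequence + post
    offset = len(pre)

    # Window 1: guide read as 5' arm; window 2: star-cluster window
    # ending at the precursor 3' terminus.
    w1 = block[offset:offset + max_precursor]
    w2 = block[offset + plen - max_precursor:offset + plen]
    reports = [
        _window_report(w1, 0, spec, loop_len, engine),
        _window_report(w2, max_precursor - plen, spec, loop_len, engine),
    ]
    for overhang_ok, mfe_ok, mm, _, _ in reports:
        if spec.weak_fold:
            if mfe_ok:          # must fail the MFE criterion in every window
                return None
            continue
        if spec.overhang == 2 and not overhang_ok:
            return None
        if spec.overhang != 2 and overhang_ok:
            return None         # blunt-duplex spec must fail the overhang check
        if not mfe_ok:
            return None
        if (mm == 0) != (spec.kind == "siRNA"):
            return None

    planted = PlantedPrecursor(
        spec=spec,
        locus=("chr1", -1, -1, "+"),    # filled at assembly
        sequence=hairpin.sequence,
        structure=hairpin.structure,
        guide_arm=hairpin.guide_arm,
        star_arm=hairpin.star_arm,
        loop=hairpin.loop,
        guide_seq=hairpin.arm_seq(hairpin.guide_arm),
        star_seq=hairpin.arm_seq(hairpin.star_arm),
        mfe=reports[0][3],
    )
    return block, planted


def _build_block(spec, config, rng, engine) -> tuple[str, PlantedPrecursor]:
    for _ in range(_MAX_ATTEMPTS):
        result = _try_build_block(spec, config, rng, engine)
        if result is not None:
            return result
    raise RuntimeError(f"could not construct a valid hairpin for {spec.id}")


def plant_genome(
    config: SimulationConfig,
    engine: FoldingEngine | None = None,
) -> GenomeResult:
    """Emit a genome FASTA dict, a GFF3 annotation table, and the truth
    registry with exact planted-locus coordinates."""
    engine = engine or default_engine()
    rng = config.rng("genome")
    specs = (config.precursor_specs if config.precursor_specs is not None
             else config.default_precursor_specs())
    intron_specs = [s for s in specs if s.context == "intron"]
    intergenic_specs = [s for s in specs if s.context != "intron"]

    truth = PlantedTruth()
    parts: list[str] = []
    features: list[dict] = []
    cursor = 0

    def emit(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    def gap() -> None:
        emit(random_seq(rng, int(rng.integers(60, 120)), gc=config.background_gc))

    def feature(ftype, start, end, strand, attrs) -> None:
        features.append({
            "seqid": "chr1", "source": "synthio", "type": ftype,
            "start": start + 1, "end": end, "score": ".",
            "strand": strand, "phase": ".", "attributes": attrs,
        })

    intron_iter = iter(intron_specs)
    for g in range(config.n_genes):
        gap()
        gene_start = cursor
        exon1 = emit(random_seq(rng, 120, gc=config.background_gc))
        spec = next(intron_iter, None)
        intron_start = cursor
        if spec is not None:
            pad = random_seq(rng, 20, gc=config.background_gc)
            block, planted = _build_block(spec, config, rng, engine)
            emit(pad)
            block_start = emit(block)
            prec_start = block_start + _FLANK + (90 - len(planted.sequence))
            planted.locus = ("chr1", prec_start, prec_start + len(planted.sequence), "+")
            truth.add_precursor(planted)
            emit(random_seq(rng, 20, gc=config.background_gc))
        else:
            emit(random_seq(rng, 150, gc=config.background_gc))
        intron_end = cursor
        exon2 = emit(random_seq(rng, 120, gc=config.background_gc))
        gene_end = cursor
        gid = f"sgene-{g + 1:03d}"
        strand = "+" if g % 2 == 0 else "-"
        feature("gene", gene_start, gene_end, strand, f"ID={gid}")
        feature("exon", exon1, exon1 + 120, strand, f"Parent={gid}")
        feature("intron", intron_start, intron_end, strand, f"Parent={gid}")
        feature("exon", exon2, exon2 + 120, strand, f"Parent={gid}")

    remaining = list(intron_iter)
    if remaining:
        raise ValueError(
            f"{len(remaining)} intron-context precursors but only "
            f"{config.n_genes} genes")

    for spec in intergenic_specs:
        gap()
        block, planted = _build_block(spec, config, rng, engine)
        block_start = emit(block)
        prec_start = block_start + _FLANK + (90 - len(planted.sequence))
        planted.locus = ("chr1", prec_start, prec_start + len(planted.sequence), "+")
        truth.add_precursor(planted)
    gap()

    if cursor > config.genome_len:
        raise ValueError(
            f"genome_len={config.genome_len} too short: need {cursor} nt "
            "to place all loci without overlap")
    parts.append(random_seq(rng, config.genome_len - cursor, gc=config.background_gc))
    genome = {"chr1": "".join(parts)}

    for planted in truth.precursors.values():
        _, lo, hi, _ = planted.locus
        feature("smrna_precursor", lo, hi, "+", f"ID={planted.spec.id}")
        assert genome["chr1"][lo:hi] == planted.sequence

    annotation = pd.DataFrame(features, columns=GFF3_COLUMNS)
    return GenomeResult(genome=genome, annotation=annotation, truth=truth)
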