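"""Planting of animal-like seed sites and plant-like near-perfect
sites in synthetic 3'UTR and CDS backgrounds.

Backgrounds are scrubbed of accidental matches before insertion: any
reverse-complement seed (smRNA nt 2-7) occurrence and any full-length
window within 4 mismatches of a planted smRNA is mutated away, so that
roundtrip assertions on the planted registry are exact. After
insertion every planted site is re-verified with the downstream
scanners; flanking bases are resampled on the rare occasion an
insertion creates a spurious neighbouring match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import DNA, complement, encode, random_seq, revcomp, to_dna
from ..target_animal import find_seed_sites
from ..target_plant import _window_mismatches
from .config import PlantedSiteSpec, SimulationConfig

_MAX_ATTEMPTS = 50
_SCRUB_MM = 4   # near-match scrub radius for full-length plant-like windows


@dataclass
class PlantedSiteRecord:
    smrna_id: str
    gene_id: str
    region: str
    position: int                 # seed-match start (animal) / window start (plant)
    site_class: str | None = None
    mismatch_count: int | None = None


@dataclass
class TargetFixture:
    utrs: dict[str, str] = field(default_factory=dict)
    cds: dict[str, str] = field(default_factory=dict)
    registry: list[PlantedSiteRecord] = field(default_factory=list)

    def region_seq(self, gene_id: str, region: str) -> str:
        store = self.utrs if region == "UTR3" else self.cds
        return store[gene_id]

    def genes(self) -> dict[tuple[str, str], str]:
        out = {(g, "UTR3"): s for g, s in self.utrs.items()}
        out.update({(g, "CDS"): s for g, s in self.cds.items()})
        return out


def scrub_background(
    seq: str, smrnas: dict[str, str], rng: np.random.Generator,
    scrub_mm: int = _SCRUB_MM,
) -> str:
    """Mutate away accidental seed matches and near-full-length matches
    for every smRNA (both handled iteratively until clean)."""
    chars = list(to_dna(seq))
    for _ in range(100):
        dirty = False
        text = "".join(chars)
        for smrna in smrnas.values():
            s = to_dna(smrna)
            motif = revcomp(s[1:7])
            pos = text.find(motif)
            while pos != -1:
                i = pos + 3
                chars[i] = rng.choice([b for b in DNA if b != chars[i]])
                dirty = True
                text = "".join(chars)
                pos = text.find(motif, pos + 1)
            qrc = revcomp(s)
            if len(text) >= len(qrc):
                mm = _window_mismatches(encode(qrc), encode(text))
                for w in np.nonzero(mm <= scrub_mm)[0]:
                    need = scrub_mm + 1 - mm[w]
                    matching = [k for k in range(len(qrc))
                                if chars[w + k] == qrc[k]]
                    for k in rng.choice(matching, size=need, replace=False):
                        chars[w + k] = rng.choice([b for b in DNA if b != qrc[k]])
                    dirty = True
                    text = "".join(chars)
        if not dirty:
            return text
    raise RuntimeError("background scrubbing did not converge")


def _animal_site_block(smrna: str, site_class: str, rng: np.random.Generator) -> str:
    """8-nt target block [m8 context][seed match][A1 context]."""
    s = to_dna(smrna)
    motif = revcomp(s[1:7])
    m8 = complement(s[7])
    if site_class in ("8mer", "7mer-m8"):
        x = m8
    else:
        x = rng.choice([b for b in DNA if b != m8])
    if site_class in ("8mer", "7mer-A1"):
        y = "A"
    else:
        y = rng.choice([b for b in DNA if b != "A"])
    return x + motif + y


def _plant_site_block(smrna: str, mismatches: int, rng: np.random.Generator) -> str:
    site = list(revcomp(to_dna(smrna)))
    if not 0 <= mismatches <= 4:
        raise ValueError("plant-like mismatch_count must be in 0..4")
    if mismatches:
        idx = rng.choice(np.arange(1, len(site) - 1), size=mismatches, replace=False)
        for k in idx:
            site[k] = rng.choice([b for b in DNA if b != site[k]])
    return "".join(site)


def plant_target_sites(
    config: SimulationConfig,
    smrnas: dict[str, str],
    specs: list[PlantedSiteSpec] | None = None,
) -> TargetFixture:
    """Generate scrubbed UTR/CDS backgrounds and insert the requested
    sites; the registry records the exact position and class of each."""
    rng = config.rng("targets")
    specs = specs if specs is not None else config.planted_sites
    fixture = TargetFixture()
    gene_ids = [f"gene-{i + 1:03d}" for i in range(config.n_genes)]
    for gid in gene_ids:
        fixture.utrs[gid] = scrub_background(
            random_seq(rng, config.utr_len, gc=config.background_gc), smrnas, rng)
        fixture.cds[gid] = scrub_background(
            random_seq(rng, config.cds_len, gc=config.background_gc), smrnas, rng)

    for spec in specs:
        if spec.gene_id not in gene_ids:
            raise ValueError(f"unknown gene {spec.gene_id}")
        store = fixture.utrs if spec.region == "UTR3" else fixture.cds
        seq = store[spec.gene_id]
        smrna = to_dna(smrnas[spec.smrna_id])
        for attempt in range(_MAX_ATTEMPTS):
            if spec.site_class is not None:
                block = _animal_site_block(smrna, spec.site_class, rng)
                # Block spans [p-1, p+7) around the seed-match start p.
                p = (spec.position if spec.position is not None
                     else int(rng.integers(1, len(seq) - 7)))
                if p < 1 or p + 7 > len(seq):
                    raise ValueError(
                        f"site at {p} would truncate at a sequence boundary")
                candidate = seq[:p - 1] + block + seq[p + 7:]
                before = {s.utr_position for s in find_seed_sites(smrna, seq)}
                after = {s.utr_position: s.site_class
                         for s in find_seed_sites(smrna, candidate)}
                if (set(after) == before | {p}
                        and after.get(p) == spec.site_class):
                    store[spec.gene_id] = candidate
                    fixture.registry.append(PlantedSiteRecord(
                        spec.smrna_id, spec.gene_id, spec.region, p,
                        site_class=spec.site_class))
                    break
            else:
                block = _plant_site_block(smrna, spec.mismatch_count, rng)
                L = len(block)
                p = (spec.position if spec.position is not None
                     else int(rng.integers(0, len(seq) - L + 1)))
                if p < 0 or p + L > len(seq):
                    raise ValueError(
                        f"site at {p} would truncate at a sequence boundary")
                candidate = seq[:p] + block + seq[p + L:]
                qrc = encode(revcomp(smrna))
                before_hits = set(np.nonzero(
                    _window_mismatches(qrc, encode(seq)) <= _SCRUB_MM)[0].tolist())
                mm = _window_mismatches(qrc, encode(candidate))
                after_hits = set(np.nonzero(mm <= _SCRUB_MM)[0].tolist())
                if (after_hits == before_hits | {p}
                        and mm[p] == spec.mismatch_count):
                    store[spec.gene_id] = candidate
                    fixture.registry.append(PlantedSiteRecord(
                        spec.smrna_id, spec.gene_id, spec.region, p,
                        mismatch_count=spec.mismatch_count))
                    break
        else:
            raise RuntimeError(f"could not plant site for {spec.smrna_id}")
    return fixture
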