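"""Animal-like target prediction: seed matching in 3'UTRs with
accessibility-corrected binding energies.

A site is an exact reverse-complement match of the smRNA seed
(nucleotides 2-7) in a 3'UTR, classified into the canonical site types:

* 8mer     — seed match + complement of smRNA nt 8 + target adenine
             opposite smRNA nt 1,
* 7mer-m8  — seed match + position-8 complement only,
* 7mer-A1  — seed match + target adenine only,
* 6mer     — bare seed match (reported but non-canonical).

Binding is scored PITA-style: ddG = dG_duplex - dG_open, where
dG_duplex is the hybridization energy of the whole smRNA against the
target span and dG_open (<= 0) is the ensemble free energy the target
window must forfeit to expose the span (window = site +/- 70 nt).
Sites with ddG < -10 kcal/mol are retained, and genes with multiple
sites are aggregated with a log-mean-exp score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy.special import logsumexp

from ._seq import complement, revcomp, to_dna, to_rna

CANONICAL_CLASSES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass
class TargetSite:
    smrna_id: str
    gene_id: str
    utr_position: int          # 0-based start of the 6-nt seed match
    site_class: str            # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    dg_duplex: float | None = None
    dg_open: float | None = None
    ddg: float | None = None

    @property
    def canonical(self) -> bool:
        return self.site_class in CANONICAL_CLASSES


@dataclass
class GeneTargetScore:
    smrna_id: str
    gene_id: str
    n_sites: int
    ddg_score: float


class EnergyEngine(Protocol):
    def duplex_energy(self, smrna: str, target: str) -> float: ...

    def opening_energy(self, window: str, site_start: int, site_end: int) -> float: ...


class ViennaEnergyEngine:
    """RNAduplex hybridization + constrained-partition-function opening.

    ``opening_energy`` returns F(window) - F(window | site unpaired),
    which is <= 0: the ensemble free energy forfeited when the site is
    forced open.
    """

    def duplex_energy(self, smrna: str, target: str) -> float:
        import RNA

        duplex = RNA.duplexfold(to_rna(smrna), to_rna(target))
        return float(duplex.energy)

    def opening_energy(self, window: str, site_start: int, site_end: int) -> float:
        import RNA

        rna = to_rna(window)
        fc_free = RNA.fold_compound(rna)
        _, mfe = fc_free.mfe()
        fc_free.exp_params_rescale(mfe)
        _, f_free = fc_free.pf()

        fc_open = RNA.fold_compound(rna)
        for pos in range(site_start + 1, site_end + 1):  # 1-based
            fc_open.hc_add_up(pos, RNA.CONSTRAINT_CONTEXT_ALL_LOOPS)
        _, mfe_open = fc_open.mfe()
        fc_open.exp_params_rescale(mfe_open)
        _, f_open = fc_open.pf()
        return min(float(f_free) - float(f_open), 0.0)


class TableEnergyEngine:
    """Lookup-table engine for unit tests independent of thermodynamic
    parameter sets: energies keyed by (smrna, target) / window spans."""

    def __init__(
        self,
        duplex: dict[tuple[str, str], float] | None = None,
        opening: dict[str, float] | None = None,
        default_duplex: float = -20.0,
        default_open: float = 0.0,
    ):
        self.duplex = duplex or {}
        self.opening = opening or {}
        self.default_duplex = default_duplex
        self.default_open = default_open

    def duplex_energy(self, smrna: str, target: str) -> float:
        return self.duplex.get((to_dna(smrna), to_dna(target)), self.default_duplex)

    def opening_energy(self, window: str, site_start: int, site_end: int) -> float:
        return self.opening.get(to_dna(window), self.default_open)


def find_seed_sites(
    smrna: str, utr: str, smrna_id: str = "", gene_id: str = ""
) -> list[TargetSite]:
    """All exact reverse-complement seed (smRNA nt 2-7) matches in a UTR.

    Overlapping matches are all reported. Classification reads the
    target base immediately 5' of the seed match (opposite smRNA nt 8)
    and the base immediately 3' of it (opposite smRNA nt 1, the
    adenine-anchor position).
    """
    s = to_dna(smrna)
    if len(s) < 8:
        raise ValueError("smRNA shorter than 8 nt")
    u = to_dna(utr)
    motif = revcomp(s[1:7])           # target-strand seed match, 5'->3'
    m8_base = complement(s[7])        # expected target base 5' of the match
    sites: list[TargetSite] = []
    pos = u.find(motif)
    while pos != -1:
        has_m8 = pos - 1 >= 0 and u[pos - 1] == m8_base
        has_a1 = pos + 6 < len(u) and u[pos + 6] == "A"
        if has_m8 and has_a1:
            cls = "8mer"
        elif has_m8:
            cls = "7mer-m8"
        elif has_a1:
            cls = "7mer-A1"
        else:
            cls = "6mer"
        sites.append(TargetSite(smrna_id, gene_id, pos, cls))
        pos = u.find(motif, pos + 1)
    return sites


def target_span(smrna: str, utr: str, site: TargetSite) -> tuple[int, int]:
    """Target interval opposite the full smRNA, truncated at UTR bounds.

    With the seed match starting at p, smRNA nt 1 faces p+6 and nt L
    faces p+7-L, so the untruncated span is [p+7-L, p+7).
    """
    length = len(smrna)
    p = site.utr_position
    return max(0, p + 7 - length), min(len(utr), p + 7)


def site_energy(
    smrna: str,
    utr: str,
    site: TargetSite,
    engine: EnergyEngine,
    flank: int = 70,
) -> TargetSite:
    """Fill in dG_duplex, dG_open, and ddG for one site (in place)."""
    u = to_dna(utr)
    lo, hi = target_span(smrna, u, site)
    if not (0 <= site.utr_position and site.utr_position + 6 <= len(u)):
        raise ValueError("site outside UTR")
    wlo, whi = max(0, lo - flank), min(len(u), hi + flank)
    try:
        site.dg_duplex = engine.duplex_energy(smrna, u[lo:hi])
        site.dg_open = engine.opening_energy(u[wlo:whi], lo - wlo, hi - wlo)
    except Exception as exc:
        raise RuntimeError(
            f"energy engine failed for {site.smrna_id} @ {site.gene_id}:"
            f"{site.utr_position}: {exc}"
        ) from exc
    site.ddg = site.dg_duplex - site.dg_open
    return site


def filter_sites(sites: Sequence[TargetSite], ddg_max: float = -10.0) -> list[TargetSite]:
    """Retain sites with ddG strictly below the cutoff (-10 kcal/mol)."""
    return [s for s in sites if s.ddg is not None and s.ddg < ddg_max]


def gene_score(
    sites: Sequence[TargetSite], mean_normalized: bool = True
) -> GeneTargetScore:
    """Aggregate the retained sites of one (smRNA, gene) pair.

    ddG_score = -ln( (1/n) sum_i exp(-ddG_i) ): a smooth minimum that a
    single dominant site saturates; with ``mean_normalized=False`` the
    1/n factor is dropped (-ln sum exp(-ddG_i)).
    """
    if not sites:
        raise ValueError("empty site list")
    ddgs = np.array([s.ddg for s in sites], dtype=float)
    if np.any(np.isnan(ddgs)):
        raise ValueError("sites must carry ddG values")
    score = -logsumexp(-ddgs)
    if mean_normalized:
        score += np.log(len(ddgs))
    ids = {(s.smrna_id, s.gene_id) for s in sites}
    if len(ids) != 1:
        raise ValueError("sites must belong to a single (smRNA, gene) pair")
    smrna_id, gene_id = next(iter(ids))
    return GeneTargetScore(smrna_id, gene_id, len(ddgs), float(score))


def scan_transcriptome(
    smrnas: dict[str, str],
    utrs: dict[str, str],
    engine: EnergyEngine | None = None,
    flank: int = 70,
    ddg_max: float | None = -10.0,
) -> list[TargetSite]:
    """Seed-scan every (smRNA, UTR) pair; score and filter when an
    energy engine is supplied."""
    sites: list[TargetSite] = []
    for sid, smrna in smrnas.items():
        for gid, utr in utrs.items():
            found = find_seed_sites(smrna, utr, smrna_id=sid, gene_id=gid)
            if engine is not None:
                for site in found:
                    site_energy(smrna, utr, site, engine, flank=flank)
            sites.extend(found)
    if engine is not None and ddg_max is not None:
        sites = filter_sites(sites, ddg_max)
    return sites


def class_frequencies(sites: Sequence[TargetSite]) -> dict[str, int]:
    """Canonical site-class tally (6mer-only matches are excluded)."""
    out = {cls: 0 for cls in CANONICAL_CLASSES}
    for s in sites:
        if s.canonical:
            out[s.site_class] += 1
    return out
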