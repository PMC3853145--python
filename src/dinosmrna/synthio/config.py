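"""Simulation configuration and planted-truth containers.

The defaults encode the study conditions the rest of the package is
tested against: 21 hairpin precursors (8 mismatched-duplex miRNAs, 13
perfect-duplex siRNAs) of 84-90 nt with 21-22 nt guides, read pileups
over 9 experimental treatments, and 9-condition count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 9 experimental treatments (reference first).
CONDITIONS = ["noon", "4C", "16C", "34C", "36C", "20g", "60g", "DC", "DS"]

# Stage-specific RNG stream labels (one stream per output file family).
_STREAMS = {
    "genome": 1, "reads": 2, "targets": 3, "expression": 4, "go": 5,
}


@dataclass
class PrecursorSpec:
    """Per-precursor construction plan."""

    id: str
    kind: str = "siRNA"                  # "miRNA" | "siRNA"
    duplex_mismatches: int = 0           # 0 iff siRNA
    guide_len: int = 22
    loop_len: int | None = None          # drawn from config range when None
    gc: float = 0.6                      # guide/stem GC content
    overhang: int = 2                    # 3' overhang on both duplex ends
    context: str = "intergenic"          # "intergenic" | "intron"
    guide_conditions: list[str] | None = None   # None -> all conditions
    star_conditions: list[str] | None = None
    jitter5: dict[int, float] | None = None     # per-precursor override
    jitter3: dict[int, float] | None = None
    weak_fold: bool = False              # construct a candidate failing MFE < -25


@dataclass
class PlantedSiteSpec:
    """A target site to plant: animal-like (site_class) or plant-like
    (mismatch_count)."""

    smrna_id: str
    gene_id: str
    region: str = "UTR3"                 # "UTR3" | "CDS"
    site_class: str | None = None        # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    mismatch_count: int | None = None    # plant-like, 0..4
    position: int | None = None          # random when None


@dataclass
class CorrelationSpec:
    smrna_id: str
    gene_id: str
    target_rho: float                    # signed population Spearman


@dataclass
class SimulationConfig:
    rng_seed: int = 0
    n_precursors: int = 21
    n_mirna: int = 8                     # rest are siRNAs
    n_conditions: int = 9
    conditions: list[str] = field(default_factory=lambda: list(CONDITIONS))
    guide_len: int = 22
    loop_len_range: tuple[int, int] = (40, 46)
    precursor_len_range: tuple[int, int] = (84, 90)
    read_depth: float = 200.0            # mean guide reads per condition
    star_weight: float = 0.25
    loop_weight: float = 0.0
    terminal_jitter5: dict[int, float] = field(
        default_factory=lambda: {0: 0.95, 1: 0.05})
    terminal_jitter3: dict[int, float] = field(
        default_factory=lambda: {0: 0.70, 1: 0.15, 2: 0.10, 3: 0.05})
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    genome_len: int = 60_000
    background_gc: float = 0.5
    n_genes: int = 40
    utr_len: int = 300
    cds_len: int = 600
    planted_sites: list[PlantedSiteSpec] = field(default_factory=list)
    correlation_plan: list[CorrelationSpec] = field(default_factory=list)
    size_factor_plan: list[float] | None = None
    precursor_specs: list[PrecursorSpec] | None = None

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        if len(self.conditions) != self.n_conditions:
            self.conditions = self.conditions[: self.n_conditions]
            if len(self.conditions) != self.n_conditions:
                raise ValueError("conditions list shorter than n_conditions")
        if min(self.n_precursors, self.n_genes, self.guide_len) < 0:
            raise ValueError("counts must be non-negative")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        lo, hi = self.loop_len_range
        plo, phi = self.precursor_len_range
        if not (plo <= 2 * self.guide_len + lo and 2 * self.guide_len + hi <= phi):
            raise ValueError(
                "loop_len_range inconsistent with precursor_len_range: "
                f"{2 * self.guide_len + lo}..{2 * self.guide_len + hi} nt "
                f"vs allowed {plo}..{phi} nt")
        for spec in self.correlation_plan:
            if abs(spec.target_rho) > 1:
                raise ValueError(f"|target_rho| > 1 for {spec.smrna_id}/{spec.gene_id}")
        if self.size_factor_plan is not None:
            if len(self.size_factor_plan) != self.n_conditions:
                raise ValueError("size_factor_plan length != n_conditions")
            if any(s <= 0 for s in self.size_factor_plan):
                raise ValueError("size factors must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stage RNG stream derived from the master seed."""
        return np.random.default_rng([self.rng_seed, _STREAMS[stream]])

    def default_precursor_specs(self) -> list[PrecursorSpec]:
        """21 precursors: 8 miRNAs (1-3 duplex mismatches) then 13
        siRNAs; 3 of them intron-hosted, the rest intergenic."""
        specs = []
        for i in range(self.n_precursors):
            is_mirna = i < self.n_mirna
            specs.append(
                PrecursorSpec(
                    id=f"pre-{i + 1:03d}",
                    kind="miRNA" if is_mirna else "siRNA",
                    duplex_mismatches=(i % 3) + 1 if is_mirna else 0,
                    guide_len=self.guide_len,
                    context="intron" if i < 3 else "intergenic",
                )
            )
        return specs


@dataclass
class PlantedPrecursor:
    """Ground truth for one planted hairpin."""

    spec: PrecursorSpec
    locus: tuple[str, int, int, str]
    sequence: str
    structure: str
    guide_arm: tuple[int, int]
    star_arm: tuple[int, int]
    loop: tuple[int, int]
    guide_seq: str
    star_seq: str
    mfe: float


@dataclass
class PlantedTruth:
    """Machine-readable registry of everything the generator planted."""

    precursors: dict[str, PlantedPrecursor] = field(default_factory=dict)
    sites: list = field(default_factory=list)
    correlations: list = field(default_factory=list)
    expected_arm_counts: object = None   # DataFrame, filled by the read simulator

    def add_precursor(self, planted: PlantedPrecursor) -> None:
        if planted.spec.id in self.precursors:
            raise ValueError(f"duplicate precursor id {planted.spec.id}")
        self.precursors[planted.spec.id] = planted

    @property
    def guide_sequences(self) -> dict[str, str]:
        return {pid: p.guide_seq for pid, p in self.precursors.items()}
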