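# Methods

This note documents the models and procedures implemented in
`dinosmrna`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## smRNA discovery

Reads are preprocessed in the order: 3′ quality trimming (bases removed
until the terminal Phred score exceeds 20), whole-read mean-quality
filtering (mean Phred must exceed 20), 3′ adapter removal, and a
minimum-insert filter (18 nt). Adapter removal matches the adapter as a
prefix against every suffix of the read, allowing 10% mismatches with a
minimum overlap of 5 nt; reads without an adapter occurrence are kept
by default (a `discard_unmatched` flag inverts this). The 10%/5-nt
parameters are the package's own choice — standard trimmer defaults —
since only the trimming tool, not its settings, is fixed by convention.

Collapsed reads are removed when they occur as an exact substring, on
either strand, of a blacklist entry (rRNA/tRNA/snoRNA or mRNA contigs).
Counts are conserved: kept plus removed equals input, per condition.

Hairpin candidates are excised from clusters of stranded, ungapped
alignments (reads within 10 nt of each other cluster together). For
each cluster, two windows of `max_precursor` = 90 nt are anchored at
the dominant read's 5′ end — one treating the read as the prospective
5′ arm, one as the 3′ arm — deduplicated, and folded. The 90-nt cap
reflects the precursor-length ceiling of hairpin-based discovery at
these read lengths. Because the guide and star pileups of one hairpin
sit further apart than the clustering gap, a locus can surface as two
shifted windows; validated records are therefore deduplicated on the
genomic interval of the guide read (lowest MFE wins).

Validation criteria, each configurable:

* **5′ homogeneity** — at least 90% of an arm's reads (count-weighted,
  pooled over conditions) share the modal 5′ position, required on both
  arms. The qualitative criterion is a "distinct 5′ terminus"; the 90%
  quantification is this package's operationalization.
* **Duplex overhang** — the guide/star duplex must carry a 2-nt 3′
  overhang on both ends, read from the fold's pair table at the
  read-defined arm intervals (scanning past terminal mismatches to the
  first inter-arm pair).
* **MFE** — fold-back minimum free energy strictly below
  −25 kcal mol⁻¹.
* **Cross-condition support** — guide detected (count ≥ 1 after
  collapsing) in ≥7 conditions, star in ≥2. "Detected" is a count of
  at least one read because validated catalogs contain star strands
  supported by as few as 2 reads in total.

Loop-derived read counts are reported in the criteria report but not
thresholded; the presence or absence of loop products is informative
about the dicing mechanism but no accepted cutoff exists.

Classification: a candidate is an siRNA iff every guide-arm position
outside the 2-nt overhang is Watson–Crick paired into the star arm
(wobble pairs count as mismatches, since duplex complementarity is a
sequence-level notion); otherwise it is a miRNA.

Folding engines are injectable. The reference engine is ViennaRNA's
nearest-neighbor MFE fold; the fallback is a Nussinov
base-pair-maximization dynamic program (minimum loop 3 nt, −1 per pair
as a surrogate energy) which satisfies the same structural contract
and is verified against exhaustive enumeration in tests. Signal-to-noise
screening against a shuffled genome is available in principle by
running discovery on a dinucleotide-shuffled background; it is not a
validation criterion here.

Genomic-context classification assigns each aligned read one category
with precedence exon > intron > repeat > other; within a feature type
a sense overlap outranks antisense. Fractions are count-weighted and
sum to 1.

Coordinates are 0-based half-open internally; GFF3 is read and written
1-based inclusive. All sequence matching is performed on an uppercase
DNA alphabet; U↔T conversion happens at I/O boundaries.

## Animal-like target prediction

A site is an exact reverse-complement match of the smRNA seed
(nucleotides 2–7) in a 3′UTR; overlapping matches all count. The target
base immediately 5′ of the match (opposite smRNA nt 8) and the base
immediately 3′ of it (opposite nt 1) determine the class: both → 8mer,
position-8 complement only → 7mer-m8, adenine only → 7mer-A1, neither →
6mer. The 7mer-A1 test demands adenine in the mRNA regardless of the
smRNA's own nt 1, following the empirical adenine-anchor convention.
6mer-only matches are excluded from canonical tallies. A site
satisfying both auxiliary conditions is always 8mer — classes are
mutually exclusive by construction.

Energies follow the PITA accessibility framework. ΔG_duplex is the
hybridization energy of the **whole** smRNA against the target span
(the interval opposite the full smRNA, truncated at UTR boundaries).
ΔG_open is defined here as F(window) − F(window | site unpaired) over a
window of the site ±70 nt: the ensemble free energy the mRNA forfeits
when the site is forced open. Under this sign convention ΔG_open ≤ 0,
ΔΔG = ΔG_duplex − ΔG_open, a structured context makes ΔΔG *less*
negative, and an unstructured context gives ΔΔG ≈ ΔG_duplex. Sites with
ΔΔG < −10 kcal mol⁻¹ are retained. The energy engine is injectable; a
lookup-table engine keeps unit tests independent of thermodynamic
parameter versions.

Multi-site genes are aggregated as
ΔΔG_score = −ln((1/n) Σᵢ e^(−ΔΔGᵢ)), computed with a numerically
stable log-sum-exp. This is a smooth minimum: it equals the single
site's ΔΔG at n = 1, equals the common value for equal sites, and
approaches min ΔΔGᵢ as one site dominates (bounded between min ΔΔGᵢ
and min ΔΔGᵢ + ln n). The published formula for this aggregation is
typographically ambiguous about the 1/n factor; the mean-normalized
reading keeps the score on the same scale as per-site ΔΔG (matching
the magnitude of reported gene-level scores), and the un-normalized
variant −ln Σ e^(−ΔΔGᵢ) is available behind `mean_normalized=False`.

## Plant-like target prediction

Every ungapped full-length window whose reverse complement differs
from the smRNA at ≤ `max_mm` positions (default 3) is a hit, over both
CDS and 3′UTR. Only antisense windows qualify; a window identical to
the smRNA in sense orientation is not a hit. G:U wobbles count as
mismatches (alignment is sequence-level); a wobble-tolerant mode is
deliberately absent by default. The scan is a vectorized sliding-window
Hamming comparison validated against an exhaustive per-window oracle
in tests.

The false-positive null draws cohorts with the native set's
cardinality and length multiset, sequences i.i.d. from the pooled
mononucleotide composition ("same overall base composition"); a
dinucleotide-preserving shuffle mode is provided as an option. For
each mismatch cutoff the estimator reports the mean random hit count
per cohort, the real:random ratio, and the closed-form expectation for
i.i.d. uniform targets, Σ_{j≤mm} C(L,j)(3/4)^j(1/4)^(L−j) per window
(≈2.486×10⁻⁹ at L = 22, mm = 3) — the analytic cross-check holds for
any query composition because the per-position match probability
against a uniform target is 1/4 regardless of the query base.
Corpus-specific ratios depend on the gene set scanned and are not
portable between corpora.

## Expression

Quantification assigns a collapsed read to an smRNA when it equals the
mature sequence optionally extended by up to 1 templated nucleotide at
the 5′ end and up to 3 at the 3′ end (resolved against the smRNA's
genomic context; extensions without context raise an error). Reads
matching several smRNAs count for all of them and are flagged.

Size factors are the DESeq median-of-ratios estimator:
s_j = median over all-positive rows of k_ij / (Π_v k_iv)^(1/m). Rows
with any zero are excluded from the reference; if no all-positive row
exists the error message suggests the pseudocount option. One exact
consequence worth noting: multiplying a column by c rescales the
geometric-mean reference too, so s_j itself gains c^((m−1)/m) while
every other factor gains c^(−1/m) — the invariant that holds exactly is
that *ratios* of size factors scale by c. After normalization the
median ratio of each column to the original reference is exactly 1 by
construction.

FPKM = count × 10⁹ / (length_bp × mapped_total). Spearman correlation
uses average ranks for ties (the conventional estimator) and is
computed for all smRNA×gene pairs via standardized rank inner products;
pairs with a constant profile are skipped rather than assigned ρ = 0.
Retention is a hard |ρ| > 0.8 threshold with no multiple-testing
control — the published analysis uses the same hard threshold without
P values, and the package follows it. Scaled (size-factor-normalized)
counts are the default correlation input; FPKM is supported.

## GO enrichment

The ontology is reduced to its is_a DAG (cycles are an error);
annotations are propagated to all ancestors. Per-term significance is
the one-sided hypergeometric tail P(X ≥ study_in). The elim pass
processes terms by decreasing depth (longest path from a root): when a
term's classic P < α, its study genes are removed from all ancestors
before those are tested. Only the study margin is reduced — the
population counts are left intact — which guarantees elim P ≥ classic
P for ancestors of significant terms and reduces exactly to classic
when nothing is significant (or α = 0). The weighted variant of the
decorrelation algorithm is not implemented; outputs are labelled
`elim`. P values are reported uncorrected: the conditional tests are
non-independent, so standard FDR machinery does not apply to them.
The three GO namespaces are handled independently.

## Synthetic data

The generator's defaults encode the study conditions used throughout
the tests: 21 precursors (8 miRNAs with 1–3 duplex mismatches, 13
perfect-duplex siRNAs; 3 intron-hosted, the rest intergenic), 22-nt
guides, loops drawn so precursors span 84–90 nt, 9 named treatment
conditions, a mean depth of 200 guide reads per condition with a star
weight of 0.25, terminal jitter of at most 1 nt (5′) and 3 nt (3′)
with the unjittered variant at 95%/70%, and the TruSeq small-RNA 3′
adapter. Guides default to GC 0.6 — stems of validated precursors are
GC-rich relative to background, and a ~20-bp duplex must clear the
−25 kcal mol⁻¹ bar. Backgrounds are i.i.d. uniform nucleotides with
configurable GC; no attempt is made to mimic Illumina error profiles,
real dinoflagellate genome composition, or minicircle biology, so
passing roundtrip tests demonstrate algorithmic correctness, not
robustness to sequencing artifacts or compositional bias.

Construction guarantees the planted truth's contract. Each hairpin is
assembled arm-by-arm (guide 5′ arm, antiparallel star arm, 2-nt 3′
overhangs, mismatches placed at internal positions with substitutions
that can pair neither Watson–Crick nor wobble) and then validated
exactly as discovery will see it: both 90-nt candidate windows are
folded with the reference engine and must pass the overhang, MFE, and
classification criteria; the construction is resampled otherwise.
Degraded specs invert the relevant check (a `weak_fold` spec must fail
the MFE bar in every window; a blunt spec must fail the overhang
check), so single-criterion perturbation tests are exact. Intron-hosted
precursors sit inside two-exon gene models; reads are emitted with
their genomic alignments resolved by construction (read mapping itself
is out of scope).

Target backgrounds are scrubbed before insertion: accidental seed
matches and full-length windows within 4 mismatches of any planted
smRNA are mutated away iteratively, making planted-site roundtrips
exact (0 false positives by construction). After insertion each site
is re-verified with the downstream scanners and flanks are resampled
on collision.

Planted correlations use a Gaussian copula: a latent bivariate normal
with Pearson r = 2 sin(πρ_s/6) has population Spearman ρ_s, giving
direct control of the planted value. Latent profiles are pushed
through a lognormal marginal (log-scale SD 0.8 around means of 200
smRNA / 500 mRNA counts) and integerized with a strictly
rank-preserving rounding, so |ρ| = 1 plans yield sample Spearman of
exactly ±1. Per-condition depth multipliers are applied after the
copula draw. Stage-level reproducibility comes from one RNG stream per
output family, derived from the master seed.

GO fixtures use a three-level DAG with 8 leaves; genes carry 1–2
random leaf annotations, and the study set is a sequential weighted
draw without replacement in which genes of the designated term carry
`odds_ratio` times the base weight (a Wallenius-type bias, default 10).

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by design:
synthetic genomes of 60 kb with 21 loci, 1,000 random 1-kb UTRs for
the seed-scan oracle, 200 random cohorts against 10⁵ scanning windows
for the false-positive null, 100 seeded replicates for correlation
recovery (with a 10⁵-draw permutation null), and 200 replicates for
enrichment power. All randomness flows from explicit seeds; identical
configuration and seed give byte-identical outputs.

## Known limitations

* Read mapping, transcriptome assembly, and differential-expression
  testing are out of scope; alignments enter as resolved coordinates
  and only the normalization half of the count-model machinery is
  implemented.
* The discovery stage assumes ungapped, stranded alignments and one
  dominant guide arm per locus; antisense overlapping precursor pairs
  would be reported as separate candidates.
* Opening energies use a hard ±70-nt window rather than a
  local-folding (RNAplfold-style) ensemble; for very long UTRs the
  window choice matters more than the engine.
* The elim pass follows the study-margin-only elimination described
  above; topGO's variants (which also prune the population margin, or
  down-weight rather than eliminate) give different ancestor P values
  on deeply nested signals.
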