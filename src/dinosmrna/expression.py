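"""Expression quantification, normalization, and smRNA-mRNA
correlation.

Count matrices are plain pandas DataFrames (rows = genes or smRNAs,
columns = conditions, non-negative integers). Normalization is the
DESeq median-of-ratios scheme: per-condition size factors are medians
of the ratios to per-row geometric means, computed over rows with no
zero count. smRNA and mRNA profiles are integrated by Spearman rank
correlation across conditions with a hard |rho| > 0.8 retention
threshold and no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._seq import to_dna


@dataclass
class NormalizationModel:
    size_factors: pd.Series    # per condition, > 0
    reference: pd.Series       # per-row geometric means (all-positive rows)


@dataclass
class GenomicContext:
    """A mature smRNA located in its precursor/genomic sequence, so that
    templated terminal extensions can be resolved."""

    sequence: str      # context sequence (precursor with flanks)
    start: int         # mature start within context
    end: int           # mature end (half-open)


def _tolerated_variants(ctx: GenomicContext, max_5p: int = 1, max_3p: int = 3) -> set[str]:
    seq = to_dna(ctx.sequence)
    variants = set()
    for d5 in range(max_5p + 1):
        for d3 in range(max_3p + 1):
            lo, hi = ctx.start - d5, ctx.end + d3
            if lo < 0 or hi > len(seq):
                if d5 > 0 or d3 > 0:
                    raise ValueError(
                        "genomic context too short for requested terminal extensions")
                continue
            variants.add(seq[lo:hi])
    return variants


def quantify_smrna(
    contexts: dict[str, GenomicContext],
    reads_by_condition: dict[str, dict[str, int]],
    conditions: list[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, list[str]]]]:
    """Count collapsed reads per smRNA with terminal-variant tolerance.

    A read is assigned to an smRNA when its sequence equals the mature
    sequence optionally extended by up to 1 templated nt at the 5' end
    and up to 3 at the 3' end. Reads matching several smRNAs are
    counted for all of them and reported in the ambiguity list.
    """
    conditions = conditions or sorted(reads_by_condition)
    variant_map: dict[str, list[str]] = {}
    for sid, ctx in contexts.items():
        for var in _tolerated_variants(ctx):
            variant_map.setdefault(var, []).append(sid)

    matrix = pd.DataFrame(0, index=list(contexts), columns=conditions, dtype=int)
    ambiguous: list[tuple[str, list[str]]] = []
    flagged: set[str] = set()
    for cond in conditions:
        for seq, count in reads_by_condition.get(cond, {}).items():
            owners = variant_map.get(to_dna(seq))
            if not owners:
                continue
            if len(owners) > 1 and seq not in flagged:
                flagged.add(seq)
                ambiguous.append((seq, sorted(owners)))
            for sid in owners:
                matrix.loc[sid, cond] += count
    return matrix, ambiguous


def size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> NormalizationModel:
    """DESeq geometric-mean (median-of-ratios) size factors.

    s_j = median over reference rows of k_ij / (prod_v k_iv)^(1/m);
    rows containing any zero are excluded from the reference.
    """
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    k = counts.astype(float) + pseudocount
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no row with all-positive counts; pass pseudocount > 0 to proceed")
    ref_rows = k.loc[positive]
    log_gm = np.log(ref_rows).mean(axis=1)
    reference = np.exp(log_gm)
    ratios = ref_rows.div(reference, axis=0)
    s = ratios.median(axis=0)
    return NormalizationModel(size_factors=s, reference=reference)


def normalize(counts: pd.DataFrame, model: NormalizationModel | None = None) -> pd.DataFrame:
    model = model or size_factors(counts)
    return counts.div(model.size_factors, axis=1)


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    mapped_total: pd.Series,
) -> pd.DataFrame:
    """FPKM = count * 1e9 / (transcript length in bp * mapped reads)."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("transcript lengths must be positive for all rows")
    mapped_total = mapped_total.reindex(counts.columns)
    if (mapped_total <= 0).any() or mapped_total.isna().any():
        raise ValueError("mapped totals must be positive for all conditions")
    return counts.mul(1e9).div(lengths, axis=0).div(mapped_total, axis=1)


def spearman_matrix(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho (average-rank ties) between the rows of two
    matrices sharing the same ordered condition columns.

    Constant rows produce NaN columns/rows (zero rank variance).
    """
    if list(a.columns) != list(b.columns):
        raise ValueError("matrices must share the same ordered condition set")
    n = a.shape[1]
    ra = rankdata(a.values, axis=1)
    rb = rankdata(b.values, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    sa = np.sqrt((ra ** 2).sum(axis=1))
    sb = np.sqrt((rb ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra @ rb.T) / np.outer(sa, sb)
    rho[sa == 0, :] = np.nan
    rho[:, sb == 0] = np.nan
    return pd.DataFrame(rho, index=a.index, columns=b.index)


def correlate_pairs(
    smrna: pd.DataFrame,
    mrna: pd.DataFrame,
    threshold: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every smRNA row with every mRNA row across conditions.

    Returns (records, summary): records has one row per retained pair
    (|rho| strictly > threshold) with columns smrna_id, gene_id, rho,
    sign; summary tallies negative/positive/total retained genes per
    smRNA. Pairs with a constant profile are skipped.
    """
    if smrna.shape[1] < 5:
        raise ValueError("need at least 5 shared conditions")
    rho = spearman_matrix(smrna, mrna)
    stacked = rho.stack(future_stack=True).rename("rho").reset_index()
    stacked.columns = ["smrna_id", "gene_id", "rho"]
    stacked = stacked.dropna(subset=["rho"])
    records = stacked[stacked["rho"].abs() > threshold].copy()
    records["sign"] = np.where(records["rho"] > 0, "positive", "negative")
    records = records.reset_index(drop=True)

    summary = (
        records.groupby("smrna_id")["sign"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(smrna.index, fill_value=0)
        .reindex(columns=["negative", "positive"], fill_value=0)
    )
    summary["total"] = summary["negative"] + summary["positive"]
    summary.index.name = "smrna_id"
    return records, summary
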