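"""Biology-facing eQTL statistics.

Local/distant classification (local = same chromosome and within 25 kb of the
gene start), hotspot detection (one variant associated with many genes),
counting summaries, enrichment of low-frequency variants among hits (Fisher's
exact test on the source-population MAF), generic categorical enrichment, and
effect-size comparisons between groups of eQTL (Mann-Whitney-Wilcoxon).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOCAL_WINDOW_BP = 25_000
LOWFREQ_MAF = 0.05
RARE_MAF = 0.01


@dataclass
class EnrichmentTable:
    """2x2 contingency table with fold enrichment, odds ratio and Fisher p.

    Rows are the two groups compared (e.g. hit vs non-hit variants), columns
    the category of interest vs the rest.  fold = (a/(a+b)) / (c/(c+d)) is
    the ratio of the two row rates; the odds ratio and two-sided p come from
    Fisher's exact test.
    """

    a: int
    b: int
    c: int
    d: int
    fold: float
    odds_ratio: float
    p_value: float
    label: str = ""


def enrichment_2x2(a: int, b: int, c: int, d: int, label: str = "") -> EnrichmentTable:
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("degenerate 2x2 table: empty row")
    rate1 = a / (a + b)
    rate2 = c / (c + d)
    fold = rate1 / rate2 if rate2 > 0 else float("inf")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentTable(a, b, c, d, fold, float(odds), float(p), label)


def classify_local_distant(
    eqtls: pd.DataFrame,
    gene_table: pd.DataFrame,
    window: int = LOCAL_WINDOW_BP,
) -> pd.DataFrame:
    """Attach gene coordinates and a locality label to each eQTL record.

    ``eqtls`` needs variant chrom/pos columns (``chrom``, ``pos``) and a
    ``trait_id`` naming the gene; ``gene_table`` has gene_id, chrom, start
    (rows with missing coordinates yield locality "unplaced", e.g. genes
    acquired by horizontal transfer with no reference position).
    local: same chromosome and |pos - gene_start| <= window.
    """
    genes = gene_table.set_index("gene_id")
    out = eqtls.copy()
    gene_chrom = out["trait_id"].map(genes["chrom"])
    gene_start = out["trait_id"].map(genes["start"])
    out["gene_chrom"] = gene_chrom
    out["gene_start"] = gene_start
    unplaced = gene_chrom.isna() | gene_start.isna()
    same = (out["chrom"].astype(str) == gene_chrom.astype(str)) & ~unplaced
    dist = (out["pos"].astype(float) - gene_start.astype(float)).abs()
    local = same & (dist <= window)
    out["locality"] = np.where(unplaced, "unplaced", np.where(local, "local", "distant"))
    return out


def detect_hotspots(eqtls: pd.DataFrame, min_genes: int = 20) -> pd.DataFrame:
    """Variants associated with at least ``min_genes`` distinct genes.

    Expects one row per (variant, gene) association (pruned eQTL set).
    """
    if len(eqtls) == 0:
        return pd.DataFrame(columns=["variant_id", "n_genes", "genes"])
    dedup = eqtls.drop_duplicates(subset=["variant_id", "trait_id"])
    grouped = dedup.groupby("variant_id")["trait_id"].agg(list)
    rows = [
        {"variant_id": v, "n_genes": len(gs), "genes": sorted(gs)}
        for v, gs in grouped.items()
        if len(gs) >= min_genes
    ]
    return (
        pd.DataFrame(rows, columns=["variant_id", "n_genes", "genes"])
        .sort_values("n_genes", ascending=False)
        .reset_index(drop=True)
    )


def summarize_counts(eqtls: pd.DataFrame) -> dict:
    """Headline counts: eQTL, genes, variants and the two mean ratios.

    Records are deduplicated on (variant, gene); eQTL-per-gene is
    n_eqtl/n_genes and genes-per-variant n_eqtl/n_unique_variants.
    """
    dedup = eqtls.drop_duplicates(subset=["variant_id", "trait_id"])
    n_eqtl = len(dedup)
    n_genes = dedup["trait_id"].nunique()
    n_variants = dedup["variant_id"].nunique()
    if n_eqtl == 0:
        logger.warning("summarize_counts: empty eQTL set")
        return {
            "n_eqtl": 0,
            "n_genes": 0,
            "n_unique_variants": 0,
            "eqtl_per_gene": 0.0,
            "genes_per_variant": 0.0,
        }
    return {
        "n_eqtl": n_eqtl,
        "n_genes": n_genes,
        "n_unique_variants": n_variants,
        "eqtl_per_gene": n_eqtl / n_genes,
        "genes_per_variant": n_eqtl / n_variants,
    }


def maf_enrichment(
    hit_variants: list[str] | pd.Series,
    tested_variants: pd.DataFrame,
    cutoff: float = LOWFREQ_MAF,
) -> EnrichmentTable:
    """Low-frequency enrichment of hit variants, on the SOURCE-population MAF.

    ``tested_variants`` is the variant metadata of every variant entering
    the scan, with a ``population_maf`` column (frequency in the natural
    source population, not the diallel panel — the diallel artificially
    raises the panel frequency of every parental allele).  The 2x2 compares
    hit vs non-hit variants split at MAF < cutoff.
    """
    if cutoff <= 0:
        raise ValueError("MAF cutoff must be positive (degenerate column otherwise)")
    maf = tested_variants.set_index("id")["population_maf"]
    if maf.isna().any():
        bad = list(maf.index[maf.isna()])[:5]
        raise ValueError(f"variants without population MAF: {bad}")
    hit_set = set(hit_variants)
    unknown = hit_set - set(maf.index)
    if unknown:
        raise ValueError(f"hit variants absent from tested set: {sorted(unknown)[:5]}")
    is_hit = maf.index.isin(hit_set)
    low = (maf < cutoff).to_numpy()
    a = int((is_hit & low).sum())
    b = int((is_hit & ~low).sum())
    c = int((~is_hit & low).sum())
    d = int((~is_hit & ~low).sum())
    return enrichment_2x2(a, b, c, d, label=f"MAF<{cutoff}")


def category_enrichment(
    in_set: pd.Series | list[str],
    labels: pd.Series,
) -> dict[str, EnrichmentTable]:
    """Per-category association-rate enrichment.

    ``labels`` maps every item (gene or variant id) to a category; ``in_set``
    lists the items associated with an eQTL.  For each category the 2x2 is
    rows (category, other categories) x columns (in set, not in set), so the
    fold is the ratio of association rates, e.g. accessory genes associated
    at 40.5% vs core genes at 26.9% gives fold ~1.51.
    """
    labels = pd.Series(labels)
    items_in = set(in_set)
    unknown = items_in - set(labels.index)
    if unknown:
        raise ValueError(f"items without category label: {sorted(unknown)[:5]}")
    out: dict[str, EnrichmentTable] = {}
    in_mask = labels.index.isin(items_in)
    for cat in labels.unique():
        m = (labels == cat).to_numpy()
        a = int((m & in_mask).sum())
        b = int((m & ~in_mask).sum())
        c = int((~m & in_mask).sum())
        d = int((~m & ~in_mask).sum())
        if c + d == 0:
            # single category covering everything: enrichment is 1 by definition
            out[cat] = EnrichmentTable(a, b, 0, 0, 1.0, 1.0, 1.0, str(cat))
            continue
        out[cat] = enrichment_2x2(a, b, c, d, label=str(cat))
    return out


def compare_effect_sizes(
    effects_a: np.ndarray, effects_b: np.ndarray
) -> dict:
    """Two-sided Mann-Whitney-Wilcoxon comparison of |beta| distributions.

    Exact enumeration when the pooled sample is small (<= 20, no ties);
    normal approximation with tie correction otherwise.  Also reports
    medians and quartiles per group.
    """
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    q = lambda x: dict(zip(("q1", "median", "q3"), np.percentile(x, [25, 50, 75])))
    return {
        "u_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "group_a": q(a),
        "group_b": q(b),
    }
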