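"""Expression phenotypes: TPM normalisation, trait filters and z-scoring.

Gene-level read counts are converted to transcripts per million (TPM):

    tpm_g = 1e6 * (c_g / l_g) / sum_j (c_j / l_j)

per hybrid, where c is the read count and l the annotated gene length.
Accessory genes (ORFs variably present across isolates) that are absent from
a hybrid but have a reference-genome ortholog get their reads re-attributed
to the ortholog before normalisation.  Traits enter association as per-gene
z-scores (sample SD, n-1 convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Genes x hybrids read counts with gene metadata.

    ``genes`` is a DataFrame with columns gene_id, length and optionally
    accessory (bool) and ortholog (reference counterpart of an accessory
    gene).  ``present`` (genes x hybrids bool) flags per-hybrid gene
    presence; None means all present.
    """

    genes: pd.DataFrame
    hybrids: list[str]
    counts: np.ndarray
    present: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.hybrids)):
            raise ValueError("counts shape does not match genes x hybrids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.genes["length"].to_numpy() <= 0).any():
            raise ValueError("gene lengths must be positive")


@dataclass
class TraitMatrix:
    """Genes x hybrids trait values at a named processing stage."""

    gene_ids: list[str]
    hybrids: list[str]
    values: np.ndarray
    stage: str  # tpm | log2tpm1 | zscore

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.hybrids)):
            raise ValueError("values shape does not match genes x hybrids")


def merge_accessory_counts(cm: CountMatrix) -> CountMatrix:
    """Re-attribute reads of absent accessory genes to their orthologs.

    For each hybrid where an accessory gene with a reference ortholog is
    flagged absent, its counts are added to the ortholog's counts and the
    accessory entry zeroed for that hybrid.  Identity when there are no
    accessory genes or no presence flags.
    """
    genes = cm.genes
    if "accessory" not in genes.columns or cm.present is None:
        return CountMatrix(genes.copy(), list(cm.hybrids), cm.counts.copy(), cm.present)
    counts = cm.counts.copy()
    gene_index = {g: i for i, g in enumerate(genes["gene_id"])}
    orthologs = genes.get("ortholog")
    n_merged = 0
    for i, row in genes.iterrows():
        if not bool(row.get("accessory", False)):
            continue
        ortho = None if orthologs is None else row.get("ortholog")
        if ortho is None or (isinstance(ortho, float) and math.isnan(ortho)) or ortho == "":
            continue
        if ortho not in gene_index:
            raise KeyError(f"ortholog {ortho!r} of accessory gene {row['gene_id']!r} not in table")
        j = gene_index[ortho]
        absent = ~cm.present[i, :]
        counts[j, absent] += counts[i, absent]
        counts[i, absent] = 0
        n_merged += int(absent.sum())
    logger.info("accessory merge: re-attributed counts in %d (gene, hybrid) cells", n_merged)
    return CountMatrix(genes.copy(), list(cm.hybrids), counts, cm.present)


def compute_tpm(cm: CountMatrix) -> TraitMatrix:
    """Length-normalised transcripts per million; columns sum to 1e6."""
    lengths = cm.genes["length"].to_numpy(dtype=float)
    rate = cm.counts / lengths[:, None]
    totals = rate.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        bad = [cm.hybrids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero count columns for hybrids: {bad}")
    tpm = 1e6 * rate / totals
    return TraitMatrix(list(cm.genes["gene_id"]), list(cm.hybrids), tpm, stage="tpm")


def filter_expressed_genes(tm: TraitMatrix) -> TraitMatrix:
    """Keep genes expressed (tpm > 0) in at least half of the samples.

    "Zero in more than half" is the drop rule, so a gene zero in exactly
    half of the samples is kept.
    """
    if tm.stage != "tpm":
        raise ValueError("expressed-gene filter applies to the tpm stage")
    n = len(tm.hybrids)
    nonzero = (tm.values > 0).sum(axis=1)
    keep = nonzero >= math.ceil(n / 2)
    logger.info("expression filter: kept %d/%d genes", int(keep.sum()), len(keep))
    return TraitMatrix(
        [g for g, k in zip(tm.gene_ids, keep) if k],
        list(tm.hybrids),
        tm.values[keep, :],
        stage="tpm",
    )


def log2_tpm1(tm: TraitMatrix) -> TraitMatrix:
    if tm.stage != "tpm":
        raise ValueError("log transform applies to the tpm stage")
    return TraitMatrix(
        list(tm.gene_ids), list(tm.hybrids), np.log2(tm.values + 1.0), stage="log2tpm1"
    )


def summarize_abundance_dispersion(tm: TraitMatrix) -> pd.DataFrame:
    """Per-gene abundance and dispersion of log2(tpm+1).

    Abundance is the mean; dispersion is the mean absolute deviation about
    the mean (not the median-based MAD).
    """
    log_tm = log2_tpm1(tm) if tm.stage == "tpm" else tm
    x = log_tm.values
    mean = x.mean(axis=1)
    mad = np.abs(x - mean[:, None]).mean(axis=1)
    return pd.DataFrame(
        {"gene_id": log_tm.gene_ids, "abundance": mean, "dispersion": mad}
    )


def zscore_traits(tm: TraitMatrix, ddof: int = 1) -> TraitMatrix:
    """Standardise each gene to mean 0, SD 1 (sample SD by default).

    Zero-variance genes cannot be z-scored and are dropped with a warning.
    """
    x = tm.values
    if not np.isfinite(x).all():
        raise ValueError("non-finite trait values")
    sd = x.std(axis=1, ddof=ddof)
    keep = sd > 0
    if (~keep).any():
        dropped = [g for g, k in zip(tm.gene_ids, keep) if not k]
        logger.warning("dropping %d zero-variance traits: %s", len(dropped), dropped[:5])
    x = x[keep, :]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return TraitMatrix(
        [g for g, k in zip(tm.gene_ids, keep) if k],
        list(tm.hybrids),
        z,
        stage="zscore",
    )
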