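"""Permutation significance thresholds, cross-class adjustment, hit calling.

Genome-wide significance is calibrated empirically: trait values are shuffled
across hybrids (genotypes untouched, so LD is preserved), the scan's minimum
p-value per permutation is recorded, and the threshold is the 5% quantile of
those minima.  In "pooled" mode (the default, a single condition-wide value)
the per-trait quantiles are averaged across traits; "per-trait" mode keeps
one threshold per trait.

Because SNP and SV scans use genotype matrices of very different sizes, their
raw thresholds are adjusted to a common footing by normalising to the total
number of variants:

    adjThresh_SNP = thresh_SNP * n_SNP / (n_SNP + n_SV)
    adjThresh_SV  = thresh_SV  * n_SV  / (n_SNP + n_SV)

Hits pass on strict p < adjusted threshold; linked hits of the same trait
(|r| > 0.8) are pruned down to the lowest-p representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .mixed_model import EigenKinship, KinshipMatrix, LMMScanner

logger = logging.getLogger(__name__)


@dataclass
class ThresholdSet:
    """Raw and cross-class-adjusted significance thresholds."""

    raw: dict[str, float]            # variant class -> raw threshold
    adjusted: dict[str, float]       # variant class -> adjusted threshold
    n_variants: dict[str, int]
    n_permutations: int
    level: float = 0.05
    mode: str = "pooled"
    per_trait: dict[str, dict[str, float]] = field(default_factory=dict)


def permutation_threshold(
    traits_values: np.ndarray,
    trait_ids: list[str],
    matrix: GenotypeMatrix,
    kinship: KinshipMatrix | EigenKinship,
    n_perm: int = 100,
    level: float = 0.05,
    mode: str = "pooled",
    seed: int = 0,
    shared_permutations: bool = True,
) -> ThresholdSet:
    """Permutation-calibrated scan threshold for one variant class.

    For each permutation the trait values are shuffled across hybrids and
    the minimum scan p-value recorded.  The per-trait threshold is the
    empirical ``level`` quantile (type-7 linear interpolation) of that
    trait's minima; "pooled" mode averages those quantiles across traits
    into one condition-wide threshold.  One shuffled index set per
    permutation is shared across traits by default.
    """
    if mode not in ("pooled", "per-trait"):
        raise ValueError(f"unknown threshold mode {mode!r}")
    if n_perm < 20:
        logger.warning("n_perm=%d is low; quantile estimate will be unstable", n_perm)
    traits_values = np.asarray(traits_values, dtype=float)
    scanner = LMMScanner(matrix, kinship)
    n = scanner.n
    rng = np.random.default_rng(seed)
    if shared_permutations:
        perms = [rng.permutation(n) for _ in range(n_perm)]
    quantiles = {}
    for tid, y in zip(trait_ids, traits_values):
        if not shared_permutations:
            perms = [rng.permutation(n) for _ in range(n_perm)]
        minima = np.array([scanner.min_p(y[perm]) for perm in perms])
        quantiles[tid] = float(np.quantile(minima, level))
    cls = matrix.source
    per_trait = {cls: quantiles}
    if mode == "pooled":
        raw = {cls: float(np.mean(list(quantiles.values())))}
    else:
        raw = {cls: float(np.mean(list(quantiles.values())))}  # summary value
    return ThresholdSet(
        raw=raw,
        adjusted=dict(raw),
        n_variants={cls: matrix.n_variants},
        n_permutations=n_perm,
        level=level,
        mode=mode,
        per_trait=per_trait,
    )


def adjust_class_thresholds(
    raw_snp: float, raw_sv: float, n_snps: int, n_svs: int
) -> ThresholdSet:
    """Normalise the per-class raw thresholds to the total variant count."""
    if n_snps < 0 or n_svs < 0 or n_snps + n_svs == 0:
        raise ValueError("variant counts must be non-negative and not both zero")
    total = n_snps + n_svs
    adjusted_snp = raw_snp * n_snps / total
    adjusted_sv = raw_sv * n_svs / total
    return ThresholdSet(
        raw={"SNP": raw_snp, "SV": raw_sv},
        adjusted={"SNP": adjusted_snp, "SV": adjusted_sv},
        n_variants={"SNP": n_snps, "SV": n_svs},
        n_permutations=0,
        mode="adjusted",
    )


def call_hits(
    records: pd.DataFrame,
    thresholds: ThresholdSet,
    variant_class: str | None = None,
    trait_thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Flag records passing their class threshold (strict p < threshold).

    ``variant_class`` names the class of all records when they carry no
    ``variant_class`` column.  With ``trait_thresholds`` (per-trait mode)
    each record is compared to its own trait's threshold instead.
    """
    records = records.copy()
    if len(records) == 0:
        records["passes"] = pd.Series(dtype=bool)
        return records
    if trait_thresholds is not None:
        thr = records["trait_id"].map(trait_thresholds).to_numpy(dtype=float)
    elif "variant_class" in records.columns:
        thr = records["variant_class"].map(thresholds.adjusted).to_numpy(dtype=float)
    else:
        if variant_class is None:
            raise ValueError("variant_class needed when records carry none")
        thr = np.full(len(records), thresholds.adjusted[variant_class])
    p = np.clip(records["p_value"].to_numpy(dtype=float), np.nextafter(0, 1), 1.0)
    records["passes"] = p < thr
    return records


def prune_linked_hits(
    hits: pd.DataFrame,
    matrix: GenotypeMatrix,
    r_threshold: float = 0.8,
) -> pd.DataFrame:
    """Per trait, keep the lowest-p hit of every linkage group.

    Hits are sorted by ascending p (ties broken by chromosome, position) and
    kept greedily iff |r| <= ``r_threshold`` against every already-kept hit
    of the same trait.  Pruned hits record the variant that displaced them.
    The greedy-versus-kept rule makes the output canonical regardless of
    input order.
    """
    if len(hits) == 0:
        out = hits.copy()
        out["kept"] = pd.Series(dtype=bool)
        out["pruned_by"] = pd.Series(dtype=object)
        return out
    var_meta = matrix.variants.set_index("id")
    vindex = {v: i for i, v in enumerate(matrix.variants["id"])}
    x = matrix.dosages.astype(float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore"):
        z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, np.nan)
    n = x.shape[0]

    hits = hits.copy()
    hits["_chrom"] = hits["variant_id"].map(var_meta["chrom"])
    hits["_pos"] = hits["variant_id"].map(var_meta["pos"])
    hits = hits.sort_values(["trait_id", "p_value", "_chrom", "_pos"], kind="mergesort")
    kept_flags = []
    pruned_by = []
    for _, group in hits.groupby("trait_id", sort=False):
        kept: list[str] = []
        for _, row in group.iterrows():
            vid = row["variant_id"]
            zi = z[:, vindex[vid]]
            pruner = None
            for kid in kept:
                r = float(zi @ z[:, vindex[kid]]) / n
                if abs(r) > r_threshold:
                    pruner = kid
                    break
            if pruner is None:
                kept.append(vid)
                kept_flags.append(True)
                pruned_by.append(None)
            else:
                kept_flags.append(False)
                pruned_by.append(pruner)
    hits["kept"] = kept_flags
    hits["pruned_by"] = pruned_by
    return hits.drop(columns=["_chrom", "_pos"]).reset_index(drop=True)
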