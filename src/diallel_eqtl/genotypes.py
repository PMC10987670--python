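"""Diallel cross design and hybrid genotype matrices.

A diallel panel crosses a set of haploid parents in all non-reciprocal pair
combinations (optionally including selfs).  Hybrid genotypes are fully
determined by the parental haplotypes: the dosage of the alternate allele in
hybrid {a, b} is simply hap_a + hap_b, so a variant carried by k of n parents
has a full-panel allele frequency of exactly k/n when all C(n,2)+n hybrids
are present.

Coordinates are 1-based inclusive (VCF convention) throughout.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns every variant metadata table carries.  Optional columns
#: (sv_type, length, annotation, population_maf) may be absent or NaN.
VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "variant_class")


def hybrid_id(parent_a: str, parent_b: str) -> str:
    """Canonical unordered hybrid identifier."""
    a, b = sorted((parent_a, parent_b))
    return f"{a}x{b}"


@dataclass(frozen=True)
class CrossDesign:
    """A non-reciprocal diallel cross: one hybrid per unordered parent pair."""

    parents: tuple[str, ...]
    hybrids: tuple[tuple[str, str], ...]
    #: hybrids that actually carry phenotypes; None means all of them
    phenotyped: tuple[str, ...] | None = None

    @property
    def hybrid_ids(self) -> list[str]:
        return [hybrid_id(a, b) for a, b in self.hybrids]

    @property
    def n_heterozygous(self) -> int:
        return sum(a != b for a, b in self.hybrids)

    @property
    def n_homozygous(self) -> int:
        return sum(a == b for a, b in self.hybrids)

    def phenotyped_ids(self) -> list[str]:
        if self.phenotyped is None:
            return self.hybrid_ids
        return list(self.phenotyped)


@dataclass
class GenotypeMatrix:
    """Hybrids x variants allele-dosage matrix with per-variant metadata.

    ``dosages`` holds the count of alternate-allele copies (0/1/2) with
    hybrids in rows and variants in columns, in the order of ``hybrids`` and
    ``variants``.  The same container is used for SNPs and for structural
    variants (``source`` tag).
    """

    hybrids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    source: str = "SNP"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.hybrids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.hybrids)} hybrids x {len(self.variants)} variants"
            )
        if self.dosages.size and not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_hybrids(self, ids: list[str]) -> "GenotypeMatrix":
        index = {h: i for i, h in enumerate(self.hybrids)}
        missing = [h for h in ids if h not in index]
        if missing:
            raise KeyError(f"unknown hybrids: {missing[:5]}")
        rows = [index[h] for h in ids]
        return GenotypeMatrix(
            hybrids=list(ids),
            variants=self.variants.copy(),
            dosages=self.dosages[rows, :],
            source=self.source,
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            hybrids=list(self.hybrids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
            source=self.source,
        )


def enumerate_crosses(parent_ids, include_selfs: bool = True) -> CrossDesign:
    """All unordered distinct parent pairs, plus selfs when requested.

    26 parents with selfs give the canonical 325 heterozygous + 26
    homozygous = 351 hybrids.
    """
    parent_ids = list(parent_ids)
    if len(parent_ids) < 2:
        raise ValueError("need at least two parents")
    if len(set(parent_ids)) != len(parent_ids):
        raise ValueError("duplicate parent ids")
    pairs = [tuple(sorted(p)) for p in itertools.combinations(parent_ids, 2)]
    if include_selfs:
        pairs += [(p, p) for p in parent_ids]
    pairs.sort()
    return CrossDesign(parents=tuple(parent_ids), hybrids=tuple(pairs))


def infer_hybrid_genotypes(
    parent_haplotypes: pd.DataFrame,
    design: CrossDesign,
    variants: pd.DataFrame | None = None,
    source: str = "SNP",
) -> GenotypeMatrix:
    """Combine haploid parental genotypes into hybrid dosages.

    ``parent_haplotypes`` is a parents x variants 0/1 DataFrame (rows indexed
    by parent id).  dosage(hybrid {a,b}, v) = hap_a(v) + hap_b(v); selfs are
    homozygous everywhere.
    """
    missing = [p for p in design.parents if p not in parent_haplotypes.index]
    if missing:
        raise KeyError(f"no haplotype for parents: {missing}")
    hap = parent_haplotypes.loc[list(design.parents)]
    if hap.isna().any().any():
        bad = [
            (parent, col)
            for parent, row in hap.iterrows()
            for col, v in row.items()
            if pd.isna(v)
        ]
        raise ValueError(f"missing parental calls (parent, variant): {bad[:5]}")
    values = hap.to_numpy(dtype=np.int8)
    if values.size and not np.isin(values, (0, 1)).all():
        raise ValueError("parental haplotypes must be 0/1")
    pidx = {p: i for i, p in enumerate(design.parents)}
    rows_a = np.array([pidx[a] for a, _ in design.hybrids])
    rows_b = np.array([pidx[b] for _, b in design.hybrids])
    dosages = values[rows_a, :] + values[rows_b, :]
    if variants is None:
        variants = pd.DataFrame(
            {
                "id": list(parent_haplotypes.columns),
                "chrom": "NA",
                "pos": np.arange(1, values.shape[1] + 1),
                "ref": "N",
                "alt": "N",
                "variant_class": source,
            }
        )
    return GenotypeMatrix(
        hybrids=design.hybrid_ids,
        variants=variants.reset_index(drop=True),
        dosages=dosages,
        source=source,
    )


def compute_panel_maf(
    matrix: GenotypeMatrix, included_hybrids: list[str] | None = None
) -> np.ndarray:
    """Minor allele frequency per variant over the included hybrids.

    Allele frequency f = mean(dosage)/2; MAF = min(f, 1-f).
    """
    if included_hybrids is not None:
        if len(included_hybrids) == 0:
            raise ValueError("empty hybrid inclusion set")
        matrix = matrix.subset_hybrids(included_hybrids)
    f = matrix.dosages.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def parent_carrier_counts(parent_haplotypes: pd.DataFrame) -> np.ndarray:
    """Number of parents carrying the alternate allele, per variant."""
    return parent_haplotypes.to_numpy(dtype=np.int64).sum(axis=0)


def remove_singletons(
    matrix: GenotypeMatrix,
    parent_haplotypes: pd.DataFrame,
    minor_allele_symmetric: bool = True,
) -> GenotypeMatrix:
    """Drop variants whose minor allele is private to a single parent.

    A variant present in exactly one parent is perfectly confounded with
    that parent's whole genome in a diallel, so it is removed.  By symmetry
    of allele labels a variant ABSENT from exactly one parent (carrier count
    n-1) is a singleton of the reference allele and is removed as well when
    ``minor_allele_symmetric`` (default).
    """
    ids = list(matrix.variants["id"])
    missing = [v for v in ids if v not in parent_haplotypes.columns]
    if missing:
        raise KeyError(f"parental haplotypes missing variants: {missing[:5]}")
    counts = parent_carrier_counts(parent_haplotypes[ids])
    n = parent_haplotypes.shape[0]
    alt_singleton = counts == 1
    ref_singleton = counts == n - 1
    drop = alt_singleton | ref_singleton if minor_allele_symmetric else alt_singleton
    logger.info(
        "singleton filter: removed %d alt-singletons, %d ref-singletons, kept %d/%d",
        int(alt_singleton.sum()),
        int(ref_singleton.sum()) if minor_allele_symmetric else 0,
        int((~drop).sum()),
        len(counts),
    )
    return matrix.subset_variants(~drop)


def filter_biallelic(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep only biallelic records (single ALT allele, no comma)."""
    if len(variants) == 0:
        return variants.copy()
    alt = variants["alt"].astype(str)
    keep = ~alt.str.contains(",")
    logger.info("biallelic filter: dropped %d multi-allelic records", int((~keep).sum()))
    return variants.loc[keep].reset_index(drop=True)


def compute_ld(
    matrix: GenotypeMatrix, i: int, j: int
) -> tuple[float, float]:
    """Pearson correlation r (and r^2) between two variants' dosage vectors.

    Returns (nan, nan) with a warning for zero-variance variants.
    """
    x = matrix.dosages[:, i].astype(float)
    y = matrix.dosages[:, j].astype(float)
    if x.std() == 0 or y.std() == 0:
        logger.warning("LD undefined for zero-variance variant pair (%d, %d)", i, j)
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """r^2 between all columns; zero-variance columns yield nan rows/cols."""
    x = dosages.astype(float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - x.mean(axis=0)) / sd
    r = z.T @ z / x.shape[0]
    return r * r


def ld_filter_matrix(
    matrix: GenotypeMatrix, r2_threshold: float = 0.8, window: int = 50
) -> GenotypeMatrix:
    """Greedy LD pruning in genome order.

    A variant is kept iff its r^2 with every previously kept variant in the
    trailing ``window`` is <= ``r2_threshold``.  Deterministic; monomorphic
    variants are dropped (their LD is undefined).
    """
    if matrix.n_variants == 0:
        return matrix
    order = np.lexsort(
        (matrix.variants["pos"].to_numpy(), matrix.variants["chrom"].to_numpy())
    )
    x = matrix.dosages[:, order].astype(float)
    sd = x.std(axis=0)
    kept_local: list[int] = []
    kept_cols: list[np.ndarray] = []  # standardized kept columns (recent first)
    n = x.shape[0]
    for idx in range(x.shape[1]):
        if sd[idx] == 0:
            continue
        z = (x[:, idx] - x[:, idx].mean()) / sd[idx]
        recent = kept_cols[-window:] if window else kept_cols
        ok = True
        for zk in recent:
            r = float(zk @ z) / n
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            kept_local.append(idx)
            kept_cols.append(z)
    kept_original = np.sort(order[kept_local])
    mask = np.zeros(matrix.n_variants, dtype=bool)
    mask[kept_original] = True
    logger.info(
        "LD filter (r2>%s, window=%d): kept %d/%d variants",
        r2_threshold,
        window,
        int(mask.sum()),
        matrix.n_variants,
    )
    return matrix.subset_variants(mask)
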