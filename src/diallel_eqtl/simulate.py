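"""Synthetic diallel study generator with known ground truth.

Emulates the statistical structure the analysis assumes: a large natural
source population whose site-frequency spectrum is dominated by
low-frequency alleles (~92.7% of polymorphic sites at MAF < 0.05), 26
haploid parents sampled from it, the 351-hybrid non-reciprocal diallel, an
SV catalog with realistic type proportions, and z-scored expression traits
with planted local/distant eQTL, trans hotspots and a controlled
heritability distribution.

Population haplotypes combine two layers:

* a founder-mosaic backbone (Li-Stephens flavour): each haplotype copies one
  of ``founder_count`` founder labels, switching along the chromosome at
  ``switch_rate`` per bp, so nearby sites are correlated — this carries the
  common variants;
* a direct rare-mutation layer for sites whose target allele count is below
  founder resolution (< n_pop / (2 * founder_count) carriers): their
  carriers are drawn directly, like recent mutations on single lineages.

Target allele counts are drawn from a truncated power law p(k) ∝ k^(-shape)
on [1, n_pop-1]; when no shape is given it is solved numerically so the
expected fraction of sites at MAF < 0.05 matches the configured target.

Every random draw comes from a named child stream of one root seed, so
per-stage reproducibility survives re-ordering of stages.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import genotypes as gt
from .expression import TraitMatrix
from .mixed_model import estimate_kinship

logger = logging.getLogger(__name__)

#: SV type proportions from the parental catalog (1032 insertions, 543
#: deletions, 250 duplications, 65 contractions, 33 translocations, 30
#: inversions out of 1953).
DEFAULT_SV_WEIGHTS = {
    "insertion": 1032 / 1953,
    "deletion": 543 / 1953,
    "duplication": 250 / 1953,
    "contraction": 65 / 1953,
    "translocation": 33 / 1953,
    "inversion": 30 / 1953,
}

LTR_LENGTH = 340     # bp, solo long terminal repeat
TY_LENGTH = 6_000    # bp, full Ty element


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_pop: int = 1011
    n_parents: int = 26
    n_chromosomes: int = 16
    genome_length: int = 12_200_000
    n_snps: int = 5_000
    n_svs: int = 1_953
    founder_count: int = 20
    switch_rate: float = 1e-6          # per-bp mosaic switch probability
    sfs_shape: float | None = None     # None: solved from target_lowfreq_fraction
    target_lowfreq_fraction: float = 0.927
    n_genes: int = 500
    accessory_fraction: float = 0.068  # 422 accessory of 6186 expressed genes
    target_h2_median: float = 0.28
    h2_beta_a: float = 1.5             # Beta shape a of the per-gene h2 draw
    causal_gene_fraction: float = 0.5  # genes with at least one planted eQTL
    n_causal_per_gene: int = 2
    causal_variance_share: float = 0.5  # fraction of h2 carried by planted eQTL
    hotspot_count: int = 4
    hotspot_gene_range: tuple[int, int] = (20, 80)
    local_fraction: float = 0.25
    local_window: int = 25_000
    local_effect_multiplier: float = 1.5
    lowfreq_causal_multiplier: float = 1.0
    accessory_causal_multiplier: float = 1.0
    sv_type_weights: dict = field(default_factory=lambda: dict(DEFAULT_SV_WEIGHTS))
    sv_ty_fraction: float = 0.4
    sv_position_jitter: int = 20
    sv_length_jitter: float = 0.05
    sv_sfs_shape: float = 1.0
    include_selfs: bool = True

    def __post_init__(self) -> None:
        for name in ("n_pop", "n_parents", "n_chromosomes", "genome_length",
                     "n_snps", "n_genes", "founder_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("switch_rate", "target_lowfreq_fraction", "local_fraction",
                     "causal_gene_fraction", "causal_variance_share",
                     "accessory_fraction", "sv_ty_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.target_h2_median < 1.0:
            raise ValueError("target_h2_median must be in [0, 1)")
        if abs(sum(self.sv_type_weights.values()) - 1.0) > 1e-9:
            raise ValueError("sv_type_weights must sum to 1")
        if self.n_snps > self.genome_length:
            raise ValueError("too dense: more SNPs than base pairs")
        if self.n_parents > self.n_pop:
            raise ValueError("cannot sample more parents than the population holds")
        lo, hi = self.hotspot_gene_range
        if self.hotspot_count > 0 and hi > self.n_genes:
            raise ValueError("hotspot_gene_range exceeds n_genes")

    def stream(self, name: str) -> np.random.Generator:
        """Named child RNG stream derived from the root seed."""
        key = zlib.crc32(name.encode("utf8"))
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class SimulationTruth:
    """Planted ground truth enabling recovery-based checks."""

    population_maf: pd.Series                 # per variant id
    parent_haplotypes: pd.DataFrame           # parents x variants, 0/1
    causal_effects: pd.DataFrame              # variant_id, gene_id, beta, var_explained, is_local, is_hotspot
    trait_h2: pd.Series                       # realized per-gene h2
    hotspot_variants: list[str]
    gene_table: pd.DataFrame | None = None
    sv_truth: pd.DataFrame | None = None


def tune_sfs_shape(n_pop: int, target_lowfreq_fraction: float, cutoff: float = 0.05) -> float:
    """Solve p(k) ∝ k^(-shape) so the expected MAF<cutoff fraction hits target."""
    k = np.arange(1, n_pop)
    low = np.minimum(k, n_pop - k) / n_pop < cutoff

    def frac(shape: float) -> float:
        w = k.astype(float) ** (-shape)
        return float(w[low].sum() / w.sum())

    lo, hi = 0.05, 8.0
    if not frac(lo) <= target_lowfreq_fraction <= frac(hi):
        raise ValueError("low-frequency target unreachable with a power-law SFS")
    return float(optimize.brentq(lambda a: frac(a) - target_lowfreq_fraction, lo, hi, xtol=1e-10))


def _chromosome_layout(config: SimulationConfig) -> tuple[np.ndarray, int]:
    chrom_len = config.genome_length // config.n_chromosomes
    return np.array([chrom_len] * config.n_chromosomes), chrom_len


def _draw_positions(config: SimulationConfig, rng: np.random.Generator, n_sites: int):
    """Sites placed uniformly over equal-length chromosomes, sorted."""
    _, chrom_len = _chromosome_layout(config)
    chroms = np.sort(rng.integers(0, config.n_chromosomes, size=n_sites))
    pos = rng.integers(1, chrom_len + 1, size=n_sites)
    order = np.lexsort((pos, chroms))
    return chroms[order], pos[order]


def simulate_source_population(config: SimulationConfig):
    """Source-population haplotypes with a controlled frequency spectrum.

    Returns (variant table, haplotype matrix (n_pop x sites, 0/1),
    population MAF array).  Monomorphic sites (possible only in degenerate
    configurations) are dropped; the realized MAF<0.05 fraction is logged.
    """
    rng = config.stream("source_population")
    shape = config.sfs_shape
    if shape is None:
        shape = tune_sfs_shape(config.n_pop, config.target_lowfreq_fraction)
        logger.info("SFS shape tuned to %.4f for target %.3f", shape, config.target_lowfreq_fraction)
    n, s = config.n_pop, config.n_snps
    k_support = np.arange(1, n)
    pk = k_support.astype(float) ** (-shape)
    pk /= pk.sum()
    target_k = rng.choice(k_support, size=s, p=pk)

    chroms, pos = _draw_positions(config, rng, s)

    # founder-label mosaic, Markov along each chromosome
    labels = np.empty((n, s), dtype=np.int32)
    prev_chrom = None
    prev_pos = None
    for j in range(s):
        if chroms[j] != prev_chrom:
            labels[:, j] = rng.integers(0, config.founder_count, size=n)
        else:
            p_switch = 1.0 - np.exp(-config.switch_rate * (pos[j] - prev_pos))
            switch = rng.random(n) < p_switch
            labels[:, j] = labels[:, j - 1]
            if switch.any():
                labels[switch, j] = rng.integers(0, config.founder_count, size=int(switch.sum()))
        prev_chrom, prev_pos = chroms[j], pos[j]

    rare_cut = n / (2 * config.founder_count)
    haps = np.zeros((n, s), dtype=np.int8)
    for j in range(s):
        k = int(target_k[j])
        if k < rare_cut or config.founder_count == 1:
            carriers = rng.choice(n, size=k, replace=False)
            haps[carriers, j] = 1
            continue
        counts = np.bincount(labels[:, j], minlength=config.founder_count)
        order = rng.permutation(config.founder_count)
        chosen = np.zeros(config.founder_count, dtype=bool)
        cum = 0
        for f in order:
            if abs(cum + counts[f] - k) < abs(cum - k):
                chosen[f] = True
                cum += counts[f]
        if cum == 0 or cum == n:
            carriers = rng.choice(n, size=k, replace=False)
            haps[carriers, j] = 1
        else:
            haps[chosen[labels[:, j]], j] = 1

    counts = haps.sum(axis=0)
    poly = (counts > 0) & (counts < n)
    haps = haps[:, poly]
    chroms, pos, counts = chroms[poly], pos[poly], counts[poly]
    maf = np.minimum(counts, n - counts) / n

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=len(pos))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
    variants = pd.DataFrame(
        {
            "id": [f"snp{i:06d}" for i in range(len(pos))],
            "chrom": [f"chr{c + 1:02d}" for c in chroms],
            "pos": pos,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "variant_class": "SNP",
            "population_maf": maf,
        }
    )
    frac_low = float((maf < 0.05).mean()) if len(maf) else float("nan")
    logger.info(
        "source population: %d/%d polymorphic sites retained, MAF<0.05 fraction %.4f",
        len(pos), s, frac_low,
    )
    return variants, haps, maf


def sample_parents(
    variants: pd.DataFrame,
    population_haplotypes: np.ndarray,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Sample n_parents haploid genomes without replacement.

    Returns a parents x variants 0/1 DataFrame (rows P01..Pnn, columns
    variant ids).
    """
    rng = config.stream("sample_parents")
    rows = rng.choice(config.n_pop, size=config.n_parents, replace=False)
    ids = [f"P{i + 1:02d}" for i in range(config.n_parents)]
    return pd.DataFrame(
        population_haplotypes[rows, :], index=ids, columns=list(variants["id"])
    )


def simulate_gene_table(config: SimulationConfig) -> pd.DataFrame:
    """Genes placed uniformly over the genome; a fraction flagged accessory."""
    rng = config.stream("genes")
    chroms, starts = _draw_positions(config, rng, config.n_genes)
    accessory = rng.random(config.n_genes) < config.accessory_fraction
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(config.n_genes)],
            "chrom": [f"chr{c + 1:02d}" for c in chroms],
            "start": starts,
            "strand": rng.choice(["+", "-"], size=config.n_genes),
            "accessory": accessory,
        }
    )


def _h2_beta_b(config: SimulationConfig) -> float:
    """Solve the Beta b parameter so the h2 median equals the target."""
    from scipy.stats import beta as beta_dist

    target = config.target_h2_median
    a = config.h2_beta_a
    if target <= 0:
        return float("inf")
    f = lambda b: beta_dist.ppf(0.5, a, b) - target
    return float(optimize.brentq(f, 1e-3, 1e4, xtol=1e-10))


def simulate_expression(
    parent_haplotypes: pd.DataFrame,
    design: gt.CrossDesign,
    variants: pd.DataFrame,
    config: SimulationConfig,
    gene_table: pd.DataFrame | None = None,
) -> tuple[TraitMatrix, SimulationTruth, gt.GenotypeMatrix]:
    """Z-scored traits with planted eQTL over the diallel hybrids.

    For gene g: z_g = sum_v beta_vg x_v + u_g + e_g with u_g ~ N(0, K) and
    e_g white noise.  The three components are rescaled empirically so the
    realized variance shares are exactly (h2*rho, h2*(1-rho), 1-h2) with
    rho = causal_variance_share and h2 drawn from a Beta law whose median is
    the target; traits therefore have unit variance and the realized h2
    distribution has the configured median up to sampling error of the Beta
    draws.  Causal variants are oversampled from population-MAF<0.05 sites
    by ``lowfreq_causal_multiplier``; local causal variants sit within
    ``local_window`` of their gene start.  Returns the trait matrix, the
    planted truth, and the singleton-filtered hybrid genotype matrix used.
    """
    rng = config.stream("expression")
    matrix = gt.infer_hybrid_genotypes(parent_haplotypes, design, variants=variants)
    # drop sites monomorphic among the sampled parents (uninformative in the
    # panel even though polymorphic in the source population)
    counts = gt.parent_carrier_counts(parent_haplotypes[list(matrix.variants["id"])])
    matrix = matrix.subset_variants((counts > 0) & (counts < config.n_parents))
    matrix = gt.remove_singletons(matrix, parent_haplotypes)
    if gene_table is None:
        gene_table = simulate_gene_table(config)
    lo, hi = config.hotspot_gene_range
    if config.hotspot_count > 0 and hi > len(gene_table):
        raise ValueError("hotspot_gene_range exceeds the number of genes")

    n_hyb = matrix.n_hybrids
    m = matrix.n_variants
    x = matrix.dosages.astype(float)
    x_sd = x.std(axis=0)
    pop_maf = matrix.variants["population_maf"].to_numpy()

    # polygenic draws share the panel's kinship structure
    kin = estimate_kinship(matrix, "centered_grm")
    lam, u_mat = np.linalg.eigh(kin.values)
    lam = np.clip(lam, 0.0, None)
    k_root = u_mat * np.sqrt(lam)

    # per-gene h2 from a Beta law whose median is the target; stratified
    # (permuted Latin-hypercube) quantile draws pin the empirical median of
    # the panel to the target within O(1/n_genes)
    from scipy.stats import beta as beta_dist

    b = _h2_beta_b(config)
    n_g = len(gene_table)
    if np.isfinite(b):
        u = rng.permutation((np.arange(n_g) + rng.random(n_g)) / n_g)
        h2 = beta_dist.ppf(u, config.h2_beta_a, b)
    else:
        h2 = np.zeros(n_g)

    # per-variant causal sampling weights
    w = np.where(pop_maf < 0.05, config.lowfreq_causal_multiplier, 1.0)
    w = np.where(x_sd > 0, w, 0.0)

    gene_ids = list(gene_table["gene_id"])
    acc_mult = np.where(
        gene_table.get("accessory", pd.Series(False, index=gene_table.index)).to_numpy(),
        config.accessory_causal_multiplier, 1.0,
    )
    p_causal = np.clip(config.causal_gene_fraction * acc_mult, 0.0, 1.0)
    has_causal = rng.random(len(gene_ids)) < p_causal

    # hotspots: single variants with effects on many genes
    hotspot_vids: list[str] = []
    hotspot_assignments: dict[int, list[int]] = {}
    if config.hotspot_count > 0:
        panel_maf = gt.compute_panel_maf(matrix)
        eligible = np.flatnonzero((panel_maf >= 0.1) & (x_sd > 0))
        picks = rng.choice(eligible, size=config.hotspot_count, replace=False)
        for v in picks:
            n_targets = int(rng.integers(lo, hi + 1))
            targets = rng.choice(len(gene_ids), size=n_targets, replace=False)
            hotspot_assignments[int(v)] = list(map(int, targets))
            hotspot_vids.append(matrix.variants["id"].iloc[int(v)])

    vchrom = matrix.variants["chrom"].to_numpy()
    vpos = matrix.variants["pos"].to_numpy()

    values = np.empty((len(gene_ids), n_hyb))
    causal_rows = []
    realized_h2 = np.empty(len(gene_ids))
    for gi, gid in enumerate(gene_ids):
        causal: list[tuple[int, float, bool, bool]] = []  # (variant idx, raw beta, local, hotspot)
        if has_causal[gi]:
            n_c = config.n_causal_per_gene
            n_local = int(rng.binomial(n_c, config.local_fraction))
            local_mask = (
                (vchrom == gene_table["chrom"].iloc[gi])
                & (np.abs(vpos - gene_table["start"].iloc[gi]) <= config.local_window)
                & (w > 0)
            )
            local_idx = np.flatnonzero(local_mask)
            chosen_local = []
            if n_local > 0 and len(local_idx) > 0:
                pw = w[local_idx] / w[local_idx].sum()
                chosen_local = list(
                    rng.choice(local_idx, size=min(n_local, len(local_idx)), replace=False, p=pw)
                )
            n_distant = n_c - len(chosen_local)
            distant_pool = np.flatnonzero((w > 0) & ~np.isin(np.arange(m), chosen_local))
            pw = w[distant_pool] / w[distant_pool].sum()
            chosen_distant = list(rng.choice(distant_pool, size=n_distant, replace=False, p=pw))
            for v in chosen_local:
                causal.append((int(v), rng.normal() * config.local_effect_multiplier, True, False))
            for v in chosen_distant:
                causal.append((int(v), rng.normal(), False, False))
        for v, targets in hotspot_assignments.items():
            if gi in targets:
                causal.append((v, rng.normal(), False, True))

        h2_g = float(h2[gi])
        noise = rng.normal(size=n_hyb)
        poly = k_root @ rng.normal(size=n_hyb)
        rho = config.causal_variance_share if causal else 0.0
        causal_part = np.zeros(n_hyb)
        if causal:
            for v, beta_raw, _, _ in causal:
                causal_part += beta_raw * x[:, v]
            if causal_part.std() == 0:
                rho = 0.0
                causal = []
                causal_part = np.zeros(n_hyb)

        # orthogonalise the three components so their empirical variance
        # shares are exactly (h2*rho, h2*(1-rho), 1-h2)
        def _demean(a):
            return a - a.mean()

        def _residual(a, basis):
            a = _demean(a)
            for bvec in basis:
                denom = bvec @ bvec
                if denom > 0:
                    a = a - (a @ bvec) / denom * bvec
            return a

        c_part = _demean(causal_part)
        p_part = _residual(poly, [c_part] if causal else [])
        n_part = _residual(noise, [c_part, p_part] if causal else [p_part])
        scale_c = np.sqrt(h2_g * rho) / c_part.std() if causal else 0.0
        scale_p = np.sqrt(h2_g * (1.0 - rho)) / p_part.std() if p_part.std() > 0 else 0.0
        scale_n = np.sqrt(1.0 - h2_g) / n_part.std()
        values[gi] = scale_c * c_part + scale_p * p_part + scale_n * n_part
        tot = values[gi].var()
        realized_h2[gi] = h2_g if tot > 0 else 0.0
        for v, beta_raw, is_local, is_hot in causal:
            beta_eff = scale_c * beta_raw
            causal_rows.append(
                {
                    "variant_id": matrix.variants["id"].iloc[v],
                    "gene_id": gid,
                    "beta": beta_eff,
                    "var_explained": beta_eff**2 * x[:, v].var() / tot,
                    "is_local": is_local,
                    "is_hotspot": is_hot,
                }
            )

    traits = TraitMatrix(gene_ids, list(matrix.hybrids), values, stage="zscore")
    truth = SimulationTruth(
        population_maf=pd.Series(
            matrix.variants["population_maf"].to_numpy(), index=matrix.variants["id"]
        ),
        parent_haplotypes=parent_haplotypes,
        causal_effects=pd.DataFrame(
            causal_rows,
            columns=["variant_id", "gene_id", "beta", "var_explained", "is_local", "is_hotspot"],
        ),
        trait_h2=pd.Series(realized_h2, index=gene_ids),
        hotspot_variants=hotspot_vids,
        gene_table=gene_table,
    )
    return traits, truth, matrix


def zscores_to_counts(
    traits: TraitMatrix, config: SimulationConfig, mean_log_tpm: float = 4.0,
    expression_sd: float = 0.25, library_size: int = 2_000_000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Inverse transform emitting synthetic gene-level read counts.

    Per gene a baseline log2 expression is drawn, the z-score modulates it
    multiplicatively, and Poisson counts are sampled at a fixed library
    size; gene lengths are drawn uniformly in [500, 3000] bp.  Returns
    (gene metadata with lengths, genes x hybrids count matrix).
    """
    rng = config.stream("counts")
    n_genes, n_hyb = traits.values.shape
    base = rng.normal(mean_log_tpm, 1.0, size=n_genes)
    log_expr = base[:, None] + expression_sd * traits.values
    expr = 2.0**log_expr
    lengths = rng.integers(500, 3001, size=n_genes)
    rate = expr * lengths[:, None]
    rate = rate / rate.sum(axis=0, keepdims=True) * library_size
    counts = rng.poisson(rate)
    meta = pd.DataFrame({"gene_id": traits.gene_ids, "length": lengths})
    return meta, counts


def simulate_sv_catalog(config: SimulationConfig):
    """Per-parent SV call sets with known merge groups and Ty status.

    ``n_svs`` true events are drawn with type proportions from
    ``sv_type_weights``; a fraction ``sv_ty_fraction`` are transposon
    derived, with lengths near 340 bp (solo LTR) or 6 kb (full Ty).
    Presence/absence per parent follows a truncated power-law SFS over
    carrier counts (the reference-like first parent carries nothing).  Each
    carrier emits one jittered call.  Returns (calls, ty_library, truth).
    """
    rng = config.stream("sv_catalog")
    types = list(config.sv_type_weights)
    probs = np.array([config.sv_type_weights[t] for t in types], dtype=float)
    sv_types = rng.choice(types, size=config.n_svs, p=probs / probs.sum())
    chroms, starts = _draw_positions(config, rng, config.n_svs)
    # spread events out so distinct events do not collide within merge tolerance
    is_ty = rng.random(config.n_svs) < config.sv_ty_fraction
    ltr = rng.random(config.n_svs) < 0.7
    lengths = np.where(
        is_ty,
        np.where(ltr, rng.normal(LTR_LENGTH, 25, config.n_svs), rng.normal(TY_LENGTH, 400, config.n_svs)),
        np.exp(rng.normal(np.log(400), 0.9, config.n_svs)),
    )
    lengths = np.maximum(lengths, 50).astype(int)

    k_support = np.arange(1, config.n_parents)
    pk = k_support.astype(float) ** (-config.sv_sfs_shape)
    pk /= pk.sum()
    carrier_counts = rng.choice(k_support, size=config.n_svs, p=pk)

    parents = [f"P{i + 1:02d}" for i in range(config.n_parents)]
    bases = np.array(list("ACGT"))
    call_rows = []
    truth_rows = []
    ty_rows = []
    for i in range(config.n_svs):
        chrom = f"chr{chroms[i] + 1:02d}"
        start = int(starts[i])
        length = int(lengths[i])
        seq = "".join(rng.choice(bases, size=min(length, 2_000))) if sv_types[i] == "insertion" else ""
        carriers = rng.choice(np.arange(1, config.n_parents), size=int(carrier_counts[i]), replace=False)
        truth_rows.append(
            {
                "true_id": f"tsv{i:05d}",
                "chrom": chrom,
                "start": start,
                "sv_type": sv_types[i],
                "length": length,
                "ty_related": bool(is_ty[i]),
                "carriers": sorted(parents[c] for c in carriers),
            }
        )
        if is_ty[i]:
            # Ty library interval covering most of the event footprint
            cov = int(length * (0.8 + 0.15 * rng.random()))
            off = int(rng.integers(0, max(length - cov, 1)))
            ty_rows.append({"chrom": chrom, "start": start + off, "end": start + off + cov - 1,
                            "label": "LTR" if length < 1000 else "Ty"})
        for c in carriers:
            jitter = int(rng.integers(-config.sv_position_jitter, config.sv_position_jitter + 1))
            lj = max(50, int(round(length * (1.0 + rng.uniform(-config.sv_length_jitter, config.sv_length_jitter)))))
            call_seq = seq
            if seq:
                # a few base substitutions between carriers
                s = list(seq)
                for pos_mut in rng.integers(0, len(s), size=max(1, len(s) // 100)):
                    s[pos_mut] = str(rng.choice(bases))
                call_seq = "".join(s)
            call_rows.append(
                {
                    "id": f"tsv{i:05d}_{parents[c]}",
                    "genome": parents[c],
                    "chrom": chrom,
                    "start": start + jitter,
                    "end": start + jitter + lj - 1,
                    "sv_type": sv_types[i],
                    "length": lj,
                    "sequence": call_seq,
                    "true_id": f"tsv{i:05d}",
                }
            )
    calls = pd.DataFrame(call_rows)
    ty_library = pd.DataFrame(ty_rows, columns=["chrom", "start", "end", "label"])
    truth = pd.DataFrame(truth_rows)
    # some non-Ty decoy intervals so flagging is not trivially all-positive
    if len(ty_library) == 0:
        ty_library = pd.DataFrame(columns=["chrom", "start", "end", "label"])
    return calls, ty_library, truth


def simulate_design(config: SimulationConfig) -> gt.CrossDesign:
    parents = [f"P{i + 1:02d}" for i in range(config.n_parents)]
    return gt.enumerate_crosses(parents, include_selfs=config.include_selfs)
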