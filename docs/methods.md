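# Methods

Statistical models, numerical choices and limitations of `diallel-eqtl`.

## 1. Panel structure and genotype inference

A non-reciprocal diallel over `n` haploid parents contains `C(n,2)` heterozygous
hybrids plus `n` selfs; for `n = 26` this is 325 + 26 = 351. A hybrid's dosage at
a biallelic site is the sum of its two parental haploid alleles, so genotypes
are exact and deterministic given phased parents. Over the full panel a variant
carried by `k` parents appears with allele frequency exactly `k/n`
(each parent contributes `n + 1` haploid genomes out of `n(n + 1)` total).

Variants carried by exactly one parent (or all but one) are removed before
mapping: their hybrid dosage never reaches homozygous-alternate, and with a
single carrier the dosage vector is a scaled indicator of one parent, fully
confounded with that parent's polygenic contribution.

## 2. Expression processing

* **TPM**: counts divided by gene length in kb, column-normalised to 1e6.
* **Accessory genes**: where an accessory gene is absent from a hybrid's two
  parents, reads mapping to it are merged into its reference ortholog for that
  hybrid; total reads are conserved.
* **Expressed-gene filter**: genes with non-zero expression in at least half
  the hybrids are retained.
* **Traits**: `log2(TPM + 1)` is computed for abundance summaries; mapping
  traits are per-gene z-scores (mean 0, SD 1, `ddof = 1`). Zero-variance genes
  are dropped.

## 3. Linear mixed model

Per trait `y` (z-scored, length `N` hybrids):

```
y = mu·1 + g + e,   g ~ N(0, sigma2_g K),   e ~ N(0, sigma2_e I)
```

* **Kinship** `K`: centered GRM `Z Zᵀ / m` on column-standardised dosages of an
  LD-pruned variant set (greedy r² > 0.8 filter within a sliding window), with
  a 1e-8 diagonal ridge for numerical PSD-ness. An allele-sharing estimator is
  available as an alternative.
* **REML**: the restricted likelihood is profiled down to
  `h2 = sigma2_g / (sigma2_g + sigma2_e)` using the eigendecomposition
  `K = U Λ Uᵀ` (computed once per panel) and maximised by bounded Brent search
  on `[0, 1 − 1e-6]` with tolerance 1e-8. Boundary solutions are reported with
  `converged = False`; an identity-like `K` is flagged `degenerate`.
* **Scan**: FaST-LMM-style rotated GLS. With `y* = Uᵀy`, `x* = Uᵀx` and weights
  `w_i = 1 / (h2·λ_i + 1 − h2)` at the trait's null REML `h2`, each variant is
  tested by weighted least squares of `y*` on `[1, x*]`; the Wald statistic
  `t = β̂ / se(β̂)` is referred to Student's t with `N − 2` degrees of freedom.
  This is algebraically identical to explicit GLS with
  `W = h2·K + (1 − h2)·I` (verified to |Δlog10 p| < 1e-6 against a
  brute-force oracle in the acceptance suite). `h2` is *not* re-estimated per
  variant and there is no leave-one-chromosome-out correction, matching the
  study design. Effect size is reported as `|β̂|` in trait SD units per allele
  copy.

## 4. Significance calibration

* **Permutation thresholds**: trait values are shuffled across hybrids
  (genotypes, and hence LD, untouched); the minimum scan p-value is recorded
  per permutation; the threshold is the empirical 5% quantile (numpy type-7)
  of those minima. "Pooled" mode averages per-trait quantiles into one
  condition-wide threshold; "per-trait" mode keeps one threshold per trait.
  One shared set of shuffle indices is used across traits by default.
* **Cross-class adjustment**: SNP and SV scans differ hugely in variant count,
  so raw thresholds are normalised to the total:
  `adj_c = raw_c · n_c / (n_SNP + n_SV)`. With equal raw thresholds the two
  adjusted/raw ratios sum to exactly 1; with `n_SV = 0` the SNP threshold is
  unchanged.
* **Calling and pruning**: hits pass on strict `p < threshold`. Per trait,
  hits are sorted by ascending p and kept greedily iff `|r| ≤ 0.8` against all
  already-kept hits; pruned hits record which variant displaced them. The
  greedy-versus-kept rule makes the output order-invariant.

## 5. Downstream statistics

* **Locality**: an eQTL within 25 kb of its gene's start on the same
  chromosome is *local*, otherwise *distant*; genes without coordinates are
  *unplaced*.
* **Hotspots**: variants associated with at least 20 distinct genes.
* **Low-frequency enrichment**: 2×2 table of {hit, non-hit} × {population
  MAF < 0.05, ≥ 0.05} among tested variants; fold is the row-rate ratio and
  the p-value is Fisher's exact (two-sided). The non-hit denominator (rather
  than all-tested) reproduces the study's printed worked ratio exactly.
* **Category enrichment**: association *rates* per gene category (e.g.
  accessory vs core) compared by the same 2×2 machinery.
* **Effect-size comparison**: Mann-Whitney U, exact when the pooled sample is
  ≤ 20 without ties, asymptotic tie-corrected otherwise.

## 6. SV catalog

* **Merging**: per-genome calls are linked if they share type and chromosome,
  start within 100 bp (ends too, for inversions/translocations), size ratio
  ≥ 0.8, and — for insertions — Needleman-Wunsch sequence identity ≥ 0.7
  (via `edlib`). Connected components (union-find) become catalog entries; the
  representative is the member with the median start. Merging is invariant to
  input order.
* **Ty flagging**: an SV is Ty-related iff the union of Ty-library intervals
  covers *strictly more than half* of its footprint (overlaps are merged, so
  overlapping library entries are not double-counted). Ty-related SVs split
  into solo-LTR (< 1 kb) vs full/partial elements (≥ 1 kb).
* **SV genotypes**: hybrid dosage = number of carrier parents among its two;
  variants are labelled class `SV` and singleton events are dropped by
  default, mirroring the SNP filter.

## 7. Synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes, plus ground truth for recovery tests. It is **not** a population-
genetic simulator (no coalescent, no mutation/recombination process, no
selection).

* **Source population**: target allele counts follow a truncated power law
  `p(k) ∝ k^(−shape)` on `[1, n_pop − 1]`; `shape` is solved numerically so the
  expected fraction of sites at MAF < 0.05 matches the configured target
  (default 0.927). Haplotypes combine a founder-mosaic backbone (Markov
  switching along each chromosome at `switch_rate` per bp — this carries
  common variants and produces LD) with a direct rare-carrier layer for sites
  below founder resolution. `switch_rate = 1` yields effectively LD-free
  panels.
* **Traits**: per gene, `z = c + u + e` with `c` the planted causal
  combination, `u` a polygenic draw with the panel's own kinship covariance,
  and `e` white noise. The three parts are orthogonalised and rescaled so the
  realized variance shares are exactly `(h2·ρ, h2·(1−ρ), 1−h2)`; `h2` is drawn
  from a Beta law whose parameters are solved so the panel median equals the
  target, with stratified quantile draws pinning the empirical median.
  Ground truth records each planted effect's variant, gene, β and realized
  variance explained.
* **Hotspots**: single panel-common variants (panel MAF ≥ 0.1) assigned to a
  configurable number of target genes.
* **Counts layer**: z-scores can be inverted to synthetic Poisson read counts
  (fixed library size, log-normal baselines, uniform gene lengths) so the
  expression-processing chain is exercised end-to-end.
* **SV calls**: true events with the study's type proportions; carriers drawn
  from a power-law SFS (the reference-like first parent carries nothing); each
  carrier emits one call with jittered position/length and mutated insertion
  sequence; Ty-derived events get library intervals covering ~80-95% of their
  footprint.

All draws come from named child streams of one root seed, so each stage is
independently reproducible.

## 8. Numerical choices

* Kinship eigendecomposition once per panel (`numpy.linalg.eigh`), eigenvalues
  clipped at 0.
* REML by `scipy.optimize.minimize_scalar(method="bounded")`; explicit edge
  checks at `h2 ∈ {0, 1 − 1e-6}`.
* Quantiles: numpy default (type-7 linear interpolation).
* Fisher exact and Mann-Whitney from `scipy.stats`; VCF I/O via `cyvcf2`;
  sequence identity via `edlib` (Needleman-Wunsch distance / max length).
* Dosages stored as `int8`; scans vectorised over variants per trait.

## 9. Limitations

* **~25 effective genetic degrees of freedom.** Every dosage vector in a
  26-parent diallel lies in the ≤26-dimensional span of the parental indicator
  vectors. The kinship built from those same dosages therefore has rank ~26,
  and whitening by it absorbs a large part of any true causal signal (proximal
  contamination; there is no LOCO correction, by design). Consequences: weak
  planted effects (variance explained ≲ 10%) are usually *correctly*
  non-significant after permutation calibration, and power analyses must plant
  strong effects.
* **Two-carrier "twins".** Variants carried by the same two parents have
  identical hybrid dosage patterns (`|r| = 1`) regardless of their population
  MAFs; there are only `C(26,2) = 325` distinct two-carrier patterns. LD
  pruning then assigns hit credit within a twin group by an arbitrary
  tie-break, which systematically dilutes low-frequency enrichment measured on
  pruned hit sets. Enrichment recovery is therefore assessed by crediting
  detection at the planted variant itself.
* **Panel attrition.** Only sites with 2-24 parental carriers are testable;
  with a rare-dominated source SFS this keeps ~8% of polymorphic sites, so
  simulated panels need several-fold more source sites than desired tested
  variants.
* The generator's genome is simplistic: equal-length chromosomes, uniform site
  and gene placement, no reference bias, no mapping noise beyond the Poisson
  count layer.
* `fit_variance_components` reports boundary optima (`h2 = 0` or `~1`) as
  non-converged rather than failing; callers should treat `h2g` as censored
  there.
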