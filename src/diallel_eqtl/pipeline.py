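"""End-to-end orchestration: simulate -> genotypes -> expression -> GWAS -> report.

The nine stages (simulate, genotype, expression, kinship_h2, scan_snp,
scan_sv, thresholds, call_prune, report) each write their artifacts into the
output directory and append to a JSON manifest carrying parameters, seeds
and checksums, so a rerun with the same configuration reproduces identical
files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import eqtl_analysis, expression, genotypes, io, mixed_model, significance, simulate, sv_catalog

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serialisable to/from YAML."""

    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    kinship_estimator: str = "centered_grm"
    r2_threshold: float = 0.8        # LD filter for the kinship matrix
    ld_window: int = 50
    n_perm: int = 100
    level: float = 0.05
    threshold_mode: str = "pooled"
    r_prune_threshold: float = 0.8   # |r| for pruning linked hits
    local_window: int = 25_000
    maf_cutoff: float = 0.05
    rare_cutoff: float = 0.01
    hotspot_min_genes: int = 20
    ty_length_boundary: int = 1_000
    sv_position_tol: int = 100
    sv_size_ratio_min: float = 0.8
    sv_seq_identity_min: float = 0.7
    run_sv: bool = True
    use_count_layer: bool = True     # re-derive z-scores through synthetic counts

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        for name in ("r2_threshold", "r_prune_threshold", "maf_cutoff", "rare_cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["simulation"]["hotspot_gene_range"] = list(
            payload["simulation"]["hotspot_gene_range"]
        )
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim_payload = payload.pop("simulation", {})
        if "hotspot_gene_range" in sim_payload:
            sim_payload["hotspot_gene_range"] = tuple(sim_payload["hotspot_gene_range"])
        if "sv_type_weights" in sim_payload and sim_payload["sv_type_weights"] is not None:
            sim_payload["sv_type_weights"] = dict(sim_payload["sv_type_weights"])
        sim = simulate.SimulationConfig(**sim_payload)
        return cls(simulation=sim, **payload)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on synthetic data and return the results bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = io.Manifest(outdir, params=dataclasses.asdict(config))
    sim = config.simulation
    results: dict = {}

    # -- simulate -----------------------------------------------------------
    variants, pop_haps, pop_maf = simulate.simulate_source_population(sim)
    parents = simulate.sample_parents(variants, pop_haps, sim)
    design = simulate.simulate_design(sim)
    gene_table = simulate.simulate_gene_table(sim)
    traits_true, truth, snp_matrix = simulate.simulate_expression(
        parents, design, variants, sim, gene_table
    )
    io.write_parent_vcf(outdir / "parents.vcf", variants, parents)
    gene_table.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    truth.causal_effects.to_csv(outdir / "truth_causal.tsv", sep="\t", index=False)
    io.dump_json(
        outdir / "truth_summary.json",
        {
            "maf_lt_0.05_fraction": float((pop_maf < 0.05).mean()),
            "median_realized_h2": float(truth.trait_h2.median()),
            "hotspot_variants": truth.hotspot_variants,
        },
    )
    manifest.record(
        "simulate",
        ["parents.vcf", "genes.tsv", "truth_causal.tsv", "truth_summary.json"],
        seed=sim.seed, n_variants=len(variants),
    )
    results["truth"] = truth

    # -- genotype -----------------------------------------------------------
    io.write_design(outdir / "design.tsv", design)
    io.write_genotype_matrix(outdir / "snp_matrix.tsv", snp_matrix, outdir / "snp_variants.tsv")
    manifest.record(
        "genotype", ["design.tsv", "snp_matrix.tsv", "snp_variants.tsv"],
        n_hybrids=snp_matrix.n_hybrids, n_variants=snp_matrix.n_variants,
    )
    results["snp_matrix"] = snp_matrix
    results["design"] = design

    # -- expression ---------------------------------------------------------
    if config.use_count_layer:
        gene_meta, counts = simulate.zscores_to_counts(traits_true, sim)
        cm = expression.CountMatrix(gene_meta, list(traits_true.hybrids), counts)
        tpm = expression.compute_tpm(cm)
        tpm = expression.filter_expressed_genes(tpm)
        traits = expression.zscore_traits(tpm)
    else:
        traits = traits_true
    io.write_trait_matrix(outdir / "traits_zscore.tsv", traits)
    manifest.record("expression", ["traits_zscore.tsv"], n_traits=len(traits.gene_ids))
    results["traits"] = traits

    # -- kinship + heritability --------------------------------------------
    ld_matrix = genotypes.ld_filter_matrix(snp_matrix, config.r2_threshold, config.ld_window)
    kinship = mixed_model.estimate_kinship(ld_matrix, config.kinship_estimator)
    eig = mixed_model.EigenKinship(kinship)
    h2_table, h2_median = mixed_model.estimate_h2g_panel(traits.values, traits.gene_ids, eig)
    pd.DataFrame(kinship.values, index=kinship.hybrids, columns=kinship.hybrids).to_csv(
        outdir / "kinship.tsv", sep="\t"
    )
    h2_table.to_csv(outdir / "h2.tsv", sep="\t", index=False)
    manifest.record("kinship_h2", ["kinship.tsv", "h2.tsv"], median_h2g=h2_median)
    results["h2_median"] = h2_median
    results["h2_table"] = h2_table

    # -- scans ---------------------------------------------------------------
    snp_records = mixed_model.scan_single_variants(traits.values, traits.gene_ids, snp_matrix, eig)
    snp_records.to_csv(outdir / "scan_snp.tsv", sep="\t", index=False)
    manifest.record("scan_snp", ["scan_snp.tsv"], n_records=len(snp_records))

    sv_matrix = None
    sv_records = pd.DataFrame()
    if config.run_sv:
        calls, ty_library, sv_truth = simulate.simulate_sv_catalog(sim)
        catalog, presence = sv_catalog.merge_sv_calls(
            calls, config.sv_position_tol, config.sv_size_ratio_min, config.sv_seq_identity_min
        )
        if len(ty_library):
            catalog = sv_catalog.flag_ty_related(catalog, ty_library)
            catalog = sv_catalog.split_ty_groups(catalog, config.ty_length_boundary)
        presence_full = presence.copy()
        for p in design.parents:  # reference-like parents: everything absent
            if p not in presence_full.columns:
                presence_full[p] = False
        sv_matrix = sv_catalog.build_sv_genotype_matrix(catalog, presence_full, design)
        io.write_sv_vcf(outdir / "sv_calls.vcf", calls)
        catalog.drop(columns=["members"]).to_csv(outdir / "sv_catalog.tsv", sep="\t", index=False)
        if len(ty_library):
            io.write_bed(outdir / "ty_library.bed", ty_library)
        if sv_matrix.n_variants > 0:
            sv_records = mixed_model.scan_single_variants(
                traits.values, traits.gene_ids, sv_matrix, eig
            )
        sv_records.to_csv(outdir / "scan_sv.tsv", sep="\t", index=False)
        manifest.record(
            "scan_sv",
            ["sv_calls.vcf", "sv_catalog.tsv", "scan_sv.tsv"]
            + (["ty_library.bed"] if len(ty_library) else []),
            n_svs=int(sv_matrix.n_variants), n_records=len(sv_records),
        )
        results["sv_matrix"] = sv_matrix
        results["sv_truth"] = sv_truth
    else:
        manifest.record("scan_sv", [], skipped=True)

    # -- thresholds ----------------------------------------------------------
    thr_snp = significance.permutation_threshold(
        traits.values, traits.gene_ids, snp_matrix, eig,
        n_perm=config.n_perm, level=config.level, mode=config.threshold_mode,
        seed=sim.seed + 1,
    )
    raw_sv = thr_snp.raw["SNP"]
    n_sv = 0
    if config.run_sv and sv_matrix is not None and sv_matrix.n_variants > 0:
        thr_sv = significance.permutation_threshold(
            traits.values, traits.gene_ids, sv_matrix, eig,
            n_perm=config.n_perm, level=config.level, mode=config.threshold_mode,
            seed=sim.seed + 2,
        )
        raw_sv = thr_sv.raw["SV"]
        n_sv = sv_matrix.n_variants
    thresholds = significance.adjust_class_thresholds(
        thr_snp.raw["SNP"], raw_sv, snp_matrix.n_variants, n_sv
    )
    thresholds.n_permutations = config.n_perm
    thresholds.level = config.level
    io.dump_json(
        outdir / "thresholds.json",
        {
            "raw": thresholds.raw, "adjusted": thresholds.adjusted,
            "n_variants": thresholds.n_variants, "n_permutations": config.n_perm,
            "level": config.level, "mode": config.threshold_mode, "seed": sim.seed,
        },
    )
    manifest.record("thresholds", ["thresholds.json"], **thresholds.adjusted)
    results["thresholds"] = thresholds

    # -- call + prune --------------------------------------------------------
    called = significance.call_hits(snp_records, thresholds, variant_class="SNP")
    hits = called[called["passes"]]
    pruned = significance.prune_linked_hits(hits, snp_matrix, config.r_prune_threshold)
    eqtls = pruned[pruned["kept"]].copy() if len(pruned) else pruned
    if config.run_sv and len(sv_records):
        called_sv = significance.call_hits(sv_records, thresholds, variant_class="SV")
        sv_hits = called_sv[called_sv["passes"]]
        sv_pruned = significance.prune_linked_hits(sv_hits, sv_matrix, config.r_prune_threshold)
        sv_eqtls = sv_pruned[sv_pruned["kept"]].copy() if len(sv_pruned) else sv_pruned
    else:
        sv_eqtls = pd.DataFrame()
    eqtls.to_csv(outdir / "eqtl_snp.tsv", sep="\t", index=False)
    sv_eqtls.to_csv(outdir / "eqtl_sv.tsv", sep="\t", index=False)
    manifest.record(
        "call_prune", ["eqtl_snp.tsv", "eqtl_sv.tsv"],
        n_snp_eqtl=len(eqtls), n_sv_eqtl=len(sv_eqtls),
    )
    results["snp_eqtls"] = eqtls
    results["sv_eqtls"] = sv_eqtls

    # -- report --------------------------------------------------------------
    vmeta = snp_matrix.variants.set_index("id")
    report = eqtls.copy()
    if len(report):
        report["chrom"] = report["variant_id"].map(vmeta["chrom"])
        report["pos"] = report["variant_id"].map(vmeta["pos"])
        report = eqtl_analysis.classify_local_distant(report, gene_table, config.local_window)
    summary = eqtl_analysis.summarize_counts(report)
    hotspots = eqtl_analysis.detect_hotspots(report, config.hotspot_min_genes)
    enrichment = {}
    if len(report):
        enr = eqtl_analysis.maf_enrichment(
            report["variant_id"].unique(), snp_matrix.variants, config.maf_cutoff
        )
        enrichment = {
            "lowfreq_fold": enr.fold, "lowfreq_odds_ratio": enr.odds_ratio,
            "lowfreq_p": enr.p_value,
            "table": {"a": enr.a, "b": enr.b, "c": enr.c, "d": enr.d},
        }
        local = report.loc[report["locality"] == "local", "effect_size"]
        distant = report.loc[report["locality"] == "distant", "effect_size"]
        if len(local) and len(distant):
            enrichment["local_vs_distant"] = eqtl_analysis.compare_effect_sizes(local, distant)
    report.to_csv(outdir / "eqtl_report.tsv", sep="\t", index=False)
    hotspots.to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
    io.dump_json(outdir / "enrichment.json", {"summary": summary, **enrichment})
    manifest.record(
        "report", ["eqtl_report.tsv", "hotspots.tsv", "enrichment.json"], **summary
    )
    results["report"] = report
    results["summary"] = summary
    results["hotspots"] = hotspots
    results["enrichment"] = enrichment
    return results
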