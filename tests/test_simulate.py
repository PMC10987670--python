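import numpy as np
import pandas as pd
import pytest

from diallel_eqtl import (
    SimulationConfig,
    merge_sv_calls,
    sample_parents,
    simulate_design,
    simulate_expression,
    simulate_source_population,
    simulate_sv_catalog,
    tune_sfs_shape,
    zscores_to_counts,
)


class TestTuneSfsShape:
    def test_hits_target_fraction(self):
        n = 1000
        shape = tune_sfs_shape(n, 0.9)
        k = np.arange(1, n)
        w = k.astype(float) ** (-shape)
        low = np.minimum(k, n - k) / n < 0.05
        assert w[low].sum() / w.sum() == pytest.approx(0.9, abs=1e-8)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            tune_sfs_shape(1000, 0.001)


class TestSourcePopulation:
    def test_shapes_and_polymorphism(self, small_cfg):
        variants, haps, maf = simulate_source_population(small_cfg)
        assert haps.shape == (small_cfg.n_pop, len(variants))
        assert set(np.unique(haps)) <= {0, 1}
        counts = haps.sum(axis=0)
        assert counts.min() >= 1 and counts.max() <= small_cfg.n_pop - 1
        np.testing.assert_allclose(
            maf, np.minimum(counts, small_cfg.n_pop - counts) / small_cfg.n_pop
        )

    def test_realized_lowfreq_fraction_near_target(self):
        cfg = SimulationConfig(seed=3, n_pop=800, n_snps=4000, n_genes=10,
                               hotspot_count=0)
        variants, haps, maf = simulate_source_population(cfg)
        assert abs((maf < 0.05).mean() - cfg.target_lowfreq_fraction) < 0.05

    def test_positions_sorted_within_chromosome(self, small_cfg):
        variants, _, _ = simulate_source_population(small_cfg)
        for _, grp in variants.groupby("chrom"):
            assert grp.pos.is_monotonic_increasing

    def test_deterministic_same_seed(self, small_cfg):
        v1, h1, _ = simulate_source_population(small_cfg)
        v2, h2, _ = simulate_source_population(small_cfg)
        pd.testing.assert_frame_equal(v1, v2)
        np.testing.assert_array_equal(h1, h2)


class TestSampleParentsAndDesign:
    def test_parent_ids_and_shape(self, small_cfg):
        variants, haps, _ = simulate_source_population(small_cfg)
        parents = sample_parents(variants, haps, small_cfg)
        assert list(parents.index) == [f"P{i + 1:02d}" for i in range(26)]
        assert parents.shape == (26, len(variants))
        assert set(np.unique(parents.values)) <= {0, 1}

    def test_design_counts(self, small_cfg):
        design = simulate_design(small_cfg)
        assert len(design.hybrids) == 351


class TestSimulateExpression:
    def test_traits_unit_variance_and_h2(self, small_sim):
        traits, truth = small_sim["traits"], small_sim["truth"]
        np.testing.assert_allclose(traits.values.var(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(traits.values.mean(axis=1), 0.0, atol=1e-9)
        assert ((truth.trait_h2 >= 0) & (truth.trait_h2 < 1)).all()

    def test_causal_effects_reference_panel_variants(self, small_sim):
        truth, matrix = small_sim["truth"], small_sim["matrix"]
        ce = truth.causal_effects
        assert set(ce.variant_id) <= set(matrix.variants["id"])
        assert set(ce.gene_id) <= set(small_sim["traits"].gene_ids)
        assert ((ce.var_explained >= 0) & (ce.var_explained <= 1)).all()

    def test_hotspot_variants_recorded(self, small_sim):
        truth = small_sim["truth"]
        assert len(truth.hotspot_variants) == 1
        hot = truth.causal_effects[truth.causal_effects.is_hotspot]
        assert set(hot.variant_id) == set(truth.hotspot_variants)
        # hotspot hits the configured number of genes
        assert 5 <= hot.gene_id.nunique() <= 10

    def test_deterministic_same_seed(self, small_cfg, small_sim):
        variants, haps, _ = simulate_source_population(small_cfg)
        parents = sample_parents(variants, haps, small_cfg)
        design = simulate_design(small_cfg)
        traits2, truth2, _ = simulate_expression(parents, design, variants, small_cfg)
        np.testing.assert_array_equal(small_sim["traits"].values, traits2.values)
        pd.testing.assert_frame_equal(small_sim["truth"].causal_effects, truth2.causal_effects)

    def test_panel_filters_applied(self, small_sim):
        # every retained variant is carried by >= 2 and <= n-2 parents
        parents = small_sim["parents"]
        sub = parents[list(small_sim["matrix"].variants["id"])]
        k = sub.sum(axis=0)
        assert (k >= 2).all() and (k <= 24).all()


class TestConfigValidation:
    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_pop=0)
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_genes=-5)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="causal_gene_fraction"):
            SimulationConfig(causal_gene_fraction=1.5)

    def test_hotspot_range_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="hotspot_gene_range"):
            SimulationConfig(n_genes=10, hotspot_gene_range=(20, 80))

    def test_too_many_parents_rejected(self):
        with pytest.raises(ValueError, match="parents"):
            SimulationConfig(n_pop=10, n_parents=26)

    def test_sv_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(sv_type_weights={"deletion": 0.5})


class TestSvCatalogSimulation:
    def test_type_proportions_and_first_parent_empty(self):
        cfg = SimulationConfig(seed=5, n_snps=100, n_genes=10, n_svs=600,
                               hotspot_count=0)
        calls, ty_lib, truth = simulate_sv_catalog(cfg)
        assert len(truth) == 600
        frac_ins = (truth.sv_type == "insertion").mean()
        assert abs(frac_ins - 1032 / 1953) < 0.07
        # the reference-like first parent never carries an SV
        assert "P01" not in set(calls.genome)
        assert abs(truth.ty_related.mean() - cfg.sv_ty_fraction) < 0.07

    def test_merge_recovers_true_events(self):
        cfg = SimulationConfig(seed=9, n_snps=100, n_genes=10, n_svs=150,
                               hotspot_count=0)
        calls, _, truth = simulate_sv_catalog(cfg)
        catalog, presence = merge_sv_calls(calls)
        # merging the jittered per-parent calls should reassemble most true
        # events (distinct events can occasionally collide by position)
        assert abs(len(catalog) - len(truth)) <= 0.05 * len(truth)
        # carrier counts of recovered events match the truth distribution
        assert catalog.n_carriers.sum() == len(calls)


class TestZscoresToCounts:
    def test_roundtrip_correlation(self, small_cfg, small_sim):
        traits = small_sim["traits"]
        meta, counts = zscores_to_counts(traits, small_cfg)
        assert counts.shape == traits.values.shape
        assert (counts >= 0).all()
        assert list(meta.gene_id) == traits.gene_ids
        # log counts correlate with the z-scores that generated them
        rs = []
        for i in range(len(traits.gene_ids)):
            with np.errstate(divide="ignore"):
                lc = np.log2(counts[i] + 1.0)
            if lc.std() > 0:
                rs.append(np.corrcoef(traits.values[i], lc)[0, 1])
        assert np.median(rs) > 0.3
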