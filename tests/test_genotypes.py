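import numpy as np
import pandas as pd
import pytest

from diallel_eqtl import (
    GenotypeMatrix,
    compute_ld,
    compute_panel_maf,
    enumerate_crosses,
    filter_biallelic,
    infer_hybrid_genotypes,
    ld_filter_matrix,
    remove_singletons,
)
from diallel_eqtl.genotypes import hybrid_id, parent_carrier_counts


class TestEnumerateCrosses:
    def test_counts_with_selfs(self):
        design = enumerate_crosses([f"P{i:02d}" for i in range(1, 27)])
        assert len(design.hybrids) == 351
        assert design.n_heterozygous == 325
        assert design.n_homozygous == 26

    def test_counts_without_selfs(self):
        design = enumerate_crosses(["A", "B", "C", "D"], include_selfs=False)
        assert len(design.hybrids) == 6
        assert design.n_homozygous == 0

    def test_duplicate_parents_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_crosses(["A", "A", "B"])

    def test_too_few_parents_rejected(self):
        with pytest.raises(ValueError):
            enumerate_crosses(["A"])

    def test_hybrid_id_is_order_invariant(self):
        assert hybrid_id("B", "A") == hybrid_id("A", "B") == "AxB"


class TestInferHybridGenotypes:
    def test_dosage_is_haplotype_sum(self, toy_parents):
        design = enumerate_crosses(["A", "B", "C"])
        matrix = infer_hybrid_genotypes(toy_parents, design)
        got = dict(zip(matrix.hybrids, matrix.dosages.tolist()))
        assert got["AxB"] == [1, 1, 2, 0]
        assert got["AxC"] == [0, 1, 2, 1]
        assert got["BxC"] == [1, 0, 2, 1]

    def test_selfs_are_homozygous(self, toy_parents):
        design = enumerate_crosses(["A", "B", "C"])
        matrix = infer_hybrid_genotypes(toy_parents, design)
        for p in "ABC":
            row = matrix.dosages[matrix.hybrids.index(f"{p}x{p}")]
            assert set(row) <= {0, 2}
            np.testing.assert_array_equal(row, 2 * toy_parents.loc[p].to_numpy())

    def test_missing_parent_rejected(self, toy_parents):
        design = enumerate_crosses(["A", "B", "Z"])
        with pytest.raises(KeyError, match="Z"):
            infer_hybrid_genotypes(toy_parents, design)

    def test_nan_call_rejected(self, toy_parents):
        hap = toy_parents.astype(float)
        hap.loc["A", "v1"] = np.nan
        design = enumerate_crosses(["A", "B", "C"])
        with pytest.raises(ValueError, match="missing parental calls"):
            infer_hybrid_genotypes(hap, design)

    def test_non_binary_rejected(self, toy_parents):
        hap = toy_parents.copy()
        hap.loc["A", "v1"] = 2
        design = enumerate_crosses(["A", "B", "C"])
        with pytest.raises(ValueError, match="0/1"):
            infer_hybrid_genotypes(hap, design)


class TestPanelMaf:
    def test_matches_carrier_fraction(self, toy_parents):
        design = enumerate_crosses(["A", "B", "C"])
        matrix = infer_hybrid_genotypes(toy_parents, design)
        maf = compute_panel_maf(matrix)
        counts = parent_carrier_counts(toy_parents)
        expected = np.minimum(counts / 3, 1 - counts / 3)
        np.testing.assert_allclose(maf, expected)

    def test_empty_inclusion_rejected(self, toy_parents):
        design = enumerate_crosses(["A", "B", "C"])
        matrix = infer_hybrid_genotypes(toy_parents, design)
        with pytest.raises(ValueError):
            compute_panel_maf(matrix, included_hybrids=[])


class TestRemoveSingletons:
    def test_drops_alt_and_ref_singletons(self):
        hap = pd.DataFrame(
            {
                "alt1": [1, 0, 0, 0],   # alt singleton -> dropped
                "ref1": [1, 1, 1, 0],   # ref singleton -> dropped
                "keep": [1, 1, 0, 0],
                "mono": [0, 0, 0, 0],   # not a singleton; kept by this filter
            },
            index=list("ABCD"),
            dtype=np.int8,
        )
        design = enumerate_crosses(list("ABCD"))
        matrix = infer_hybrid_genotypes(hap, design)
        out = remove_singletons(matrix, hap)
        assert list(out.variants["id"]) == ["keep", "mono"]

    def test_asymmetric_mode_keeps_ref_singletons(self):
        hap = pd.DataFrame(
            {"alt1": [1, 0, 0, 0], "ref1": [1, 1, 1, 0]}, index=list("ABCD"), dtype=np.int8
        )
        design = enumerate_crosses(list("ABCD"))
        matrix = infer_hybrid_genotypes(hap, design)
        out = remove_singletons(matrix, hap, minor_allele_symmetric=False)
        assert list(out.variants["id"]) == ["ref1"]

    def test_missing_haplotype_column_rejected(self, toy_parents):
        design = enumerate_crosses(["A", "B", "C"])
        matrix = infer_hybrid_genotypes(toy_parents, design)
        with pytest.raises(KeyError):
            remove_singletons(matrix, toy_parents.drop(columns=["v2"]))


def test_filter_biallelic_drops_multiallelic():
    variants = pd.DataFrame(
        {
            "id": ["a", "b", "c"],
            "chrom": "I",
            "pos": [1, 2, 3],
            "ref": "A",
            "alt": ["T", "T,G", "C"],
            "variant_class": "SNP",
        }
    )
    out = filter_biallelic(variants)
    assert list(out["id"]) == ["a", "c"]
    assert len(filter_biallelic(variants.iloc[:0])) == 0


class TestLd:
    def _matrix(self, cols: dict):
        ids = list(cols)
        variants = pd.DataFrame(
            {
                "id": ids,
                "chrom": "I",
                "pos": np.arange(1, len(ids) + 1),
                "ref": "A",
                "alt": "T",
                "variant_class": "SNP",
            }
        )
        dosages = np.column_stack([cols[i] for i in ids]).astype(np.int8)
        hybrids = [f"h{i}" for i in range(dosages.shape[0])]
        return GenotypeMatrix(hybrids, variants, dosages)

    def test_compute_ld_perfect_and_inverse(self):
        m = self._matrix({"x": [0, 1, 2, 0], "same": [0, 1, 2, 0], "inv": [2, 1, 0, 2]})
        r, r2 = compute_ld(m, 0, 1)
        assert r == pytest.approx(1.0)
        r, r2 = compute_ld(m, 0, 2)
        assert r == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_compute_ld_monomorphic_is_nan(self):
        m = self._matrix({"x": [0, 1, 2, 0], "mono": [1, 1, 1, 1]})
        r, r2 = compute_ld(m, 0, 1)
        assert np.isnan(r) and np.isnan(r2)

    def test_ld_filter_drops_duplicates_and_monomorphic(self):
        m = self._matrix(
            {"x": [0, 1, 2, 0, 1], "dup": [0, 1, 2, 0, 1], "mono": [2] * 5, "y": [1, 0, 0, 2, 1]}
        )
        out = ld_filter_matrix(m, r2_threshold=0.8)
        assert list(out.variants["id"]) == ["x", "y"]

    def test_ld_filter_keeps_everything_below_threshold(self, small_sim):
        matrix = small_sim["matrix"]
        out = ld_filter_matrix(matrix, r2_threshold=1.0)
        # r^2 can only reach 1.0 for exact duplicates; threshold is not strict
        assert out.n_variants <= matrix.n_variants


class TestGenotypeMatrixValidation:
    def test_shape_mismatch_rejected(self, toy_parents):
        design = enumerate_crosses(["A", "B", "C"])
        matrix = infer_hybrid_genotypes(toy_parents, design)
        with pytest.raises(ValueError, match="shape"):
            GenotypeMatrix(matrix.hybrids, matrix.variants, matrix.dosages[:, :2])

    def test_bad_dosage_rejected(self, toy_parents):
        design = enumerate_crosses(["A", "B", "C"])
        matrix = infer_hybrid_genotypes(toy_parents, design)
        bad = matrix.dosages.copy()
        bad[0, 0] = 3
        with pytest.raises(ValueError, match="dosages"):
            GenotypeMatrix(matrix.hybrids, matrix.variants, bad)

    def test_subset_hybrids_unknown_id(self, toy_parents):
        design = enumerate_crosses(["A", "B", "C"])
        matrix = infer_hybrid_genotypes(toy_parents, design)
        with pytest.raises(KeyError):
            matrix.subset_hybrids(["AxB", "nope"])

    def test_subset_roundtrip(self, toy_parents):
        design = enumerate_crosses(["A", "B", "C"])
        matrix = infer_hybrid_genotypes(toy_parents, design)
        sub = matrix.subset_hybrids(["AxB", "BxC"])
        assert sub.n_hybrids == 2
        mask = np.array([True, False, True, False])
        subv = matrix.subset_variants(mask)
        assert list(subv.variants["id"]) == ["v1", "v3"]
        np.testing.assert_array_equal(subv.dosages, matrix.dosages[:, mask])
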