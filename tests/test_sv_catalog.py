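import pandas as pd
import pytest

from diallel_eqtl import (
    build_sv_genotype_matrix,
    enumerate_crosses,
    flag_ty_related,
    merge_sv_calls,
    sequence_identity,
    split_ty_groups,
)


def _call(id, genome, start, sv_type="deletion", length=500, chrom="I", sequence=""):
    return {
        "id": id,
        "genome": genome,
        "chrom": chrom,
        "start": start,
        "end": start + length - 1,
        "sv_type": sv_type,
        "length": length,
        "sequence": sequence,
    }


class TestSequenceIdentity:
    def test_identical(self):
        assert sequence_identity("ACGTACGT", "acgtacgt") == 1.0

    def test_single_mismatch(self):
        assert sequence_identity("ACGT", "ACGA") == pytest.approx(0.75)

    def test_bounds(self):
        assert 0.0 <= sequence_identity("AAAA", "TTTT") <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_identity("", "ACGT")


class TestMergeSvCalls:
    def test_jittered_calls_merge(self):
        calls = pd.DataFrame(
            [_call("c1", "P01", 1000), _call("c2", "P02", 1050), _call("c3", "P03", 1090)]
        )
        catalog, presence = merge_sv_calls(calls)
        assert len(catalog) == 1
        assert catalog.n_carriers.iloc[0] == 3
        assert presence.iloc[0].all()
        # representative is the member with the median start
        assert catalog.start.iloc[0] == 1050

    def test_position_tolerance_boundary(self):
        calls = pd.DataFrame([_call("c1", "P01", 1000), _call("c2", "P02", 1101)])
        catalog, _ = merge_sv_calls(calls, position_tol=100)
        assert len(catalog) == 2
        calls2 = pd.DataFrame([_call("c1", "P01", 1000), _call("c2", "P02", 1100)])
        catalog2, _ = merge_sv_calls(calls2, position_tol=100)
        assert len(catalog2) == 1

    def test_different_type_not_merged(self):
        calls = pd.DataFrame(
            [_call("c1", "P01", 1000), _call("c2", "P02", 1000, sv_type="duplication")]
        )
        catalog, _ = merge_sv_calls(calls)
        assert len(catalog) == 2

    def test_size_ratio_gate(self):
        calls = pd.DataFrame(
            [_call("c1", "P01", 1000, length=500), _call("c2", "P02", 1000, length=300)]
        )
        catalog, _ = merge_sv_calls(calls, size_ratio_min=0.8)
        assert len(catalog) == 2

    def test_insertion_sequence_gate(self):
        near = _call("c2", "P02", 1000, sv_type="insertion", length=8, sequence="ACGTACGA")
        far = _call("c3", "P03", 1000, sv_type="insertion", length=8, sequence="TTTTTTTT")
        base = _call("c1", "P01", 1000, sv_type="insertion", length=8, sequence="ACGTACGT")
        catalog, _ = merge_sv_calls(pd.DataFrame([base, near, far]))
        # base+near identical enough (7/8); far is not
        assert len(catalog) == 2
        assert sorted(catalog.n_carriers) == [1, 2]

    def test_input_order_invariance(self):
        calls = pd.DataFrame(
            [_call("c1", "P01", 1000), _call("c2", "P02", 1050), _call("c3", "P03", 4000)]
        )
        cat1, pres1 = merge_sv_calls(calls)
        cat2, pres2 = merge_sv_calls(calls.iloc[::-1].reset_index(drop=True))
        assert list(cat1.start) == list(cat2.start)
        pd.testing.assert_frame_equal(
            pres1.reset_index(drop=True), pres2.reset_index(drop=True)
        )

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            merge_sv_calls(pd.DataFrame([{"id": "x"}]))


class TestTyFlagging:
    def _library(self):
        return pd.DataFrame({"chrom": ["I", "I"], "start": [1000, 1200], "end": [1299, 1399]})

    def test_strict_half_boundary(self):
        # SV length 100 at 1250: covered 1250..1299 and 1200..1399 union -> full
        svs = pd.DataFrame(
            [
                # overlap exactly 50 of 100 -> NOT flagged
                {"chrom": "I", "start": 1350, "length": 100, "sv_type": "deletion"},
                # overlap 51 of 100 -> flagged
                {"chrom": "I", "start": 1349, "length": 100, "sv_type": "deletion"},
            ]
        )
        out = flag_ty_related(svs, self._library())
        assert list(out.ty_related) == [False, True]

    def test_union_overlap_not_double_counted(self):
        # overlapping library entries on the same span
        lib = pd.DataFrame({"chrom": ["I", "I"], "start": [1000, 1000], "end": [1099, 1099]})
        svs = pd.DataFrame([{"chrom": "I", "start": 1000, "length": 200, "sv_type": "deletion"}])
        out = flag_ty_related(svs, lib)
        # overlap is 100 of 200 = exactly half -> not flagged
        assert not out.ty_related.iloc[0]

    def test_other_chromosome_ignored(self):
        svs = pd.DataFrame([{"chrom": "II", "start": 1000, "length": 100, "sv_type": "deletion"}])
        out = flag_ty_related(svs, self._library())
        assert not out.ty_related.iloc[0]

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            flag_ty_related(pd.DataFrame(), pd.DataFrame(columns=["chrom", "start", "end"]))


class TestSplitTyGroups:
    def test_length_boundary(self):
        catalog = pd.DataFrame(
            {
                "length": [340, 999, 1000, 6000, 400],
                "ty_related": [True, True, True, True, False],
            }
        )
        out = split_ty_groups(catalog, length_boundary=1000)
        assert list(out.ty_group) == [
            "LTR_only", "LTR_only", "full_or_partial_Ty", "full_or_partial_Ty", "none",
        ]

    def test_requires_flags(self):
        with pytest.raises(ValueError, match="flag_ty_related"):
            split_ty_groups(pd.DataFrame({"length": [100]}))


class TestBuildSvGenotypeMatrix:
    def _inputs(self):
        calls = pd.DataFrame(
            [
                _call("c1", "A", 1000),
                _call("c2", "B", 1010),
                _call("c3", "A", 5000, sv_type="insertion", length=300, sequence="ACGT" * 75),
                _call("c4", "C", 9000),
                _call("c5", "D", 9010),
            ]
        )
        catalog, presence = merge_sv_calls(calls)
        for p in ["A", "B", "C", "D"]:
            if p not in presence.columns:
                presence[p] = False
        design = enumerate_crosses(["A", "B", "C", "D"])
        return catalog, presence, design

    def test_dosages_follow_presence(self):
        catalog, presence, design = self._inputs()
        matrix = build_sv_genotype_matrix(catalog, presence, design, drop_singletons=False)
        assert matrix.source == "SV"
        assert matrix.n_variants == 3
        row = dict(zip(matrix.hybrids, matrix.dosages[:, 0]))
        assert row["AxB"] == 2 and row["AxC"] == 1 and row["CxD"] == 0

    def test_singletons_dropped_by_default(self):
        catalog, presence, design = self._inputs()
        matrix = build_sv_genotype_matrix(catalog, presence, design)
        # the insertion private to parent A is removed
        assert matrix.n_variants == 2
        assert all(t == "deletion" for t in matrix.variants.sv_type)

    def test_missing_parent_rejected(self):
        catalog, presence, design = self._inputs()
        with pytest.raises(KeyError, match="absent"):
            build_sv_genotype_matrix(catalog, presence.drop(columns=["D"]), design)
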