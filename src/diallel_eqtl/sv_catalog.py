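"""Structural-variant catalog: cross-genome merging, Ty flagging, genotypes.

SVs (>= 50 bp) are called independently against the reference in each
parental genome, so the same event appears once per carrier.  Calls are
collapsed into population-level occurrences when they have the same type,
nearby breakpoints, similar size and (for insertions with sequences) similar
sequence; merge groups are the connected components of that link relation.

SVs derived from Ty retrotransposons are flagged when Ty/LTR intervals cover
strictly more than half of the SV footprint, and split into solo-LTR events
(~340 bp) versus full or partial Ty elements (~6 kb) at a length boundary.
"""

from __future__ import annotations

import logging

import edlib
import numpy as np
import pandas as pd

from .genotypes import CrossDesign, GenotypeMatrix, infer_hybrid_genotypes, remove_singletons

logger = logging.getLogger(__name__)

SV_TYPES = ("insertion", "deletion", "duplication", "contraction", "translocation", "inversion")
MIN_SV_LENGTH = 50
TY_LENGTH_BOUNDARY = 1_000  # bp: below = solo LTR, at/above = full/partial Ty

#: call-set columns required for merging
SV_CALL_COLUMNS = ("id", "genome", "chrom", "start", "end", "sv_type", "length")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    Unit-cost global (NW) edit distance; identity = 1 - dist/max(len).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    dist = edlib.align(seq_a.upper(), seq_b.upper(), mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(seq_a), len(seq_b))


def _linked(
    a: pd.Series,
    b: pd.Series,
    position_tol: int,
    size_ratio_min: float,
    seq_identity_min: float,
) -> bool:
    if a["sv_type"] != b["sv_type"] or a["chrom"] != b["chrom"]:
        return False
    if abs(int(a["start"]) - int(b["start"])) > position_tol:
        return False
    # translocations and inversions must agree on both breakpoints
    if a["sv_type"] in ("translocation", "inversion"):
        if abs(int(a["end"]) - int(b["end"])) > position_tol:
            return False
    la, lb = int(a["length"]), int(b["length"])
    if min(la, lb) / max(la, lb) < size_ratio_min:
        return False
    if a["sv_type"] == "insertion":
        sa = a.get("sequence")
        sb = b.get("sequence")
        if isinstance(sa, str) and sa and isinstance(sb, str) and sb:
            if sequence_identity(sa, sb) < seq_identity_min:
                return False
    return True


def merge_sv_calls(
    calls: pd.DataFrame,
    position_tol: int = 100,
    size_ratio_min: float = 0.8,
    seq_identity_min: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse per-genome SV calls into a population catalog.

    ``calls`` holds one row per call with columns id, genome, chrom, start,
    end, sv_type, length and optionally sequence.  Returns
    ``(catalog, presence)``: the catalog has one representative row per
    merge group (member with the median start; ties broken by lowest genome
    id) plus ``merge_group`` and ``members``; ``presence`` is a groups x
    genomes boolean table.  The result is invariant to input order.
    """
    missing = [c for c in SV_CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call set missing columns: {missing}")
    calls = calls.sort_values(["chrom", "sv_type", "start", "genome", "id"]).reset_index(drop=True)
    n = len(calls)
    uf = _UnionFind(n)
    starts = calls["start"].to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            if calls.at[j, "chrom"] != calls.at[i, "chrom"] or calls.at[j, "sv_type"] != calls.at[i, "sv_type"]:
                break
            if starts[j] - starts[i] > position_tol:
                break
            if _linked(calls.iloc[i], calls.iloc[j], position_tol, size_ratio_min, seq_identity_min):
                uf.union(i, j)
    calls = calls.assign(_root=[uf.find(i) for i in range(n)])
    genomes = sorted(calls["genome"].unique())
    reps = []
    presence_rows = []
    for gid, (_, group) in enumerate(calls.groupby("_root", sort=True)):
        group = group.sort_values(["start", "genome"])
        med = group["start"].median()
        rep = group.iloc[(group["start"] - med).abs().argsort(kind="mergesort").iloc[0]]
        rep = rep.drop(labels="_root").copy()
        rep["merge_group"] = gid
        rep["members"] = list(group["id"])
        rep["n_carriers"] = group["genome"].nunique()
        reps.append(rep)
        carriers = set(group["genome"])
        presence_rows.append([g in carriers for g in genomes])
    catalog = pd.DataFrame(reps).reset_index(drop=True)
    presence = pd.DataFrame(presence_rows, columns=genomes)
    presence.index = catalog["merge_group"]
    logger.info("SV merge: %d calls -> %d occurrences across %d genomes", n, len(catalog), len(genomes))
    return catalog, presence


def _interval_union_overlap(start: int, end: int, intervals: list[tuple[int, int]]) -> int:
    """Bp of [start, end] (1-based inclusive) covered by the interval union."""
    clipped = sorted(
        (max(s, start), min(e, end)) for s, e in intervals if min(e, end) >= max(s, start)
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered


def flag_ty_related(catalog: pd.DataFrame, ty_library: pd.DataFrame) -> pd.DataFrame:
    """Flag SVs covered by Ty/LTR elements on strictly more than half their length.

    ``ty_library`` holds 1-based inclusive intervals (chrom, start, end).
    Overlap is the union of interval intersections, so overlapping library
    entries are not double-counted.  An overlap of exactly 50% is NOT
    flagged.
    """
    if len(ty_library) == 0:
        raise ValueError("empty Ty library")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, row in ty_library.iterrows():
        by_chrom.setdefault(str(row["chrom"]), []).append((int(row["start"]), int(row["end"])))
    out = catalog.copy()
    flags = []
    for _, sv in out.iterrows():
        length = int(sv["length"])
        footprint_end = int(sv["start"]) + length - 1
        overlap = _interval_union_overlap(
            int(sv["start"]), footprint_end, by_chrom.get(str(sv["chrom"]), [])
        )
        flags.append(overlap * 2 > length)
    out["ty_related"] = flags
    logger.info("Ty flagging: %d/%d SVs Ty-related", int(np.sum(flags)), len(out))
    return out


def split_ty_groups(catalog: pd.DataFrame, length_boundary: int = TY_LENGTH_BOUNDARY) -> pd.DataFrame:
    """Split Ty-related SVs into LTR-only (< boundary) vs full/partial Ty."""
    out = catalog.copy()
    if "ty_related" not in out.columns:
        raise ValueError("run flag_ty_related first")
    group = np.where(
        ~out["ty_related"].to_numpy(dtype=bool),
        "none",
        np.where(out["length"].to_numpy() < length_boundary, "LTR_only", "full_or_partial_Ty"),
    )
    out["ty_group"] = group
    return out


def build_sv_genotype_matrix(
    catalog: pd.DataFrame,
    presence: pd.DataFrame,
    design: CrossDesign,
    drop_singletons: bool = True,
) -> GenotypeMatrix:
    """Hybrid SV dosages from parental presence/absence.

    dosage(hybrid {a,b}) = presence_a + presence_b.  A reference-like parent
    with no calls must still appear as an all-absent column of ``presence``.
    Singleton SVs (present in exactly one parent) are removed by default.
    """
    missing = [p for p in design.parents if p not in presence.columns]
    if missing:
        raise KeyError(f"parents absent from SV presence table: {missing}")
    hap = presence[list(design.parents)].T.astype(np.int8)
    hap.columns = [f"sv{g}" for g in catalog["merge_group"]]
    variants = pd.DataFrame(
        {
            "id": [f"sv{g}" for g in catalog["merge_group"]],
            "chrom": catalog["chrom"].to_numpy(),
            "pos": catalog["start"].to_numpy(),
            "ref": "N",
            "alt": "<SV>",
            "variant_class": "SV",
            "sv_type": catalog["sv_type"].to_numpy(),
            "length": catalog["length"].to_numpy(),
        }
    )
    if "ty_group" in catalog.columns:
        variants["ty_group"] = catalog["ty_group"].to_numpy()
    matrix = infer_hybrid_genotypes(hap, design, variants=variants, source="SV")
    if drop_singletons:
        matrix = remove_singletons(matrix, hap)
    return matrix
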