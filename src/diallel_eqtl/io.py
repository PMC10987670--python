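"""File formats: minimal VCF, BED, delimited matrices, JSON manifests.

All genomic coordinates are 1-based inclusive internally (VCF convention);
BED's 0-based half-open intervals are converted at the boundary.  Every
writer/reader pair round-trips losslessly for the fields the pipeline uses.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import CrossDesign, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF (parental haploid genotypes; SV records with SVTYPE/SVLEN/END)

def write_parent_vcf(path, variants: pd.DataFrame, parent_haplotypes: pd.DataFrame) -> None:
    """Minimal VCF with one haploid GT column per parent."""
    path = Path(path)
    parents = list(parent_haplotypes.index)
    hap = parent_haplotypes.to_numpy(dtype=int)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=diallel-eqtl\n")
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(parents) + "\n")
        for j, row in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(str(int(g)) for g in hap[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_parent_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a parental VCF back into (variant table, parents x variants 0/1)."""
    vcf = VCF(str(path))
    parents = list(vcf.samples)
    rows = []
    haps = []
    for v in vcf:
        alt = ",".join(v.ALT) if v.ALT else "."
        rows.append(
            {
                "id": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": alt,
                "variant_class": "SNP",
            }
        )
        # haploid GT: first allele index per sample; -1 for missing
        alleles = np.array([g[0] for g in v.genotypes], dtype=float)
        alleles[alleles < 0] = np.nan
        haps.append(alleles)
    variants = pd.DataFrame(rows)
    hap = pd.DataFrame(
        np.array(haps).T if haps else np.empty((len(parents), 0)),
        index=parents,
        columns=list(variants["id"]) if len(variants) else [],
    )
    return variants, hap


def write_sv_vcf(path, calls: pd.DataFrame) -> None:
    """One record per SV call with SVTYPE/SVLEN/END INFO keys.

    The carrier genome is stored in the SOURCE INFO key so per-genome call
    sets survive the round trip.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=diallel-eqtl\n")
        for chrom in pd.unique(calls["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SOURCE,Number=1,Type=String,Description="Carrier genome">\n')
        fh.write('##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted sequence">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in calls.itertuples(index=False):
            info = (
                f"SVTYPE={row.sv_type};SVLEN={int(row.length)};END={int(row.end)};"
                f"SOURCE={row.genome}"
            )
            seq = getattr(row, "sequence", "")
            if isinstance(seq, str) and seq:
                info += f";SEQ={seq}"
            fh.write(f"{row.chrom}\t{int(row.start)}\t{row.id}\tN\t<SV>\t.\tPASS\t{info}\n")


def read_sv_vcf(path) -> pd.DataFrame:
    vcf = VCF(str(path))
    rows = []
    for v in vcf:
        rows.append(
            {
                "id": v.ID,
                "genome": v.INFO.get("SOURCE"),
                "chrom": v.CHROM,
                "start": v.POS,
                "end": int(v.INFO.get("END")),
                "sv_type": v.INFO.get("SVTYPE"),
                "length": int(v.INFO.get("SVLEN")),
                "sequence": v.INFO.get("SEQ") or "",
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "genome", "chrom", "start", "end", "sv_type", "length", "sequence"]
    )


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk, 1-based inclusive in memory)

def write_bed(path, intervals: pd.DataFrame) -> None:
    """``intervals`` holds 1-based inclusive chrom/start/end (+ optional label)."""
    out = intervals.copy()
    out["bed_start"] = out["start"].astype(int) - 1
    out["bed_end"] = out["end"].astype(int)
    cols = ["chrom", "bed_start", "bed_end"]
    if "label" in out.columns:
        cols.append("label")
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "start": raw[1].astype(int) + 1,
            "end": raw[2].astype(int),
        }
    )
    if raw.shape[1] > 3:
        out["label"] = raw[3]
    return out


# ---------------------------------------------------------------------------
# Delimited matrices

def write_genotype_matrix(path, matrix: GenotypeMatrix, meta_path=None) -> None:
    df = pd.DataFrame(matrix.dosages, index=matrix.hybrids, columns=matrix.variants["id"])
    df.to_csv(path, sep="\t", index_label="hybrid")
    if meta_path is not None:
        matrix.variants.to_csv(meta_path, sep="\t", index=False)


def read_genotype_matrix(path, meta_path, source: str = "SNP") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="hybrid")
    variants = pd.read_csv(meta_path, sep="\t")
    if list(df.columns) != list(variants["id"].astype(str)):
        raise ValueError("dosage columns and variant metadata disagree")
    return GenotypeMatrix(
        hybrids=list(df.index), variants=variants, dosages=df.to_numpy(dtype=np.int8),
        source=source,
    )


def write_trait_matrix(path, traits) -> None:
    """Traits written genes x hybrids with the stage recorded in a comment line."""
    with open(path, "w") as fh:
        fh.write(f"#stage={traits.stage}\n")
        pd.DataFrame(traits.values, index=traits.gene_ids, columns=traits.hybrids).to_csv(
            fh, sep="\t", index_label="gene_id"
        )


def read_trait_matrix(path):
    from .expression import TraitMatrix

    with open(path) as fh:
        first = fh.readline().strip()
        stage = first.split("=", 1)[1] if first.startswith("#stage=") else "tpm"
        df = pd.read_csv(fh, sep="\t", index_col="gene_id")
    return TraitMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float), stage=stage)


def write_design(path, design: CrossDesign) -> None:
    pd.DataFrame(design.hybrids, columns=["parent_a", "parent_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_design(path) -> CrossDesign:
    df = pd.read_csv(path, sep="\t")
    hybrids = tuple(tuple(sorted((a, b))) for a, b in zip(df["parent_a"], df["parent_b"]))
    parents = tuple(sorted(set(df["parent_a"]) | set(df["parent_b"])))
    return CrossDesign(parents=parents, hybrids=hybrids)


# ---------------------------------------------------------------------------
# Manifest

def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    """Per-stage record of parameters, artifacts and checksums."""

    def __init__(self, outdir, params: dict | None = None):
        self.outdir = Path(outdir)
        self.data = {"params": params or {}, "stages": {}}

    def record(self, stage: str, artifacts: list[str], **info) -> None:
        self.data["stages"][stage] = {
            "status": "complete",
            "artifacts": artifacts,
            "checksums": {a: _checksum(self.outdir / a) for a in artifacts},
            **info,
        }
        self.write()

    def write(self) -> None:
        (self.outdir / "manifest.json").write_text(json.dumps(self.data, indent=2, default=str))


def dump_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
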