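"""Readers and writers for the plain-text interchange formats.

Counts/dosage/metadata/GWAS tables are TSV; gene coordinates are BED
(0-based half-open, converted to the package's 1-based inclusive
convention on read); gene sets are GMT; genotypes round-trip through a
minimal VCF v4.2 with GT fields (read via cyvcf2).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BloodtxError, ExpressionMatrix, GenotypeMatrix

# --- expression ------------------------------------------------------------


def write_counts_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path, genes: pd.DataFrame, unit: str = "raw-count",
                    ) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = values.index.difference(genes.index)
    if len(missing):
        raise BloodtxError(f"genes without annotation: {list(missing[:5])}")
    return ExpressionMatrix(values, genes.loc[values.index], unit=unit)


def write_bed(genes: pd.DataFrame, path) -> None:
    """Gene coordinates as BED (0-based half-open)."""
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"] - 1,
        "end": genes["stop"],
        "name": genes.index,
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name"],
                      dtype={"chrom": str})
    genes = pd.DataFrame({
        "chrom": bed["chrom"],
        "start": bed["start"] + 1,
        "stop": bed["end"],
        "length": bed["end"] - bed["start"],
    })
    genes.index = pd.Index(bed["name"], name="gene_id")
    return genes


# --- genotypes -------------------------------------------------------------


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    merged = pd.concat([geno.snps, geno.dosages], axis=1)
    merged.to_csv(path, sep="\t", index_label="snp_id")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id",
                     dtype={"chrom": str})
    ann_cols = ["chrom", "pos", "ref", "alt"]
    return GenotypeMatrix(df.drop(columns=ann_cols), df[ann_cols])


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with GT genotypes (missing -> ./.)."""
    samples = list(geno.sample_ids)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        dos = geno.dosages.to_numpy()
        for i, (sid, ann) in enumerate(geno.snps.iterrows()):
            gts = ["./." if np.isnan(d) else gt_map[float(d)] for d in dos[i]]
            fh.write(f"{ann['chrom']}\t{int(ann['pos'])}\t{sid}\t{ann['ref']}"
                     f"\t{ann['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = vcf.samples
    rows, ann = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        ann.append((var.ID, var.CHROM, var.POS, var.REF, alt))
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0],
                           default=np.nan)
        rows.append(dosage)
    vcf.close()
    snps = pd.DataFrame(ann, columns=["snp_id", "chrom", "pos", "ref", "alt"]
                        ).set_index("snp_id")
    dosages = pd.DataFrame(np.array(rows), index=snps.index, columns=samples)
    return GenotypeMatrix(dosages, snps)


# --- gene sets, metadata, GWAS ---------------------------------------------


def write_gmt(collection: dict, path, source: str = "bloodtx") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write(name + "\t" + source + "\t" + "\t".join(genes) + "\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = parts[2:]
    return out


def write_metadata_tsv(labels: pd.Series, path, extra: pd.DataFrame | None = None) -> None:
    df = labels.to_frame()
    if extra is not None:
        df = df.join(extra)
    df.to_csv(path, sep="\t", index_label="sample")


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_gwas_tsv(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
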