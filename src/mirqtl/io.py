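"""Readers and writers for the pipeline's plain-text exchange formats.

All tabular interchange is TSV with documented headers; genotypes can also be
round-tripped through a minimal VCF carrying GT and DS FORMAT fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SUMSTAT_COLUMNS, ExpressionMatrix, GenotypeMatrix, PhenomeTable

__all__ = [
    "write_genotype_tsv", "read_genotype_tsv",
    "write_vcf", "read_vcf",
    "write_expression_tsv", "read_expression_tsv",
    "write_sumstats_tsv", "read_sumstats_tsv",
    "write_phenome_tsv", "read_phenome_tsv",
]


def write_genotype_tsv(geno: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write sample×variant dosage TSV plus a variant-metadata TSV."""
    prefix = Path(prefix)
    dosage_path = prefix.with_suffix(".dosage.tsv")
    meta_path = prefix.with_suffix(".variants.tsv")
    df = pd.DataFrame(geno.dosage, index=geno.samples, columns=geno.variant_ids)
    df.index.name = "sample_id"
    df.to_csv(dosage_path, sep="\t", float_format="%.6g")
    geno.variants.to_csv(meta_path, sep="\t", index=False, float_format="%.10g")
    return dosage_path, meta_path


def read_genotype_tsv(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".dosage.tsv"), sep="\t", index_col="sample_id")
    meta = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t",
                       dtype={"chrom": str})
    return GenotypeMatrix(samples=df.index.tolist(), variants=meta,
                          dosage=df.to_numpy(dtype=float))


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> Path:
    """Minimal VCF 4.2 with GT and DS per sample. Dosages are hard counts."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in geno.variants.iterrows():
            dos = geno.dosage[:, j]
            cells = [f"{gt_codes[int(round(d))]}:{d:g}" for d in dos]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t"
                     f"{row.other_allele}\t{row.effect_allele}\t.\t.\t.\tGT:DS\t"
                     + "\t".join(cells) + "\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read the minimal VCF written by :func:`write_vcf` (DS field preferred)."""
    samples: list[str] = []
    metas = []
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            ds_i = fmt.index("DS") if "DS" in fmt else None
            vals = []
            for cell in parts[9:]:
                fields = cell.split(":")
                if ds_i is not None:
                    vals.append(float(fields[ds_i]))
                else:
                    gt = fields[fmt.index("GT")]
                    vals.append(float(gt.count("1")))
            dos = np.array(vals)
            metas.append({"variant_id": vid, "chrom": chrom, "pos": pos,
                          "effect_allele": alt, "other_allele": ref,
                          "eaf": float(dos.mean() / 2.0)})
            rows.append(dos)
    variants = pd.DataFrame(metas)
    dosage = np.array(rows).T
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_expression_tsv(expr: ExpressionMatrix, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    expr_path = prefix.with_suffix(".expression.tsv")
    cov_path = prefix.with_suffix(".covariates.tsv")
    df = pd.DataFrame(expr.values, index=expr.samples, columns=expr.mirna_ids)
    df.index.name = "sample_id"
    df.to_csv(expr_path, sep="\t", float_format="%.8g")
    cov = expr.covariates.copy()
    cov.insert(0, "sample_id", expr.samples)
    cov.to_csv(cov_path, sep="\t", index=False, float_format="%.8g")
    return expr_path, cov_path


def read_expression_tsv(prefix: str | Path) -> ExpressionMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".expression.tsv"), sep="\t",
                     index_col="sample_id")
    cov = pd.read_csv(prefix.with_suffix(".covariates.tsv"), sep="\t")
    cov = cov.drop(columns=["sample_id"])
    return ExpressionMatrix(samples=df.index.tolist(), mirna_ids=df.columns.tolist(),
                            values=df.to_numpy(dtype=float), covariates=cov)


def write_sumstats_tsv(stats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in SUMSTAT_COLUMNS if c in stats.columns]
    extra = [c for c in stats.columns if c not in cols]
    stats[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_sumstats_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_phenome_tsv(phenome: PhenomeTable, path: str | Path) -> Path:
    """Long format: sample_id, phecode, status (1 case / 0 control / -1 excluded)."""
    path = Path(path)
    long = phenome.status.stack().rename("status").reset_index()
    long.columns = ["sample_id", "phecode", "status"]
    long.to_csv(path, sep="\t", index=False)
    return path


def read_phenome_tsv(path: str | Path) -> PhenomeTable:
    long = pd.read_csv(path, sep="\t", dtype={"phecode": str})
    wide = long.pivot(index="sample_id", columns="phecode", values="status")
    return PhenomeTable(samples=wide.index.tolist(), phecodes=wide.columns.tolist(),
                        status=wide)
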