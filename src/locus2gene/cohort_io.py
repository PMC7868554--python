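"""Readers/writers for the pipeline's standard formats plus marker-level QC.

Formats: GWAS summary-statistic TSV (configurable header mapping), VCF 4.x
or delimited dosage matrices for genotypes, TSV expression matrices (genes x
individuals), TSV or GFF3 gene annotation, BED output for regions.

Marker QC keeps biallelic variants with minor-allele frequency above the
threshold and a Hardy-Weinberg chi-square (1 df, on hard-called genotype
counts) p-value above the threshold; an optional imputation-quality column
can be thresholded when provided, since dosage files carry no such score
themselves.  Sample-level QC (relatedness, ancestry outliers) is not part of
this package.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .syndata import ExpressionMatrix, GenotypeMatrix, VARIANT_COLUMNS

logger = logging.getLogger(__name__)

GWAS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p_value", "eaf",
]

_NUCLEOTIDES = set("ACGT")


def normalize_chrom(label: object) -> str:
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def read_gwas(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read GWAS summary statistics into the canonical column layout.

    ``column_map`` maps canonical names (see GWAS_COLUMNS) to the file's
    header names; canonical names present verbatim need no mapping entry.
    Malformed rows (p outside (0, 1], non-positive SE, identical or
    non-nucleotide alleles, unparsable numbers) are dropped with their
    1-based data line numbers logged.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    colmap = dict(column_map or {})
    rename = {}
    for canonical in GWAS_COLUMNS:
        source = colmap.get(canonical, canonical)
        if source not in raw.columns:
            raise ValueError(f"required column {canonical!r} (file column {source!r}) missing")
        rename[source] = canonical
    df = raw.rename(columns=rename)[GWAS_COLUMNS].copy()

    for col in ("pos",):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("beta", "se", "p_value", "eaf"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    numeric_ok = df[["pos", "beta", "se", "p_value", "eaf"]].notna().all(axis=1)
    allele_ok = (
        df["effect_allele"].fillna("").map(lambda a: bool(a) and set(a) <= _NUCLEOTIDES)
        & df["other_allele"].fillna("").map(lambda a: bool(a) and set(a) <= _NUCLEOTIDES)
        & (df["effect_allele"] != df["other_allele"])
    )
    p_ok = (df["p_value"] > 0) & (df["p_value"] <= 1)
    se_ok = (df["se"] > 0) | (df["p_value"] == 1)
    valid = numeric_ok & allele_ok & p_ok & se_ok
    if not valid.all():
        bad_lines = (np.flatnonzero(~valid.to_numpy()) + 1).tolist()
        logger.warning(
            "read_gwas: rejected %d malformed rows at data lines %s",
            len(bad_lines), bad_lines[:20],
        )
    out = df[valid].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    return out


def write_gwas(gwas: pd.DataFrame, path: str | Path) -> None:
    gwas[GWAS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from VCF (GT and/or DS) or a delimited dosage matrix.

    Delimited layout: columns variant_id, chrom, pos, ref, alt, then one
    column per sample holding dosages.  In VCF mode DS is preferred over GT
    when both are present; multi-allelic records are skipped with a logged
    count.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dosage matrix missing columns {missing}")
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    if not samples:
        raise ValueError("no sample columns in dosage matrix")
    variants = df[VARIANT_COLUMNS].copy()
    variants["chrom"] = variants["chrom"].map(normalize_chrom)
    dosages = df[samples].to_numpy(float).T
    if np.isnan(dosages).any():
        raise ValueError("missing dosages in matrix")
    return GenotypeMatrix(individuals=samples, variants=variants, dosages=dosages)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")
    rows, cols = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, float).reshape(len(samples))
        else:
            gts = np.asarray(rec.gt_types)  # 0=hom ref,1=het,2=unknown,3=hom alt
            if (gts == 2).any():
                raise ValueError(f"missing genotype at {rec.ID}")
            dose = np.where(gts == 3, 2.0, gts.astype(float))
        vid = rec.ID if rec.ID not in (None, ".") else f"snp_{rec.CHROM}_{rec.POS}"
        rows.append((vid, normalize_chrom(rec.CHROM), rec.POS, rec.REF, rec.ALT[0]))
        cols.append(dose)
    if n_multi:
        logger.warning("read_genotypes: skipped %d multi-allelic VCF records", n_multi)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(
        individuals=samples, variants=variants, dosages=np.column_stack(cols)
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT (rounded dosage) and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in dict.fromkeys(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.individuals) + "\n")
        gt_codes = ("0/0", "0/1", "1/1")
        for j, row in geno.variants.iterrows():
            dose = geno.dosages[:, j]
            hard = np.clip(np.rint(dose), 0, 2).astype(int)
            cells = [f"{gt_codes[h]}:{d:.3f}" for h, d in zip(hard, dose)]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def write_dosage_matrix(geno: GenotypeMatrix, path: str | Path) -> None:
    df = geno.variants.copy()
    block = pd.DataFrame(geno.dosages.T, columns=geno.individuals)
    pd.concat([df, block], axis=1).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# expression + annotation
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """TSV with gene ids in the first column, one column per individual."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        individuals=list(df.columns),
        genes=list(df.index),
        values=df.to_numpy(float).T,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        expr.values.T, index=pd.Index(expr.genes, name="gene_id"), columns=expr.individuals
    ).to_csv(path, sep="\t", float_format="%.6g")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation from a TSV (gene_id, chrom, start, end[, strand]) or GFF3."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if path.suffix in (".gff", ".gff3") or first.startswith("##gff"):
        return _read_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["gene_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    if "strand" not in df.columns:
        df["strand"] = "."
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["start"] > df["end"]).any():
        raise ValueError("annotation has start > end")
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def _read_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", feat.attributes.get("ID", [feat.id]))[0]
        rows.append((gid, normalize_chrom(feat.seqid), feat.start, feat.end, feat.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Regions (1-based inclusive) written as standard 0-based half-open BED."""
    out = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"].astype(int) - 1,
            "end": regions["end"].astype(int),
            "name": regions.get("region_id", regions.index.astype(str)),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------

def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Hardy-Weinberg chi-square (1 df) from hard-called genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def filter_variants(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    rsq: Mapping[str, float] | None = None,
    rsq_min: float = 0.8,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove variants failing MAF, Hardy-Weinberg, or imputation-quality filters.

    Returns the filtered matrix plus a report with one row per removed
    variant (columns variant_id, reason).  Hard calls for the HWE count table
    are dosages rounded to the nearest integer.
    """
    af = geno.allele_freq()
    maf = np.minimum(af, 1.0 - af)
    hard = np.clip(np.rint(geno.dosages), 0, 2).astype(int)

    removed: list[tuple[str, str]] = []
    keep = np.ones(geno.n_variants, dtype=bool)
    for j, vid in enumerate(geno.variants["variant_id"]):
        if maf[j] <= maf_min:
            removed.append((vid, "MAF"))
            keep[j] = False
            continue
        counts = np.bincount(hard[:, j], minlength=3)
        _, p_hwe = hwe_chisq(counts[2], counts[1], counts[0])  # AA = hom alt
        if p_hwe <= hwe_p_min:
            removed.append((vid, "HWE"))
            keep[j] = False
            continue
        if rsq is not None and rsq.get(vid, 1.0) <= rsq_min:
            removed.append((vid, "RSQ"))
            keep[j] = False
    report = pd.DataFrame(removed, columns=["variant_id", "reason"])
    if len(removed):
        logger.info("filter_variants: removed %d of %d variants", len(removed), geno.n_variants)
    filtered = GenotypeMatrix(
        individuals=list(geno.individuals),
        variants=geno.variants[keep].reset_index(drop=True),
        dosages=geno.dosages[:, keep].copy(),
    )
    return filtered, report
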