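"""Standard-format IO, variant QC, and SNP-to-gene window assignment.

Readers use the established parsers (cyvcf2 for VCF, pyranges for GFF3,
pandas for TSV) and enforce the pipeline's contracts: biallelic variants
only, minor allele count >= 2, MAF >= 0.05, no missing genotypes; 1-based
fully-closed genomic intervals; consistent sample/gene namespaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr
from intervaltree import IntervalTree

from humiclink.config import LakeMetadata, SimulationConfig
from humiclink.types import SNP_CATEGORIES, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VariantQC",
    "read_vcf_genotypes",
    "write_vcf",
    "read_gff_genes",
    "write_gff3",
    "read_counts",
    "write_counts",
    "read_sample_metadata",
    "read_snp_table",
    "assign_snps_to_genes",
    "classify_snps_by_deg",
    "write_dataset",
    "read_dataset",
    "validate_dataset",
]


# ---------------------------------------------------------------------------
# VCF


@dataclass
class VariantQC:
    """Variant-level QC contract applied on read.

    Depth/quality thresholds are applied only when the corresponding VCF
    fields exist; RNA-seq derived VCFs vary in their annotations.
    """

    maf: float = 0.05
    min_mac: int = 2
    min_mean_depth: float = 10.0
    min_qual: float = 30.0


def read_vcf_genotypes(path, qc: VariantQC | None = None) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into a dosage matrix plus SNP-record skeletons.

    Filters, in order: biallelic only (multiallelic records are dropped and
    counted, not fatal); minor allele count >= ``qc.min_mac``; MAF >=
    ``qc.maf``; any missing genotype drops the variant; mean depth and
    QUAL filters apply only if the fields are present.
    """
    from cyvcf2 import VCF

    qc = qc or VariantQC()
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)
    if n == 0:
        raise ValueError(f"VCF {path} contains no samples")

    kept_rows, kept_dosages = [], []
    n_multi = n_mac = n_maf = n_missing = n_depth = n_qual = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types)  # 0/1/2, 3 = missing under gts012
        if (gt == 3).any():
            n_missing += 1
            continue
        ac = int(gt.sum())
        mac = min(ac, 2 * n - ac)
        if mac < qc.min_mac:
            n_mac += 1
            continue
        p = ac / (2 * n)
        if min(p, 1 - p) < qc.maf:
            n_maf += 1
            continue
        if var.QUAL is not None and var.QUAL < qc.min_qual:
            n_qual += 1
            continue
        try:
            depth = var.format("DP")
        except KeyError:
            depth = None  # DP absent from the header: depth filter skipped
        if depth is not None and np.nanmean(depth) < qc.min_mean_depth:
            n_depth += 1
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        kept_rows.append(
            {
                "snp_id": snp_id,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "maf": min(p, 1 - p),
            }
        )
        kept_dosages.append(gt.astype(np.int8))
    vcf.close()

    dropped = {
        "multiallelic": n_multi,
        "missing_gt": n_missing,
        "mac": n_mac,
        "maf": n_maf,
        "qual": n_qual,
        "depth": n_depth,
    }
    logger.info("VCF %s: kept %d variants, dropped %s", path, len(kept_rows), dropped)
    snps = pd.DataFrame(kept_rows, columns=["snp_id", "chrom", "pos", "ref", "alt", "maf"])
    dosages = (
        np.vstack(kept_dosages).T if kept_dosages else np.empty((n, 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(sample_ids=samples, snp_ids=snps["snp_id"].tolist(), dosages=dosages)
    return gm, snps


def write_vcf(gm: GenotypeMatrix, snps: pd.DataFrame, path) -> None:
    """Write a minimal VCF v4.2 (GT only, biallelic) for the dosage matrix."""
    snps = snps.set_index("snp_id").loc[gm.snp_ids].reset_index()
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].to_numpy()))
        for j in order:
            row = snps.iloc[j]
            gts = "\t".join(gt_strings[gm.dosages[:, j]])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / tables


def read_gff_genes(path) -> pd.DataFrame:
    """Read gene features from GFF3 into 1-based inclusive coordinates."""
    df = pr.read_gff3(str(path)).df
    df = df[df["Feature"] == "gene"]
    genes = pd.DataFrame(
        {
            "gene_id": df["ID"].astype(str),
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int) + 1,  # pyranges is 0-based half-open
            "end": df["End"].astype(int),
            "strand": df["Strand"].astype(str),
        }
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    dup = genes["gene_id"][genes["gene_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicated gene_id in {path}: {list(dup)}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError(f"gene with start > end in {path}")
    return genes


def write_gff3(genes: pd.DataFrame, path) -> None:
    gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": genes["chrom"],
                "Source": "humiclink",
                "Feature": "gene",
                "Start": genes["start"] - 1,
                "End": genes["end"],
                "Score": ".",
                "Strand": genes["strand"],
                "Frame": ".",
                "ID": genes["gene_id"],
            }
        )
    )
    gr.to_gff3(str(path))


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples raw count TSV; all cells must be integers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicated gene_id in {path}: {list(dup)}")
    dupc = df.columns[df.columns.duplicated()].unique()
    if len(dupc):
        raise ValueError(f"duplicated sample_id in {path}: {list(dupc)}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValueError(f"non-integer count in {path} at gene {gene!r}, sample {col!r}")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "lake", "ecotype", "sex", "total_length_mm", "latitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata {path} missing columns: {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicated sample_id in {path}: {list(dup)}")
    bad = ~df["ecotype"].isin(["humic", "clear"])
    if bad.any():
        raise ValueError(f"unknown ecotype values: {df['ecotype'][bad].unique().tolist()}")
    return df


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "chrom", "pos", "category", "outlier"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table {path} missing columns: {sorted(missing)}")
    bad = ~df["category"].isin(SNP_CATEGORIES)
    if bad.any():
        raise ValueError(f"unknown SNP categories: {df['category'][bad].unique().tolist()}")
    df["outlier"] = df["outlier"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# window assignment and DEG classification


def assign_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 5_000
) -> dict[str, list[str]]:
    """Map gene_id -> SNP ids with pos in [start - flank, end + flank].

    Intervals are 1-based and closed at both ends; the left flank is clamped
    at position 1. A SNP may map to multiple genes.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes.itertuples():
        lo = max(1, gene.start - flank_bp)
        hi = gene.end + flank_bp
        trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi + 1, gene.gene_id)

    mapping: dict[str, list[str]] = {g: [] for g in genes["gene_id"]}
    for snp in snps.itertuples():
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        for iv in sorted(tree[snp.pos]):
            mapping[iv.data].append(snp.snp_id)
    return mapping


def classify_snps_by_deg(
    snps: pd.DataFrame,
    gene_to_snps: dict[str, list[str]],
    deg_genes: set[str],
    expressed_genes: set[str],
) -> pd.Series:
    """Per-SNP class: DEG, nonDEG or unassigned (disjoint and exhaustive).

    DEG wins when a SNP lies in both a DEG and a non-DEG expressed-gene
    window (precedence rule); nonDEG requires a window of a gene expressed
    in the tissue; all other SNPs are unassigned.
    """
    deg_genes = set(deg_genes)
    expressed_genes = set(expressed_genes)
    stray = deg_genes - expressed_genes
    if stray:
        raise ValueError(f"DEG genes absent from the expressed set: {sorted(stray)[:10]}")
    in_deg: set[str] = set()
    in_expr: set[str] = set()
    for gene_id, snp_ids in gene_to_snps.items():
        if gene_id in deg_genes:
            in_deg.update(snp_ids)
        if gene_id in expressed_genes:
            in_expr.update(snp_ids)
    cls = []
    for s in snps["snp_id"]:
        if s in in_deg:
            cls.append("DEG")
        elif s in in_expr:
            cls.append("nonDEG")
        else:
            cls.append("unassigned")
    return pd.Series(cls, index=snps["snp_id"].tolist(), name="deg_class")


# ---------------------------------------------------------------------------
# dataset directory round trip


def write_dataset(ds, outdir) -> None:
    """Write a simulated dataset directory (VCF, GFF3, TSVs, config YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(ds.genotypes, ds.snps, outdir / "genotypes.vcf")
    write_gff3(ds.genes, outdir / "genes.gff3")
    ds.snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
    ds.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    pd.DataFrame([vars(l) for l in ds.lakes]).to_csv(outdir / "lakes.tsv", sep="\t", index=False)
    for tissue, counts in ds.counts.items():
        write_counts(counts, outdir / f"counts_{tissue}.tsv")
    ds.deg_truth.to_csv(outdir / "truth_deg.tsv", sep="\t", index=False)
    ds.eqtl_truth.to_csv(outdir / "truth_eqtl.tsv", sep="\t", index=False)
    ds.config.to_yaml(outdir / "config.yaml")


def read_dataset(indir):
    """Read a dataset directory back into in-memory objects."""
    from humiclink.simulate import SimulatedDataset, SimulatedExpression

    indir = Path(indir)
    cfg = SimulationConfig.from_yaml(indir / "config.yaml")
    # simulated VCFs carry no depth/qual fields; the conditional filters skip
    gm, _ = read_vcf_genotypes(indir / "genotypes.vcf", VariantQC(maf=0.0, min_mac=0))
    genes = read_gff_genes(indir / "genes.gff3")
    snps = read_snp_table(indir / "snps.tsv")
    # restore original SNP order and drop variants lost to QC if any
    snps = snps[snps["snp_id"].isin(gm.snp_ids)].reset_index(drop=True)
    gm = gm.subset_snps(
        np.array([gm.snp_ids.index(s) for s in snps["snp_id"]], dtype=int)
    )
    samples = read_sample_metadata(indir / "samples.tsv")
    lakes_df = pd.read_csv(indir / "lakes.tsv", sep="\t")
    lakes = [LakeMetadata(**row) for row in lakes_df.to_dict("records")]
    counts = {
        p.stem.removeprefix("counts_"): read_counts(p)
        for p in sorted(indir.glob("counts_*.tsv"))
    }
    deg_truth = pd.read_csv(indir / "truth_deg.tsv", sep="\t")
    eqtl_truth = pd.read_csv(indir / "truth_eqtl.tsv", sep="\t")
    expr = SimulatedExpression(counts=counts, deg_truth=deg_truth, eqtl_truth=eqtl_truth)
    return SimulatedDataset(
        config=cfg,
        lakes=lakes,
        samples=samples,
        genes=genes,
        snps=snps,
        genotypes=gm,
        lake_freqs=pd.DataFrame(),
        expression=expr,
    )


def validate_dataset(indir) -> list[str]:
    """Validate namespaces and shapes of a dataset directory; return notices."""
    ds = read_dataset(indir)
    notices = []
    sample_set = set(ds.samples["sample_id"])
    if set(ds.genotypes.sample_ids) != sample_set:
        raise ValueError("sample ids differ between VCF and sample metadata")
    gene_set = set(ds.genes["gene_id"])
    for tissue, counts in ds.counts.items():
        unknown = set(counts.columns) - sample_set
        if unknown:
            raise ValueError(f"counts for {tissue} carry unknown samples: {sorted(unknown)}")
        stray = set(counts.index) - gene_set
        if stray:
            raise ValueError(f"counts for {tissue} carry unknown genes: {sorted(stray)[:10]}")
        notices.append(f"{tissue}: {counts.shape[0]} genes x {counts.shape[1]} samples")
    notices.append(f"{len(ds.snps)} SNPs, {int(ds.snps['outlier'].sum())} outliers")
    return notices
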