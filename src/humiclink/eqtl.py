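"""cis-eQTL scan and eSNP outlier enrichment.

The scan tests each SNP within +/-50 kb of a gene body for an additive
linear (least-squares) genotype effect on log2 normalized expression,
accounting for sex, ecotype and the first two normalized genotype-PCA
scores; p-values come from the t distribution and Benjamini-Hochberg FDR is
applied across all tested pairs within a tissue. Enrichment of
selection-outlier SNPs among the significant eSNPs is tested with a 2x2
chi-square using the Yates continuity correction against the genome-wide
outlier/non-outlier tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from humiclink.reference_tables import WGS_NONOUTLIER_SNPS, WGS_OUTLIER_SNPS
from humiclink.types import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "eqtl_filters",
    "genotype_pca",
    "cis_scan",
    "esnp_outlier_chisq",
    "beta_concordance",
    "summarize_eqtls",
    "EqtlSummary",
]

P_FLOOR = 1e-300  # reporting floor to avoid underflow-driven zeros


def eqtl_filters(gm: GenotypeMatrix, maf_min: float = 0.10) -> GenotypeMatrix:
    """Drop SNPs with MAF below ``maf_min`` (inclusive keep at the threshold)
    or whose observed genotypes are exclusively heterozygous (dosage
    multiset == {1}), which carry no additive contrast."""
    maf = gm.maf()
    all_het = (gm.dosages == 1).all(axis=0)
    keep = (maf >= maf_min) & ~all_het
    return gm.subset_snps(keep)


def genotype_pca(gm: GenotypeMatrix, n_pc: int = 2) -> pd.DataFrame:
    """Normalized PCA scores of column-standardized dosages.

    Scores are z-normalized per component (mean 0, SD 1); the sign of each
    component is fixed by making its largest-|loading| entry positive.
    """
    if gm.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    if n_pc > gm.n_samples:
        raise ValueError("more PCs requested than samples")
    x = gm.dosages.astype(float)
    sd = x.std(axis=0)
    poly = sd > 0
    if poly.sum() < 2:
        raise ValueError("PCA needs at least 2 polymorphic SNPs")
    xs = (x[:, poly] - x[:, poly].mean(axis=0)) / sd[poly]
    pca = PCA(n_components=n_pc, svd_solver="full")  # exact and deterministic
    scores = pca.fit_transform(xs)
    for j in range(n_pc):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    ssd = scores.std(axis=0)
    ssd[ssd == 0] = 1.0
    scores = (scores - scores.mean(axis=0)) / ssd
    return pd.DataFrame(
        scores, index=gm.sample_ids, columns=[f"PC{j+1}" for j in range(n_pc)]
    )


def _covariate_matrix(meta: pd.DataFrame, pcs: pd.DataFrame | None) -> np.ndarray:
    cols = [
        np.ones(len(meta)),
        (meta["sex"] == "M").to_numpy(float),
        (meta["ecotype"] == "humic").to_numpy(float),
    ]
    names = ["intercept", "sex", "ecotype"]
    if pcs is not None:
        for c in pcs.columns:
            cols.append(pcs.loc[meta["sample_id"], c].to_numpy(float))
            names.append(c)
    C = np.column_stack(cols)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError(f"collinear covariates among {names}")
    return C


def cis_candidate_pairs(
    genes: pd.DataFrame, snps: pd.DataFrame, window: int = 50_000
) -> pd.DataFrame:
    """Enumerate gene-SNP pairs with the SNP inside [start-window, end+window]
    on the same chromosome (closed interval)."""
    rows = []
    for chrom, g in genes.groupby("chrom"):
        s = snps[snps["chrom"] == chrom]
        if s.empty:
            continue
        pos = s["pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        ids_sorted = s["snp_id"].to_numpy()[order]
        for gene in g.itertuples():
            lo = max(1, gene.start - window)
            hi = gene.end + window
            a = np.searchsorted(pos_sorted, lo, side="left")
            b = np.searchsorted(pos_sorted, hi, side="right")
            for sid in ids_sorted[a:b]:
                rows.append((gene.gene_id, sid))
    return pd.DataFrame(rows, columns=["gene_id", "snp_id"])


def cis_scan(
    logmat: pd.DataFrame,
    gm: GenotypeMatrix,
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    window: int = 50_000,
    pcs: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Additive linear cis-eQTL scan for one tissue.

    Expression and genotypes must cover the same individuals (the frame is
    aligned on the intersection order of ``logmat`` columns). Each candidate
    pair is fit by OLS of expression on dosage plus covariates via
    Frisch-Waugh-Lovell residualization (exact OLS t statistics); BH FDR is
    applied across all tested pairs within the tissue.
    """
    samples = [s for s in logmat.columns if s in set(gm.sample_ids)]
    if len(samples) != len(logmat.columns) or len(samples) != gm.n_samples:
        raise ValueError("expression and genotype matrices must cover the same individuals")
    gm = gm.subset_samples(samples)
    meta = meta.set_index("sample_id").loc[samples].reset_index()

    pairs = cis_candidate_pairs(genes[genes["gene_id"].isin(logmat.index)], snps, window)
    pairs = pairs[pairs["snp_id"].isin(set(gm.snp_ids))]
    if pairs.empty:
        return pd.DataFrame(
            columns=["tissue", "gene_id", "snp_id", "beta", "t_stat", "p", "fdr", "significant"]
        )

    C = _covariate_matrix(meta, pcs)
    n, kc = C.shape
    k = kc + 1  # + genotype
    dof = n - k
    if dof < 1:
        raise ValueError("not enough samples for the covariate design")
    # residual-maker projection for the covariates
    Cpinv = np.linalg.pinv(C)
    proj = lambda A: A - C @ (Cpinv @ A)  # noqa: E731

    Y = logmat.loc[:, samples].to_numpy(float).T  # samples x genes
    Yr = proj(Y)
    G = gm.dosages.astype(float)
    Gr = proj(G)
    gene_ix = {g: j for j, g in enumerate(logmat.index)}
    snp_ix = {s: j for j, s in enumerate(gm.snp_ids)}

    gi = pairs["gene_id"].map(gene_ix).to_numpy()
    si = pairs["snp_id"].map(snp_ix).to_numpy()
    gx = Gr[:, si]  # samples x pairs
    yy = Yr[:, gi]
    gg = (gx * gx).sum(axis=0)
    gy = (gx * yy).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / gg, 0.0)
    rss = (yy * yy).sum(axis=0) - beta * gy
    sigma2 = np.maximum(rss, 0.0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(gg > 0, sigma2 / gg, np.inf))
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
        t = np.where(np.isfinite(se) | (se == 0), t, 0.0)  # no genotype spread
        t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), dof), P_FLOOR)

    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "tissue": tissue,
            "gene_id": pairs["gene_id"].to_numpy(),
            "snp_id": pairs["snp_id"].to_numpy(),
            "beta": beta,
            "t_stat": t,
            "p": p,
            "fdr": q,
            "significant": q <= fdr,
        }
    )
    return out.reset_index(drop=True)


def esnp_outlier_chisq(
    n_out_esnp: int,
    n_non_esnp: int,
    n_out_wgs: int = WGS_OUTLIER_SNPS,
    n_non_wgs: int = WGS_NONOUTLIER_SNPS,
) -> tuple[float, float]:
    """Yates-corrected 2x2 chi-square of outlier frequency among eSNPs.

    Rows are (genome-wide outlier, genome-wide non-outlier) and (eSNP
    outlier, eSNP non-outlier), exactly as tabulated in the source analysis
    (the rows are not disjoint; the genome row is the reference universe).
    Returns (chi2, two-sided p); an expected cell of zero is undefined and
    returns (nan, nan).
    """
    if min(n_out_esnp, n_non_esnp, n_out_wgs, n_non_wgs) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[n_out_wgs, n_non_wgs], [n_out_esnp, n_non_esnp]], dtype=float)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


@dataclass
class EqtlSummary:
    tissue: str
    n_eqtls: int
    n_egenes: int
    n_esnps: int
    n_outlier_esnps: int
    chi2_yates: float
    p_enrich: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_eqtls(
    eqtl_table: pd.DataFrame, outlier_snps: set[str], tissue: str | None = None
) -> EqtlSummary:
    """Tally significant pairs into eQTL/eGene/eSNP counts plus the Yates
    outlier-enrichment test against the genome-wide reference tallies."""
    sig = eqtl_table[eqtl_table["significant"]]
    tissue = tissue or (sig["tissue"].iloc[0] if len(sig) else "")
    esnps = set(sig["snp_id"])
    n_out = len(esnps & outlier_snps)
    n_non = len(esnps) - n_out
    chi2, p = esnp_outlier_chisq(n_out, n_non)
    return EqtlSummary(
        tissue=tissue,
        n_eqtls=len(sig),
        n_egenes=sig["gene_id"].nunique(),
        n_esnps=len(esnps),
        n_outlier_esnps=n_out,
        chi2_yates=chi2,
        p_enrich=p,
    )


def beta_concordance(tables: dict[str, pd.DataFrame]) -> tuple[float, pd.DataFrame]:
    """Cross-tissue sign agreement of regulatory effects.

    For every gene-SNP pair significant in >= 2 tissues, record whether all
    betas share a sign; returns (% concordant, per-pair detail). With no
    shared pairs the percentage is NaN (with a notice in the log).
    """
    if len(tables) < 2:
        raise ValueError("need eQTL tables from at least two tissues")
    sig = pd.concat(
        [t[t["significant"]][["tissue", "gene_id", "snp_id", "beta"]] for t in tables.values()],
        ignore_index=True,
    )
    grouped = sig.groupby(["gene_id", "snp_id"]).agg(
        n_tissues=("tissue", "nunique"), n_pos=("beta", lambda b: int((b > 0).sum())),
        n_neg=("beta", lambda b: int((b < 0).sum())),
    )
    shared = grouped[grouped["n_tissues"] >= 2].copy()
    if shared.empty:
        logger.warning("no gene-SNP pair is significant in >= 2 tissues")
        return float("nan"), shared.reset_index()
    shared["concordant"] = (shared["n_pos"] == 0) | (shared["n_neg"] == 0)
    pct = 100.0 * shared["concordant"].mean()
    return float(pct), shared.reset_index()
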