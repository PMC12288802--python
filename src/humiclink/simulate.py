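"""Synthetic study-design generator.

Generates lakes, samples, gene/SNP annotation, Balding-Nichols genotypes and
negative-binomial expression counts with the statistical structure the
downstream analysis assumes:

* two lake ecotypes (humic vs. clear-water) with disjoint water chemistry;
* per-lake allele frequencies drifted around an ancestral frequency with a
  Balding-Nichols Beta model parameterised by ``drift_F``;
* a fraction of SNPs planted as selection outliers whose ecotype mean
  frequencies are separated by ``outlier_delta`` before drift;
* per-tissue planted DEG effects (ecotype log2 fold changes) and planted
  cis-eQTL effects (log2 expression per alt allele, SNP inside the gene's
  +/-50 kb window), on top of sex / log10(length) / log10(latitude)
  covariate effects;
* negative-binomial counts with log-normal library-size factors.

Also houses the population-genetic utilities used to validate the generator:
the mean absolute ecotype allele-frequency difference (delta), the
delta-based outlier flagging rule (mean + 2.5 SD), and the Hudson FST
estimator (ratio of averages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from humiclink._rng import substream
from humiclink.config import (
    CLEAR_COLOUR_RANGE,
    CLEAR_DOC_RANGE,
    HUMIC_COLOUR_RANGE,
    HUMIC_DOC_RANGE,
    LATITUDE_RANGE,
    LONGITUDE_RANGE,
    LakeMetadata,
    SimulationConfig,
)
from humiclink.types import GenotypeMatrix

__all__ = [
    "simulate_lakes",
    "simulate_samples",
    "simulate_annotation",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_dataset",
    "compute_delta",
    "flag_outliers_by_delta",
    "hudson_fst",
    "SimulatedGenotypes",
    "SimulatedExpression",
    "SimulatedDataset",
]


# ---------------------------------------------------------------------------
# lakes and samples


def simulate_lakes(n_humic: int, n_clear: int, seed: int) -> list[LakeMetadata]:
    """Draw lake metadata with ecotype-conditional water chemistry.

    DOC and colour are uniform within the observed ecotype ranges (disjoint
    between ecotypes); latitudes span the study region.
    """
    if n_humic < 0 or n_clear < 0:
        raise ValueError("lake counts must be non-negative")
    rng = substream(seed, "lakes")
    lakes: list[LakeMetadata] = []
    for i in range(n_humic):
        lakes.append(
            LakeMetadata(
                lake_id=f"H{i + 1:02d}",
                ecotype="humic",
                latitude=float(rng.uniform(*LATITUDE_RANGE)),
                longitude=float(rng.uniform(*LONGITUDE_RANGE)),
                doc=float(rng.uniform(*HUMIC_DOC_RANGE)),
                colour=float(rng.uniform(*HUMIC_COLOUR_RANGE)),
            )
        )
    for i in range(n_clear):
        lakes.append(
            LakeMetadata(
                lake_id=f"C{i + 1:02d}",
                ecotype="clear",
                latitude=float(rng.uniform(*LATITUDE_RANGE)),
                longitude=float(rng.uniform(*LONGITUDE_RANGE)),
                doc=float(rng.uniform(*CLEAR_DOC_RANGE)),
                colour=float(rng.uniform(*CLEAR_COLOUR_RANGE)),
            )
        )
    return lakes


def simulate_samples(cfg: SimulationConfig, lakes: Sequence[LakeMetadata]) -> pd.DataFrame:
    """Individuals sampled per lake, with sex, total length and latitude.

    Sexes alternate within a lake (the study aimed for one male and one
    female per lake); total length is drawn around a typical adult size.
    """
    rng = substream(cfg.seed, "samples")
    rows = []
    for lake in lakes:
        for j in range(cfg.n_ind_per_lake):
            rows.append(
                {
                    "sample_id": f"{lake.lake_id}_{j + 1}",
                    "lake": lake.lake_id,
                    "ecotype": lake.ecotype,
                    "sex": "F" if j % 2 == 0 else "M",
                    "total_length_mm": float(np.round(np.clip(rng.normal(185.0, 30.0), 90.0, 400.0))),
                    "latitude": lake.latitude,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place non-overlapping genes and SNPs; assign one annotation category per SNP.

    Returns ``(genes, snps)`` frames. Coordinates are 1-based inclusive.
    In-gene SNPs draw a category from ``cfg.category_probs``; SNPs within
    ``flank_bp`` of a gene edge get the strand-aware 5k-upstream /
    5k-downstream label (nearest gene wins when flanks overlap); the rest are
    intergenic.
    """
    rng = substream(cfg.seed, "annotation")
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1

    gene_rows = []
    gid = 0
    for c in range(cfg.n_chromosomes):
        n_c = int(per_chrom[c])
        lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n_c)
        total = int(lengths.sum())
        free = cfg.chrom_length_bp - total
        if free < 0:
            raise ValueError(
                f"requested gene length {total} bp exceeds chromosome capacity "
                f"{cfg.chrom_length_bp} bp on chr{c + 1}"
            )
        # uniform non-overlapping placement: sorted gap anchors + cumulative lengths
        anchors = np.sort(rng.integers(0, free + 1, size=n_c))
        starts = anchors + np.concatenate([[0], np.cumsum(lengths)[:-1]]) + 1
        strands = rng.choice(["+", "-"], size=n_c)
        for i in range(n_c):
            gid += 1
            gene_rows.append(
                {
                    "gene_id": f"g{gid:05d}",
                    "chrom": f"chr{c + 1}",
                    "start": int(starts[i]),
                    "end": int(starts[i] + lengths[i] - 1),
                    "strand": strands[i],
                }
            )
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    per_chrom_snps = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom_snps[: cfg.n_snps % cfg.n_chromosomes] += 1
    snp_rows = []
    sid = 0
    bases = np.array(list("ACGT"))
    for c in range(cfg.n_chromosomes):
        n_c = int(per_chrom_snps[c])
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=n_c, replace=False)) + 1
        chrom = f"chr{c + 1}"
        g = genes[genes["chrom"] == chrom]
        cats = _assign_categories(
            pos, g["start"].to_numpy(), g["end"].to_numpy(), g["strand"].to_numpy(),
            cfg.flank_bp, dict(cfg.category_probs), rng,
        )
        ref = bases[rng.integers(0, 4, size=n_c)]
        alt = np.array([bases[(list(bases).index(r) + rng.integers(1, 4)) % 4] for r in ref])
        for i in range(n_c):
            sid += 1
            snp_rows.append(
                {
                    "snp_id": f"s{sid:06d}",
                    "chrom": chrom,
                    "pos": int(pos[i]),
                    "ref": ref[i],
                    "alt": alt[i],
                    "category": cats[i],
                    "outlier": False,
                }
            )
    snps = pd.DataFrame(
        snp_rows,
        columns=["snp_id", "chrom", "pos", "ref", "alt", "category", "outlier"],
    )
    return genes, snps


def _assign_categories(pos, starts, ends, strands, flank, probs, rng):
    """Position-based category per SNP on one chromosome (genes sorted by start)."""
    order = np.argsort(starts)
    starts, ends, strands = starts[order], ends[order], strands[order]
    in_gene_cats = list(probs.keys())
    in_gene_p = np.array([probs[k] for k in in_gene_cats])
    out = []
    for p in np.asarray(pos):
        idx = np.searchsorted(starts, p, side="right") - 1
        if idx >= 0 and starts[idx] <= p <= ends[idx]:
            out.append(str(rng.choice(in_gene_cats, p=in_gene_p)))
            continue
        # distance to the right flank of gene idx and the left flank of gene idx+1
        cands = []
        if idx >= 0 and 0 < p - ends[idx] <= flank:
            side = "5k-downstream" if strands[idx] == "+" else "5k-upstream"
            cands.append((p - ends[idx], side))
        if idx + 1 < len(starts) and 0 < starts[idx + 1] - p <= flank:
            side = "5k-upstream" if strands[idx + 1] == "+" else "5k-downstream"
            cands.append((starts[idx + 1] - p, side))
        out.append(min(cands)[1] if cands else "intergenic")
    return out


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class SimulatedGenotypes:
    genotypes: GenotypeMatrix
    snps: pd.DataFrame  # with outlier truth set
    lake_freqs: pd.DataFrame  # lakes x snps realized per-lake allele frequency
    ancestral_freq: np.ndarray


def simulate_genotypes(
    cfg: SimulationConfig,
    lakes: Sequence[LakeMetadata],
    snps: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> SimulatedGenotypes:
    """Balding-Nichols genotypes with planted ecotype-divergent outliers.

    Per-SNP ancestral frequencies are uniform in ``ancestral_freq_range``.
    For planted outliers the two ecotype base frequencies are separated by
    ``outlier_delta`` (centred on the ancestral frequency, clipped into
    [0.01, 0.99]) *before* per-lake drift, so outliers remain detectable
    above drift noise. Each lake then draws its frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F); F = 0 is the no-drift limit. Genotypes are
    Binomial(2, lake frequency): dosages 0/1/2 with no missing entries.
    """
    if not lakes:
        raise ValueError("at least one lake is required")
    if cfg.drift_F >= 1.0:
        raise ValueError("drift_F must be < 1")
    rng = substream(cfg.seed, "genotypes")
    n_snps = len(snps)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=n_snps)

    snps = snps.copy()
    n_out = int(round(cfg.outlier_fraction * n_snps))
    out_idx = rng.choice(n_snps, size=n_out, replace=False)
    outlier = np.zeros(n_snps, dtype=bool)
    outlier[out_idx] = True
    snps["outlier"] = outlier

    # ecotype base frequencies
    p_h = p_anc.copy()
    p_c = p_anc.copy()
    if n_out:
        half = cfg.outlier_delta / 2.0
        centre = np.clip(p_anc[out_idx], 0.01 + half, 0.99 - half)
        sign = rng.choice([-1.0, 1.0], size=n_out)
        p_h[out_idx] = centre + sign * half
        p_c[out_idx] = centre - sign * half

    F = cfg.drift_F
    freq_rows = []
    for lake in lakes:
        pe = p_h if lake.ecotype == "humic" else p_c
        if F == 0.0:
            freq_rows.append(pe.copy())
        else:
            a = pe * (1.0 - F) / F
            b = (1.0 - pe) * (1.0 - F) / F
            freq_rows.append(rng.beta(a, b))
    lake_freqs = pd.DataFrame(
        np.vstack(freq_rows) if freq_rows else np.empty((0, n_snps)),
        index=[l.lake_id for l in lakes],
        columns=snps["snp_id"].tolist(),
    )

    if samples is None:
        samples = simulate_samples(cfg, lakes)
    dosages = np.empty((len(samples), n_snps), dtype=np.int8)
    for i, lake_id in enumerate(samples["lake"]):
        dosages[i] = rng.binomial(2, lake_freqs.loc[lake_id].to_numpy())
    gm = GenotypeMatrix(
        sample_ids=samples["sample_id"].tolist(),
        snp_ids=snps["snp_id"].tolist(),
        dosages=dosages,
    )
    return SimulatedGenotypes(genotypes=gm, snps=snps, lake_freqs=lake_freqs, ancestral_freq=p_anc)


# ---------------------------------------------------------------------------
# delta, outlier flagging, FST


def compute_delta(
    lake_freqs: pd.DataFrame | np.ndarray,
    ecotypes: Sequence[str],
    method: str = "pair_mean",
) -> np.ndarray:
    """Per-SNP ecotype allele-frequency divergence delta in [0, 1].

    ``pair_mean`` (default): mean over all humic x clear lake pairs of
    |p_humic - p_clear|. ``ecotype_mean``: |mean over humic lakes - mean
    over clear lakes|.
    """
    freqs = np.asarray(lake_freqs, dtype=float)
    eco = np.asarray(ecotypes)
    if freqs.shape[0] != len(eco):
        raise ValueError("one ecotype label per lake row is required")
    h = freqs[eco == "humic"]
    c = freqs[eco == "clear"]
    if h.shape[0] == 0 or c.shape[0] == 0:
        raise ValueError("both ecotypes need at least one lake")
    if method == "pair_mean":
        return np.abs(h[:, None, :] - c[None, :, :]).mean(axis=(0, 1))
    if method == "ecotype_mean":
        return np.abs(h.mean(axis=0) - c.mean(axis=0))
    raise ValueError(f"unknown method {method!r}")


def flag_outliers_by_delta(delta: np.ndarray, k_sd: float = 2.5) -> np.ndarray:
    """Flag SNPs with delta above mean + k_sd standard deviations (ddof=1).

    A constant delta vector (SD = 0) yields zero flags, not an error.
    """
    delta = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta must be finite")
    if delta.size < 2:
        return np.zeros(delta.shape, dtype=bool)
    thr = delta.mean() + k_sd * delta.std(ddof=1)
    return delta > thr


def hudson_fst(gm: GenotypeMatrix, populations: Sequence[str]) -> pd.DataFrame:
    """Pairwise Hudson FST (ratio of averages over SNPs) between populations.

    Per SNP and population pair, with sample allele frequencies p1, p2 and
    allele counts n1, n2:

        N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        D = p1(1-p2) + p2(1-p1)

    and FST = sum(N)/sum(D). Returns a symmetric matrix with zero diagonal;
    a pair monomorphic at every SNP is undefined and reported as NaN with a
    warning.
    """
    pops = np.asarray(populations)
    if len(pops) != gm.n_samples:
        raise ValueError("one population label per sample is required")
    labels = list(dict.fromkeys(pops))
    if len(labels) < 2:
        raise ValueError("at least two populations are required")
    for lab in labels:
        if (pops == lab).sum() < 2:
            raise ValueError(f"population {lab!r} has fewer than 2 individuals")

    freqs, counts = {}, {}
    for lab in labels:
        d = gm.dosages[pops == lab]
        freqs[lab] = d.mean(axis=0) / 2.0
        counts[lab] = 2 * d.shape[0]

    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            p1, p2 = freqs[a], freqs[b]
            n1, n2 = counts[a], counts[b]
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            if den.sum() == 0.0:
                warnings.warn(
                    f"populations {a}/{b} are monomorphic at every SNP; FST undefined",
                    stacklevel=2,
                )
                fst = np.nan
            else:
                fst = float(num.sum() / den.sum())
            out.loc[a, b] = out.loc[b, a] = fst
    return out


# ---------------------------------------------------------------------------
# expression


@dataclass
class SimulatedExpression:
    counts: dict  # tissue -> DataFrame genes x samples (raw integer counts)
    deg_truth: pd.DataFrame  # tissue, gene_id, log2fc
    eqtl_truth: pd.DataFrame  # gene_id, snp_id, beta (applied in all tissues)
    library_factors: dict = field(default_factory=dict)  # tissue -> Series per sample


def _cis_window_snps(gene, snps: pd.DataFrame, window: int) -> pd.DataFrame:
    lo = max(1, gene.start - window)
    hi = gene.end + window
    return snps[(snps["chrom"] == gene.chrom) & snps["pos"].between(lo, hi)]


def validate_planted_eqtls(
    genes: pd.DataFrame, snps: pd.DataFrame, truth: pd.DataFrame, window: int
) -> None:
    """Raise if any planted eQTL SNP lies outside its gene's cis window."""
    g = genes.set_index("gene_id")
    s = snps.set_index("snp_id")
    for row in truth.itertuples():
        gene = g.loc[row.gene_id]
        snp = s.loc[row.snp_id]
        lo = max(1, gene.start - window)
        hi = gene.end + window
        if snp.chrom != gene.chrom or not (lo <= snp.pos <= hi):
            raise ValueError(
                f"planted eQTL SNP {row.snp_id} outside the +/-{window} bp cis "
                f"window of gene {row.gene_id}"
            )


def simulate_expression(
    cfg: SimulationConfig,
    genes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    snps: pd.DataFrame,
) -> SimulatedExpression:
    """Negative-binomial counts with planted DEG, eQTL and covariate effects.

    The per-sample log2 mean of gene g is

        base_g + b_sex*sex + b_len*log10(TL) + b_lat*log10(lat)
               + humic_i * log2FC_g         (planted DEGs, per tissue)
               + beta_g * dosage_i(snp_g)   (planted cis-eQTLs, all tissues)

    with covariates centred so planted effects do not shift the overall
    expression scale. Counts are NB with variance mu + mu^2 * dispersion,
    scaled by a log-normal per-sample library factor.
    """
    rng = substream(cfg.seed, "expression")
    n_genes = len(genes)
    n_samples = len(samples)
    gene_ids = genes["gene_id"].tolist()

    base = rng.uniform(*cfg.baseline_log2_range, size=n_genes)

    sex = (samples["sex"] == "M").to_numpy(float)
    loglen = np.log10(samples["total_length_mm"].to_numpy(float))
    loglat = np.log10(samples["latitude"].to_numpy(float))
    eff = dict(cfg.covariate_effects)
    cov_term = (
        eff.get("sex", 0.0) * (sex - sex.mean())
        + eff.get("log10_length", 0.0) * (loglen - loglen.mean())
        + eff.get("log10_latitude", 0.0) * (loglat - loglat.mean())
    )
    humic = (samples["ecotype"] == "humic").to_numpy(float)

    # planted cis-eQTLs: shared across tissues, SNP drawn inside the window
    n_eqtl = int(round(cfg.eqtl_fraction * n_genes))
    maf = genotypes.maf()
    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}
    eqtl_rows = []
    if n_eqtl:
        maf_lo, maf_hi = cfg.eqtl_snp_maf_range
        candidates = []
        for gene in genes.itertuples():
            win = _cis_window_snps(gene, snps, cfg.cis_window_bp)
            ok = [s for s in win["snp_id"] if maf_lo <= maf[snp_pos[s]] <= maf_hi]
            if ok:
                candidates.append((gene.gene_id, ok))
        pick = rng.choice(len(candidates), size=min(n_eqtl, len(candidates)), replace=False)
        for i in pick:
            gene_id, ok = candidates[i]
            snp_id = ok[rng.integers(len(ok))]
            beta = float(rng.uniform(*cfg.eqtl_beta_range) * rng.choice([-1.0, 1.0]))
            eqtl_rows.append({"gene_id": gene_id, "snp_id": snp_id, "beta": beta})
    eqtl_truth = pd.DataFrame(eqtl_rows, columns=["gene_id", "snp_id", "beta"])
    validate_planted_eqtls(genes, snps, eqtl_truth, cfg.cis_window_bp)

    eqtl_term = np.zeros((n_samples, n_genes))
    gene_col = {g: j for j, g in enumerate(gene_ids)}
    for row in eqtl_truth.itertuples():
        dos = genotypes.dosages[:, snp_pos[row.snp_id]].astype(float)
        eqtl_term[:, gene_col[row.gene_id]] = row.beta * (dos - dos.mean())

    deg_rows = []
    counts: dict[str, pd.DataFrame] = {}
    libfactors: dict[str, pd.Series] = {}
    r = np.inf if cfg.nb_dispersion == 0 else 1.0 / cfg.nb_dispersion
    for tissue in cfg.tissues:
        n_deg = int(round(cfg.deg_fraction(tissue) * n_genes))
        deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
        log2fc = rng.uniform(*cfg.deg_log2fc_range, size=n_deg) * rng.choice([-1.0, 1.0], size=n_deg)
        deg_term = np.zeros((n_samples, n_genes))
        for j, fc in zip(deg_idx, log2fc):
            deg_term[:, j] = fc * (humic - humic.mean())
            deg_rows.append({"tissue": tissue, "gene_id": gene_ids[j], "log2fc": float(fc)})

        log2mu = base[None, :] + cov_term[:, None] + deg_term + eqtl_term
        lib = np.exp(rng.normal(0.0, cfg.library_factor_sd, size=n_samples))
        mu = (2.0 ** log2mu) * lib[:, None]
        if np.isinf(r):
            mat = rng.poisson(mu)
        else:
            p = r / (r + mu)
            mat = rng.negative_binomial(r, p)
        counts[tissue] = pd.DataFrame(
            mat.T.astype(np.int64), index=gene_ids, columns=samples["sample_id"].tolist()
        )
        libfactors[tissue] = pd.Series(lib, index=samples["sample_id"].tolist())

    deg_truth = pd.DataFrame(deg_rows, columns=["tissue", "gene_id", "log2fc"])
    return SimulatedExpression(
        counts=counts, deg_truth=deg_truth, eqtl_truth=eqtl_truth, library_factors=libfactors
    )


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    lakes: list[LakeMetadata]
    samples: pd.DataFrame
    genes: pd.DataFrame
    snps: pd.DataFrame
    genotypes: GenotypeMatrix
    lake_freqs: pd.DataFrame
    expression: SimulatedExpression

    @property
    def counts(self) -> dict:
        return self.expression.counts

    @property
    def deg_truth(self) -> pd.DataFrame:
        return self.expression.deg_truth

    @property
    def eqtl_truth(self) -> pd.DataFrame:
        return self.expression.eqtl_truth


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage under one root seed and return the dataset."""
    lakes = simulate_lakes(cfg.n_humic_lakes, cfg.n_clear_lakes, cfg.seed)
    samples = simulate_samples(cfg, lakes)
    genes, snps = simulate_annotation(cfg)
    sg = simulate_genotypes(cfg, lakes, snps, samples)
    expr = simulate_expression(cfg, genes, sg.genotypes, samples, sg.snps)
    return SimulatedDataset(
        config=cfg,
        lakes=lakes,
        samples=samples,
        genes=genes,
        snps=sg.snps,
        genotypes=sg.genotypes,
        lake_freqs=sg.lake_freqs,
        expression=expr,
    )
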