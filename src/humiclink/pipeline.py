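"""End-to-end pipeline orchestrator.

Runs simulate -> io -> sample QC -> differential expression -> outlier
enrichment -> cis-eQTL -> integration on a seeded synthetic dataset (or a
pre-existing dataset directory) and writes machine-readable TSV/JSON
reports plus a run manifest. Report files contain no wall-clock timestamps,
so a seeded run is checksum-reproducible; timestamps go to the log only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import humiclink
from humiclink.config import SimulationConfig
from humiclink.dataio import assign_snps_to_genes, classify_snps_by_deg, write_dataset
from humiclink.enrichment import category_enrichment, enrichment_counts, permutation_test
from humiclink.eqtl import beta_concordance, cis_scan, eqtl_filters, genotype_pca, summarize_eqtls
from humiclink.expression import de_test, filter_low_expression, mds_qc, normalize_and_log
from humiclink.report import integrate, lake_stats
from humiclink.simulate import simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineResult", "report_checksums"]


@dataclass
class PipelineResult:
    outdir: Path
    dataset: object
    deg_tables: dict
    enrichment: dict
    category_tables: dict
    eqtl_tables: dict
    eqtl_summaries: dict
    integration: object
    lake_tests: dict
    manifest: dict
    excluded_samples: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - annotate stage and re-raise
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrapper

    return deco


def run_pipeline(
    cfg: SimulationConfig,
    outdir,
    seed: int | None = None,
    n_perm: int = 1000,
    write_inputs: bool = True,
) -> PipelineResult:
    """Execute every stage on a seeded synthetic dataset and write reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "seed": seed})

    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("humiclink")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir, n_perm, write_inputs)
    finally:
        root.removeHandler(fh)
        fh.close()


def _run(cfg, outdir, n_perm, write_inputs):
    logger.info("pipeline start: seed=%d, %d SNPs, %d genes", cfg.seed, cfg.n_snps, cfg.n_genes)

    ds = _stage("simulate")(simulate_dataset)(cfg)
    if write_inputs:
        _stage("write-inputs")(write_dataset)(ds, outdir / "dataset")

    gene_windows = assign_snps_to_genes(ds.snps, ds.genes, flank_bp=cfg.flank_bp)
    outlier_flags = ds.snps["outlier"].to_numpy(bool)
    outlier_snps = set(ds.snps.loc[ds.snps["outlier"], "snp_id"])

    deg_tables, enrich_results, category_tables = {}, {}, {}
    eqtl_tables, eqtl_summaries, excluded = {}, {}, {}

    gm_f = _stage("eqtl-filters")(eqtl_filters)(ds.genotypes)
    pcs = _stage("genotype-pca")(genotype_pca)(gm_f, n_pc=2)

    for tissue in cfg.tissues:
        counts = ds.counts[tissue]
        filtered = _stage("low-count-filter")(filter_low_expression)(counts)
        _, logmat = _stage("normalize")(normalize_and_log)(filtered)
        qc = _stage("mds-qc")(mds_qc)(logmat)
        keep = [s for s in logmat.columns if not qc.outlier_flags[s]]
        excluded[tissue] = [s for s in logmat.columns if qc.outlier_flags[s]]
        if excluded[tissue]:
            logger.info("%s: excluded samples %s", tissue, excluded[tissue])
        logmat = logmat[keep]

        deg = _stage("de-test")(de_test)(logmat, ds.samples, tissue)
        deg_tables[tissue] = deg

        expressed = set(filtered.index)
        deg_set = set(deg.loc[deg["is_deg"], "gene_id"])
        classes = _stage("classify")(classify_snps_by_deg)(
            ds.snps, gene_windows, deg_set, expressed
        )
        res = _stage("permutation")(permutation_test)(
            classes, outlier_flags, n_perm=n_perm, seed=cfg.seed, tissue=tissue
        )
        enrich_results[tissue] = res

        deg_window = {s for g in deg_set for s in gene_windows.get(g, [])}
        expr_window = {s for g in expressed for s in gene_windows.get(g, [])}
        category_tables[tissue] = _stage("category-enrichment")(category_enrichment)(
            ds.snps, deg_window, expr_window, tissue=tissue
        )

        gm_t = gm_f.subset_samples(keep)
        pcs_t = pcs.loc[keep]
        eqtl = _stage("cis-scan")(cis_scan)(
            logmat, gm_t, ds.genes, ds.snps, ds.samples, tissue,
            window=cfg.cis_window_bp, pcs=pcs_t,
        )
        eqtl_tables[tissue] = eqtl
        eqtl_summaries[tissue] = summarize_eqtls(eqtl, outlier_snps, tissue)

    # combined eSNP enrichment across tissues
    all_sig = pd.concat([t[t["significant"]] for t in eqtl_tables.values()], ignore_index=True)
    # combined counts are unions of distinct pairs/SNPs/genes across tissues
    all_sig = all_sig.drop_duplicates(subset=["gene_id", "snp_id"])
    eqtl_summaries["combined"] = summarize_eqtls(
        all_sig.assign(significant=True), outlier_snps, "combined"
    )

    conc_pct = float("nan")
    if len(eqtl_tables) >= 2:
        conc_pct, _ = _stage("beta-concordance")(beta_concordance)(eqtl_tables)

    integration = _stage("integrate")(integrate)(
        deg_tables, ds.genes, ds.snps, eqtl_tables,
        candidate_flank_bp=cfg.flank_bp, beta_concordance_pct=conc_pct,
    )
    lake_tests = {v: _stage("lake-stats")(lake_stats)(ds.lakes, v) for v in ("doc", "colour")}

    manifest = {
        "package": "humiclink",
        "version": humiclink.__version__,
        "seed": cfg.seed,
        "n_perm": n_perm,
        "thresholds": {"deg_fdr": 0.05, "eqtl_fdr": 0.05, "maf_min": 0.10,
                       "cis_window_bp": cfg.cis_window_bp, "flank_bp": cfg.flank_bp},
        "config": cfg.to_dict(),
        "excluded_samples": excluded,
        "deg_precedence": "SNPs in overlapping DEG/non-DEG windows are classed DEG",
    }

    _write_reports(outdir, deg_tables, enrich_results, category_tables,
                   eqtl_tables, eqtl_summaries, integration, lake_tests, manifest)
    logger.info("pipeline done: reports in %s", outdir)
    return PipelineResult(
        outdir=outdir, dataset=ds, deg_tables=deg_tables, enrichment=enrich_results,
        category_tables=category_tables, eqtl_tables=eqtl_tables,
        eqtl_summaries=eqtl_summaries, integration=integration, lake_tests=lake_tests,
        manifest=manifest, excluded_samples=excluded,
    )


def _write_reports(outdir, deg_tables, enrich, category_tables, eqtl_tables,
                   eqtl_summaries, integration, lake_tests, manifest):
    rep = Path(outdir) / "reports"
    rep.mkdir(exist_ok=True)
    pd.concat(deg_tables.values(), ignore_index=True).to_csv(
        rep / "deg.tsv", sep="\t", index=False
    )
    pd.DataFrame([r.to_dict() for r in enrich.values()]).to_csv(
        rep / "outlier_enrichment.tsv", sep="\t", index=False
    )
    pd.concat(category_tables.values(), ignore_index=True).to_csv(
        rep / "category_enrichment.tsv", sep="\t", index=False
    )
    pd.concat(eqtl_tables.values(), ignore_index=True).to_csv(
        rep / "cis_eqtl.tsv", sep="\t", index=False
    )
    pd.DataFrame([s.to_dict() for s in eqtl_summaries.values()]).to_csv(
        rep / "eqtl_summary.tsv", sep="\t", index=False
    )
    integration.per_tissue.to_csv(rep / "integration.tsv", sep="\t", index=False)
    venns = {
        "deg": {"+".join(k): v for k, v in integration.deg_venn.items()},
        "egene": {"+".join(k): v for k, v in integration.egene_venn.items()},
        "esnp": {"+".join(k): v for k, v in integration.esnp_venn.items()},
        "beta_concordance_pct": integration.beta_concordance_pct,
    }
    (rep / "venn.json").write_text(json.dumps(venns, indent=2, sort_keys=True))
    (rep / "lake_stats.json").write_text(json.dumps(lake_tests, indent=2, sort_keys=True))
    (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def report_checksums(outdir) -> dict[str, str]:
    """SHA-256 of every report file plus the manifest (log excluded)."""
    outdir = Path(outdir)
    sums = {}
    targets = sorted((outdir / "reports").glob("*")) + [outdir / "manifest.json"]
    for p in targets:
        sums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return sums
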