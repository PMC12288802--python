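"""Cross-layer integration: DEG/outlier/eQTL overlaps, Venn counts, lake stats."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from humiclink.dataio import assign_snps_to_genes

__all__ = ["integrate", "venn_counts", "lake_stats", "IntegrationReport"]


@dataclass
class IntegrationReport:
    per_tissue: pd.DataFrame
    deg_venn: dict
    egene_venn: dict
    esnp_venn: dict
    beta_concordance_pct: float = float("nan")
    notes: list[str] = field(default_factory=list)


def _pct(a: int, b: int) -> float:
    return round(100.0 * a / b, 1) if b else float("nan")


def integrate(
    deg_tables: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    eqtl_tables: dict[str, pd.DataFrame] | None = None,
    candidate_flank_bp: int = 5_000,
    beta_concordance_pct: float = float("nan"),
) -> IntegrationReport:
    """Assemble the per-tissue integration table and cross-tissue Venn counts.

    A *candidate* gene harbours >= 1 outlier SNP within its gene body +/-5 kb
    window; candidate DEGs and candidate eGenes are the intersections of
    those sets with the DEG and eGene sets. Percentages carry their stated
    denominators: up/down and candidate-DEG % of DEGs.
    """
    gene_universe = set(genes["gene_id"])
    for tissue, table in deg_tables.items():
        stray = set(table["gene_id"]) - gene_universe
        if stray:
            raise ValueError(f"DEG table {tissue} has unknown genes: {sorted(stray)[:10]}")

    outlier_snps = snps[snps["outlier"].astype(bool)]
    mapping = assign_snps_to_genes(outlier_snps, genes, flank_bp=candidate_flank_bp)
    candidate_genes = {g for g, s in mapping.items() if s}

    eqtl_tables = eqtl_tables or {}
    rows = []
    for tissue, table in deg_tables.items():
        expressed = set(table["gene_id"])
        degs = set(table.loc[table["is_deg"], "gene_id"])
        n_up = int((table["is_deg"] & (table["direction"] == "up-in-humic")).sum())
        n_down = int((table["is_deg"] & (table["direction"] == "down-in-humic")).sum())
        cand_deg = degs & candidate_genes
        row = {
            "tissue": tissue,
            "n_expressed": len(expressed),
            "n_deg": len(degs),
            "n_up": n_up,
            "n_down": n_down,
            "pct_up": _pct(n_up, len(degs)),
            "pct_down": _pct(n_down, len(degs)),
            "n_candidate_deg": len(cand_deg),
            "pct_candidate_deg": _pct(len(cand_deg), len(degs)),
        }
        eq = eqtl_tables.get(tissue)
        if eq is not None:
            egenes = set(eq.loc[eq["significant"], "gene_id"])
            row.update(
                {
                    "n_egenes": len(egenes),
                    "n_egene_deg": len(egenes & degs),
                    "n_candidate_egene": len(egenes & candidate_genes),
                    "n_candidate_egene_deg": len(egenes & candidate_genes & degs),
                }
            )
        rows.append(row)
    per_tissue = pd.DataFrame(rows)

    deg_sets = {
        t: set(tab.loc[tab["is_deg"], "gene_id"]) for t, tab in deg_tables.items()
    }
    egene_sets = {
        t: set(tab.loc[tab["significant"], "gene_id"]) for t, tab in eqtl_tables.items()
    }
    esnp_sets = {
        t: set(tab.loc[tab["significant"], "snp_id"]) for t, tab in eqtl_tables.items()
    }
    return IntegrationReport(
        per_tissue=per_tissue,
        deg_venn=venn_counts(deg_sets) if deg_sets else {},
        egene_venn=venn_counts(egene_sets) if egene_sets else {},
        esnp_venn=venn_counts(esnp_sets) if esnp_sets else {},
        beta_concordance_pct=beta_concordance_pct,
    )


def venn_counts(named_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exact element counts of every non-empty Venn region of up to 5 sets.

    Keys are tuples of the set names a region belongs to (and implicitly
    excludes the rest); counts over all regions conserve set sizes.
    """
    names = list(named_sets)
    if len(names) > 5:
        raise ValueError("venn_counts supports at most 5 sets; use a pairwise matrix instead")
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inc in combinations(names, r):
            exc = [n for n in names if n not in inc]
            region = set.intersection(*(named_sets[n] for n in inc)) if inc else set()
            for n in exc:
                region = region - named_sets[n]
            out[tuple(inc)] = len(region)
    return out


def lake_stats(lakes, value: str = "colour") -> dict:
    """Group medians/ranges plus a two-sided Mann-Whitney U test by ecotype.

    ``value`` is a LakeMetadata field (``colour`` or ``doc``). The median is
    the mean of the central order statistics for even n; the U test is exact
    for group sizes <= 20 and a tie-corrected normal approximation above.
    """
    df = lakes if isinstance(lakes, pd.DataFrame) else pd.DataFrame([vars(l) for l in lakes])
    humic = df.loc[df["ecotype"] == "humic", value].to_numpy(float)
    clear = df.loc[df["ecotype"] == "clear", value].to_numpy(float)
    if len(humic) == 0 or len(clear) == 0:
        raise ValueError("both ecotypes need at least one lake")
    method = "exact" if max(len(humic), len(clear)) <= 20 else "asymptotic"
    try:
        res = stats.mannwhitneyu(humic, clear, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the tie-corrected normal
        res = stats.mannwhitneyu(humic, clear, alternative="two-sided", method="asymptotic")
    return {
        "variable": value,
        "median_humic": float(np.median(humic)),
        "median_clear": float(np.median(clear)),
        "range_humic": (float(humic.min()), float(humic.max())),
        "range_clear": (float(clear.min()), float(clear.max())),
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "method": method,
    }
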