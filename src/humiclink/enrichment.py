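"""Outlier-SNP enrichment in DEG windows: permutation test and category contrasts.

The permutation test asks whether selection-outlier SNPs are over- (or
under-) represented inside DEG windows relative to non-DEG expressed-gene
windows. The statistic is

    stat = freq_DEG - freq_nonDEG,   freq = outliers / (outliers + non-outliers)

within each class, and the null is built by reassigning the fixed number of
outlier labels uniformly at random without replacement across *all* SNPs
(including unassigned ones), which preserves the genome-wide outlier count
and incorporates differences in SNP density among genes. Class-wise outlier
counts under this shuffle follow the multivariate hypergeometric
distribution, which is how replicates are drawn; an exhaustive mode
enumerates all C(n, k) label placements exactly via integer combinatorics.

Two p-values are reported: ``p_paper`` = #{permuted stat strictly greater
than observed}/n_perm (can be 0), and the add-one Monte-Carlo estimator
``p_mc`` = (#greater + 1)/(n_perm + 1). Deficiency is assessed with the
mirrored (strictly smaller) statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from humiclink._rng import substream

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "enrichment_counts", "permutation_test", "category_enrichment"]


@dataclass
class EnrichmentResult:
    """Counts, frequencies and permutation p-values for one tissue."""

    tissue: str
    n_out_deg: int
    n_non_deg_class: int
    n_out_nondeg: int
    n_non_nondeg: int
    freq_deg: float
    freq_nondeg: float
    stat_obs: float
    n_perm: int = 0
    n_perm_greater: int = 0
    n_perm_less: int = 0
    n_perm_equal: int = 0
    p_paper: float = float("nan")
    p_mc: float = float("nan")
    p_deficiency_paper: float = float("nan")
    p_deficiency_mc: float = float("nan")
    mode: str = "none"
    seed: int | None = None
    degenerate: bool = False
    notices: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["notices"] = "; ".join(self.notices)
        return d


def _tally(classes: pd.Series, outliers: np.ndarray) -> tuple[int, int, int, int, int, int]:
    cls = np.asarray(classes)
    out = np.asarray(outliers, dtype=bool)
    if cls.shape != out.shape:
        raise ValueError("classes and outlier flags must align")
    deg = cls == "DEG"
    nondeg = cls == "nonDEG"
    return (
        int((deg & out).sum()),
        int((deg & ~out).sum()),
        int((nondeg & out).sum()),
        int((nondeg & ~out).sum()),
        int(deg.sum()),
        int(nondeg.sum()),
    )


def enrichment_counts(
    classes: pd.Series, outliers: np.ndarray, tissue: str = ""
) -> EnrichmentResult:
    """Class-wise outlier tallies and frequencies (no permutation).

    freq = outliers / (outliers + non-outliers) within each class. An empty
    DEG class yields missing frequencies with a notice.
    """
    od, nd, on, nn, d, m = _tally(classes, outliers)
    notices = []
    if d == 0:
        notices.append("empty DEG class; frequencies undefined, test skipped")
        freq_deg = float("nan")
    else:
        freq_deg = od / d
    freq_nondeg = on / m if m else float("nan")
    stat = freq_deg - freq_nondeg if d and m else float("nan")
    return EnrichmentResult(
        tissue=tissue,
        n_out_deg=od,
        n_non_deg_class=nd,
        n_out_nondeg=on,
        n_non_nondeg=nn,
        freq_deg=freq_deg,
        freq_nondeg=freq_nondeg,
        stat_obs=stat,
        notices=notices,
    )


def permutation_test(
    classes: pd.Series,
    outliers: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    tissue: str = "",
    mode: str = "auto",
    exhaustive_limit: float = 1e5,
) -> EnrichmentResult:
    """Genome-wide label-shuffling permutation test for outlier enrichment.

    ``mode='auto'`` switches to exact enumeration when the number of label
    placements C(n_snps, n_outliers) does not exceed ``exhaustive_limit``;
    ``'exhaustive'`` and ``'monte-carlo'`` force either route. Tie
    comparisons use exact integer cross-multiplication, never float
    equality. The total outlier count is conserved in every replicate by
    construction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    out = np.asarray(outliers, dtype=bool)
    res = enrichment_counts(classes, out, tissue)
    od, on = res.n_out_deg, res.n_out_nondeg
    d = res.n_out_deg + res.n_non_deg_class
    m = res.n_out_nondeg + res.n_non_nondeg
    n = len(out)
    u = n - d - m
    k = int(out.sum())
    if k > n:
        raise ValueError("more outliers than SNPs")
    if d == 0 or m == 0:
        res.notices.append("degenerate class structure; permutation skipped")
        res.degenerate = True
        return res

    total_placements = comb(n, k)
    if mode == "auto":
        mode = "exhaustive" if total_placements <= exhaustive_limit else "monte-carlo"

    # stat > obs  <=>  m*(x - od) > d*(z - on), exact in integers
    if mode == "exhaustive":
        greater = less = equal = 0
        for x in range(max(0, k - m - u), min(d, k) + 1):
            wx = comb(d, x)
            for z in range(max(0, k - x - u), min(m, k - x) + 1):
                w = wx * comb(m, z) * comb(u, k - x - z)
                lhs = m * (x - od)
                rhs = d * (z - on)
                if lhs > rhs:
                    greater += w
                elif lhs < rhs:
                    less += w
                else:
                    equal += w
        n_eff = total_placements
    elif mode == "monte-carlo":
        rng = substream(seed, f"permutation:{tissue}")
        draws = rng.multivariate_hypergeometric([d, m, u], k, size=n_perm)
        x, z = draws[:, 0].astype(np.int64), draws[:, 1].astype(np.int64)
        lhs = m * (x - od)
        rhs = d * (z - on)
        greater = int((lhs > rhs).sum())
        less = int((lhs < rhs).sum())
        equal = int((lhs == rhs).sum())
        n_eff = n_perm
    else:
        raise ValueError(f"unknown mode {mode!r}")

    res.mode = mode
    res.seed = seed
    res.n_perm = n_eff
    res.n_perm_greater = greater
    res.n_perm_less = less
    res.n_perm_equal = equal
    res.p_paper = greater / n_eff
    res.p_mc = (greater + 1) / (n_eff + 1)
    res.p_deficiency_paper = less / n_eff
    res.p_deficiency_mc = (less + 1) / (n_eff + 1)
    if equal == n_eff:
        res.degenerate = True
        res.notices.append("every permuted statistic ties the observed one")
    return res


def category_enrichment(
    snps: pd.DataFrame,
    deg_window_snps: set[str],
    expressed_window_snps: set[str],
    yates: bool = True,
    tissue: str = "",
) -> pd.DataFrame:
    """Per-annotation-category 2x2 chi-square contrast of outlier frequency.

    For each category c the table is (outlier, non-outlier) x (SNPs of c in
    DEG windows, SNPs of c in expressed-gene windows); Yates continuity
    correction is applied by default (toggle with ``yates``). Categories
    with any expected cell below 1, or absent from DEG windows, are skipped
    with a notice. ``direction`` is excess/deficiency from the sign of
    observed - expected in the DEG/outlier cell.
    """
    required = {"snp_id", "category", "outlier"}
    missing = required - set(snps.columns)
    if missing:
        raise ValueError(f"snps frame missing columns: {sorted(missing)}")
    in_deg = snps["snp_id"].isin(deg_window_snps)
    in_expr = snps["snp_id"].isin(expressed_window_snps)
    out = snps["outlier"].astype(bool)

    rows = []
    for cat in sorted(snps["category"].unique()):
        of_cat = snps["category"] == cat
        a = int((of_cat & in_deg & out).sum())  # outlier, DEG window
        b = int((of_cat & in_deg & ~out).sum())
        c = int((of_cat & in_expr & out).sum())
        d = int((of_cat & in_expr & ~out).sum())
        row = {
            "tissue": tissue,
            "category": cat,
            "n_out_deg": a,
            "n_non_deg": b,
            "n_out_expr": c,
            "n_non_expr": d,
            "chi2": float("nan"),
            "p": float("nan"),
            "direction": "",
            "note": "",
        }
        table = np.array([[a, b], [c, d]], dtype=float)
        if a + b == 0:
            row["note"] = "category absent from DEG windows; skipped"
            logger.info("category %s absent from DEG windows in %s; skipped", cat, tissue)
        else:
            expected = stats.contingency.expected_freq(table)
            if (expected < 1.0).any():
                row["note"] = "expected cell < 1; skipped"
                logger.info("category %s has expected cell < 1 in %s; skipped", cat, tissue)
            else:
                chi2, p, _, exp = stats.chi2_contingency(table, correction=yates)
                row["chi2"] = float(chi2)
                row["p"] = float(p)
                row["direction"] = "excess" if a >= exp[0, 0] else "deficiency"
        rows.append(row)
    return pd.DataFrame(rows)
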