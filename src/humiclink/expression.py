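"""Low-count filtering, normalization, sample QC and differential expression.

Differential expression between ecotypes is a covariate-adjusted Gaussian
linear model on log2 median-of-ratios-normalized counts (per-gene OLS with
design ~ log10(latitude) + log10(total length) + sex + ecotype, optionally
+PC1 +PC2), with Benjamini-Hochberg adjustment within tissue and a DEG call
at adjusted p <= 0.05. This is a deliberate, documented stand-in for a
negative-binomial Wald test: DEG calls are pluggable via
:func:`ingest_deg_table` so external caller output can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "filter_low_expression",
    "normalize_and_log",
    "mds_qc",
    "de_test",
    "ingest_deg_table",
    "direction_imbalance_test",
    "MdsResult",
]


def filter_low_expression(
    counts: pd.DataFrame, min_count: int = 10, max_below: int = 15
) -> pd.DataFrame:
    """Drop rare transcripts: remove a gene iff more than ``max_below``
    samples have fewer than ``min_count`` raw reads (strict '>')."""
    n_below = (counts < min_count).sum(axis=1)
    return counts.loc[n_below <= max_below]


def normalize_and_log(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the log2 normalized matrix.

    The size factor of a sample is the median, over genes positive in every
    sample, of count / geometric-mean(count across samples); output is
    log2(count / size_factor + 1). If no gene is positive everywhere, fall
    back to total-count scaling with a logged notice.
    """
    mat = counts.to_numpy(float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        ref = mat[positive]
        geo = np.exp(np.mean(np.log(ref), axis=1))
        sf = np.median(ref / geo[:, None], axis=0)
    else:
        logger.warning("no gene positive in all samples; falling back to total-count scaling")
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    logmat = pd.DataFrame(
        np.log2(mat / sf[None, :] + 1.0), index=counts.index, columns=counts.columns
    )
    return size_factors, logmat


@dataclass
class MdsResult:
    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray
    outlier_flags: pd.Series
    distances: pd.Series  # robust distance of each sample from the median point


def mds_qc(
    logmat: pd.DataFrame,
    k: int = 2,
    flag_madsd: float = 4.0,
    distance: str | None = "euclidean",
    dist_matrix: np.ndarray | None = None,
) -> MdsResult:
    """Classical (Torgerson) MDS of samples plus automated outlier flagging.

    The distance is pluggable: pass ``dist_matrix`` directly, or use the
    default Euclidean distance on the log2 matrix columns. A sample is
    flagged when its distance from the coordinate-wise median point exceeds
    the median of such distances by more than ``flag_madsd`` x MAD — an
    auditable replacement for by-eye outlier exclusion.
    """
    sample_ids = list(logmat.columns)
    n = len(sample_ids)
    if n < 3:
        raise ValueError("MDS QC needs at least 3 samples")
    if dist_matrix is None:
        if distance != "euclidean":
            raise ValueError(f"unknown distance {distance!r}; pass dist_matrix instead")
        x = logmat.to_numpy(float).T
        diff = x[:, None, :] - x[None, :, :]
        dist_matrix = np.sqrt((diff**2).sum(axis=2))
    dm = np.asarray(dist_matrix, float)

    if np.allclose(dm, 0.0):
        coords = pd.DataFrame(
            np.zeros((n, k)), index=sample_ids, columns=[f"MDS{i+1}" for i in range(k)]
        )
        zero = pd.Series(np.zeros(n), index=sample_ids)
        return MdsResult(coords, np.zeros(k), zero.astype(bool), zero)

    ord_res = pcoa(DistanceMatrix(dm, ids=sample_ids), number_of_dimensions=min(k, n - 1))
    coords = ord_res.samples.iloc[:, :k].copy()
    coords.columns = [f"MDS{i+1}" for i in range(coords.shape[1])]
    eigvals = ord_res.eigvals.to_numpy()[:k]

    med = coords.median(axis=0)
    d = np.sqrt(((coords - med) ** 2).sum(axis=1))
    mad = float((d - d.median()).abs().median())
    flags = (d - d.median()) > flag_madsd * mad
    return MdsResult(coords, eigvals, flags.rename("outlier"), d.rename("distance"))


def _design_matrix(
    meta: pd.DataFrame, pcs: pd.DataFrame | None = None
) -> tuple[np.ndarray, list[str], int]:
    """Design: intercept + log10(lat) + log10(TL) + sex + ecotype (+PCs)."""
    cols = {
        "intercept": np.ones(len(meta)),
        "log10_latitude": np.log10(meta["latitude"].to_numpy(float)),
        "log10_length": np.log10(meta["total_length_mm"].to_numpy(float)),
        "sex": (meta["sex"] == "M").to_numpy(float),
        # clear = 0, humic = 1 so a positive coefficient is up-in-humic
        "ecotype": (meta["ecotype"] == "humic").to_numpy(float),
    }
    if pcs is not None:
        for c in pcs.columns:
            cols[c] = pcs.loc[meta["sample_id"], c].to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) > len(kept):
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, names, names.index("ecotype")


def de_test(
    logmat: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    pcs: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene OLS of log2 normalized expression on the covariate design.

    Returns a frame with ``gene_id tissue log2fc p p_adj direction is_deg``.
    The ecotype coefficient is the log2 fold change (humic vs. clear);
    two-sided p-values come from the t distribution with n - k df; BH is
    applied across genes within the tissue; DEG at p_adj <= alpha.
    Zero-variance genes get p = 1 and a flag.
    """
    meta = meta.set_index("sample_id").loc[list(logmat.columns)].reset_index()
    if (meta["ecotype"] == "humic").sum() < 2 or (meta["ecotype"] == "clear").sum() < 2:
        raise ValueError("need at least 2 samples per ecotype")
    X, names, eco_ix = _design_matrix(meta, pcs)
    Y = logmat.to_numpy(float).T  # samples x genes
    n, kcol = X.shape
    df = n - kcol
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y
    resid = Y - X @ B
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[eco_ix, eco_ix], 0.0))
    beta = B[eco_ix]

    zero_var = Y.var(axis=0) <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_var | (se == 0.0), 1.0, p)

    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene_id": logmat.index,
            "tissue": tissue,
            "log2fc": beta,
            "t_stat": t,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(beta >= 0, "up-in-humic", "down-in-humic"),
            "is_deg": p_adj <= alpha,
            "zero_variance": zero_var,
        }
    )
    return out.reset_index(drop=True)


def ingest_deg_table(path_or_frame) -> pd.DataFrame:
    """Accept an externally computed DEG table, bypassing the internal test.

    Requires columns ``gene_id tissue log2fc p p_adj``; recomputes
    ``direction`` and ``is_deg`` so the downstream invariants hold.
    """
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(
        path_or_frame, sep="\t"
    )
    required = {"gene_id", "tissue", "log2fc", "p", "p_adj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    df = df.copy()
    df["direction"] = np.where(df["log2fc"] >= 0, "up-in-humic", "down-in-humic")
    df["is_deg"] = df["p_adj"] <= 0.05
    return df


def direction_imbalance_test(
    n_up: int, n_down: int, yates: bool = False
) -> tuple[float, float]:
    """1-df chi-square goodness of fit of (up, down) DEG counts vs 50:50.

    No continuity correction by default (``yates=True`` enables it). Both
    counts zero is undefined and returns (nan, nan).
    """
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    total = n_up + n_down
    if total == 0:
        return float("nan"), float("nan")
    expected = total / 2.0
    if yates:
        dev = max(abs(n_up - expected) - 0.5, 0.0)
    else:
        dev = abs(n_up - expected)
    chi2 = 2.0 * dev**2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
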