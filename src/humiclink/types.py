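"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "SNP_CATEGORIES"]

SNP_CATEGORIES = (
    "intron",
    "synonymous",
    "non-synonymous",
    "3'UTR",
    "5'UTR",
    "5k-upstream",
    "5k-downstream",
    "intergenic",
)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alt-allele dosage matrix (values 0/1/2, no missing).

    The substrate for MAF filters, genotype PCA, the cis-eQTL scan and
    Hudson FST. Rows are samples, columns are SNPs.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # shape (n_samples, n_snps), int8

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be 0, 1 or 2 with no missing entries")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def alt_freq(self) -> np.ndarray:
        """Per-SNP alt-allele sample frequency."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, in [0, 0.5]."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            snp_ids=list(self.snp_ids),
            dosages=self.dosages[idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)
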