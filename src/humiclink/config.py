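"""Simulation configuration and lake metadata types.

The defaults reproduce the study design that the analysis assumes: 16 lake
populations (8 humic / 8 clear-water) under strong drift, ~1.3% of SNPs
planted as selection outliers with an elevated ecotype allele-frequency
difference, tissue-specific DEG fractions matching the observed per-tissue
DEG/expressed ratios, planted cis-eQTL effects inside +/-50 kb windows, and
negative-binomial read counts with sex/length/latitude covariate effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

__all__ = ["SimulationConfig", "LakeMetadata", "DEFAULT_TISSUES"]

DEFAULT_TISSUES = ("gill", "spleen", "olfactory_rosette", "whole_eye", "liver")

# Per-tissue DEG fractions of expressed genes in the study (e.g. gill
# 4311/18446); used as planted-DEG fractions by default.
_DEFAULT_DEG_FRACTIONS = {
    "gill": 0.234,
    "spleen": 0.053,
    "olfactory_rosette": 0.037,
    "whole_eye": 0.028,
    "liver": 0.016,
}

# Ecotype-conditional water chemistry ranges (survey Table-derived):
# disjoint by construction between humic and clear-water lakes.
CLEAR_DOC_RANGE = (5.27, 16.78)
HUMIC_DOC_RANGE = (17.41, 66.10)
CLEAR_COLOUR_RANGE = (15.0, 30.0)
HUMIC_COLOUR_RANGE = (172.5, 752.5)
LATITUDE_RANGE = (57.5, 59.5)
LONGITUDE_RANGE = (25.0, 27.5)


@dataclass(frozen=True)
class LakeMetadata:
    """One study lake: identity, ecotype and water chemistry."""

    lake_id: str
    ecotype: str  # "humic" or "clear"
    latitude: float
    longitude: float
    doc: float  # dissolved organic carbon, mg/L
    colour: float  # water colour, mgPt/L

    def __post_init__(self) -> None:
        if self.ecotype not in ("humic", "clear"):
            raise ValueError(f"unknown ecotype {self.ecotype!r}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study-design generator.

    Proportions are in [0, 1]; ``drift_F`` is the per-lake Balding-Nichols
    divergence in [0, 1); ``outlier_delta`` is the target mean absolute
    ecotype allele-frequency difference planted at true outlier SNPs;
    ``eqtl_beta_range`` is in log2 expression units per alt allele.
    """

    n_humic_lakes: int = 8
    n_clear_lakes: int = 8
    n_ind_per_lake: int = 2
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_chromosomes: int = 4
    chrom_length_bp: int = 5_000_000
    n_genes: int = 400
    n_snps: int = 8_000
    flank_bp: int = 5_000
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    # probabilities of in-gene annotation categories
    category_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "intron": 0.62,
            "synonymous": 0.12,
            "non-synonymous": 0.10,
            "3'UTR": 0.09,
            "5'UTR": 0.07,
        }
    )
    drift_F: float = 0.15
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    outlier_fraction: float = 0.0126
    outlier_delta: float = 0.35
    deg_fraction_per_tissue: Mapping[str, float] | float = field(
        default_factory=lambda: dict(_DEFAULT_DEG_FRACTIONS)
    )
    deg_log2fc_range: tuple[float, float] = (0.5, 2.0)
    eqtl_fraction: float = 0.02
    eqtl_beta_range: tuple[float, float] = (0.5, 1.5)
    # planted eQTL SNPs are drawn from this realized-MAF window
    eqtl_snp_maf_range: tuple[float, float] = (0.10, 0.50)
    cis_window_bp: int = 50_000
    nb_dispersion: float = 0.1
    # log2 baseline of expressed (post-filter) genes: 32-4096 mean counts
    baseline_log2_range: tuple[float, float] = (5.0, 12.0)
    library_factor_sd: float = 0.1
    # coefficients on (sex indicator, log10 total length, log10 latitude)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"sex": 0.1, "log10_length": 0.5, "log10_latitude": 0.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_humic_lakes", "n_clear_lakes", "n_ind_per_lake"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("outlier_fraction", "eqtl_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.drift_F < 1.0:
            raise ValueError(f"drift_F={self.drift_F} outside [0, 1)")
        if not 0.0 <= self.outlier_delta <= 1.0:
            raise ValueError("outlier_delta outside [0, 1]")
        # planted ecotype frequencies are clipped into [0.01, 0.99]; the full
        # separation must be representable inside those bounds
        if self.outlier_delta > 0.98:
            raise ValueError("outlier_delta not reachable within frequency bounds [0.01, 0.99]")
        if self.n_snps < self.n_genes:
            raise ValueError("n_snps must be >= n_genes")
        fr = self.deg_fraction_per_tissue
        if isinstance(fr, Mapping):
            for t, v in fr.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"deg fraction for {t} outside [0, 1]")
        elif not 0.0 <= fr <= 1.0:
            raise ValueError("deg_fraction_per_tissue outside [0, 1]")
        p = dict(self.category_probs)
        if abs(sum(p.values()) - 1.0) > 1e-9:
            raise ValueError("category_probs must sum to 1")

    def deg_fraction(self, tissue: str) -> float:
        fr = self.deg_fraction_per_tissue
        if isinstance(fr, Mapping):
            return float(fr.get(tissue, 0.0))
        return float(fr)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        for k in ("gene_length_range", "deg_log2fc_range", "eqtl_beta_range",
                  "eqtl_snp_maf_range", "baseline_log2_range", "ancestral_freq_range"):
            d[k] = list(d[k])
        d["category_probs"] = dict(self.category_probs)
        d["covariate_effects"] = dict(self.covariate_effects)
        if isinstance(self.deg_fraction_per_tissue, Mapping):
            d["deg_fraction_per_tissue"] = dict(self.deg_fraction_per_tissue)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "tissues" in d:
            d["tissues"] = tuple(d["tissues"])
        for k in ("gene_length_range", "deg_log2fc_range", "eqtl_beta_range",
                  "eqtl_snp_maf_range", "baseline_log2_range", "ancestral_freq_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
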