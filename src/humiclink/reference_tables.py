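"""Published field-survey and genome-scan reference values used as inputs.

These constants calibrate the synthetic-data generator and feed the
desk-scale statistics (group medians, class frequencies, Yates chi-square
enrichment) that the package recomputes from printed counts rather than from
raw sequence data.

``STUDY_LAKES``
    Water chemistry for the 16 study lakes (8 humic, 8 clear-water) in
    Estonia: dissolved organic carbon (DOC, mg/L) and water colour (mgPt/L),
    with coordinates. Humic and clear-water ranges are disjoint by
    construction of the study design.

``WGS_OUTLIER_SNPS`` / ``WGS_NONOUTLIER_SNPS``
    Genome-wide tallies from the prior whole-genome scan for footprints of
    selection: 10,245 outlier SNPs among 810,591 total.

``DEG_WINDOW_SNP_COUNTS``
    Per-tissue counts of outlier / non-outlier SNPs inside DEG windows and
    non-DEG expressed-gene windows (gene body plus 5 kb flanks).

``ESNP_COUNTS``
    Per-tissue outlier / non-outlier counts among eSNPs (SNPs significantly
    associated with expression in the cis-eQTL scan).

``DEG_DIRECTION_COUNTS``
    Per-tissue expressed-gene and DEG tallies with up/down regulation in the
    humic ecotype.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "STUDY_LAKES",
    "WGS_OUTLIER_SNPS",
    "WGS_NONOUTLIER_SNPS",
    "DEG_WINDOW_SNP_COUNTS",
    "ESNP_COUNTS",
    "DEG_DIRECTION_COUNTS",
]

STUDY_LAKES = pd.DataFrame(
    [
        # lake_id, ecotype, longitude, latitude, doc_mg_l, colour_mgpt_l
        ("EANT", "clear", 59.060, 26.240, 13.38, 17.5),
        ("EHIN", "clear", 57.577, 27.230, 13.91, 15.0),
        ("EVER", "clear", 57.811, 27.047, 16.78, 27.5),
        ("EPAI", "clear", 57.911, 27.191, 10.23, 30.0),
        ("EPII", "clear", 58.018, 26.791, 8.34, 20.0),
        ("ESAA", "clear", 58.554, 26.606, 11.24, 27.5),
        ("EUIA", "clear", 57.953, 26.636, 6.68, 20.0),
        ("EVII", "clear", 59.448, 26.010, 5.27, 17.5),
        ("EHEI", "humic", 58.025, 26.831, 33.28, 315.0),
        ("EHOL", "humic", 58.041, 27.198, 50.04, 520.0),
        ("EKUU", "humic", 57.957, 27.161, 47.10, 447.5),
        ("ELOO", "humic", 58.936, 25.082, 17.41, 172.5),
        ("EMAT", "humic", 59.061, 25.514, 41.63, 307.5),
        ("EMEE", "humic", 58.141, 27.385, 47.77, 517.5),
        ("EUDR", "humic", 59.370, 25.924, 34.26, 267.5),
        ("EVIR", "humic", 58.026, 27.255, 66.10, 752.5),
    ],
    columns=["lake_id", "ecotype", "longitude", "latitude", "doc", "colour"],
)

# Genome-wide scan tallies: 10,245 outliers among 810,591 SNPs.
WGS_OUTLIER_SNPS = 10_245
WGS_NONOUTLIER_SNPS = 800_346

# Outlier / non-outlier SNP counts within DEG and non-DEG expressed-gene
# windows, per tissue.
DEG_WINDOW_SNP_COUNTS = pd.DataFrame(
    [
        ("gill", 2093, 137_311, 4366, 341_128),
        ("spleen", 481, 27_404, 5164, 390_353),
        ("olfactory_rosette", 291, 23_712, 6023, 449_271),
        ("whole_eye", 190, 14_844, 6527, 488_753),
        ("liver", 66, 6821, 4962, 362_489),
    ],
    columns=["tissue", "n_out_deg", "n_non_deg", "n_out_nondeg", "n_non_nondeg"],
).set_index("tissue")

# Outlier / non-outlier counts among eSNPs per tissue (plus all tissues
# combined), tested for enrichment against the genome-wide tallies.
ESNP_COUNTS = pd.DataFrame(
    [
        ("gill", 16, 783),
        ("spleen", 21, 537),
        ("olfactory_rosette", 31, 1294),
        ("whole_eye", 7, 461),
        ("liver", 1, 154),
        ("combined", 52, 2464),
    ],
    columns=["tissue", "n_outlier_esnp", "n_nonoutlier_esnp"],
).set_index("tissue")

# Expressed genes, DEGs and their regulation direction in the humic ecotype.
DEG_DIRECTION_COUNTS = pd.DataFrame(
    [
        ("gill", 18_446, 4311, 1996, 2315),
        ("spleen", 16_685, 891, 314, 577),
        ("olfactory_rosette", 18_980, 705, 259, 446),
        ("whole_eye", 20_189, 557, 194, 363),
        ("liver", 15_020, 241, 144, 97),
    ],
    columns=["tissue", "n_expressed", "n_deg", "n_up", "n_down"],
).set_index("tissue")
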