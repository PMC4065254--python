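"""Published reference values for the B6 Min colony and the B6.SNV lines.

These constants are the study conditions the package is built around: the
closed-colony negative-binomial tumor-count parameters, the maximum-
likelihood class weights of the segregating modifier mixture, the
per-chromosome counts of line-specific candidate SNVs in the six isogenic
mapping-partner lines (B6.SNVb/c/e/f/g/h), the ENU mutation spectrum of the
13,172 line-specific variants, the Sequenom validation accounting for the
B6.SNVg marker panel, and mm9 chromosome lengths.
"""

from __future__ import annotations

__all__ = [
    "COLONY_MEAN_TUMOR_COUNT",
    "COLONY_NB_SHAPE",
    "MODIFIER_CLASS_WEIGHTS",
    "SNV_LINES",
    "RELATED_PAIR",
    "LINE_SPECIFIC_COUNTS",
    "RELATED_PAIR_SHARED_COUNTS",
    "ENU_SPECTRUM_COUNTS",
    "SPONTANEOUS_AT_TA",
    "ENU_RATE_NUMERATOR",
    "ENU_RATE_GENOME_BP",
    "VALIDATION_CATEGORY_COUNTS",
    "MM9_CHROM_SIZES",
    "mm9_chrom_sizes",
]

# Closed C57BL/6JD-Apc(Min) colony tumor multiplicity: NB(mean, shape),
# variance = mean + mean^2/shape.
COLONY_MEAN_TUMOR_COUNT = 99.8
COLONY_NB_SHAPE = 9.8

# ML estimates of the segregating three-component mixture over mutagenized
# kindreds: (unaffected, dominant suppressor, dominant enhancer).
MODIFIER_CLASS_WEIGHTS = (0.39, 0.41, 0.20)

SNV_LINES = ("b", "c", "e", "f", "g", "h")

# B6.SNVg and B6.SNVh share a first-generation parent; all other lines are
# independent lineages.
RELATED_PAIR = ("g", "h")

# Per-chromosome counts of candidate SNVs found in exactly one line.
# Column order follows SNV_LINES. Column totals: 3246, 2932, 2051, 1198,
# 1225, 2520 (grand total 13,172).
LINE_SPECIFIC_COUNTS: dict[str, tuple[int, ...]] = {
    "1": (300, 300, 89, 108, 52, 81),
    "2": (206, 232, 51, 53, 121, 78),
    "3": (244, 198, 144, 56, 47, 263),
    "4": (348, 215, 254, 174, 36, 105),
    "5": (95, 246, 110, 104, 82, 218),
    "6": (175, 108, 54, 49, 96, 56),
    "7": (187, 57, 127, 57, 46, 236),
    "8": (179, 84, 78, 46, 81, 138),
    "9": (132, 63, 108, 33, 106, 42),
    "10": (114, 216, 115, 62, 79, 127),
    "11": (159, 71, 76, 34, 75, 37),
    "12": (149, 121, 119, 43, 34, 122),
    "13": (120, 185, 57, 40, 31, 104),
    "14": (114, 103, 158, 26, 36, 221),
    "15": (92, 69, 117, 59, 29, 67),
    "16": (163, 57, 42, 35, 43, 160),
    "17": (138, 180, 85, 97, 47, 113),
    "18": (92, 111, 39, 48, 61, 136),
    "19": (54, 89, 75, 6, 36, 51),
    "X": (185, 227, 153, 68, 87, 165),
}

# Candidate SNVs found in both lines of the related pair (g, h) but in no
# other line; column total 792.
RELATED_PAIR_SHARED_COUNTS: dict[str, int] = {
    "1": 9, "2": 19, "3": 54, "4": 21, "5": 46, "6": 49, "7": 102,
    "8": 92, "9": 12, "10": 73, "11": 5, "12": 10, "13": 70, "14": 23,
    "15": 15, "16": 98, "17": 54, "18": 7, "19": 11, "X": 22,
}

# Mutational spectrum of the 13,172 line-specific candidate variants,
# counts per ordered ref>alt substitution.
ENU_SPECTRUM_COUNTS: dict[tuple[str, str], int] = {
    ("A", "G"): 2142,
    ("T", "C"): 2497,
    ("C", "T"): 1540,
    ("G", "A"): 1435,
    ("A", "C"): 516,
    ("T", "G"): 598,
    ("C", "A"): 683,
    ("G", "T"): 649,
    ("A", "T"): 1114,
    ("T", "A"): 1352,
    ("C", "G"): 332,
    ("G", "C"): 314,
}

# AT<->TA transversions among spontaneous B6 SNVs across 18 strains,
# (numerator, denominator) -- the comparison point for the ENU spectrum's
# 18.7% AT<->TA share.
SPONTANEOUS_AT_TA = (14_849_300, 164_137_670)

# Per-bp ENU mutation rate bookkeeping: ~1.3e4 candidate SNVs over six
# genomes of ~2e9 covered bp each.
ENU_RATE_NUMERATOR = 1.3e4
ENU_RATE_GENOME_BP = 6 * 2e9

# Sequenom validation accounting of the 148 assayed B6.SNVg candidate sites.
VALIDATION_CATEGORY_COUNTS: dict[str, int] = {
    "assay_failure": 8,
    "reference_divergence": 5,
    "call_error": 1,
    "residual_heterozygous": 11,
    "validated_homozygous": 123,
}

# mm9/NCBIm37 chromosome lengths (bp), 19 autosomes + X.
MM9_CHROM_SIZES: dict[str, int] = {
    "1": 197_195_432,
    "2": 181_748_087,
    "3": 159_599_783,
    "4": 155_630_120,
    "5": 152_537_259,
    "6": 149_517_037,
    "7": 152_524_553,
    "8": 131_738_871,
    "9": 124_076_172,
    "10": 129_993_255,
    "11": 121_843_856,
    "12": 121_257_530,
    "13": 120_284_312,
    "14": 125_194_864,
    "15": 103_494_974,
    "16": 98_319_150,
    "17": 95_272_651,
    "18": 90_772_031,
    "19": 61_342_430,
    "X": 166_650_296,
}


def mm9_chrom_sizes() -> "ChromSizes":
    """Default mouse chromosome sizes as a :class:`ChromSizes`."""
    from .genome import ChromSizes

    return ChromSizes(dict(MM9_CHROM_SIZES))
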