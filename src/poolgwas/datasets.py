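"""Published replication-stage genotype counts used as the worked example.

These are the genotype distributions printed for the five significant
SNP x subtype contrasts of a pooled-sample endometriosis GWAS
replication study (OMA = ovarian endometrioma cases, DIG = deep
infiltrating endometriosis with intestinal involvement, CTR =
controls).  Counts are (hom-ref, het, hom-alt) in the allele order of
the published table; the printed odds ratios and 95% confidence
intervals are reproduced from these counts by
:func:`poolgwas.assoc.allelic_or`.
"""

from __future__ import annotations

from .assoc import GenotypeCounts

__all__ = ["REPLICATION_COUNTS", "PUBLISHED_RESULTS"]

#: Genotype counts per contrast; keys are "<snp>_<subtype>".
REPLICATION_COUNTS: dict[str, GenotypeCounts] = {
    "rs227849_OMA": GenotypeCounts(
        snp_id="rs227849", case_label="OMA", control_label="CTR",
        case=(7, 27, 16), control=(39, 39, 17),
    ),
    "rs4703908_OMA": GenotypeCounts(
        snp_id="rs4703908", case_label="OMA", control_label="CTR",
        case=(24, 21, 5), control=(64, 30, 1),
    ),
    "rs2479037_OMA": GenotypeCounts(
        snp_id="rs2479037", case_label="OMA", control_label="CTR",
        case=(0, 3, 63), control=(5, 25, 160),
    ),
    "rs966674_OMA": GenotypeCounts(
        snp_id="rs966674", case_label="OMA", control_label="CTR",
        case=(50, 17, 3), control=(169, 22, 1),
    ),
    "rs4703908_DIG": GenotypeCounts(
        snp_id="rs4703908", case_label="DIG", control_label="CTR",
        case=(15, 22, 0), control=(64, 30, 1),
    ),
}

#: Published OR (95% CI) and allele percentages for the same contrasts.
#: ``p_geno`` is the printed chi-square P where it is reproducible from
#: the genotype counts (the rs2479037 printed P of 0.005 is not — no
#: standard test on its printed counts yields it — so it is omitted).
PUBLISHED_RESULTS: dict[str, dict] = {
    "rs227849_OMA": {
        "or": 2.31, "ci": (1.41, 3.78), "p_geno": 0.003,
        "ctrl_pct": (61.6, 38.4), "case_pct": (41.0, 59.0),
    },
    "rs4703908_OMA": {
        "or": 2.22, "ci": (1.26, 3.92), "p_geno": 0.009,
        "ctrl_pct": (83.2, 16.8), "case_pct": (69.0, 31.0),
    },
    "rs2479037_OMA": {
        "or": 4.36, "ci": (1.32, 14.43), "p_geno": None,
        "ctrl_pct": (9.2, 90.8), "case_pct": (2.3, 97.7),
    },
    "rs966674_OMA": {
        "or": 2.95, "ci": (1.60, 5.42), "p_geno": 0.002,
        "ctrl_pct": (93.7, 6.3), "case_pct": (83.6, 16.4),
    },
    "rs4703908_DIG": {
        "or": 2.09, "ci": (1.12, 3.91), "p_geno": 0.012,
        "ctrl_pct": (83.2, 16.8), "case_pct": (70.3, 29.7),
    },
}
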