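"""The six-SNP candidate panel and the covariable layout shared across modules.

The panel covers lipid-modulating loci near SORT1, HMGCR, MLXIPL, FADS2, APOE
and MAFB, genotyped as minor-allele counts in a pediatric cohort.  Minor allele
frequencies and per-SNP genotype missingness defaults are calibration estimates
(see docs/methods.md); they are configurable everywhere they are used.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Panel order used for all tabular output and for the covariable layout.
RSIDS = ["rs599839", "rs3846663", "rs3812316", "rs174570", "rs4420638", "rs6102059"]

GENES = {
    "rs599839": "SORT1",
    "rs3846663": "HMGCR",
    "rs3812316": "MLXIPL",
    "rs174570": "FADS2",
    "rs4420638": "APOE",
    "rs6102059": "MAFB",
}

# Calibrated from the printed per-SNP standard errors of the additive scan
# (SE ~ 1/sqrt(2 N p (1-p)) for a standardized phenotype); not literature values.
DEFAULT_MAF = {
    "rs599839": 0.26,
    "rs3846663": 0.39,
    "rs3812316": 0.12,
    "rs174570": 0.12,
    "rs4420638": 0.17,
    "rs6102059": 0.285,
}

# Per-SNP genotype missingness rates reproducing the varying complete-case
# counts of the classical scan (564-584 of 594).
DEFAULT_GENO_MISSING = {
    "rs599839": 0.030,
    "rs3846663": 0.037,
    "rs3812316": 0.051,
    "rs174570": 0.027,
    "rs4420638": 0.017,
    "rs6102059": 0.032,
}


@dataclass(frozen=True)
class SnpInfo:
    """One panel variant: rsid, nearby gene label and minor-allele frequency."""

    rsid: str
    gene_label: str
    maf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: maf must be in (0, 0.5], got {self.maf}")


def default_panel() -> list[SnpInfo]:
    return [SnpInfo(rsid, GENES[rsid], DEFAULT_MAF[rsid]) for rsid in RSIDS]


#: Covariable layout of the Bayesian selection problem: age, BMI SDS and sex,
#: then a recessive (1{genotype==0}) and dominant (1{genotype==2}) indicator
#: per SNP, in panel order.  15 columns per lipid phenotype.
COVARIABLE_LABELS = ["age", "bmi_sds", "sex"] + [
    f"{rsid}_{part}_" for rsid in RSIDS for part in ("rec", "dom")
]

GENETIC_LABELS = COVARIABLE_LABELS[3:]
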