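"""Transformations feeding both analysis tracks.

Lipid concentrations are log-transformed (natural log) and standardized to
zero mean and unit variance so effect estimates are dimensionless; age and
BMI SDS are standardized without the log.  Standardization statistics are
computed over the individuals with a non-missing value for that column, not
over complete cases, so the Bayesian module can keep every individual.

Genetic design encodings (genotype g = minor-allele count):

=================  ======================================
``additive``       g
``dominant_major`` 1{g <= 1}  (carries >= 1 major allele)
``recessive_major``1{g == 0}  (homozygous major)
``part_rec``       1{g == 0}  (recessive part indicator)
``part_dom``       1{g == 2}  (dominant part indicator)
=================  ======================================

``part_rec``/``part_dom`` together span any co-dominance pattern relative to
the heterozygote and are the covariable pair used by the Bayesian model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort_io import CohortTable
from .panel import RSIDS

GENETIC_MODELS = ("additive", "dominant_major", "recessive_major", "part_rec", "part_dom")

#: obesity cut-off: BMI SDS strictly above 1.88 (~97th percentile)
OBESITY_CUTOFF = 1.88

PHENOTYPES = ["bmi_sds", "tc", "hdl_c", "ldl_c", "tg"]
ZCOL = {"tc": "z_tc", "hdl_c": "z_hdl", "ldl_c": "z_ldl", "tg": "z_tg",
        "bmi_sds": "z_bmi_sds", "age": "z_age"}


def standardize(values, ddof: int = 1) -> np.ndarray:
    """(v - mean) / SD over non-missing entries; missing stays missing."""
    v = np.asarray(values, dtype=float)
    obs = v[np.isfinite(v)]
    if len(np.unique(obs)) < 2:
        raise ValueError("standardize: need >= 2 distinct non-missing values")
    sd = obs.std(ddof=ddof)
    if sd == 0:
        raise ValueError("standardize: constant vector has undefined SD")
    return (v - obs.mean()) / sd


def log_standardize(values, ddof: int = 1) -> np.ndarray:
    """Standardized natural log; all non-missing values must be > 0."""
    v = np.asarray(values, dtype=float)
    if np.any(np.isfinite(v) & (v <= 0)):
        raise ValueError("log_standardize: non-positive value")
    return standardize(np.log(v), ddof=ddof)


def encode_genetic_model(genotypes, model: str) -> np.ndarray:
    """Design column for one inheritance model; missing propagates as NaN."""
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}; expected one of {GENETIC_MODELS}")
    g = np.asarray(genotypes, dtype=float)
    finite = np.isfinite(g)
    if np.any(finite & ~np.isin(g, (0.0, 1.0, 2.0))):
        raise ValueError("genotypes must be in {0, 1, 2} or missing")
    out = np.full_like(g, np.nan)
    if model == "additive":
        out[finite] = g[finite]
    elif model == "dominant_major":
        out[finite] = (g[finite] <= 1).astype(float)
    elif model in ("recessive_major", "part_rec"):
        out[finite] = (g[finite] == 0).astype(float)
    else:  # part_dom
        out[finite] = (g[finite] == 2).astype(float)
    return out


def classify_obesity(bmi_sds, cutoff: float = OBESITY_CUTOFF) -> np.ndarray:
    """'obese' iff BMI SDS > cutoff (strict); missing -> None (unclassified)."""
    v = np.atleast_1d(np.asarray(bmi_sds, dtype=float))
    out = np.where(v > cutoff, "obese", "non_obese").astype(object)
    out[~np.isfinite(v)] = None
    return out


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.  Robust
    for the rare-homozygote cells of low-MAF SNPs where the chi-square
    approximation fails.

    ``n0``/``n1``/``n2`` are genotype counts (by minor-allele count; the test
    is symmetric in the labelling of the two homozygote classes).
    """
    counts = (n0, n1, n2)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n0, n1, n2 = (int(c) for c in counts)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all-zero genotype counts")
    rare = min(2 * n0 + n1, 2 * n2 + n1)  # copies of the rarer allele
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rr = (rare - hets) // 2
    n_cc = n - n_rr - hets
    logw = (gammaln(n + 1) - gammaln(n_rr + 1) - gammaln(hets + 1) - gammaln(n_cc + 1)
            + hets * np.log(2.0))
    logw -= logw.max()
    prob = np.exp(logw)
    prob /= prob.sum()
    p_obs = prob[hets == n1][0]
    # small tolerance so ties in probability are included on either side
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class HweReport:
    rsid: str
    n0: int
    n1: int
    n2: int
    p_value: float


def hwe_report(cohort: CohortTable) -> pd.DataFrame:
    """Per-SNP genotype counts and exact-test p-values for the panel."""
    rows = []
    for rsid in RSIDS:
        g = cohort.data[rsid].to_numpy(dtype=float)
        g = g[np.isfinite(g)]
        n0, n1, n2 = int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
        rows.append(HweReport(rsid, n0, n1, n2, hwe_exact_test(n0, n1, n2)))
    return pd.DataFrame([r.__dict__ for r in rows])


def make_analysis_matrix(
    cohort: CohortTable,
    ddof: int = 1,
    sex_coding: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-individual analysis matrix with standardized phenotypes/covariates.

    Columns: ``z_tc``/``z_hdl``/``z_ldl``/``z_tg`` (log-scale z-scores),
    ``z_bmi_sds``, ``z_age``, ``sex_code`` and the raw genotype columns
    (0/1/2/NaN) for on-demand encoding.  The sex coding (default male=0,
    female=1) is recorded in ``attrs`` because reported sex effects are
    sign-ambiguous without it.
    """
    sex_coding = dict(sex_coding or {"male": 0, "female": 1})
    df = cohort.data
    out = pd.DataFrame({"sample_id": df["sample_id"].to_numpy()})
    for lipid, col in (("tc", "z_tc"), ("hdl_c", "z_hdl"), ("ldl_c", "z_ldl"), ("tg", "z_tg")):
        out[col] = log_standardize(df[lipid].to_numpy(dtype=float), ddof=ddof)
    out["z_bmi_sds"] = standardize(df["bmi_sds"].to_numpy(dtype=float), ddof=ddof)
    out["z_age"] = standardize(df["age"].to_numpy(dtype=float), ddof=ddof)
    out["sex_code"] = df["sex"].map(sex_coding).to_numpy(dtype=float)
    for rsid in RSIDS:
        out[rsid] = df[rsid].to_numpy(dtype=float)
    out.attrs["sex_coding"] = sex_coding
    out.attrs["ddof"] = ddof
    return out
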