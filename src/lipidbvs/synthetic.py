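"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator emulates a mainly obese pediatric cohort: Hardy-Weinberg
genotypes at configurable MAFs, covariates matched to the study's
median/IQR summaries (age ~ scaled Beta on [5, 18]; BMI SDS a two-part
truncated-normal mixture reproducing the 122/472 non-obese/obese split),
and correlated log-normal lipids.  True effects are specified on the
standardized latent log-lipid scale (SD units) against the 15-covariable
layout, so classical and Bayesian modules see consistent truth; additive
per-allele effects are injected through the recessive/dominant indicator
decomposition (rec = -a, dom = +a).

Total cholesterol is not modelled directly: its latent z is a linear blend
of the LDL latent plus independent noise, calibrated to the target TC-LDL
log-scale correlation (0.91 by default).  Residual covariance diagonals are
set to 1 minus the variance explained by the injected effects so latent
lipids have unit total variance and injected effects are recovered without
shrinkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable
from .panel import COVARIABLE_LABELS, DEFAULT_GENO_MISSING, DEFAULT_MAF, RSIDS

TRAITS = ("hdl_c", "ldl_c", "tg")

#: lipid log-scale location/spread calibrated to the study's median (IQR):
#: TC 4.08 (0.99), HDL 1.22 (0.37), LDL 2.46 (0.89), TG 0.99 (0.70) mmol/L.
DEFAULT_LIPID_SCALE = {
    "tc": (math.log(4.08), 0.179),
    "hdl_c": (math.log(1.22), 0.224),
    "ldl_c": (math.log(2.46), 0.267),
    "tg": (math.log(0.99), 0.513),
}


def _effects_frame(entries: dict[str, dict[str, float]]) -> pd.DataFrame:
    eff = pd.DataFrame(0.0, index=list(TRAITS), columns=COVARIABLE_LABELS)
    for trait, d in entries.items():
        for lab, val in d.items():
            eff.loc[trait, lab] = val
    return eff


def additive_snp_entry(rsid: str, per_allele: float) -> dict[str, float]:
    """rec/dom indicator pair encoding an additive per-allele effect."""
    return {f"{rsid}_rec_": -per_allele, f"{rsid}_dom_": +per_allele}


def table2_effects() -> pd.DataFrame:
    """Default truth: the headline additive lipid effects plus the dominant
    covariate effects (BMI SDS on HDL and LDL, age and BMI SDS on TG)."""
    ldl = {}
    ldl.update(additive_snp_entry("rs599839", -0.30))
    ldl.update(additive_snp_entry("rs4420638", +0.382))
    ldl["bmi_sds"] = 0.146
    return _effects_frame({
        "hdl_c": {"bmi_sds": -0.21},
        "ldl_c": ldl,
        "tg": {"age": 0.172, "bmi_sds": 0.255},
    })


def table4_effects() -> pd.DataFrame:
    """Recessive-indicator truth pattern: rec effects only, +-0.35 scale."""
    return _effects_frame({
        "hdl_c": {"bmi_sds": -0.21},
        "ldl_c": {"rs599839_rec_": 0.35, "rs4420638_rec_": -0.35, "bmi_sds": 0.15},
        "tg": {"age": 0.172, "bmi_sds": 0.255},
    })


def null_effects() -> pd.DataFrame:
    return _effects_frame({})


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions."""

    n: int = 594
    mafs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MAF))
    effects: pd.DataFrame = field(default_factory=table2_effects)
    tc_loading: float = 0.91
    residual_corr: np.ndarray = field(default_factory=lambda: np.array(
        [[1.0, 0.10, -0.35], [0.10, 1.0, 0.25], [-0.35, 0.25, 1.0]]))
    lipid_scale: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LIPID_SCALE))
    age_beta: tuple[float, float] = (1.7, 1.6)
    age_range: tuple[float, float] = (5.0, 18.0)
    female_frac: float = 317 / 594
    obese_frac: float = 472 / 594
    bmi_obese: tuple[float, float] = (2.45, 0.6)      # pre-truncation loc/scale
    bmi_nonobese: tuple[float, float] = (1.1, 0.8)
    obesity_cutoff: float = 1.88
    geno_missing: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENO_MISSING))
    lipid_missing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rsid, maf in self.mafs.items():
            if not (0.0 < maf <= 0.5):
                raise ValueError(f"maf for {rsid} must be in (0, 0.5]")
        for rate in list(self.geno_missing.values()) + [self.lipid_missing]:
            if not (0.0 <= rate < 1.0):
                raise ValueError("missingness rates must be in [0, 1)")
        eff = self.effects
        if list(eff.index) != list(TRAITS) or list(eff.columns) != COVARIABLE_LABELS:
            raise ValueError("effects must be a traits x 15-covariable frame in canonical order")
        if not (0.0 <= self.tc_loading < 1.0):
            raise ValueError("tc_loading must be in [0, 1)")


def independent_null_config(**overrides) -> SyntheticConfig:
    """Null cohort with mutually independent phenotypes (identity residual
    covariance, zero TC blending, no covariate effects) for nominal-FWER
    checks against the independent-test Sidak oracle."""
    cfg = SyntheticConfig(effects=null_effects(), tc_loading=0.0,
                          residual_corr=np.eye(3), **overrides)
    return cfg


def residual_covariance(config: SyntheticConfig) -> np.ndarray:
    """Residual covariance of the latent (HDL, LDL, TG) z-scores.

    Diagonals complement the variance explained by the injected effects
    (covariables independent across SNPs; the rec/dom pair of one SNP shares
    the underlying genotype, hence covariance -p0*p2).
    """
    explained = np.zeros(3)
    f = config.female_frac
    var_cols = {"age": 1.0, "bmi_sds": 1.0, "sex": f * (1 - f)}
    for t, trait in enumerate(TRAITS):
        w = config.effects.loc[trait]
        tot = sum(w[lab] ** 2 * v for lab, v in var_cols.items())
        for rsid in RSIDS:
            p = config.mafs[rsid]
            p0, p2 = (1 - p) ** 2, p ** 2
            br, bd = w[f"{rsid}_rec_"], w[f"{rsid}_dom_"]
            tot += (br ** 2 * p0 * (1 - p0) + bd ** 2 * p2 * (1 - p2)
                    - 2 * br * bd * p0 * p2)
        explained[t] = tot
    diag = 1.0 - explained
    if np.any(diag <= 0.05):
        raise ValueError("injected effects explain nearly all variance; reduce them")
    d = np.sqrt(diag)
    return config.residual_corr * np.outer(d, d)


def injected_additive_effect(config: SyntheticConfig, phenotype: str, rsid: str) -> float:
    """True per-minor-allele effect on the standardized log scale.

    TC inherits the LDL effect through the blending loading.
    """
    if phenotype == "tc":
        return config.tc_loading * injected_additive_effect(config, "ldl_c", rsid)
    w = config.effects.loc[phenotype]
    return float((w[f"{rsid}_dom_"] - w[f"{rsid}_rec_"]) / 2.0)


def _sample_bmi_sds(config: SyntheticConfig, rng, n: int) -> np.ndarray:
    cut = config.obesity_cutoff
    obese = rng.random(n) < config.obese_frac
    out = np.empty(n)
    loc, sc = config.bmi_obese
    a = (cut - loc) / sc
    out[obese] = stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sc,
                                     size=obese.sum(), random_state=rng)
    loc, sc = config.bmi_nonobese
    b = (cut - loc) / sc
    out[~obese] = stats.truncnorm.rvs(-np.inf, b, loc=loc, scale=sc,
                                      size=(~obese).sum(), random_state=rng)
    return out


def generate_cohort(config: SyntheticConfig | None = None, seed: int | None = None) -> CohortTable:
    """Generate one cohort table; byte-identical for identical seeds."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    genotypes = {rsid: rng.binomial(2, config.mafs[rsid], size=n).astype(float)
                 for rsid in RSIDS}
    a, b = config.age_beta
    lo, hi = config.age_range
    age = lo + (hi - lo) * rng.beta(a, b, size=n)
    sex_f = rng.random(n) < config.female_frac
    bmi = _sample_bmi_sds(config, rng, n)

    # design in analysis coordinates (z-scored covariates, 0/1 sex)
    cols = {
        "age": (age - age.mean()) / age.std(ddof=1),
        "bmi_sds": (bmi - bmi.mean()) / bmi.std(ddof=1),
        "sex": sex_f.astype(float),
    }
    for rsid in RSIDS:
        g = genotypes[rsid]
        cols[f"{rsid}_rec_"] = (g == 0).astype(float)
        cols[f"{rsid}_dom_"] = (g == 2).astype(float)
    Xd = np.column_stack([cols[lab] for lab in COVARIABLE_LABELS])

    Sigma = residual_covariance(config)
    L = np.linalg.cholesky(Sigma)
    noise = rng.standard_normal((n, 3)) @ L.T
    latent = Xd @ config.effects.to_numpy().T + noise     # (n, 3): hdl, ldl, tg
    lam = config.tc_loading
    tc_z = lam * latent[:, 1] + math.sqrt(1 - lam ** 2) * rng.standard_normal(n)

    zmap = {"hdl_c": latent[:, 0], "ldl_c": latent[:, 1], "tg": latent[:, 2], "tc": tc_z}
    lipids = {}
    for lipid, (mu, sd) in config.lipid_scale.items():
        lipids[lipid] = np.exp(mu + sd * zmap[lipid])

    # missingness (genotypes become code 3 on disk; NaN in memory)
    for rsid in RSIDS:
        rate = config.geno_missing.get(rsid, 0.0)
        if rate > 0:
            genotypes[rsid][rng.random(n) < rate] = np.nan
    if config.lipid_missing > 0:
        for lipid in lipids:
            lipids[lipid][rng.random(n) < config.lipid_missing] = np.nan

    df = pd.DataFrame({"sample_id": [f"S{i + 1:04d}" for i in range(n)]})
    for rsid in RSIDS:
        df[rsid] = genotypes[rsid]
    for lipid in ("hdl_c", "ldl_c", "tc", "tg"):
        df[lipid] = lipids[lipid]
    df["age"] = age
    df["sex"] = np.where(sex_f, "female", "male")
    df["bmi_sds"] = bmi
    return CohortTable(df).validate()


def generate_null_cohort(config: SyntheticConfig | None = None,
                         seed: int | None = None) -> CohortTable:
    """As :func:`generate_cohort` with every genetic effect zeroed."""
    config = config or SyntheticConfig()
    eff = config.effects.copy()
    eff.loc[:, COVARIABLE_LABELS[3:]] = 0.0
    return generate_cohort(replace(config, effects=eff), seed=seed)
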