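"""Classical association fits and the min-p FWER engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidbvs import (SyntheticConfig, default_family, fit_association,
                      fwer_threshold, generate_cohort, make_analysis_matrix,
                      run_association_scan)
from lipidbvs.classical import _family_pvalues, _observed_pvalues
from lipidbvs.synthetic import independent_null_config


def _toy_matrix(n=8, seed=0, with_nan=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "z_ldl": rng.standard_normal(n),
        "z_age": rng.standard_normal(n),
        "sex_code": rng.integers(0, 2, n).astype(float),
        "z_bmi_sds": rng.standard_normal(n),
        "rs599839": rng.integers(0, 3, n).astype(float),
    })
    if with_nan:
        df.loc[0, "rs599839"] = np.nan
    return df


def _normal_equation_oracle(y, exog):
    """Direct (X'X)^-1 X'y with the classical variance formula."""
    xtx_inv = np.linalg.inv(exog.T @ exog)
    beta = xtx_inv @ exog.T @ y
    resid = y - exog @ beta
    df_resid = len(y) - exog.shape[1]
    s2 = resid @ resid / df_resid
    se = np.sqrt(np.diag(s2 * xtx_inv))
    return beta, se, df_resid


def test_fit_matches_normal_equation_oracle_8_rows():
    mat = _toy_matrix(n=8, seed=4)
    res = fit_association(mat, "ldl_c", "rs599839", "additive")
    y = mat["z_ldl"].to_numpy()
    exog = np.column_stack([np.ones(8), mat["rs599839"],
                            mat[["z_age", "sex_code", "z_bmi_sds"]].to_numpy()])
    beta, se, dfree = _normal_equation_oracle(y, exog)
    assert abs(res.beta - beta[1]) < 1e-10
    assert abs(res.se - se[1]) < 1e-10
    tq = stats.t.ppf(0.975, dfree)
    assert abs(res.ci_low - (beta[1] - tq * se[1])) < 1e-10


def test_fit_matches_oracle_on_random_matrices():
    """Normal-equation agreement on 100 random small design matrices."""
    for seed in range(100):
        mat = _toy_matrix(n=25, seed=seed + 10, with_nan=(seed % 3 == 0))
        res = fit_association(mat, "ldl_c", "rs599839", "additive")
        mask = np.isfinite(mat["rs599839"])
        y = mat.loc[mask, "z_ldl"].to_numpy()
        exog = np.column_stack([
            np.ones(mask.sum()), mat.loc[mask, "rs599839"],
            mat.loc[mask, ["z_age", "sex_code", "z_bmi_sds"]].to_numpy()])
        beta, se, _ = _normal_equation_oracle(y, exog)
        assert abs(res.beta - beta[1]) < 1e-10 and abs(res.se - se[1]) < 1e-10
        assert res.n == int(mask.sum())


def test_null_phenotype_rarely_exceeds_three_se():
    """Under no genetic effect, |beta| < 3 SE in nearly all seeds."""
    hits = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        n = 2000
        mat = pd.DataFrame({
            "z_ldl": rng.standard_normal(n),
            "z_age": rng.standard_normal(n),
            "sex_code": rng.integers(0, 2, n).astype(float),
            "z_bmi_sds": rng.standard_normal(n),
            "rs599839": rng.binomial(2, 0.3, n).astype(float),
        })
        res = fit_association(mat, "ldl_c", "rs599839", "additive")
        hits += abs(res.beta) < 3 * res.se
    assert hits >= 38


def test_scan_cardinality_and_order():
    cohort = generate_cohort(SyntheticConfig(n=150), seed=5)
    mat = make_analysis_matrix(cohort)
    out = run_association_scan(mat, phenotypes=("ldl_c", "tg"),
                               snps=("rs599839",), models=("additive",))
    assert len(out) == 2
    assert out["phenotype"].tolist() == ["ldl_c", "tg"]


def test_beta_invariant_to_phenotype_rescaling():
    """Scaling raw lipids (units) leaves standardized betas unchanged."""
    cohort = generate_cohort(SyntheticConfig(n=250), seed=11)
    a = make_analysis_matrix(cohort)
    scaled = cohort.data.copy()
    scaled["ldl_c"] = scaled["ldl_c"] * 38.67   # mmol/L -> mg/dL
    from lipidbvs import CohortTable
    b = make_analysis_matrix(CohortTable(scaled).validate())
    ra = fit_association(a, "ldl_c", "rs4420638", "additive")
    rb = fit_association(b, "ldl_c", "rs4420638", "additive")
    assert abs(ra.beta - rb.beta) < 1e-8 and abs(ra.p - rb.p) < 1e-8


def test_monomorphic_snp_names_degenerate_column():
    mat = _toy_matrix(n=30, seed=1)
    mat["rs599839"] = 0.0
    with pytest.raises(ValueError, match="rs599839"):
        fit_association(mat, "ldl_c", "rs599839", "additive")


def test_scan_reports_degenerate_combination_as_untestable():
    """A single-class design column yields an untestable row, not a crash."""
    mat = _toy_matrix(n=30, seed=1)
    mat["rs599839"] = np.where(np.arange(30) % 2 == 0, 0.0, 1.0)  # no g==2
    out = run_association_scan(mat, phenotypes=("ldl_c",), snps=("rs599839",),
                               models=("additive", "part_dom"))
    assert len(out) == 2
    additive = out[out["model"] == "additive"].iloc[0]
    assert additive["note"] == "" and np.isfinite(additive["beta"])
    part_dom = out[out["model"] == "part_dom"].iloc[0]
    assert part_dom["note"].startswith("untestable") and np.isnan(part_dom["beta"])


def test_permutation_engine_matches_fit_on_identity(frozen_matrix):
    """The vectorized cross-product path reproduces the OLS p-values exactly."""
    fam = default_family()
    pv = _observed_pvalues(frozen_matrix, fam)
    for i in (0, 13, 44, 61, 89):
        pheno, rsid, model = fam[i]
        ref = fit_association(frozen_matrix, pheno, rsid, model)
        assert abs(pv[i] - ref.p) < 1e-10


def test_single_test_family_gives_nominal_threshold(frozen_matrix):
    res = fwer_threshold(frozen_matrix, family=[("ldl_c", "rs599839", "additive")],
                         n_replicates=2000, seed=5)
    assert 0.035 <= res.alpha_star <= 0.05


def test_threshold_decreases_on_nested_families(frozen_matrix):
    small = default_family(phenotypes=("ldl_c",), models=("additive",))
    res_small = fwer_threshold(frozen_matrix, family=small, n_replicates=1500, seed=9)
    res_full = fwer_threshold(frozen_matrix, n_replicates=1500, seed=9)
    assert res_full.alpha_star <= res_small.alpha_star
    for res in (res_small, res_full):
        assert res.bonferroni_bound <= res.alpha_star <= res.target_fwer


def test_threshold_matches_sidak_for_independent_tests():
    """alpha* within Monte-Carlo error of the closed-form Sidak bound when
    phenotypes are mutually independent and only the additive scan is run."""
    cohort = generate_cohort(independent_null_config(), seed=21)
    mat = make_analysis_matrix(cohort)
    fam = default_family(models=("additive",))       # 30 independent tests
    res = fwer_threshold(mat, family=fam, n_replicates=4000, seed=3)
    sidak = 1 - 0.95 ** (1 / 30)
    assert abs(res.alpha_star - sidak) < 4e-4


def test_parametric_null_in_band(frozen_matrix):
    res = fwer_threshold(frozen_matrix, n_replicates=2000, seed=17, method="parametric")
    assert res.bonferroni_bound <= res.alpha_star <= res.target_fwer
    assert res.alpha_star < 5e-3


def test_seed_is_mandatory(frozen_matrix):
    with pytest.raises(ValueError, match="seed"):
        fwer_threshold(frozen_matrix, n_replicates=1000)
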