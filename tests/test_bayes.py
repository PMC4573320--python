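"""Bayesian variable selection: oracle identities, Bayes factors, sampler."""

import math

import numpy as np
import pytest

from lipidbvs import (SamplerConfig, SyntheticConfig, bayes_factor_from_probability,
                      bma_effects, build_problem, enumerate_model_posteriors,
                      generate_cohort, generate_null_cohort, inclusion_probabilities,
                      make_analysis_matrix, run_selection)
from lipidbvs.bayes import SelectionProblem, evidence_label
from lipidbvs.panel import COVARIABLE_LABELS
from lipidbvs.synthetic import null_effects


def _toy_problem(n=200, k=3, seed=5, beta=(0.7, 0.0, 0.0)):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    y = X @ np.asarray(beta)[:k] + rng.standard_normal(n)
    prob = SelectionProblem(Y=y[:, None], X=X, G=np.empty((n, 0)), y_labels=["y"],
                            x_labels=[f"x{i}" for i in range(k)], snp_cols=[],
                            cont_cols=[], binary_cols=[])
    return y, X, prob


# --- Bayes factor arithmetic -------------------------------------------------

@pytest.mark.parametrize("p,expected", [(0.9189, 371267.0), (0.0308, 1041.3), (0.5349, 37688.0)])
def test_bayes_factor_reproduces_published_rows(p, expected):
    """Posterior odds over uniform-prior odds matches the published pairs."""
    bf = bayes_factor_from_probability(p, 15)
    assert abs(bf - expected) / expected < 2e-3


def test_bayes_factor_identity_points():
    assert abs(bayes_factor_from_probability(2.0 ** -15, 15) - 1.0) < 1e-12
    assert math.isinf(bayes_factor_from_probability(1.0, 15))
    with pytest.raises(ValueError):
        bayes_factor_from_probability(0.0, 15)


def test_bayes_factor_strictly_increasing():
    ps = np.linspace(0.001, 0.999, 200)
    bfs = [bayes_factor_from_probability(p, 15) for p in ps]
    assert np.all(np.diff(bfs) > 0)


def test_evidence_scale_boundaries():
    assert evidence_label(150) == "decisive"
    assert evidence_label(50) == "strong"
    assert evidence_label(5) == "substantial"
    assert evidence_label(2) == "bare mention"
    assert evidence_label(0.5) == "counter-evidence"


# --- enumeration oracle ------------------------------------------------------

def test_enumeration_degenerate_no_covariables():
    rng = np.random.default_rng(0)
    en = enumerate_model_posteriors(rng.standard_normal(50), np.empty((50, 0)), sigma2=1.0)
    assert len(en) == 1 and abs(en["probability"].iloc[0] - 1.0) < 1e-12


def test_enumeration_strong_effect_dominates():
    rng = np.random.default_rng(2)
    n = 200
    X = np.linalg.qr(rng.standard_normal((n, 2)))[0] * math.sqrt(n)  # orthogonal cols
    y = 1.0 * X[:, 0] + 0.1 * rng.standard_normal(n)
    en = enumerate_model_posteriors(y, X, sigma2=0.01, tau=1.0)
    mass = sum(p for m, p in zip(en["members"], en["probability"]) if 0 in m)
    assert mass >= 0.999


def test_enumeration_swap_symmetry():
    rng = np.random.default_rng(3)
    n = 150
    x = rng.standard_normal(n)
    X = np.column_stack([x, x[::-1]])
    y = x + x[::-1] + rng.standard_normal(n)
    en = enumerate_model_posteriors(y, X, sigma2=1.0)
    p = {m: pr for m, pr in zip(en["members"], en["probability"])}
    assert abs(p[(0,)] - p[(1,)]) < 1e-9


def test_enumeration_matches_quadrature_on_one_instance():
    """Marginal-likelihood ratio cross-checked by adaptive 2-D quadrature."""
    from scipy import integrate, stats

    rng = np.random.default_rng(7)
    n, tau, musd, sig2 = 40, 0.8, 1.0, 1.0
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n)
    en = enumerate_model_posteriors(y, x[:, None], sigma2=sig2, tau=tau, intercept_sd=musd)
    p = {m: pr for m, pr in zip(en["members"], en["probability"])}
    off = 0.5 * (y @ y) / sig2       # common factor, cancels in the ratio

    def lik1(b, mu0):
        r = y - mu0 - b * x
        return math.exp(-0.5 * r @ r / sig2 + off) * stats.norm.pdf(mu0, 0, musd) \
            * stats.norm.pdf(b, 0, tau)

    def lik0(mu0):
        r = y - mu0
        return math.exp(-0.5 * r @ r / sig2 + off) * stats.norm.pdf(mu0, 0, musd)

    m1, _ = integrate.dblquad(lik1, -3, 3, -3, 3, epsabs=1e-12, epsrel=1e-10)
    m0, _ = integrate.quad(lik0, -3, 3, epsabs=1e-14, epsrel=1e-12)
    assert abs(math.log(m1 / m0) - math.log(p[(0,)] / p[()])) < 1e-6


# --- problem construction ----------------------------------------------------

def test_build_problem_keeps_all_individuals():
    cfg = SyntheticConfig(lipid_missing=0.03)
    cohort = generate_cohort(cfg, seed=8)
    mat = make_analysis_matrix(cohort)
    prob = build_problem(mat)
    assert prob.n == cfg.n                       # nothing dropped
    complete = np.isfinite(prob.Y).all(1) & np.isfinite(prob.X).all(1)
    assert complete.sum() < cfg.n                # complete-case would lose rows
    assert prob.x_labels == COVARIABLE_LABELS


def test_build_problem_requires_trait_columns():
    cohort = generate_cohort(SyntheticConfig(n=80), seed=1)
    mat = make_analysis_matrix(cohort).drop(columns=["z_tg"])
    with pytest.raises(ValueError, match="tg"):
        build_problem(mat)


def test_indicator_columns_back_genotypes():
    cohort = generate_cohort(SyntheticConfig(n=120), seed=4)
    mat = make_analysis_matrix(cohort)
    prob = build_problem(mat)
    g = prob.G[:, 0]
    rec, dom = prob.X[:, 3], prob.X[:, 4]
    fin = np.isfinite(g)
    assert np.array_equal(rec[fin], (g[fin] == 0).astype(float))
    assert np.array_equal(dom[fin], (g[fin] == 2).astype(float))
    assert not np.any((rec == 1) & (dom == 1))


# --- sampler behaviour -------------------------------------------------------

def test_model_probabilities_and_inclusion_identities():
    """Visit frequencies sum to 1 and inclusion == sum of containing models."""
    _, _, prob = _toy_problem(seed=12)
    cfg = SamplerConfig(n_iterations=4000, n_burnin=500, thin=1, n_chains=2, seed=2,
                        fixed_sigma=np.array([[1.0]]))
    s = run_selection(prob, cfg)
    mt = s.model_table("y")
    assert abs(mt["probability"].sum() - 100.0) < 1e-9
    incl = s.inclusion_matrix()
    for k, lab in enumerate(s.x_labels):
        containing = mt[mt["model"].str.split(", ").apply(lambda m: lab in m)]
        assert abs(containing["probability"].sum() / 100 - incl.loc["y", lab]) < 1e-12


def test_sampler_tracks_enumeration_inclusions():
    y, X, prob = _toy_problem(n=150, seed=20, beta=(0.5, 0.3, 0.0))
    cfg = SamplerConfig(n_iterations=20000, n_burnin=2000, thin=1, n_chains=2, seed=6,
                        fixed_sigma=np.array([[1.0]]), tau=0.7, standardize_slab=False)
    s = run_selection(prob, cfg)
    en = enumerate_model_posteriors(y, X, sigma2=1.0, tau=0.7)
    incl = s.inclusion_matrix()
    for k in range(3):
        oracle = sum(p for m, p in zip(en["members"], en["probability"]) if k in m)
        assert abs(incl.loc["y", f"x{k}"] - oracle) < 0.03


def test_bma_single_model_equals_conditional_mean():
    """A covariable included in (essentially) one model averages to that
    model's conditional posterior mean."""
    rng = np.random.default_rng(31)
    n = 300
    X = rng.standard_normal((n, 2))
    y = 1.2 * X[:, 0] + 0.05 * rng.standard_normal(n)
    prob = SelectionProblem(Y=y[:, None], X=X, G=np.empty((n, 0)), y_labels=["y"],
                            x_labels=["a", "b"], snp_cols=[], cont_cols=[], binary_cols=[])
    cfg = SamplerConfig(n_iterations=8000, n_burnin=1000, thin=1, n_chains=2, seed=3,
                        fixed_sigma=np.array([[0.0025]]), tau=1.0, standardize_slab=False)
    s = run_selection(prob, cfg)
    en = enumerate_model_posteriors(y, X, sigma2=0.0025, tau=1.0)
    top = en.iloc[0]
    eff = bma_effects(s)
    got = eff[(eff["covariable"] == "a")]["estimate"].iloc[0]
    assert abs(got - top["cond_means"][0]) < 0.02


def test_null_cohort_prior_dominated():
    """With all effects zero, inclusion stays near the prior-dominated level
    and is stable when the chain length doubles.

    Under the default slab the analytic null inclusion per covariable is
    ~0.10-0.15 with occasional chance flukes (|t| ~ 2.5 gives inclusion
    ~0.6, expected under once per 36 covariable-trait pairs), so the bounds
    are a mean below 0.25 and at most 3 of 36 genetic inclusions above 0.5.
    """
    import warnings

    cfg = SyntheticConfig(n=600, effects=null_effects(), geno_missing={})
    cohort = generate_cohort(cfg, seed=40)
    prob = build_problem(make_analysis_matrix(cohort))
    base = SamplerConfig(n_iterations=4000, n_burnin=800, thin=1, n_chains=2, seed=5)
    double = SamplerConfig(n_iterations=8000, n_burnin=800, thin=1, n_chains=2, seed=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s1 = run_selection(prob, base)
        s2 = run_selection(prob, double)
    i1, i2 = s1.inclusion_matrix().to_numpy(), s2.inclusion_matrix().to_numpy()
    assert np.max(np.abs(i1 - i2)) < 0.08
    genetic = s1.inclusion_matrix().loc[:, s1.x_labels[3:]].to_numpy()
    assert genetic.mean() < 0.25
    assert (genetic < 0.5).sum() >= genetic.size - 3


def test_snp_label_swap_leaves_summaries_equivalent():
    """Exchanging two null SNPs' columns relabels but does not change results."""
    cfg = SyntheticConfig(n=400, effects=null_effects(), geno_missing={})
    cohort = generate_cohort(cfg, seed=50)
    prob = build_problem(make_analysis_matrix(cohort))
    swapped = SelectionProblem(
        Y=prob.Y, X=prob.X.copy(), G=prob.G.copy(), y_labels=prob.y_labels,
        x_labels=prob.x_labels, snp_cols=prob.snp_cols, cont_cols=prob.cont_cols,
        binary_cols=prob.binary_cols)
    # swap rs174570 (cols 9,10; G col 3) with rs3812316 (cols 7,8; G col 2) - both MAF 0.12
    swapped.X[:, [7, 8, 9, 10]] = swapped.X[:, [9, 10, 7, 8]]
    swapped.G[:, [2, 3]] = swapped.G[:, [3, 2]]
    cfg_s = SamplerConfig(n_iterations=4000, n_burnin=1000, thin=1, n_chains=2, seed=77)
    a = run_selection(prob, cfg_s).inclusion_matrix()
    b = run_selection(swapped, cfg_s).inclusion_matrix()
    for trait in a.index:
        assert abs(a.loc[trait, "rs3812316_rec_"] - b.loc[trait, "rs174570_rec_"]) < 0.08
        assert abs(a.loc[trait, "rs174570_dom_"] - b.loc[trait, "rs3812316_dom_"]) < 0.08


def test_missing_data_chain_runs_and_flags_convergence():
    cfg = SyntheticConfig(n=200, lipid_missing=0.05)
    cohort = generate_cohort(cfg, seed=13)
    prob = build_problem(make_analysis_matrix(cohort))
    scfg = SamplerConfig(n_iterations=1200, n_burnin=300, thin=2, n_chains=2, seed=1)
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s = run_selection(prob, scfg)
    assert np.isfinite(s.inclusion_matrix().to_numpy()).all()
    ip = inclusion_probabilities(s)
    assert set(ip.columns) >= {"trait", "covariable", "probability", "inclusion_bf"}
    assert ((ip["probability"] >= 0) & (ip["probability"] <= 1)).all()


def test_seed_required_and_determinism():
    _, _, prob = _toy_problem(seed=2)
    with pytest.raises(ValueError, match="seed"):
        run_selection(prob, SamplerConfig(n_iterations=200, n_burnin=50, seed=None))
    cfg = SamplerConfig(n_iterations=600, n_burnin=100, thin=1, n_chains=1, seed=11,
                        fixed_sigma=np.array([[1.0]]))
    a = run_selection(prob, cfg)
    b = run_selection(prob, cfg)
    assert np.array_equal(a.gamma, b.gamma) and np.allclose(a.effects, b.effects)
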