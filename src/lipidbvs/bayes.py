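"""Multivariate Bayesian variable selection for the joint lipid phenotype.

Model
-----
For individual i with covariable vector x_i (15 entries: age, BMI SDS, sex
and a recessive/dominant indicator pair per SNP) and lipid vector
y_i = (z_HDL, z_LDL, z_TG):

    y_i ~ MVN( mu0 + (gamma * B) x_i , Sigma )

where gamma is a 3x15 binary inclusion matrix, B a 3x15 effect matrix in SD
units, and Sigma the 3x3 residual covariance linking the traits.  Priors:
independent Bernoulli(1/2) on each gamma entry (uniform over the 2^15 models
per trait), B_jk ~ N(0, tau^2), mu0_j ~ N(0, intercept_sd^2), Sigma
inverse-Wishart.  Missing lipids are imputed from the MVN conditional inside
the chain; missing genotypes from Hardy-Weinberg at the running allele
frequency (the two indicator parts of one SNP are a single underlying
trinomial genotype, so "both parts = 1" can never be imputed); missing
continuous covariates from the observed mean/variance.

Sampling
--------
Each gamma entry is updated by a collapsed Gibbs step: conditional on Sigma
and the other traits' residuals, trait j is a univariate normal regression
with known noise variance, so the effect can be integrated out analytically
and the inclusion indicator drawn from its exact conditional odds.  Included
effects and intercepts get conjugate normal draws, Sigma an inverse-Wishart
draw.  Posterior model probabilities are visit frequencies of covariable
subsets after burn-in across chains.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import COVARIABLE_LABELS, RSIDS

logger = logging.getLogger(__name__)

DEFAULT_TRAITS = ("hdl_c", "ldl_c", "tg")
_TRAIT_ZCOL = {"hdl_c": "z_hdl", "ldl_c": "z_ldl", "tg": "z_tg", "tc": "z_tc"}


# ---------------------------------------------------------------------------
# problem construction


@dataclass
class SelectionProblem:
    """Response matrix, covariable matrix and the genotype backing the
    indicator pairs; all individuals retained regardless of missingness."""

    Y: np.ndarray                 # (n, m) standardized responses, NaN = missing
    X: np.ndarray                 # (n, K) covariables, NaN = missing
    G: np.ndarray                 # (n, n_snps) genotypes backing the indicators
    y_labels: list[str]
    x_labels: list[str]
    snp_cols: list[tuple[int, int]]   # (rec, dom) column index pairs into X
    cont_cols: list[int]              # continuous covariable columns
    binary_cols: list[int]            # 0/1 covariable columns not SNP-backed

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]

    @property
    def n_covariables(self) -> int:
        return self.X.shape[1]


def build_problem(matrix: pd.DataFrame, traits=DEFAULT_TRAITS) -> SelectionProblem:
    """Selection problem from an analysis matrix.

    Y holds the standardized log lipids for ``traits`` (TC is excluded by
    default because of its near-collinearity with LDL-C); X holds the 15
    covariables in the documented fixed order.  No rows are dropped.
    """
    for t in traits:
        if t not in _TRAIT_ZCOL or _TRAIT_ZCOL[t] not in matrix.columns:
            raise ValueError(f"matrix lacks standardized column for trait {t!r}")
    Y = np.column_stack([matrix[_TRAIT_ZCOL[t]].to_numpy(dtype=float) for t in traits])
    cols: dict[str, np.ndarray] = {
        "age": matrix["z_age"].to_numpy(dtype=float),
        "bmi_sds": matrix["z_bmi_sds"].to_numpy(dtype=float),
        "sex": matrix["sex_code"].to_numpy(dtype=float),
    }
    G = np.column_stack([matrix[r].to_numpy(dtype=float) for r in RSIDS])
    snp_cols = []
    for s, rsid in enumerate(RSIDS):
        g = G[:, s]
        rec = np.where(np.isfinite(g), (g == 0).astype(float), np.nan)
        dom = np.where(np.isfinite(g), (g == 2).astype(float), np.nan)
        cols[f"{rsid}_rec_"] = rec
        cols[f"{rsid}_dom_"] = dom
    X = np.column_stack([cols[lab] for lab in COVARIABLE_LABELS])
    for k, lab in enumerate(COVARIABLE_LABELS):
        if not np.isfinite(X[:, k]).any():
            raise ValueError(f"covariable {lab!r} is entirely missing")
    snp_cols = [(COVARIABLE_LABELS.index(f"{r}_rec_"), COVARIABLE_LABELS.index(f"{r}_dom_"))
                for r in RSIDS]
    return SelectionProblem(
        Y=Y, X=X, G=G, y_labels=list(traits), x_labels=list(COVARIABLE_LABELS),
        snp_cols=snp_cols, cont_cols=[0, 1], binary_cols=[2],
    )


# ---------------------------------------------------------------------------
# configuration and summaries


@dataclass
class SamplerConfig:
    """MCMC settings and prior constants.

    ``tau`` is the prior SD of an included effect expressed per standard
    deviation of its covariable: with ``standardize_slab`` (default) the slab
    on covariable k is N(0, (tau / SD(x_k))^2), so indicator covariables and
    z-scored covariates carry evidence on the same scale and the model is
    invariant to linear rescaling of any covariable.  Model posteriors are
    prior-sensitive through tau (Lindley/Bartlett), so it is reported in
    output headers.  ``sigma_df``/``sigma_scale`` parameterize the
    inverse-Wishart prior on the residual covariance (defaults: m+1 degrees
    of freedom, identity scale); ``fixed_sigma`` freezes Sigma instead,
    which is what the enumeration oracle needs.
    """

    n_iterations: int = 60_000
    n_burnin: int = 10_000
    thin: int = 5
    n_chains: int = 3
    seed: int | None = None
    tau: float = 0.5
    standardize_slab: bool = True
    intercept_sd: float = 10.0
    sigma_df: int | None = None
    sigma_scale: np.ndarray | None = None
    fixed_sigma: np.ndarray | None = None
    convergence_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.n_iterations <= self.n_burnin:
            raise ValueError("n_iterations must exceed n_burnin")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


@dataclass
class PosteriorSummary:
    """Post burn-in draws plus derived tables (models, inclusions, BMA)."""

    traits: list[str]
    x_labels: list[str]
    gamma: np.ndarray             # (D, m, K) bool
    effects: np.ndarray           # (D, m, K) float, meaningful where gamma
    chain: np.ndarray             # (D,) chain index
    sigma_mean: np.ndarray
    converged: bool
    chain_inclusion: np.ndarray   # (C, m, K)
    tau: float

    @property
    def n_draws(self) -> int:
        return self.gamma.shape[0]

    def inclusion_matrix(self) -> pd.DataFrame:
        """P(gamma_jk = 1 | data) as traits x covariables DataFrame."""
        return pd.DataFrame(self.gamma.mean(axis=0), index=self.traits,
                            columns=self.x_labels)

    def model_table(self, trait: str) -> pd.DataFrame:
        """Sampled models for one trait: label, probability (%) and Bayes factor.

        Probabilities are visit frequencies and sum to 100% exactly; the BF
        follows from each probability under the uniform model prior.
        """
        j = self.traits.index(trait)
        K = len(self.x_labels)
        weights = 1 << np.arange(K, dtype=np.int64)
        codes = self.gamma[:, j, :] @ weights
        uniq, counts = np.unique(codes, return_counts=True)
        probs = counts / counts.sum()
        labels = []
        for code in uniq:
            members = [self.x_labels[k] for k in range(K) if (int(code) >> k) & 1]
            labels.append(", ".join(members) if members else "null")
        bf = [bayes_factor_from_probability(p, K) if p < 1.0 else math.inf for p in probs]
        df = pd.DataFrame({"model": labels, "probability": probs * 100.0, "bayes_factor": bf})
        df = df.sort_values(["probability", "model"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
        return df


def run_selection(problem: SelectionProblem, config: SamplerConfig) -> PosteriorSummary:
    """Run the indicator Gibbs sampler; deterministic given ``config.seed``.

    Flags (but still returns) a non-converged result when any covariable's
    inclusion probability differs by more than ``convergence_tol`` across
    chains.
    """
    if config.seed is None:
        raise ValueError("SamplerConfig.seed is mandatory for reproducibility")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chains)
    gammas, betas, chains = [], [], []
    sigma_acc = np.zeros((problem.n_traits, problem.n_traits))
    for c, child in enumerate(children):
        g_draws, b_draws, sig_mean = _run_chain(problem, config, np.random.default_rng(child))
        gammas.append(g_draws)
        betas.append(b_draws)
        chains.append(np.full(len(g_draws), c))
        sigma_acc += sig_mean
    gamma = np.concatenate(gammas)
    effects = np.concatenate(betas)
    chain = np.concatenate(chains)
    chain_incl = np.stack([g.mean(axis=0) for g in gammas])
    spread = chain_incl.max(axis=0) - chain_incl.min(axis=0)
    converged = bool(spread.max() <= config.convergence_tol) if config.n_chains > 1 else True
    if not converged:
        warnings.warn(
            "cross-chain inclusion probabilities differ by "
            f"{spread.max():.3f} > {config.convergence_tol}; increase n_iterations",
            RuntimeWarning, stacklevel=2,
        )
    return PosteriorSummary(
        traits=list(problem.y_labels), x_labels=list(problem.x_labels),
        gamma=gamma, effects=effects, chain=chain,
        sigma_mean=sigma_acc / config.n_chains, converged=converged,
        chain_inclusion=chain_incl, tau=config.tau,
    )


def _run_chain(problem: SelectionProblem, config: SamplerConfig, rng) -> tuple:
    Y = problem.Y.copy()
    X = problem.X.copy()
    G = problem.G.copy()
    n, m = Y.shape
    K = X.shape[1]
    if config.standardize_slab:
        sd_k = np.nanstd(problem.X, axis=0)
        if np.any(sd_k <= 0):
            bad = problem.x_labels[int(np.argmin(sd_k))]
            raise ValueError(f"constant covariable {bad!r}: slab scale undefined")
        tau2 = (config.tau / sd_k) ** 2          # per-covariable slab variance
    else:
        tau2 = np.full(K, config.tau ** 2)
    mu_var = config.intercept_sd ** 2

    ymis = ~np.isfinite(Y)
    gmis = ~np.isfinite(G)
    miss_snps = [s for s in range(G.shape[1]) if gmis[:, s].any()]
    cont_mis = {k: ~np.isfinite(problem.X[:, k]) for k in problem.cont_cols
                if (~np.isfinite(problem.X[:, k])).any()}
    bin_mis = {k: ~np.isfinite(problem.X[:, k]) for k in problem.binary_cols
               if (~np.isfinite(problem.X[:, k])).any()}
    cont_stats = {k: (np.nanmean(problem.X[:, k]), max(np.nanstd(problem.X[:, k]), 1e-12))
                  for k in cont_mis}
    bin_freq = {k: np.nanmean(problem.X[:, k]) for k in bin_mis}

    # initial imputations
    for s in miss_snps:
        p_hat = np.clip(np.nanmean(G[:, s]) / 2.0, 1e-3, 1 - 1e-3)
        probs = [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat ** 2]
        G[gmis[:, s], s] = rng.choice(3, size=gmis[:, s].sum(), p=probs)
        rec_k, dom_k = problem.snp_cols[s]
        X[:, rec_k] = (G[:, s] == 0).astype(float)
        X[:, dom_k] = (G[:, s] == 2).astype(float)
    for k, mask in cont_mis.items():
        mu, sd = cont_stats[k]
        X[mask, k] = rng.normal(mu, sd, size=mask.sum())
    for k, mask in bin_mis.items():
        X[mask, k] = (rng.random(mask.sum()) < bin_freq[k]).astype(float)
    Y[ymis] = 0.0

    gamma = rng.random((m, K)) < 0.5
    B = np.zeros((m, K))
    mu0 = np.zeros(m)
    if config.fixed_sigma is not None:
        Sigma = np.array(config.fixed_sigma, dtype=float).reshape(m, m)
    else:
        Sigma = np.eye(m)
    df0 = config.sigma_df if config.sigma_df is not None else m + 1
    S0 = (np.array(config.sigma_scale, dtype=float)
          if config.sigma_scale is not None else np.eye(m))

    n_rec = (config.n_iterations - config.n_burnin) // config.thin
    g_draws = np.empty((n_rec, m, K), dtype=bool)
    b_draws = np.zeros((n_rec, m, K))
    sig_sum = np.zeros((m, m))
    rec = 0

    W = gamma * B
    M = mu0 + X @ W.T
    E = Y - M
    Gram = X.T @ X
    colsum = X.sum(axis=0)
    has_impute = bool(miss_snps or cont_mis or bin_mis or ymis.any())

    for it in range(config.n_iterations):
        # ---- imputation ----------------------------------------------------
        if has_impute:
            W = gamma * B
            if miss_snps or cont_mis or bin_mis:
                for s in miss_snps:
                    p_hat = np.clip(G[:, s].mean() / 2.0, 1e-3, 1 - 1e-3)
                    probs = np.array([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat ** 2])
                    rows = np.flatnonzero(gmis[:, s])
                    draws = rng.choice(3, size=len(rows), p=probs)
                    G[rows, s] = draws
                    rec_k, dom_k = problem.snp_cols[s]
                    X[rows, rec_k] = (draws == 0).astype(float)
                    X[rows, dom_k] = (draws == 2).astype(float)
                for k, mask in cont_mis.items():
                    mu, sd = cont_stats[k]
                    X[mask, k] = rng.normal(mu, sd, size=mask.sum())
                for k, mask in bin_mis.items():
                    X[mask, k] = (rng.random(mask.sum()) < bin_freq[k]).astype(float)
                Gram = X.T @ X
                colsum = X.sum(axis=0)
            M = mu0 + X @ W.T
            if ymis.any():
                rows = np.flatnonzero(ymis.any(axis=1))
                for i in rows:
                    mis = ymis[i]
                    obs = ~mis
                    if obs.any():
                        So = Sigma[np.ix_(obs, obs)]
                        Smo = Sigma[np.ix_(mis, obs)]
                        cond_mu = M[i, mis] + Smo @ np.linalg.solve(So, Y[i, obs] - M[i, obs])
                        cond_S = (Sigma[np.ix_(mis, mis)]
                                  - Smo @ np.linalg.solve(So, Smo.T))
                    else:
                        cond_mu = M[i, mis]
                        cond_S = Sigma[np.ix_(mis, mis)]
                    Y[i, mis] = rng.multivariate_normal(cond_mu, cond_S)
            E = Y - M

        # ---- gamma / B / mu0 sweep ----------------------------------------
        Lam = np.linalg.inv(Sigma)
        for j in range(m):
            s2 = 1.0 / Lam[j, j]
            # conditional-residual offset from the other traits (fixed in sweep)
            offset = s2 * (E @ Lam[:, j]) - E[:, j]
            Ej = E[:, j]
            v = X.T @ Ej                      # running x_k . E_j
            xoff = X.T @ offset
            ssum = Ej.sum()
            osum = offset.sum()
            for k in range(K):
                old = B[j, k] if gamma[j, k] else 0.0
                sxr = v[k] + xoff[k] + old * Gram[k, k]
                a = Gram[k, k] / s2 + 1.0 / tau2[k]
                b = sxr / s2
                log_bf = -0.5 * math.log(tau2[k] * a) + 0.5 * b * b / a
                log_bf = min(max(log_bf, -700.0), 700.0)
                p_inc = 1.0 / (1.0 + math.exp(-log_bf))
                if rng.random() < p_inc:
                    gamma[j, k] = True
                    B[j, k] = rng.normal(b / a, math.sqrt(1.0 / a))
                else:
                    gamma[j, k] = False
                    B[j, k] = 0.0
                new = B[j, k]
                if new != old:
                    delta = old - new       # E_j += delta * x_k
                    v += delta * Gram[:, k]
                    ssum += delta * colsum[k]
            # intercept (always included, N(0, mu_var) prior)
            a = n / s2 + 1.0 / mu_var
            b = (ssum + osum + mu0[j] * n) / s2
            new_mu = rng.normal(b / a, math.sqrt(1.0 / a))
            mu0[j] = new_mu
            # reconstruct E_j exactly (kills bookkeeping drift)
            E[:, j] = Y[:, j] - mu0[j] - X @ (gamma[j] * B[j])

        # ---- Sigma ---------------------------------------------------------
        if config.fixed_sigma is None:
            S = S0 + E.T @ E
            Sigma = stats.invwishart.rvs(df=df0 + n, scale=S, random_state=rng)
            Sigma = np.atleast_2d(Sigma)

        # ---- record --------------------------------------------------------
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0 and rec < n_rec:
            g_draws[rec] = gamma
            b_draws[rec] = B
            sig_sum += Sigma
            rec += 1

    return g_draws[:rec], b_draws[:rec], sig_sum / max(rec, 1)


# ---------------------------------------------------------------------------
# derived quantities


def bayes_factor_from_probability(p_m: float, k: int) -> float:
    """Model Bayes factor from a posterior model probability.

    Posterior odds p/(1-p) divided by the prior odds of one model under the
    uniform prior over the 2^k covariable subsets.  p_m == 1 overflows to inf.
    """
    if not (0.0 < p_m <= 1.0):
        raise ValueError("p_m must be in (0, 1]")
    if p_m == 1.0:
        return math.inf
    n_models = 2 ** k
    prior_odds = 1.0 / (n_models - 1)
    return (p_m / (1.0 - p_m)) / prior_odds


def evidence_label(bf: float) -> str:
    """Jeffreys-style verbal scale for a Bayes factor."""
    if bf > 100:
        return "decisive"
    if bf > 10:
        return "strong"
    if bf > 3.2:
        return "substantial"
    if bf >= 1:
        return "bare mention"
    return "counter-evidence"


def inclusion_probabilities(summary: PosteriorSummary) -> pd.DataFrame:
    """Per trait x covariable: inclusion probability, inclusion BF, evidence.

    The inclusion Bayes factor is p/(1-p) because the prior inclusion odds
    are 1 under the Bernoulli(1/2) prior.
    """
    incl = summary.inclusion_matrix()
    rows = []
    for trait in summary.traits:
        for lab in summary.x_labels:
            p = float(incl.loc[trait, lab])
            bf = math.inf if p == 1.0 else p / (1.0 - p)
            rows.append({"trait": trait, "covariable": lab, "probability": p,
                         "inclusion_bf": bf, "evidence": evidence_label(bf)})
    return pd.DataFrame(rows)


def bma_effects(summary: PosteriorSummary, floor: float = 0.005) -> pd.DataFrame:
    """Model-averaged effect and SD over the draws that include the covariable.

    Covariables with inclusion probability <= ``floor`` (reporting floor
    0.5%) are omitted; a covariable never included has no estimate at all.
    """
    incl = summary.inclusion_matrix()
    rows = []
    for j, trait in enumerate(summary.traits):
        for k, lab in enumerate(summary.x_labels):
            p = float(incl.loc[trait, lab])
            if p <= floor:
                continue
            sel = summary.gamma[:, j, k]
            draws = summary.effects[sel, j, k]
            if len(draws) == 0:
                continue
            sd = float(draws.std(ddof=1)) if len(draws) > 1 else float("nan")
            rows.append({"trait": trait, "covariable": lab, "probability": p,
                         "estimate": float(draws.mean()), "sd": sd,
                         "n_draws": int(len(draws))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact enumeration oracle (small single-trait problems)


def enumerate_model_posteriors(
    y: np.ndarray,
    X: np.ndarray,
    sigma2: float,
    tau: float | np.ndarray = 1.0,
    intercept_sd: float = 10.0,
) -> pd.DataFrame:
    """Exact model posteriors for a single-trait, known-variance problem.

    For each of the 2^k covariable subsets the marginal likelihood is the
    closed-form MVN density y ~ N(0, sigma2 I + intercept_sd^2 J +
    X_S diag(tau_S^2) X_S'); posteriors are normalized under the uniform
    model prior.  ``tau`` may be a scalar or a per-covariable vector of slab
    SDs.  Also returns each subset's conditional posterior effect means, so
    BMA identities can be checked exactly.  Refuses k > 10.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k > 10:
        raise ValueError("enumeration refused for k > 10 covariables")
    tau_vec = np.broadcast_to(np.asarray(tau, dtype=float), (k,))
    base = sigma2 * np.eye(n) + intercept_sd ** 2 * np.ones((n, n))
    rows = []
    for code in range(2 ** k):
        members = [c for c in range(k) if (code >> c) & 1]
        Xs = X[:, members]
        cov = base + (Xs * tau_vec[members] ** 2) @ Xs.T
        chol = np.linalg.cholesky(cov)
        alpha = np.linalg.solve(chol, y)
        loglik = -0.5 * (alpha @ alpha) - np.log(np.diag(chol)).sum() - 0.5 * n * math.log(2 * math.pi)
        # conditional posterior mean of [mu0, b_S]
        D = np.column_stack([np.ones(n), Xs])
        prior_prec = np.diag([1.0 / intercept_sd ** 2]
                             + [1.0 / tau_vec[c] ** 2 for c in members])
        post_prec = D.T @ D / sigma2 + prior_prec
        mean = np.linalg.solve(post_prec, D.T @ y / sigma2)
        cond = dict(zip(members, mean[1:]))
        rows.append({"code": code, "members": tuple(members), "loglik": loglik,
                     "cond_means": cond})
    df = pd.DataFrame(rows)
    w = np.exp(df["loglik"] - df["loglik"].max())
    df["probability"] = w / w.sum()
    return df.sort_values("probability", ascending=False).reset_index(drop=True)
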