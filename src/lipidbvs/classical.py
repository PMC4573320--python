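"""Per-SNP linear association and the simulated-null family-wise threshold.

Each test regresses a standardized phenotype on one genetic design column
plus adjustments (age and sex for BMI SDS as outcome; age, sex and BMI SDS
for lipids), on the complete cases of that combination.  The multiplicity
threshold is the empirical 5%-quantile of the minimum p-value over the test
family under a joint permutation of the genotype rows (a Westfall-Young
min-p scheme): all six SNP columns move together, so the phenotype
correlation structure and covariate-phenotype relationships are preserved
while every SNP effect is destroyed.  A parametric multivariate-normal null
is available behind ``method="parametric"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import RSIDS
from .preprocess import ZCOL, encode_genetic_model

SCAN_MODELS = ("additive", "dominant_major", "recessive_major")
LIPID_PHENOS = ("tc", "hdl_c", "ldl_c", "tg")


def default_adjustments(phenotype: str) -> list[str]:
    """Age+sex for BMI SDS as outcome; age+sex+BMI SDS for lipids."""
    if phenotype == "bmi_sds":
        return ["z_age", "sex_code"]
    return ["z_age", "sex_code", "z_bmi_sds"]


@dataclass
class AssocResult:
    """One classical test: N, beta (SD units), SE, 95% CI and p-value."""

    phenotype: str
    rsid: str
    model: str
    n: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if not (self.ci_low < self.beta < self.ci_high):
            raise ValueError("CI must bracket beta")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p-value outside (0, 1]")


def fit_association(
    matrix: pd.DataFrame,
    phenotype: str,
    rsid: str,
    model: str = "additive",
    adjustments: list[str] | None = None,
) -> AssocResult:
    """OLS of the standardized phenotype on one genetic design column.

    Complete cases for this combination only; CI from the t quantile at the
    residual degrees of freedom.  Rank-deficient designs (e.g. a monomorphic
    SNP) raise with the degenerate column named.
    """
    if adjustments is None:
        adjustments = default_adjustments(phenotype)
    ycol = ZCOL[phenotype]
    y = matrix[ycol].to_numpy(dtype=float)
    x = encode_genetic_model(matrix[rsid].to_numpy(dtype=float), model)
    C = matrix[list(adjustments)].to_numpy(dtype=float)
    mask = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(C), axis=1)
    n = int(mask.sum())
    k = C.shape[1] + 2
    if n < k:
        raise ValueError(f"too few complete cases ({n}) for {phenotype} x {rsid} x {model}")
    exog = np.column_stack([np.ones(n), x[mask], C[mask]])
    names = ["const", f"{rsid}[{model}]"] + list(adjustments)
    sds = exog.std(axis=0)
    if np.any(sds[1:] == 0):
        bad = names[1:][int(np.argmin(sds[1:]))]
        raise ValueError(f"degenerate (constant) design column: {bad}")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError(f"rank-deficient design for {phenotype} x {rsid} x {model}")
    fit = sm.OLS(y[mask], exog).fit()
    beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    tq = stats.t.ppf(0.975, fit.df_resid)
    return AssocResult(phenotype, rsid, model, n, float(beta), float(se),
                       float(beta - tq * se), float(beta + tq * se), float(p))


def run_association_scan(
    matrix: pd.DataFrame,
    phenotypes: tuple[str, ...] = ("bmi_sds",) + LIPID_PHENOS,
    snps: tuple[str, ...] = tuple(RSIDS),
    models: tuple[str, ...] = SCAN_MODELS,
) -> pd.DataFrame:
    """One row per phenotype x SNP x model, in deterministic order.

    Degenerate combinations (monomorphic or single-class design columns) are
    reported as untestable rows (NaN statistics, reason in ``note``) rather
    than silently dropped; any other fit error propagates, tagged with the
    combination.
    """
    rows = []
    for phenotype in phenotypes:
        for rsid in snps:
            for model in models:
                try:
                    res = fit_association(matrix, phenotype, rsid, model)
                except ValueError as exc:
                    msg = str(exc)
                    if "degenerate" in msg or "rank-deficient" in msg:
                        rows.append({"phenotype": phenotype, "rsid": rsid,
                                     "model": model, "n": 0, "beta": np.nan,
                                     "se": np.nan, "ci_low": np.nan,
                                     "ci_high": np.nan, "p": np.nan,
                                     "note": f"untestable: {msg}"})
                        continue
                    raise ValueError(f"{phenotype} x {rsid} x {model}: {exc}") from exc
                rows.append({**res.__dict__, "note": ""})
    return pd.DataFrame(rows)


@dataclass
class FwerResult:
    """Simulated per-test significance threshold controlling the FWER."""

    alpha_star: float
    target_fwer: float
    n_replicates: int
    n_tests: int
    method: str
    family: list = field(repr=False, default_factory=list)
    min_p: np.ndarray | None = field(repr=False, default=None)

    @property
    def bonferroni_bound(self) -> float:
        return self.target_fwer / self.n_tests

    def __post_init__(self) -> None:
        lo = self.bonferroni_bound
        if not (lo <= self.alpha_star <= self.target_fwer):
            raise ValueError(
                f"alpha_star {self.alpha_star:g} outside [{lo:g}, {self.target_fwer:g}]"
            )


def default_family(
    phenotypes=("bmi_sds",) + LIPID_PHENOS,
    snps=tuple(RSIDS),
    models=SCAN_MODELS,
) -> list[tuple[str, str, str]]:
    return [(p, s, m) for p in phenotypes for s in snps for m in models]


def _family_pvalues(matrix: pd.DataFrame, family, idx: np.ndarray) -> np.ndarray:
    """p-values for every test in the family under each genotype-row permutation.

    ``idx`` has shape (R, n); row r maps analysis row i to genotype source row
    ``idx[r, i]`` (all six SNP columns move together).  Returns (R, n_tests).
    Cross-products are accumulated with a 0/1 validity weight so each
    replicate uses exactly the complete cases of its permuted genotype column;
    this reproduces :func:`fit_association` p-values exactly (tested on the
    identity permutation).
    """
    R, n = idx.shape
    out = np.empty((R, len(family)), dtype=float)
    # group family members by (snp, model) so each permuted column is built once
    by_col: dict[tuple[str, str], list[int]] = {}
    for t, (pheno, rsid, model) in enumerate(family):
        by_col.setdefault((rsid, model), []).append(t)

    pheno_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def pheno_parts(phenotype):
        if phenotype not in pheno_cache:
            adj = default_adjustments(phenotype)
            y = matrix[ZCOL[phenotype]].to_numpy(dtype=float)
            C = np.column_stack([np.ones(n)] + [matrix[a].to_numpy(dtype=float) for a in adj])
            base = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
            y0 = np.where(base, np.nan_to_num(y), 0.0)
            C0 = np.where(base[:, None], np.nan_to_num(C), 0.0)
            pheno_cache[phenotype] = (base, y0, C0)
        return pheno_cache[phenotype]

    for (rsid, model), tests in by_col.items():
        g = matrix[rsid].to_numpy(dtype=float)
        xsrc = encode_genetic_model(g, model)
        Xp = xsrc[idx]                      # (R, n), NaN where genotype missing
        finite_x = np.isfinite(Xp)
        X0 = np.where(finite_x, Xp, 0.0)
        for t in tests:
            phenotype = family[t][0]
            base, y0, C0 = pheno_parts(phenotype)
            q = C0.shape[1]
            W = (finite_x & base[None, :]).astype(float)
            Xw = X0 * W
            # weighted cross-products for the augmented design [C, x]
            iu = np.triu_indices(q)
            Cpair = C0[:, iu[0]] * C0[:, iu[1]]          # (n, q(q+1)/2)
            Scc_flat = W @ Cpair                         # (R, q(q+1)/2)
            Scc = np.empty((R, q, q))
            Scc[:, iu[0], iu[1]] = Scc_flat
            Scc[:, iu[1], iu[0]] = Scc_flat
            Scy = W @ (C0 * y0[:, None])                 # (R, q)
            Syy = W @ (y0 * y0)                          # (R,)
            Scx = Xw @ C0                                # (R, q)
            Sxx = (Xw * X0).sum(axis=1)
            Sxy = Xw @ y0
            N = W.sum(axis=1)

            M = np.empty((R, q + 1, q + 1))
            M[:, :q, :q] = Scc
            M[:, :q, q] = Scx
            M[:, q, :q] = Scx
            M[:, q, q] = Sxx
            rhs = np.concatenate([Scy, Sxy[:, None]], axis=1)
            beta = np.linalg.solve(M, rhs[..., None])[..., 0]      # (R, q+1)
            rss = Syy - (rhs * beta).sum(axis=1)
            df = N - (q + 1)
            Minv_xx = np.linalg.inv(M)[:, q, q]
            s2 = np.maximum(rss, 0.0) / df
            tstat = beta[:, q] / np.sqrt(s2 * Minv_xx)
            out[:, t] = 2.0 * stats.t.sf(np.abs(tstat), df)
    return out


def _observed_pvalues(matrix: pd.DataFrame, family) -> np.ndarray:
    """Family p-values on the un-permuted data (fast vectorized path)."""
    n = len(matrix)
    idx = np.arange(n)[None, :]
    return _family_pvalues(matrix, family, idx)[0]


def _parametric_min_p(matrix, family, n_replicates, rng, block=500) -> np.ndarray:
    """Min-p null from multivariate-normal phenotypes independent of genotype."""
    n = len(matrix)
    phenos = sorted({f[0] for f in family})
    Z = np.column_stack([matrix[ZCOL[p]].to_numpy(dtype=float) for p in phenos])
    corr = pd.DataFrame(Z).corr().to_numpy()
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(len(phenos)))
    # per test: residualizer against [C] on its complete cases, genotype fixed
    pre = []
    for pheno, rsid, model in family:
        adj = default_adjustments(pheno)
        x = encode_genetic_model(matrix[rsid].to_numpy(dtype=float), model)
        C = np.column_stack([np.ones(n)] + [matrix[a].to_numpy(dtype=float) for a in adj])
        mask = np.isfinite(x) & np.all(np.isfinite(C), axis=1)
        Cm = C[mask]
        Q, _ = np.linalg.qr(Cm)
        xm = x[mask] - Q @ (Q.T @ x[mask])
        norm = np.linalg.norm(xm)
        if norm == 0:
            raise ValueError(f"degenerate design column for {pheno} x {rsid} x {model}")
        xm /= norm
        dfree = mask.sum() - C.shape[1] - 1
        pre.append((phenos.index(pheno), mask, Q, xm, dfree))

    minp = np.empty(n_replicates)
    done = 0
    while done < n_replicates:
        b = min(block, n_replicates - done)
        Y = rng.standard_normal((b, n, len(phenos))) @ L.T
        pblock = np.empty((b, len(family)))
        for t, (pj, mask, Q, xm, dfree) in enumerate(pre):
            Ym = Y[:, mask, pj]
            YQ = Ym @ Q
            yry = (Ym * Ym).sum(axis=1) - (YQ * YQ).sum(axis=1)
            xy = Ym @ xm
            denom = np.maximum(yry - xy * xy, 1e-300)
            tstat = xy * np.sqrt(dfree / denom)
            pblock[:, t] = 2.0 * stats.t.sf(np.abs(tstat), dfree)
        minp[done:done + b] = pblock.min(axis=1)
        done += b
    return minp


def fwer_threshold(
    matrix: pd.DataFrame,
    family: list[tuple[str, str, str]] | None = None,
    target_fwer: float = 0.05,
    n_replicates: int = 10_000,
    seed: int | None = None,
    method: str = "permutation",
    block: int = 2_000,
) -> FwerResult:
    """Per-test significance level alpha* controlling the family-wise rate.

    alpha* is the empirical ``target_fwer`` quantile of the distribution of
    the minimum p-value over the family under the simulated null; it always
    lies between the Bonferroni bound and ``target_fwer``.
    """
    if family is None:
        family = default_family()
    if n_replicates < 1000:
        raise ValueError("n_replicates must be >= 1000 for a stable quantile")
    if seed is None:
        raise ValueError("seed is mandatory for a reproducible threshold")
    rng = np.random.default_rng(seed)
    n = len(matrix)
    if method == "permutation":
        minp = np.empty(n_replicates)
        done = 0
        while done < n_replicates:
            b = min(block, n_replicates - done)
            idx = np.argsort(rng.random((b, n)), axis=1)
            pv = _family_pvalues(matrix, family, idx)
            minp[done:done + b] = pv.min(axis=1)
            done += b
    elif method == "parametric":
        minp = _parametric_min_p(matrix, family, n_replicates, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    alpha_star = float(np.quantile(minp, target_fwer))
    # Bonferroni/target are mathematically guaranteed bounds for a valid
    # threshold; project the Monte-Carlo estimate into the feasible band.
    alpha_star = min(max(alpha_star, target_fwer / len(family)), target_fwer)
    return FwerResult(alpha_star, target_fwer, n_replicates, len(family),
                      method, family=list(family), min_p=minp)
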