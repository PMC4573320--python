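"""Assemble result artifacts: scan table, model listings, inclusion matrix,
and the end-to-end pipeline with a reproducibility manifest.

Formatting follows the conventions of the result tables this pipeline
mirrors: model probabilities to 2 decimals (percent), Bayes factors to
integers, betas to 3 decimals; full precision is preserved in the JSON
summaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import (PosteriorSummary, SamplerConfig, bma_effects, build_problem,
                    inclusion_probabilities, run_selection)
from .classical import fwer_threshold, run_association_scan
from .cohort_io import CohortTable, read_cohort, write_cohort
from .preprocess import hwe_report, make_analysis_matrix
from .synthetic import SyntheticConfig, generate_cohort


@dataclass
class ModelListing:
    """Probability-sorted model rows truncated at a cumulative threshold."""

    rows: pd.DataFrame
    threshold: float
    truncated: bool


def truncate_models(models: pd.DataFrame, threshold: float = 95.0) -> ModelListing:
    """Minimal prefix of the probability-sorted listing whose sum reaches
    ``threshold`` (both in percent).  If the total never reaches the
    threshold, all models are listed with a warning."""
    if (models["probability"] < 0).any():
        raise ValueError("negative model probability")
    ordered = models.sort_values(["probability", "model"], ascending=[False, True],
                                 kind="mergesort").reset_index(drop=True)
    cum = ordered["probability"].cumsum()
    if cum.iloc[-1] < threshold:
        warnings.warn(
            f"total listed probability {cum.iloc[-1]:.2f}% below threshold {threshold}%",
            RuntimeWarning, stacklevel=2)
        return ModelListing(ordered, threshold, truncated=False)
    stop = int(np.argmax(cum.to_numpy() >= threshold))
    return ModelListing(ordered.iloc[: stop + 1].reset_index(drop=True),
                        threshold, truncated=True)


@dataclass
class InclusionMatrix:
    """Trait x covariable grid of integer-rounded inclusion percentages.

    ``table`` holds display strings (cells rounding to 0 are blank);
    ``probabilities`` the full-precision percentages and ``effects`` the BMA
    estimates as shading metadata.
    """

    table: pd.DataFrame
    probabilities: pd.DataFrame
    effects: pd.DataFrame


def render_inclusion_matrix(summary: PosteriorSummary) -> InclusionMatrix:
    probs = summary.inclusion_matrix() * 100.0
    est = pd.DataFrame(np.nan, index=probs.index, columns=probs.columns)
    eff = bma_effects(summary, floor=0.0)
    for _, row in eff.iterrows():
        est.loc[row["trait"], row["covariable"]] = row["estimate"]
    rounded = probs.round(0).astype(int)
    table = rounded.astype(str).where(rounded > 0, "")
    return InclusionMatrix(table=table, probabilities=probs, effects=est)


def _format_models(listing: ModelListing, trait: str) -> pd.DataFrame:
    out = listing.rows.copy()
    out.insert(0, "lipid", trait)
    out["probability"] = out["probability"].round(2)
    out["bayes_factor"] = out["bayes_factor"].map(
        lambda v: int(round(v)) if np.isfinite(v) else "inf")
    return out[["lipid", "model", "probability", "bayes_factor"]]


def run_pipeline(
    out_dir: str | Path,
    cohort_path: str | Path | None = None,
    dialect: str = "csv",
    synth_config: SyntheticConfig | None = None,
    seed: int = 0,
    fwer_replicates: int = 10_000,
    sampler_config: SamplerConfig | None = None,
    model_threshold: float = 95.0,
) -> dict:
    """Read (or synthesize) a cohort, run both analysis tracks and write the
    report bundle plus a manifest; any stage failure names the stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seed_fwer, seed_mcmc, seed_synth = [int(s.generate_state(1)[0] % (2 ** 31))
                                        for s in ss.spawn(3)]

    stage = "read_cohort"
    try:
        if cohort_path is not None:
            cohort = read_cohort(cohort_path, dialect=dialect)
            source = str(cohort_path)
        else:
            cfg = synth_config or SyntheticConfig()
            cohort = generate_cohort(cfg, seed=seed_synth)
            source = f"synthetic(n={cfg.n}, seed={seed_synth})"
            write_cohort(cohort, out / "cohort.csv", dialect="csv")

        stage = "preprocess"
        hwe = hwe_report(cohort)
        hwe.to_csv(out / "hwe_report.tsv", sep="\t", index=False)
        matrix = make_analysis_matrix(cohort)

        stage = "classical_scan"
        scan = run_association_scan(matrix)
        formatted = scan.copy()
        for col in ("beta", "se", "ci_low", "ci_high"):
            formatted[col] = formatted[col].round(3)
        formatted.to_csv(out / "association_scan.tsv", sep="\t", index=False)

        stage = "fwer"
        fwer = fwer_threshold(matrix, n_replicates=fwer_replicates, seed=seed_fwer)
        (out / "fwer.json").write_text(json.dumps({
            "alpha_star": fwer.alpha_star, "target_fwer": fwer.target_fwer,
            "n_replicates": fwer.n_replicates, "n_tests": fwer.n_tests,
            "bonferroni_bound": fwer.bonferroni_bound, "method": fwer.method,
        }, indent=2))

        stage = "bayes_selection"
        scfg = sampler_config or SamplerConfig(seed=seed_mcmc)
        if scfg.seed is None:
            scfg.seed = seed_mcmc
        problem = build_problem(matrix)
        summary = run_selection(problem, scfg)
        model_frames = []
        for trait in summary.traits:
            listing = truncate_models(summary.model_table(trait), model_threshold)
            model_frames.append(_format_models(listing, trait))
        pd.concat(model_frames).to_csv(out / "bayes_models.tsv", sep="\t", index=False)
        eff = bma_effects(summary)
        eff_fmt = eff.copy()
        eff_fmt["probability"] = (eff_fmt["probability"] * 100).round(2)
        eff_fmt["estimate"] = eff_fmt["estimate"].round(3)
        eff_fmt["sd"] = eff_fmt["sd"].round(3)
        eff_fmt.to_csv(out / "bayes_effects.tsv", sep="\t", index=False)
        render_inclusion_matrix(summary).table.to_csv(out / "inclusion_matrix.tsv", sep="\t")
        (out / "bayes_summary.json").write_text(json.dumps({
            "traits": summary.traits,
            "tau": summary.tau,
            "converged": summary.converged,
            "inclusion": summary.inclusion_matrix().to_dict(),
            "sigma_mean": summary.sigma_mean.tolist(),
        }, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "source": source,
        "seed": seed,
        "derived_seeds": {"fwer": seed_fwer, "mcmc": seed_mcmc, "synthetic": seed_synth},
        "n_individuals": len(cohort),
        "fwer_replicates": fwer_replicates,
        "sampler": {"n_iterations": scfg.n_iterations, "n_burnin": scfg.n_burnin,
                    "thin": scfg.thin, "n_chains": scfg.n_chains, "tau": scfg.tau},
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
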