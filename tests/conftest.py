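"""Shared fixtures: small handmade cohorts and frozen synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lipidbvs import CohortTable, SyntheticConfig, generate_cohort, make_analysis_matrix

#: master seed for the frozen evaluation cohorts (fixed once; the three
#: cohorts are consecutive seeds so the checks do not hinge on one draw)
FROZEN_SEED = 20150916
FROZEN_SEEDS = (FROZEN_SEED, FROZEN_SEED + 1, FROZEN_SEED + 2)


def make_small_cohort(n: int = 12, seed: int = 0, **missing) -> CohortTable:
    """Small fully-synthetic cohort table for I/O and validation tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"sample_id": [f"P{i:03d}" for i in range(n)]})
    for rsid in ("rs599839", "rs3846663", "rs3812316", "rs174570", "rs4420638", "rs6102059"):
        df[rsid] = rng.integers(0, 3, size=n).astype(float)
    for lipid, med in (("hdl_c", 1.2), ("ldl_c", 2.5), ("tc", 4.1), ("tg", 1.0)):
        df[lipid] = med * np.exp(0.2 * rng.standard_normal(n))
    df["age"] = rng.uniform(5, 18, size=n)
    df["sex"] = np.where(rng.random(n) < 0.5, "female", "male")
    df["bmi_sds"] = rng.normal(2.2, 0.8, size=n)
    for col, rows in missing.items():
        df.loc[list(rows), col] = np.nan
    return CohortTable(df).validate()


@pytest.fixture(scope="session")
def frozen_cohorts():
    return [generate_cohort(SyntheticConfig(), seed=s) for s in FROZEN_SEEDS]


@pytest.fixture(scope="session")
def frozen_matrices(frozen_cohorts):
    return [make_analysis_matrix(c) for c in frozen_cohorts]


@pytest.fixture(scope="session")
def frozen_matrix(frozen_matrices):
    return frozen_matrices[0]
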