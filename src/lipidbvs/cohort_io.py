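"""Read, write and validate per-individual cohort tables.

Two on-disk dialects carry the same columns: ``"s1"`` is an xlsx spreadsheet,
``"csv"`` a UTF-8 comma-separated file.  Columns (matched case-insensitively):
``sample_id``, the six rsid genotype columns coded as minor-allele count with
``3`` meaning missing, the lipid panel ``tc``/``hdl_c``/``ldl_c``/``tg`` in
mmol/L, and the covariates ``age`` (years), ``sex`` and ``bmi_sds``.

In memory, genotype ``3`` is always converted to missing; the sentinel never
appears downstream.  Sex is normalized to the strings ``"male"``/``"female"``
(``m``/``f`` and ``0``/``1``, with 0 = male, are accepted on read).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import RSIDS

logger = logging.getLogger(__name__)

LIPIDS = ["tc", "hdl_c", "ldl_c", "tg"]
REQUIRED_COLUMNS = ["sample_id"] + RSIDS + ["hdl_c", "ldl_c", "tc", "tg", "age", "sex", "bmi_sds"]
DIALECTS = ("s1", "csv")

_SEX_MAP = {
    "m": "male", "male": "male", "0": "male",
    "f": "female", "female": "female", "1": "female",
}


class CohortValidationError(ValueError):
    """A cohort table violates the dialect contract (named column / row id)."""


@dataclass
class CohortTable:
    """Validated cohort table with explicit missingness.

    ``data`` holds one row per individual.  Genotype columns are float with
    NaN for missing; lipids and covariates are float; ``sex`` is a string
    column with values ``"male"``/``"female"``.
    """

    data: pd.DataFrame
    read_report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> "CohortTable":
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise CohortValidationError(f"missing required column: {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CohortValidationError(f"duplicate sample_id: {dup!r}")
        for rsid in RSIDS:
            vals = df[rsid].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            bad = ~np.isin(finite, (0.0, 1.0, 2.0))
            if bad.any():
                row = df.loc[np.isfinite(df[rsid].to_numpy(dtype=float)), "sample_id"].to_numpy()[bad][0]
                raise CohortValidationError(
                    f"genotype outside {{0,1,2}} for {rsid} at sample_id {row!r}"
                )
        for lipid in LIPIDS:
            vals = df[lipid].to_numpy(dtype=float)
            nonpos = np.isfinite(vals) & (vals <= 0)
            if nonpos.any():
                row = df.loc[nonpos, "sample_id"].iloc[0]
                raise CohortValidationError(
                    f"non-positive {lipid} value at sample_id {row!r} (log transform requires > 0)"
                )
        bad_sex = df["sex"].dropna()[~df["sex"].dropna().isin(["male", "female"])]
        if len(bad_sex):
            raise CohortValidationError(f"unrecognized sex value {bad_sex.iloc[0]!r}")
        return self


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    lower = {c: str(c).strip().lower() for c in df.columns}
    return df.rename(columns=lower)


def _normalize_sex(series: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return np.nan
        key = str(v).strip().lower()
        if key in ("", "nan"):
            return np.nan
        # numeric-looking values like 0.0 / 1.0
        try:
            key = str(int(float(key)))
        except ValueError:
            pass
        if key not in _SEX_MAP:
            raise CohortValidationError(f"unrecognized sex value {v!r}")
        return _SEX_MAP[key]

    return series.map(conv)


def read_cohort(path: str | Path, dialect: str = "csv") -> CohortTable:
    """Read a cohort table, mapping genotype code 3 to missing and validating.

    Raises :class:`CohortValidationError` naming the offending column or row
    for missing columns, out-of-range genotypes or non-positive lipid values.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "s1":
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, float_precision="round_trip")
    raw = _normalize_columns(raw)
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise CohortValidationError(f"missing required column: {col!r}")

    df = pd.DataFrame({"sample_id": raw["sample_id"].astype(str)})
    for rsid in RSIDS:
        vals = pd.to_numeric(raw[rsid], errors="coerce").to_numpy(dtype=float)
        raw_na = raw[rsid].isna().to_numpy()
        coerced_bad = np.isnan(vals) & ~raw_na
        if coerced_bad.any():
            row = df.loc[coerced_bad, "sample_id"].iloc[0]
            raise CohortValidationError(f"non-numeric genotype for {rsid} at sample_id {row!r}")
        finite = np.isfinite(vals)
        bad = finite & ~np.isin(vals, (0.0, 1.0, 2.0, 3.0))
        if bad.any():
            row = df.loc[bad, "sample_id"].iloc[0]
            raise CohortValidationError(
                f"genotype outside {{0,1,2,3}} for {rsid} at sample_id {row!r}"
            )
        vals[vals == 3.0] = np.nan  # 3 == missing in the S1 coding
        df[rsid] = vals
    for col in LIPIDS + ["age", "bmi_sds"]:
        df[col] = pd.to_numeric(raw[col], errors="coerce").astype(float)
    df["sex"] = _normalize_sex(raw["sex"])

    report = {col: int(df[col].isna().sum()) for col in df.columns if col != "sample_id"}
    for col, n_missing in report.items():
        if n_missing:
            logger.info("read_cohort: column %s has %d missing values", col, n_missing)
    table = CohortTable(df, read_report=report)
    return table.validate()


def write_cohort(table: CohortTable, path: str | Path, dialect: str = "csv") -> Path:
    """Write a cohort table; missing genotypes become the literal code 3.

    Missing continuous values are written as empty cells (CSV) / blank cells
    (xlsx).  The file round-trips through :func:`read_cohort`.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    table.validate()
    out = table.data.copy()
    for rsid in RSIDS:
        vals = out[rsid].to_numpy(dtype=float).copy()
        vals[np.isnan(vals)] = 3.0
        out[rsid] = vals.astype(int)
    out = out[REQUIRED_COLUMNS]
    if dialect == "s1":
        out.to_excel(path, index=False)
    else:
        out.to_csv(path, index=False)
    return path
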