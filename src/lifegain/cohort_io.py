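"""Cohort CSV schema, validation and Table-1-style descriptives.

The cohort file is plain UTF-8 CSV with a header row and '.' decimals:
one row per subject with identifiers, follow-up (entry/exit ages in
years, event flag), the ten raw lifestyle columns, and the covariate
and comorbidity flags.  Rows violating the schema (exit before entry,
ages outside 40-102, unknown category codes) are rejected, counted and
reported -- never silently fixed.  Empty cells mark missing responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import (BAND_LABELS, COMPONENTS, FOOD_CATEGORIES,
                      SMOKING_CATEGORIES, SPORTS_CATEGORIES, WALK_CATEGORIES)

__all__ = ["REQUIRED_COLUMNS", "ValidationReport", "read_cohort",
           "write_cohort", "descriptives_by_band"]

REQUIRED_COLUMNS = (
    "id", "sex", "entry_age", "exit_age", "event",
    "fruit_freq", "fish_freq", "milk_freq", "walk_cat", "sports_cat",
    "bmi", "ethanol_gday", "drinker_status", "smoking_status", "sleep_hours",
    "education", "family_history_cvd",
    "comorbid_cvd", "comorbid_cancer", "comorbid_hypertension",
    "comorbid_diabetes", "comorbid_kidney",
)

_CATEGORY_COLUMNS = {
    "fruit_freq": FOOD_CATEGORIES, "fish_freq": FOOD_CATEGORIES,
    "milk_freq": FOOD_CATEGORIES, "walk_cat": WALK_CATEGORIES,
    "sports_cat": SPORTS_CATEGORIES, "smoking_status": SMOKING_CATEGORIES,
    "drinker_status": ("non_drinker", "drinker"),
    "education": ("college_or_higher", "lower"),
}
_NUMERIC_COLUMNS = ("entry_age", "exit_age", "bmi", "ethanol_gday",
                    "sleep_hours")
_FLAG_COLUMNS = ("family_history_cvd", "comorbid_cvd", "comorbid_cancer",
                 "comorbid_hypertension", "comorbid_diabetes", "comorbid_kidney")


@dataclass
class ValidationReport:
    """Row-level schema violations found while reading a cohort file."""

    n_rows: int = 0
    n_kept: int = 0
    violations: list = field(default_factory=list)   # dicts: row, rule

    @property
    def n_rejected(self) -> int:
        return self.n_rows - self.n_kept

    def counts_by_rule(self) -> dict:
        out: dict[str, int] = {}
        for v in self.violations:
            out[v["rule"]] = out.get(v["rule"], 0) + 1
        return out

    def __str__(self) -> str:
        if not self.violations:
            return f"{self.n_kept}/{self.n_rows} rows valid"
        rules = ", ".join(f"{k}: {n}" for k, n in self.counts_by_rule().items())
        return (f"{self.n_kept}/{self.n_rows} rows valid; "
                f"rejected {self.n_rejected} ({rules})")


def read_cohort(path):
    """Read and validate a cohort CSV.

    Returns ``(df, report)``: typed records for the valid rows and a
    :class:`ValidationReport` citing each rejected row and the rule it
    broke.  A missing required column or an empty file is an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise ValueError(f"empty cohort file: {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
    bad = pd.Series(False, index=df.index)
    violations = []

    def flag(mask, rule):
        nonlocal bad
        for row in df.index[mask & ~bad]:
            violations.append({"row": int(row), "rule": rule})
        bad |= mask

    flag(~df["sex"].isin(["M", "F"]), "sex not in {M, F}")
    flag(~df["event"].isin(["0", "1"]), "event not in {0, 1}")
    flag(df["entry_age"].isna() | df["exit_age"].isna(), "non-numeric age")
    with np.errstate(invalid="ignore"):
        flag(df["exit_age"] < df["entry_age"], "exit_age < entry_age")
        flag((df["entry_age"] < 40) | (df["exit_age"] > 102),
             "age outside 40-102")
    for col, cats in _CATEGORY_COLUMNS.items():
        flag(~df[col].isin(list(cats) + [""]), f"unknown category in {col}")
    for col in _FLAG_COLUMNS:
        flag(~df[col].isin(["0", "1", ""]), f"{col} not a 0/1 flag")

    report = ValidationReport(n_rows=len(df), n_kept=int((~bad).sum()),
                              violations=violations)
    out = df[~bad].copy()
    out["event"] = out["event"].astype(int)
    for col in _FLAG_COLUMNS:
        out[col] = pd.to_numeric(out[col].replace("", "0")).astype(int)
    for col in _CATEGORY_COLUMNS:
        out[col] = out[col].replace("", np.nan)
    return out.reset_index(drop=True), report


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the schema dialect (UTF-8 CSV, '.' decimals)."""
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


_PCT_COLUMNS = {
    "fruit": "pt_fruit", "fish": "pt_fish", "milk": "pt_milk",
    "activity": "pt_activity", "bmi": "pt_bmi", "alcohol": "pt_alcohol",
    "smoking": "pt_smoking", "sleep": "pt_sleep",
}


def descriptives_by_band(df: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics per sex and score band.

    For every sex x band cell: subject count, mean (SD) entry age, the
    percentage healthy on each of the eight components, and the
    percentages with college education, family history of CVD and each
    comorbidity.  ``df`` must be scored (pt_* and score_band columns).
    Empty cells yield a zero row with n = 0.
    """
    rows = []
    for sex in ("M", "F"):
        for band in BAND_LABELS:
            cell = df[(df["sex"] == sex) & (df["score_band"] == band)]
            row = {"sex": sex, "band": band, "n": int(len(cell))}
            if len(cell) == 0:
                row.update({"age_mean": 0.0, "age_sd": 0.0})
                row.update({f"pct_{c}": 0.0 for c in COMPONENTS})
                row.update({"pct_education": 0.0, "pct_family_history": 0.0})
                row.update({f"pct_comorbid_{c}": 0.0 for c in
                            ("cvd", "cancer", "hypertension", "diabetes", "kidney")})
            else:
                row["age_mean"] = float(cell["entry_age"].mean())
                row["age_sd"] = float(cell["entry_age"].std(ddof=1)) if len(cell) > 1 else 0.0
                for comp, col in _PCT_COLUMNS.items():
                    row[f"pct_{comp}"] = float(100 * cell[col].mean())
                row["pct_education"] = float(
                    100 * (cell["education"] == "college_or_higher").mean())
                row["pct_family_history"] = float(
                    100 * cell["family_history_cvd"].mean())
                for c in ("cvd", "cancer", "hypertension", "diabetes", "kidney"):
                    row[f"pct_comorbid_{c}"] = float(
                        100 * cell[f"comorbid_{c}"].mean())
            rows.append(row)
    return pd.DataFrame(rows)
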