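"""Lifetime gains within comorbidity and multimorbidity strata.

Gains at index ages 50, 65 and 80 are re-estimated inside strata
defined either by one tracked condition (CVD, cancer, hypertension,
diabetes, kidney disease -- strata may overlap, since a subject can
carry several conditions) or by the multimorbidity count
(0 / 1 / 2 / 3+, which partitions the cohort exactly).  Condition
strata are fitted sex-specifically; multimorbidity strata pool the
sexes with a sex covariate, because sex-stratified counts in the
higher-multimorbidity cells are too small.  Strata that retain fewer
than a configurable minimum of events are skipped with a logged
reason rather than reported with unstable estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gompertz import ConvergenceError
from .uncertainty import AnalysisSpec, ResampleSpec, bootstrap_estimates

__all__ = ["StratumSpec", "run_stratified_gains", "multimorbidity_count",
           "COMORBIDITIES"]

logger = logging.getLogger(__name__)

COMORBIDITIES = ("cvd", "cancer", "hypertension", "diabetes", "kidney")
_COUNT_LEVELS = ("0", "1", "2", "3+")


@dataclass
class StratumSpec:
    """One subgroup: a condition, a multimorbidity count, or no filter."""

    kind: str = "none"                 # comorbidity | multimorbidity_count | none
    value: str | None = None           # condition name or count level
    index_ages: tuple = (50.0, 65.0, 80.0)
    adjustment: tuple = ("education", "family_history_cvd")
    pooled_sexes: bool = False

    def __post_init__(self):
        if self.kind == "comorbidity":
            if self.value not in COMORBIDITIES:
                raise ValueError(f"unknown comorbidity {self.value!r}")
        elif self.kind == "multimorbidity_count":
            if str(self.value) not in _COUNT_LEVELS:
                raise ValueError(f"multimorbidity count must be one of "
                                 f"{_COUNT_LEVELS}")
        elif self.kind != "none":
            raise ValueError(f"unknown stratum kind {self.kind!r}")


def multimorbidity_count(df: pd.DataFrame) -> pd.Series:
    """Number of tracked conditions per subject, binned as 0/1/2/3+."""
    counts = sum(df[f"comorbid_{c}"].astype(int) for c in COMORBIDITIES)
    return pd.Series(np.where(counts >= 3, "3+", counts.astype(str)),
                     index=df.index, name="multimorbidity")


def _subset(df: pd.DataFrame, stratum: StratumSpec) -> pd.DataFrame:
    if stratum.kind == "none":
        return df
    if stratum.kind == "comorbidity":
        return df[df[f"comorbid_{stratum.value}"] == 1]
    return df[multimorbidity_count(df) == str(stratum.value)]


def run_stratified_gains(df: pd.DataFrame, strata, resample_spec: ResampleSpec,
                         min_events: int = 50,
                         reference_band: str = "0-2") -> pd.DataFrame:
    """Gains versus the reference band inside each stratum.

    Returns a tidy frame with columns stratum_kind, stratum_value, sex,
    band, index_age, gain, ci_low, ci_high, n, n_events.  Skipped
    strata (too few events, a single band, or non-convergence) are
    logged and omitted.
    """
    rows = []
    for stratum in strata:
        sub = _subset(df, stratum)
        label = f"{stratum.kind}={stratum.value}"
        if len(sub) == 0:
            logger.info("stratum %s skipped: empty", label)
            continue
        if int(sub["event"].sum()) < min_events:
            logger.info("stratum %s skipped: only %d events (< %d)",
                        label, int(sub["event"].sum()), min_events)
            continue
        if sub["score_band"].nunique() < 2:
            logger.info("stratum %s skipped: single band", label)
            continue
        spec = AnalysisSpec(covariates=("band",) + tuple(stratum.adjustment),
                            reference_band=reference_band,
                            index_ages=tuple(stratum.index_ages),
                            pooled=stratum.pooled_sexes)
        try:
            boot = bootstrap_estimates(sub, spec, resample_spec)
        except (ValueError, ConvergenceError, RuntimeError) as err:
            logger.info("stratum %s skipped: %s", label, err)
            continue
        for _, r in boot.summary.iterrows():
            sexmask = slice(None) if r["sex"] == "MF" else (sub["sex"] == r["sex"])
            band_sel = sub if r["sex"] == "MF" else sub[sexmask]
            rows.append({
                "stratum_kind": stratum.kind,
                "stratum_value": "" if stratum.value is None else str(stratum.value),
                "sex": r["sex"], "band": r["band"], "index_age": r["index_age"],
                "gain": r["gain"], "ci_low": r["gain_ci_low"],
                "ci_high": r["gain_ci_high"],
                "n": int(len(band_sel)), "n_events": int(band_sel["event"].sum()),
            })
    return pd.DataFrame(rows, columns=["stratum_kind", "stratum_value", "sex",
                                       "band", "index_age", "gain", "ci_low",
                                       "ci_high", "n", "n_events"])
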