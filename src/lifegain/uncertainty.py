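"""Monte-Carlo and bootstrap intervals for expectancies and gains.

Two engines produce the sampling distribution of the life-table
quantities:

* ``subject_bootstrap`` -- resample subjects with replacement within
  sex strata, refit the Gompertz PH model, rebuild the band life
  tables, recompute remaining expectancies and gains (the production
  default, 10,000 replicates);
* ``parameter_draws`` -- draw parameter vectors from the fitted
  model's normal approximation N(estimate, vcov) and rebuild the
  tables per draw (much faster; asymptotically equivalent).

Intervals are percentile (2.5th / 97.5th at the default 95% level).
Replicates that fail to converge are dropped and counted; more than 1%
failures is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gompertz import BAND_LABELS, ConvergenceError, GompertzPH
from .lifetable import gompertz_life_table

__all__ = ["AnalysisSpec", "ResampleSpec", "BootstrapResult",
           "bootstrap_estimates", "gains_from_posterior", "band_expectancies"]


@dataclass
class AnalysisSpec:
    """What to estimate: covariates, bands, index ages, table options."""

    covariates: tuple = ("band",)
    reference_band: str = "0-2"
    index_ages: tuple = (40.0,)
    sexes: tuple = ("M", "F")
    pooled: bool = False          # single fit with a sex covariate
    terminal: str = "tail"
    start: float = 40.0
    end: float = 102.0

    @property
    def bands(self) -> tuple:
        return BAND_LABELS if "band" in self.covariates else ("all",)

    def profile(self, band: str) -> dict:
        if band in ("all", self.reference_band):
            return {}
        return {f"band_{band}": 1.0}


@dataclass
class ResampleSpec:
    """How to resample: method, replicate count, seed, CI level."""

    method: str = "subject_bootstrap"
    B: int = 10_000
    seed: int = 0
    stratify_by: tuple = ("sex",)
    ci_level: float = 0.95

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.method not in ("subject_bootstrap", "parameter_draws",
                               "posterior_draws"):
            raise ValueError(f"unknown resampling method {self.method!r}")


@dataclass
class BootstrapResult:
    """Point estimates, replicate draws and percentile summaries."""

    point: pd.DataFrame       # sex, band, index_age, ex, gain
    replicates: pd.DataFrame  # replicate, sex, band, index_age, ex, gain
    summary: pd.DataFrame     # point + ci bounds, method, B bookkeeping
    B: int
    B_effective: int
    failures: int
    method: str
    seed: int

    def write_csv(self, replicates_path, summary_path) -> None:
        self.replicates.to_csv(replicates_path, index=False)
        self.summary.to_csv(summary_path, index=False)


def band_expectancies(params, spec: AnalysisSpec, param_names,
                      age_origin: float = 40.0) -> list[dict]:
    """Remaining expectancy per band/index age from one parameter vector."""
    lam = float(np.exp(params[0]))
    gam = float(params[1])
    name_to_idx = {n: i for i, n in enumerate(param_names)}
    rows = []
    ref_ex = {}
    for band in spec.bands:
        lp = sum(params[name_to_idx[k]] * v
                 for k, v in spec.profile(band).items())
        table = gompertz_life_table(lam, gam, linpred=float(lp),
                                    start=spec.start, end=spec.end,
                                    terminal=spec.terminal, origin=age_origin,
                                    label=str(band))
        for age in spec.index_ages:
            ex = table.expectancy_at(age)
            if band in ("all", spec.reference_band):
                ref_ex[age] = ex
            rows.append({"band": band, "index_age": age, "ex": ex})
    for r in rows:
        r["gain"] = r["ex"] - ref_ex[r["index_age"]]
    return rows


def _fit_stratum(df, spec: AnalysisSpec, sex):
    covs = tuple(spec.covariates)
    if spec.pooled and "sex" not in covs:
        covs = covs + ("sex",)
    model = GompertzPH.from_dataframe(df, covariates=covs, sex=sex,
                                      reference_band=spec.reference_band)
    return model.fit()


def _strata(spec: AnalysisSpec):
    return [None] if spec.pooled else list(spec.sexes)


def bootstrap_estimates(df: pd.DataFrame, analysis_spec: AnalysisSpec,
                        resample_spec: ResampleSpec) -> BootstrapResult:
    """Sampling distributions and percentile CIs for e_x and gains.

    Subjects are resampled with replacement within sex strata (subject
    bootstrap) or parameters are drawn from the fitted normal
    approximation (parameter draws); each replicate rebuilds the band
    life tables and recomputes every target.  Deterministic given
    ``resample_spec.seed``.
    """
    if len(df) == 0 or resample_spec.B == 0:
        raise ValueError("need a non-empty cohort and B >= 1")
    spec, rs = analysis_spec, resample_spec
    strata = _strata(spec)
    ss = np.random.SeedSequence(rs.seed)
    child_seqs = ss.spawn(len(strata))

    point_rows, rep_rows = [], []
    failures = 0
    for stratum, child in zip(strata, child_seqs):
        sex_label = "MF" if stratum is None else stratum
        sub = df if stratum is None else df[df["sex"] == stratum]
        res = _fit_stratum(df, spec, stratum)
        for r in band_expectancies(res.params, spec, res.param_names,
                                   res.age_origin):
            point_rows.append({"sex": sex_label, **r})
        if rs.method == "parameter_draws":
            seed = int(child.generate_state(1)[0] % (2**31))
            draws = res.sample_params(rs.B, seed=seed)
            for b in range(rs.B):
                for r in band_expectancies(draws[b], spec, res.param_names,
                                           res.age_origin):
                    rep_rows.append({"replicate": b, "sex": sex_label, **r})
        elif rs.method == "subject_bootstrap":
            rng = np.random.default_rng(child)
            # resampling stays stratified by sex even when the fit pools sexes
            groups = [g.reset_index(drop=True)
                      for _, g in sub.groupby("sex", sort=True)] \
                if stratum is None else [sub.reset_index(drop=True)]
            for b in range(rs.B):
                boot = pd.concat([g.iloc[rng.integers(0, len(g), size=len(g))]
                                  for g in groups], ignore_index=True)
                try:
                    bres = _fit_stratum(boot, spec, stratum)
                except (ValueError, ConvergenceError):
                    failures += 1
                    continue
                for r in band_expectancies(bres.params, spec, bres.param_names,
                                           bres.age_origin):
                    rep_rows.append({"replicate": b, "sex": sex_label, **r})
        else:
            raise ValueError("posterior_draws resampling goes through "
                             "gains_from_posterior")
    if failures > 0.01 * rs.B * len(strata):
        raise RuntimeError(
            f"{failures} of {rs.B * len(strata)} bootstrap replicates failed "
            "to converge (> 1%)")

    point = pd.DataFrame(point_rows)
    reps = pd.DataFrame(rep_rows)
    alpha = 1.0 - rs.ci_level
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    sum_rows = []
    for (sexl, band, age), grp in reps.groupby(["sex", "band", "index_age"],
                                               sort=False):
        p = point[(point["sex"] == sexl) & (point["band"] == band) &
                  (point["index_age"] == age)].iloc[0]
        ex_lo, ex_hi = np.percentile(grp["ex"], qs)
        g_lo, g_hi = np.percentile(grp["gain"], qs)
        sum_rows.append({"sex": sexl, "band": band, "index_age": age,
                         "ex": p["ex"], "ex_ci_low": ex_lo, "ex_ci_high": ex_hi,
                         "gain": p["gain"], "gain_ci_low": g_lo,
                         "gain_ci_high": g_hi, "method": rs.method,
                         "B": rs.B, "seed": rs.seed})
    summary = pd.DataFrame(sum_rows)
    B_eff = rs.B * len(strata) - failures
    return BootstrapResult(point=point, replicates=reps, summary=summary,
                           B=rs.B * len(strata), B_effective=B_eff,
                           failures=failures, method=rs.method, seed=rs.seed)


def gains_from_posterior(bayes_results, index_ages=(40.0,),
                         reference_band: str = "0-2", terminal: str = "tail",
                         start: float = 40.0, end: float = 102.0,
                         level: float = 0.95):
    """Lifetime gains with credible intervals from posterior draws.

    Builds the band life tables for every posterior draw of
    (log lambda, gamma, beta...) and summarises each gain by its
    posterior median and central credible interval.  Draws implying a
    defective survival (gamma < 0) are dropped and counted.

    Returns ``(summary, n_dropped)``.
    """
    names = bayes_results.param_names
    band_names = [n for n in names if n.startswith("band_")]
    bands = [reference_band] + [n.removeprefix("band_") for n in band_names]
    spec = AnalysisSpec(covariates=("band",) if band_names else (),
                        reference_band=reference_band, index_ages=tuple(index_ages),
                        terminal=terminal, start=start, end=end)
    if not band_names:
        bands = ["all"]
    rows = []
    dropped = 0
    for d, params in enumerate(bayes_results.draws):
        if params[1] < 0:
            dropped += 1
            continue
        for r in band_expectancies(params, spec, names,
                                   bayes_results.model.age_origin):
            rows.append({"draw": d, **r})
    if not rows:
        raise ValueError("every posterior draw was defective")
    reps = pd.DataFrame(rows)
    alpha = 1 - level
    qs = [100 * alpha / 2, 50, 100 * (1 - alpha / 2)]
    out = []
    for (band, age), grp in reps.groupby(["band", "index_age"], sort=False):
        g_lo, g_med, g_hi = np.percentile(grp["gain"], qs)
        e_lo, e_med, e_hi = np.percentile(grp["ex"], qs)
        out.append({"band": band, "index_age": age,
                    "ex_median": e_med, "ex_ci_low": e_lo, "ex_ci_high": e_hi,
                    "gain_median": g_med, "gain_ci_low": g_lo,
                    "gain_ci_high": g_hi, "n_draws": len(grp)})
    return pd.DataFrame(out), dropped
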