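"""The 0-8 modifiable healthy-lifestyle score.

Eight behaviours score one point each: daily fruit, daily fish, milk
almost every day, habitual walking (>= the 0.5-1 h/day category) or
sports (>= 5 h/week), BMI in 21.0-25.0 kg/m^2, alcohol at most
46.0 g ethanol/day (non-drinkers included; drinkers below 1 g/day do
not score), non-smoking, and sleep of 5.5-7.4 h/day.  All printed
ranges are closed intervals.  Totals are analysed in six bands:
0-2, 3, 4, 5, 6 and 7-8 points.

The smoking point defaults to "current non-smoker scores 1"; a
configuration switch restricts it to never-smokers, because cohort
questionnaires differ on which of the two was recorded.

Missing responses yield an "unscorable" component (None), never a
silent 0; records with any unscorable component are removed by
:func:`complete_case_filter`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENTS", "BAND_LABELS", "FOOD_CATEGORIES", "WALK_CATEGORIES",
    "SPORTS_CATEGORIES", "SMOKING_CATEGORIES",
    "score_component", "total_score", "band_of", "score_records",
    "complete_case_filter", "LifestyleScore",
]

COMPONENTS = ("fruit", "fish", "milk", "activity", "bmi", "alcohol",
              "smoking", "sleep")
BAND_LABELS = ("0-2", "3", "4", "5", "6", "7-8")
_BAND_RANGES = {"0-2": (0, 2), "3": (3, 3), "4": (4, 4), "5": (5, 5),
                "6": (6, 6), "7-8": (7, 8)}

FOOD_CATEGORIES = ("rarely", "1-2_per_month", "1-2_per_week",
                   "3-4_per_week", "almost_daily")
WALK_CATEGORIES = ("rarely", "0.5h", "0.5-1h", "1h_plus")
SPORTS_CATEGORIES = ("rarely", "1-2h", "3-4h", "5h_plus")
SMOKING_CATEGORIES = ("never", "former", "current")

_HEALTHY_WALK = ("0.5-1h", "1h_plus")
_HEALTHY_SPORTS = ("5h_plus",)


def _missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return pd.isna(value)


def score_component(component: str, response, *, smoking_rule: str = "current"):
    """Score one component: 1 (healthy), 0 (not), or None (unscorable).

    ``response`` formats: frequency category for the three foods; a
    ``(walk_category, sports_category)`` pair for activity; numeric BMI
    and sleep hours; ``(drinker_status, ethanol_g_per_day)`` for
    alcohol (a bare number is treated as a drinker's intake); smoking
    status category.
    """
    if component not in COMPONENTS:
        raise KeyError(f"unknown component {component!r}")

    if component in ("fruit", "fish", "milk"):
        if _missing(response):
            return None
        if response not in FOOD_CATEGORIES:
            raise ValueError(f"unknown frequency category {response!r}")
        # only the top category reaches >= 1/day (>= 7/week)
        return int(response == "almost_daily")

    if component == "activity":
        walk, sports = response
        if _missing(walk) or _missing(sports):
            return None
        if walk not in WALK_CATEGORIES or sports not in SPORTS_CATEGORIES:
            raise ValueError(f"unknown activity categories {response!r}")
        return int(walk in _HEALTHY_WALK or sports in _HEALTHY_SPORTS)

    if component == "bmi":
        if _missing(response):
            return None
        return int(21.0 <= float(response) <= 25.0)

    if component == "alcohol":
        if isinstance(response, tuple):
            status, grams = response
        else:
            status, grams = "drinker", response
        if _missing(status):
            return None
        if status == "non_drinker":
            return 1
        if status != "drinker":
            raise ValueError(f"unknown drinker status {status!r}")
        if _missing(grams):
            return None
        return int(1.0 <= float(grams) <= 46.0)

    if component == "smoking":
        if _missing(response):
            return None
        if response not in SMOKING_CATEGORIES:
            raise ValueError(f"unknown smoking status {response!r}")
        if smoking_rule == "current":
            return int(response != "current")
        if smoking_rule == "never":
            return int(response == "never")
        raise ValueError(f"unknown smoking rule {smoking_rule!r}")

    # sleep
    if _missing(response):
        return None
    return int(5.5 <= float(response) <= 7.4)


def band_of(total: int) -> str:
    """The score band containing a 0-8 total."""
    for label, (lo, hi) in _BAND_RANGES.items():
        if lo <= total <= hi:
            return label
    raise ValueError(f"score {total} outside 0-8")


class LifestyleScore:
    """Total, band and per-component flags for one subject."""

    def __init__(self, flags: dict):
        if set(flags) != set(COMPONENTS):
            raise ValueError("flags must cover exactly the eight components")
        self.per_component = dict(flags)
        self.total = int(sum(flags.values()))
        self.band = band_of(self.total)

    def __repr__(self):
        return f"LifestyleScore(total={self.total}, band={self.band!r})"


def total_score(responses: dict, *, smoking_rule: str = "current") -> LifestyleScore:
    """Score all eight components; any unscorable component raises.

    ``responses`` maps component name to its raw response (see
    :func:`score_component`).
    """
    flags = {}
    for comp in COMPONENTS:
        flag = score_component(comp, responses.get(comp), smoking_rule=smoking_rule)
        if flag is None:
            raise ValueError(f"component {comp!r} unscorable (missing response)")
        flags[comp] = flag
    return LifestyleScore(flags)


def _component_flags_frame(df: pd.DataFrame, smoking_rule: str) -> pd.DataFrame:
    """Vectorised per-component flags; NaN marks unscorable."""
    out = pd.DataFrame(index=df.index)
    for comp, col in (("fruit", "fruit_freq"), ("fish", "fish_freq"),
                      ("milk", "milk_freq")):
        s = df[col]
        out[f"pt_{comp}"] = np.where(s.isna() | (s == ""), np.nan,
                                     (s == "almost_daily").astype(float))
    walk, sports = df["walk_cat"], df["sports_cat"]
    act = (walk.isin(_HEALTHY_WALK) | sports.isin(_HEALTHY_SPORTS)).astype(float)
    out["pt_activity"] = np.where(walk.isna() | (walk == "") |
                                  sports.isna() | (sports == ""), np.nan, act)
    bmi = pd.to_numeric(df["bmi"], errors="coerce")
    out["pt_bmi"] = np.where(bmi.isna(), np.nan,
                             ((bmi >= 21.0) & (bmi <= 25.0)).astype(float))
    status = df["drinker_status"]
    grams = pd.to_numeric(df["ethanol_gday"], errors="coerce")
    alc = np.where(status == "non_drinker", 1.0,
                   ((grams >= 1.0) & (grams <= 46.0)).astype(float))
    alc = np.where(status.isna() | (status == "") |
                   ((status == "drinker") & grams.isna()), np.nan, alc)
    out["pt_alcohol"] = alc
    smoke = df["smoking_status"]
    if smoking_rule == "current":
        sm = (smoke != "current").astype(float)
    elif smoking_rule == "never":
        sm = (smoke == "never").astype(float)
    else:
        raise ValueError(f"unknown smoking rule {smoking_rule!r}")
    out["pt_smoking"] = np.where(smoke.isna() | (smoke == ""), np.nan, sm)
    sleep = pd.to_numeric(df["sleep_hours"], errors="coerce")
    out["pt_sleep"] = np.where(sleep.isna(), np.nan,
                               ((sleep >= 5.5) & (sleep <= 7.4)).astype(float))
    return out


def score_records(df: pd.DataFrame, *, smoking_rule: str = "current") -> pd.DataFrame:
    """Attach pt_* flags, score_total and score_band columns.

    Rows with any unscorable component get NaN total and band; they
    are kept here and removed by :func:`complete_case_filter`.
    """
    flags = _component_flags_frame(df, smoking_rule)
    out = df.copy()
    for col in flags.columns:
        out[col] = flags[col]
    complete = flags.notna().all(axis=1)
    total = flags.sum(axis=1, skipna=False)
    out["score_total"] = total
    out["score_band"] = [band_of(int(t)) if ok else pd.NA
                         for t, ok in zip(total, complete)]
    return out


def complete_case_filter(df: pd.DataFrame):
    """Keep records with all eight components scorable.

    Returns ``(kept, report)`` where the report counts exclusions by
    sex and by missing component.  ``df`` must already carry pt_*
    columns (see :func:`score_records`).
    """
    pt_cols = [f"pt_{c}" for c in COMPONENTS]
    missing_any = df[pt_cols].isna().any(axis=1)
    kept = df[~missing_any].copy()
    excl = df[missing_any]
    report = {
        "n_input": int(len(df)),
        "n_kept": int(len(kept)),
        "n_excluded": int(len(excl)),
        "by_component": {c: int(excl[f"pt_{c}"].isna().sum()) for c in COMPONENTS
                         if excl[f"pt_{c}"].isna().any()},
        "by_sex": {s: int((excl["sex"] == s).sum())
                   for s in sorted(excl["sex"].dropna().unique())} if "sex" in df else {},
    }
    return kept, report
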