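"""Period life tables from fitted Gompertz hazards.

Single-year tables run from age 40 to 102 with a radix of 100,000 at
age 40: ``qx`` is the one-year death probability from the model's
conditional survival, ``lx`` the survivor curve, ``dx`` deaths, ``Lx``
person-years in the interval (deaths counted mid-interval), ``Tx`` the
person-years above x and ``ex = Tx / lx`` the remaining life
expectancy.  The open interval at the terminal age is closed with the
model's analytic remaining expectancy (the mean residual life of the
Gompertz law, an exponential-integral expression), so the tabulated
``e40`` matches the analytic mean rather than truncating at 102; a
hard close-out (q = 1 at the terminal age) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .gompertz import cumhaz_factor

__all__ = [
    "LifeTable",
    "gompertz_life_table",
    "life_table_from_qx",
    "closed_form_expectancy",
    "lifetime_gain",
    "compare_to_reference",
    "read_reference_table",
    "ReferenceComparison",
]


def _e1_scaled(z):
    """exp(z) * E1(z), stable for large z.

    Direct evaluation overflows once exp(z) does; beyond z = 50 the
    classical continued fraction for E1 gives the scaled product
    directly.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    out = np.empty_like(z)
    small = z <= 50.0
    out[small] = np.exp(z[small]) * special.exp1(z[small])
    big = ~small
    if np.any(big):
        zb = z[big]
        # E1(z) = e^{-z} / (z + 1 - 1^2/(z + 3 - 2^2/(z + 5 - ...)))
        cf = np.zeros_like(zb)
        for k in range(60, 0, -1):
            cf = k * k / (zb + 2 * k + 1 - cf)
        out[big] = 1.0 / (zb + 1.0 - cf)
    return out if out.size > 1 else float(out[0])


def closed_form_expectancy(lambda_: float, gamma: float, linpred=0.0,
                           age=40.0, origin: float = 40.0):
    """Mean residual life of the Gompertz PH law at ``age``.

    With theta = lambda * exp(linpred) and
    z = (theta / gamma) * exp(gamma * (age - origin)), the remaining
    expectancy is exp(z) * E1(z) / gamma; the gamma = 0 limit is the
    exponential mean 1 / theta.  Broadcasts over ``linpred`` and
    ``age``.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    if gamma < 0:
        raise ValueError("gamma < 0: defective survival, expectancy undefined")
    theta = lambda_ * np.exp(np.asarray(linpred, dtype=float))
    if gamma < 1e-12:
        out = 1.0 / theta * np.ones_like(np.asarray(age, float))
        return float(out) if np.ndim(out) == 0 else out
    z = theta / gamma * np.exp(gamma * (np.asarray(age, float) - origin))
    out = _e1_scaled(z) / gamma
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class LifeTable:
    """Period life table over [start, end] with its construction step.

    The row at age x describes the interval [x, x + step); the last row
    is the closed terminal interval.  Invariants (radix at the first
    age, monotone lx, dx = lx*qx, Tx = sum Ly, ex = Tx/lx,
    ex <= e_{x+step} + step) are asserted on construction.
    """

    ages: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray
    label: str = ""
    radix: float = 100_000.0
    step: float = 1.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        assert np.isclose(self.lx[0], self.radix), "first-age survivors != radix"
        assert np.all(np.diff(self.lx) <= 1e-9), "lx must be non-increasing"
        assert np.all((self.qx >= -1e-12) & (self.qx <= 1 + 1e-12)), "qx outside [0,1]"
        assert np.allclose(self.dx, self.lx * self.qx, atol=1e-6), "dx != lx*qx"
        assert np.allclose(self.Tx, np.cumsum(self.Lx[::-1])[::-1],
                           rtol=1e-10, atol=1e-6), "Tx != cumulative Lx"
        ok = self.lx > 0
        assert np.allclose(self.ex[ok], self.Tx[ok] / self.lx[ok],
                           rtol=1e-10, atol=1e-9), "ex != Tx/lx"
        assert np.all(np.diff(self.ex) >= -self.step - 1e-9), \
            "ex decreases faster than the interval width"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx, "lx": self.lx,
                             "dx": self.dx, "Lx": self.Lx, "Tx": self.Tx,
                             "ex": self.ex})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def expectancy_at(self, age: float) -> float:
        """ex at an age on the table grid."""
        idx = np.nonzero(np.isclose(self.ages, age))[0]
        if idx.size == 0:
            raise ValueError(f"age {age} not on the table grid")
        return float(self.ex[idx[0]])

    def survival(self) -> np.ndarray:
        """lx rescaled to survival probability from the first age."""
        return self.lx / self.lx[0]

    def plot(self, ax=None, **kwargs):
        """Survival curve lx/l_start against age."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ages, self.survival(), label=self.label or None, **kwargs)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("survival from age {:.0f}".format(self.ages[0]))
        if self.label:
            ax.legend()
        return ax


def _assemble(ages, qx, lx, Lx_last, sep, step, radix, label):
    dx = lx * qx
    Lx = np.empty_like(lx)
    Lx[:-1] = step * lx[1:] + sep * step * dx[:-1]
    Lx[-1] = Lx_last
    Tx = np.cumsum(Lx[::-1])[::-1]
    ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)
    return LifeTable(ages=ages, qx=qx, lx=lx, dx=dx, Lx=Lx, Tx=Tx, ex=ex,
                     label=label, radix=radix, step=step)


def gompertz_life_table(lambda_: float, gamma: float, linpred: float = 0.0, *,
                        start: float = 40.0, end: float = 102.0,
                        radix: float = 100_000.0, step: float = 1.0,
                        sep_factor: float = 0.5, terminal: str = "tail",
                        origin: float = 40.0, label: str = "") -> LifeTable:
    """Build a life table from a Gompertz PH hazard.

    Parameters
    ----------
    lambda_, gamma, linpred : hazard level at the origin, log-slope per
        year, and covariate log-hazard offset.
    start, end : first age and terminal age of the table.
    step : interval width in years (1.0 for single-year tables, 1/12
        for monthly refinement).
    sep_factor : fraction of the interval lived by those dying in it.
    terminal : 'tail' closes the last interval with the analytic
        remaining expectancy at ``end``; 'close' forces q = 1 there.
    """
    if end <= start:
        raise ValueError("end must exceed start")
    if gamma < 0:
        raise ValueError(
            f"gamma < 0 gives a defective survival; cannot tabulate profile "
            f"{label or linpred!r}")
    theta = lambda_ * np.exp(linpred)
    n = int(round((end - start) / step))
    ages = start + step * np.arange(n + 1)
    e_rel = ages[:-1] - origin
    q = 1.0 - np.exp(-theta * cumhaz_factor(gamma, e_rel, e_rel + step))
    surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    lx = radix * surv
    if terminal == "tail":
        qx = np.concatenate([q, [1.0]])
        e_tail = closed_form_expectancy(lambda_, gamma, linpred, age=end,
                                        origin=origin)
        Lx_last = lx[-1] * e_tail
    elif terminal == "close":
        qx = np.concatenate([q, [1.0]])
        Lx_last = sep_factor * step * lx[-1]
    else:
        raise ValueError(f"unknown terminal mode {terminal!r}")
    return _assemble(ages, qx, lx, Lx_last, sep_factor, step, radix, label)


def life_table_from_qx(ages, qx, *, radix: float = 100_000.0,
                       sep_factor: float = 0.5, label: str = "") -> LifeTable:
    """Life table from given one-year death probabilities (hard close-out).

    Used for external reference tables supplied as (age, qx); the last
    interval is closed with q = 1.
    """
    ages = np.asarray(ages, dtype=float)
    qx = np.asarray(qx, dtype=float).copy()
    if ages.size != qx.size or ages.size < 2:
        raise ValueError("need matching age/qx arrays of length >= 2")
    step = float(ages[1] - ages[0])
    qx[-1] = 1.0
    surv = np.concatenate([[1.0], np.cumprod(1.0 - qx[:-1])])
    lx = radix * surv
    Lx_last = sep_factor * step * lx[-1]
    return _assemble(ages, qx, lx, Lx_last, sep_factor, step, radix, label)


def lifetime_gain(table: LifeTable, reference: LifeTable,
                  index_age: float) -> float:
    """Difference in remaining life expectancy at ``index_age``.

    Positive values mean ``table``'s stratum outlives the reference
    stratum (conventionally the 0-2 score band).
    """
    if table.ages.shape != reference.ages.shape or \
            not np.allclose(table.ages, reference.ages):
        raise ValueError("life tables are on different age grids")
    return table.expectancy_at(index_age) - reference.expectancy_at(index_age)


@dataclass
class ReferenceComparison:
    """Per-age survival differences against a reference table."""

    frame: pd.DataFrame            # age, s_cohort, s_ref, diff
    max_abs_diff: float            # over the comparison window
    window: tuple
    e_start_diff: float            # difference in remaining expectancy at the first common age

    def __str__(self) -> str:
        lo, hi = self.window
        return (f"max |survival difference| over ages {lo:g}-{hi:g}: "
                f"{self.max_abs_diff:.4f}; e{self.frame['age'].iloc[0]:.0f} "
                f"difference: {self.e_start_diff:+.2f} years")


def read_reference_table(path) -> pd.DataFrame:
    """Read a reference life table CSV with columns age + (qx or lx)."""
    df = pd.read_csv(path)
    if "age" not in df.columns or not ({"qx", "lx"} & set(df.columns)):
        raise ValueError("reference table needs columns age and qx or lx")
    if "qx" not in df.columns:
        lx = df["lx"].to_numpy(float)
        qx = np.empty_like(lx)
        qx[:-1] = 1.0 - lx[1:] / lx[:-1]
        qx[-1] = 1.0
        df = df.assign(qx=qx)
    return df[["age", "qx"]]


def compare_to_reference(table: LifeTable, reference: pd.DataFrame | LifeTable,
                         window: tuple = (40.0, 95.0)) -> ReferenceComparison:
    """Compare a cohort life table with a reference table.

    Reports the per-age difference in survival from the first common
    age (lx/l_start scale), the maximum absolute difference over
    ``window`` and the difference in remaining life expectancy at the
    first common age.
    """
    if isinstance(reference, pd.DataFrame):
        reference = life_table_from_qx(reference["age"], reference["qx"],
                                       label="reference")
    common = np.intersect1d(np.round(table.ages, 6), np.round(reference.ages, 6))
    if common.size == 0:
        raise ValueError("no overlapping ages between the tables")
    ia = np.isin(np.round(table.ages, 6), common)
    ib = np.isin(np.round(reference.ages, 6), common)
    s_a = table.lx[ia] / table.lx[ia][0]
    s_b = reference.lx[ib] / reference.lx[ib][0]
    frame = pd.DataFrame({"age": common, "s_cohort": s_a, "s_ref": s_b,
                          "diff": s_a - s_b})
    inwin = (frame["age"] >= window[0]) & (frame["age"] <= window[1])
    max_abs = float(frame.loc[inwin, "diff"].abs().max())
    e_diff = float(table.ex[ia][0] - reference.ex[ib][0])
    return ReferenceComparison(frame=frame, max_abs_diff=max_abs,
                               window=window, e_start_diff=e_diff)
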