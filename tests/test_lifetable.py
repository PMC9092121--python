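"""Life-table construction, closed-form expectancy, gains and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from lifegain import (LifeTable, closed_form_expectancy, compare_to_reference,
                      gompertz_life_table, life_table_from_qx, lifetime_gain,
                      read_reference_table)


# --------------------------------------------------------- closed-form oracle

def test_exponential_limit_mean():
    assert closed_form_expectancy(0.02, 0.0) == pytest.approx(50.0)
    # theta scales with the linear predictor
    assert closed_form_expectancy(0.01, 0.0, linpred=np.log(2.0)) == \
        pytest.approx(50.0)


def test_expectancy_matches_numerical_integration():
    lam, gam = 1e-4, 0.1
    s = lambda t: np.exp(-lam / gam * (np.exp(gam * (t - 40)) - 1.0))
    oracle, _ = integrate.quad(s, 40.0, 400.0, epsabs=1e-12, epsrel=1e-12)
    assert closed_form_expectancy(lam, gam, age=40.0) == pytest.approx(
        oracle, abs=1e-6)


def test_expectancy_conditional_on_age_matches_integration():
    lam, gam, age = 3e-4, 0.09, 70.0
    z0 = lam / gam * np.exp(gam * (age - 40))
    s = lambda t: np.exp(z0 - lam / gam * np.exp(gam * (t - 40)))
    oracle, _ = integrate.quad(s, age, 400.0, epsabs=1e-12, epsrel=1e-12)
    assert closed_form_expectancy(lam, gam, age=age) == pytest.approx(
        oracle, abs=1e-6)


def test_mean_residual_life_inequality():
    lam, gam = 2e-4, 0.11
    ages = np.arange(40.0, 100.0, 5.0)
    e = np.array([closed_form_expectancy(lam, gam, age=a) for a in ages])
    for i in range(len(ages) - 1):
        gap = ages[i + 1] - ages[i]
        assert e[i] < e[i + 1] + gap
        assert e[i] >= e[i + 1] - 1e-12 + 0  # expectancy declines with age here


def test_defective_gamma_rejected():
    with pytest.raises(ValueError):
        closed_form_expectancy(1e-4, -0.05)
    with pytest.raises(ValueError):
        gompertz_life_table(1e-4, -0.05)


def test_scaled_e1_large_argument():
    # internal stability check: expectancy finite and positive for very high hazards
    e = closed_form_expectancy(0.5, 0.01, age=102.0)
    assert 0 < e < 2.0


# ----------------------------------------------------------- table building

def test_constant_hazard_hand_recursion():
    t = gompertz_life_table(0.5, 0.0, start=40, end=42, terminal="close")
    q = 1 - np.exp(-0.5)
    assert t.qx[0] == pytest.approx(q) and t.qx[1] == pytest.approx(q)
    assert t.lx[1] == pytest.approx(100_000 * np.exp(-0.5), rel=1e-12)
    assert t.lx[1] == pytest.approx(60_653.066, abs=0.01)


def test_negligible_hazard_gives_flat_survivors():
    t = gompertz_life_table(1e-8, 0.0, terminal="close")
    assert np.allclose(t.lx, 100_000.0, rtol=1e-5)
    # remaining expectancy = years to the table end + the close-out half-year
    assert np.allclose(t.ex, (t.ages[-1] - t.ages) + 0.5, atol=1e-3)
    # exponential tail: memoryless, so ex is flat at 1/lambda
    tail = gompertz_life_table(1e-8, 0.0, terminal="tail")
    assert np.allclose(tail.ex, 1e8, rtol=1e-4)


def test_single_year_table_matches_closed_form():
    lam, gam = 1e-4, 0.1
    t = gompertz_life_table(lam, gam)
    assert abs(t.expectancy_at(40.0) -
               closed_form_expectancy(lam, gam, age=40.0)) < 0.05


def test_monthly_refinement_converges():
    lam, gam = 5e-4, 0.12
    e_closed = closed_form_expectancy(lam, gam, age=40.0)
    monthly = gompertz_life_table(lam, gam, step=1 / 12)
    assert abs(monthly.expectancy_at(40.0) - e_closed) < 0.02


def test_terminal_treatments_and_errors():
    lam, gam = 5e-4, 0.1
    tail = gompertz_life_table(lam, gam, terminal="tail")
    hard = gompertz_life_table(lam, gam, terminal="close")
    # the hard close-out truncates person-years beyond 102
    assert tail.expectancy_at(40.0) > hard.expectancy_at(40.0)
    assert hard.qx[-1] == 1.0
    with pytest.raises(ValueError):
        gompertz_life_table(lam, gam, start=60, end=60)
    with pytest.raises(ValueError):
        gompertz_life_table(lam, gam, terminal="nope")


@settings(derandomize=True, max_examples=40, deadline=None)
@given(lam=st.floats(1e-5, 1e-3), gam=st.floats(0.05, 0.14),
       lp=st.floats(-0.8, 0.4),
       terminal=st.sampled_from(["tail", "close"]))
def test_table_invariants_hold_by_construction(lam, gam, lp, terminal):
    """Radix, monotone lx, dx = lx qx, Tx = sum Ly, ex = Tx/lx all assert on build."""
    t = gompertz_life_table(lam, gam, linpred=lp, terminal=terminal)
    t.validate()  # explicit, beyond the constructor
    assert t.lx[0] == 100_000.0
    assert np.all(np.diff(t.ex) >= -1.0 - 1e-9)


def test_proportional_hazards_ordering():
    lam, gam = 3e-4, 0.1
    low = gompertz_life_table(lam, gam, linpred=-0.5)
    high = gompertz_life_table(lam, gam, linpred=0.2)
    assert np.all(low.ex >= high.ex - 1e-12)
    assert np.all(low.lx >= high.lx)


# ------------------------------------------------------------------ gains

def test_gain_against_self_is_zero_and_dominance():
    t = gompertz_life_table(3e-4, 0.1)
    assert lifetime_gain(t, t, 40.0) == 0.0
    better = gompertz_life_table(3e-4, 0.1, linpred=-0.4)
    assert lifetime_gain(better, t, 40.0) > 0
    assert lifetime_gain(better, t, 80.0) > 0


def test_gain_matches_closed_form_difference():
    lam, gam = 2e-4, 0.1
    a = gompertz_life_table(lam, gam, linpred=-0.6)   # 6 points at -0.1/point
    ref = gompertz_life_table(lam, gam, linpred=0.0)
    closed = (closed_form_expectancy(lam, gam, linpred=-0.6, age=40.0) -
              closed_form_expectancy(lam, gam, linpred=0.0, age=40.0))
    assert lifetime_gain(a, ref, 40.0) == pytest.approx(closed, abs=0.05)


def test_gain_additivity_and_grid_mismatch():
    lam, gam = 3e-4, 0.11
    ta = gompertz_life_table(lam, gam, linpred=-0.5)
    tb = gompertz_life_table(lam, gam, linpred=-0.2)
    tc = gompertz_life_table(lam, gam, linpred=0.1)
    for age in (40.0, 65.0):
        assert lifetime_gain(ta, tc, age) == pytest.approx(
            lifetime_gain(ta, tb, age) + lifetime_gain(tb, tc, age), abs=1e-9)
    short = gompertz_life_table(lam, gam, end=100)
    with pytest.raises(ValueError, match="grid"):
        lifetime_gain(ta, short, 40.0)


# ------------------------------------------------------- reference comparison

def test_reference_comparison_identical_and_doubled(tmp_path):
    lam, gam = 4e-4, 0.1
    t = gompertz_life_table(lam, gam)
    ref_q = pd.DataFrame({"age": t.ages, "qx": t.qx})
    same = compare_to_reference(t, ref_q)
    assert same.max_abs_diff == pytest.approx(0.0, abs=1e-12)
    doubled = pd.DataFrame({"age": t.ages, "qx": np.clip(t.qx * 2, 0, 1)})
    worse = compare_to_reference(t, doubled)
    beyond41 = worse.frame["age"] > 41
    assert (worse.frame.loc[beyond41, "diff"] > 0).all()
    assert worse.e_start_diff > 0


def test_reference_reader_accepts_lx(tmp_path):
    t = gompertz_life_table(4e-4, 0.1)
    p = tmp_path / "ref.csv"
    pd.DataFrame({"age": t.ages, "lx": t.lx}).to_csv(p, index=False)
    ref = read_reference_table(p)
    assert np.allclose(ref["qx"].to_numpy()[:-1], t.qx[:-1], atol=1e-12)
    with pytest.raises(ValueError):
        bad = tmp_path / "bad.csv"
        pd.DataFrame({"age": [40]}).to_csv(bad, index=False)
        read_reference_table(bad)


def test_reference_comparison_requires_overlap():
    a = gompertz_life_table(4e-4, 0.1, start=40, end=60)
    b = life_table_from_qx(np.arange(70.0, 80.0), np.full(10, 0.1))
    with pytest.raises(ValueError, match="overlap"):
        compare_to_reference(a, b)


def test_fitted_cohort_table_self_consistent_at_large_n():
    """Fit a big uncensored cohort and compare with its own generating table."""
    from lifegain import GompertzPH, SimulationConfig, generate_cohort
    cfg = SimulationConfig(n_men=50_000, n_women=0, true_betas={},
                           moveout_rate=0.0, seed=44)
    df, _ = generate_cohort(cfg)
    res = GompertzPH(df["entry_age"], df["exit_age"], df["event"]).fit()
    fitted = res.life_table()
    truth_q = gompertz_life_table(cfg.true_lambda["M"], cfg.true_gamma["M"])
    cmp_ = compare_to_reference(fitted,
                                pd.DataFrame({"age": truth_q.ages,
                                              "qx": truth_q.qx}))
    assert cmp_.max_abs_diff <= 0.01


def test_csv_round_trip(tmp_path):
    t = gompertz_life_table(3e-4, 0.1, label="men 7-8")
    p = tmp_path / "lt.csv"
    t.write_csv(p)
    back = pd.read_csv(p)
    assert list(back.columns) == ["age", "qx", "lx", "dx", "Lx", "Tx", "ex"]
    assert np.allclose(back["ex"], t.ex)
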