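"""Gompertz proportional-hazards regression with delayed entry.

The mortality model is

    h(a | x) = lambda * exp(gamma * (a - origin)) * exp(x' beta),

with age ``a`` as the time axis (origin 40 by default).  Subjects enter
observation at their baseline age, so the likelihood conditions on
survival to entry (left truncation).  The module follows the
statsmodels convention: :class:`GompertzPH` is built from data and
``fit()`` / ``fit_bayes()`` return results objects that carry the
estimates, their covariance and derived quantities (hazard ratios,
life tables, remaining life expectancies).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "GompertzPH",
    "GompertzPHResults",
    "GompertzPHBayesResults",
    "ConvergenceError",
    "build_design",
    "cumhaz_factor",
]

BAND_LABELS = ("0-2", "3", "4", "5", "6", "7-8")


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimiser fails for a stratum."""


def cumhaz_factor(gamma: float, e, t):
    """Age integral of the baseline shape: int_e^t exp(gamma*s) ds.

    ``e`` and ``t`` are ages measured from the origin.  The gamma -> 0
    limit (t - e) is taken analytically so the exponential special case
    is exact.
    """
    e = np.asarray(e, dtype=float)
    t = np.asarray(t, dtype=float)
    if abs(gamma) < 1e-12:
        return t - e
    return np.exp(gamma * e) * np.expm1(gamma * (t - e)) / gamma


def _cumhaz_factor_dgamma(gamma: float, e, t):
    """d/dgamma of :func:`cumhaz_factor`."""
    e = np.asarray(e, dtype=float)
    t = np.asarray(t, dtype=float)
    if abs(gamma) < 1e-6:
        return 0.5 * (t * t - e * e)
    g = cumhaz_factor(gamma, e, t)
    return (t * np.exp(gamma * t) - e * np.exp(gamma * e) - g) / gamma


# ---------------------------------------------------------------------------
# design-matrix helpers

_FLAG_COLUMNS = {
    "family_history_cvd": "family_history_cvd",
    "comorbid_cvd": "comorbid_cvd",
    "comorbid_cancer": "comorbid_cancer",
    "comorbid_hypertension": "comorbid_hypertension",
    "comorbid_diabetes": "comorbid_diabetes",
    "comorbid_kidney": "comorbid_kidney",
}


def build_design(df: pd.DataFrame, covariates, reference_band: str = "0-2"):
    """Expand covariate names into a numeric design matrix.

    Supported names: ``"band"`` (score-band indicators against the
    reference band), ``"score"`` (the 0-8 total as a linear term),
    ``"sex"`` (indicator of female), ``"education"`` (indicator of
    college or higher), the binary flag columns (family history and the
    five comorbidities), or any numeric column already in ``df``.

    Returns ``(X, names)`` with ``X`` of shape (n, p).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov == "band":
            bands = [b for b in BAND_LABELS if b != reference_band]
            for b in bands:
                cols.append((df["score_band"] == b).to_numpy(float))
                names.append(f"band_{b}")
        elif cov == "score":
            cols.append(df["score_total"].to_numpy(float))
            names.append("score")
        elif cov == "sex":
            cols.append((df["sex"] == "F").to_numpy(float))
            names.append("sex_female")
        elif cov == "education":
            cols.append((df["education"] == "college_or_higher").to_numpy(float))
            names.append("education")
        elif cov in _FLAG_COLUMNS:
            cols.append(df[cov].to_numpy(float))
            names.append(cov)
        elif cov in df.columns:
            cols.append(df[cov].to_numpy(float))
            names.append(cov)
        else:
            raise KeyError(f"unknown covariate {cov!r}")
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# model


class GompertzPH:
    """Gompertz proportional-hazards model on the age scale.

    Parameters
    ----------
    entry_age, exit_age : array-like
        Ages (years) at entry into and exit from observation; the
        likelihood conditions on survival to ``entry_age``.
    event : array-like of {0, 1}
        1 if the subject died at ``exit_age``, 0 if censored.
    exog : ndarray (n, p), optional
        Covariate matrix acting log-linearly on the hazard.
    names : sequence of str
        Covariate names (length p).
    age_origin : float
        Age at which ``lambda`` is the baseline hazard (default 40).
    label : str
        Stratum label (e.g. the sex) used in messages.
    """

    def __init__(self, entry_age, exit_age, event, exog=None, names=(),
                 age_origin: float = 40.0, label: str = ""):
        entry = np.asarray(entry_age, dtype=float)
        exit_ = np.asarray(exit_age, dtype=float)
        ev = np.asarray(event, dtype=float)
        if entry.shape != exit_.shape or entry.shape != ev.shape:
            raise ValueError("entry_age, exit_age and event must share a shape")
        if np.any(exit_ < entry):
            raise ValueError("exit_age < entry_age for some subjects")
        if exog is None:
            exog = np.empty((entry.size, 0))
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        if exog.shape[0] != entry.size:
            raise ValueError("exog row count does not match subjects")
        if len(names) != exog.shape[1]:
            names = tuple(f"x{i}" for i in range(exog.shape[1]))
        self.entry = entry
        self.exit = exit_
        self.event = ev
        self.exog = exog
        self.exog_names = list(names)
        self.age_origin = float(age_origin)
        self.label = label
        self._e = entry - self.age_origin
        self._t = exit_ - self.age_origin
        self.param_names = ["log_lambda", "gamma"] + self.exog_names

    # -- constructors -------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates=(), sex=None,
                       reference_band: str = "0-2", age_origin: float = 40.0,
                       label: str | None = None):
        """Build the model from a cohort table (see the cohort schema).

        ``sex`` filters to one stratum ('M' or 'F'); ``covariates``
        are expanded by :func:`build_design`.
        """
        if sex is not None:
            df = df[df["sex"] == sex]
            if label is None:
                label = {"M": "men", "F": "women"}.get(sex, str(sex))
        X, names = build_design(df, covariates, reference_band=reference_band)
        return cls(df["entry_age"].to_numpy(float), df["exit_age"].to_numpy(float),
                   df["event"].to_numpy(float), X, names,
                   age_origin=age_origin, label=label or "")

    @property
    def nobs(self) -> int:
        return self.entry.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    # -- likelihood ---------------------------------------------------

    def loglike(self, params) -> float:
        """Left-truncated log likelihood at ``params = (log lambda, gamma, beta...)``."""
        params = np.asarray(params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite parameters")
        if self.nobs == 0:
            return 0.0
        a, gamma = params[0], params[1]
        beta = params[2:]
        xb = self.exog @ beta if beta.size else np.zeros(self.nobs)
        eta = a + xb
        with np.errstate(over="ignore", invalid="ignore"):
            g = cumhaz_factor(gamma, self._e, self._t)
            ll = np.sum(self.event * (eta + gamma * self._t)) - \
                np.sum(np.exp(eta) * g)
        # overflow at an extreme trial point: treat as arbitrarily unlikely
        return float(ll) if np.isfinite(ll) else -1e300

    def score(self, params) -> np.ndarray:
        """Gradient of :meth:`loglike`."""
        params = np.asarray(params, dtype=float)
        if self.nobs == 0:
            return np.zeros(params.size)
        a, gamma = params[0], params[1]
        beta = params[2:]
        xb = self.exog @ beta if beta.size else np.zeros(self.nobs)
        with np.errstate(over="ignore", invalid="ignore"):
            theta = np.exp(a + xb)
            g = cumhaz_factor(gamma, self._e, self._t)
            dg = _cumhaz_factor_dgamma(gamma, self._e, self._t)
            hm = theta * g
            grad = np.empty(params.size)
            grad[0] = np.sum(self.event) - np.sum(hm)
            grad[1] = np.sum(self.event * self._t) - np.sum(theta * dg)
            if beta.size:
                grad[2:] = self.exog.T @ (self.event - hm)
        return np.where(np.isfinite(grad), grad, 0.0)

    def hessian(self, params) -> np.ndarray:
        """Observed-information Hessian via central differences of the score."""
        params = np.asarray(params, dtype=float)
        p = params.size
        H = np.empty((p, p))
        for j in range(p):
            h = 1e-5 * (1.0 + abs(params[j]))
            up = params.copy(); up[j] += h
            dn = params.copy(); dn[j] -= h
            H[:, j] = (self.score(up) - self.score(dn)) / (2 * h)
        return 0.5 * (H + H.T)

    # -- fitting ------------------------------------------------------

    def _start_params(self, gamma0: float = 0.09) -> np.ndarray:
        py = np.sum(self._t - self._e)
        d = self.event.sum()
        rate = max(d, 0.5) / max(py, 1e-12)
        mid = np.mean(0.5 * (self._e + self._t))
        a0 = float(np.clip(np.log(rate) - gamma0 * mid, -20.0, 0.0))
        return np.concatenate([[a0, gamma0], np.zeros(self.exog.shape[1])])

    def _check_exog(self) -> None:
        X = self.exog
        if X.shape[1] == 0:
            return
        if np.any(np.ptp(X, axis=0) == 0):
            j = int(np.argmin(np.ptp(X, axis=0)))
            raise ValueError(f"constant covariate column {self.exog_names[j]!r}")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear covariate columns")

    def fit(self, start_params=None, fix_gamma: float | None = None,
            maxiter: int = 500, gtol: float = 1e-6) -> "GompertzPHResults":
        """Maximum-likelihood fit.

        BFGS followed by Newton polishing until the gradient max-norm is
        below ``gtol``.  ``fix_gamma`` pins the slope (the exponential
        model is ``fix_gamma=0``).  The covariance is the inverse
        observed information at the optimum.
        """
        if self.n_events < 1:
            raise ValueError(f"zero events in stratum {self.label!r}")
        self._check_exog()
        free = np.ones(2 + self.exog.shape[1], dtype=bool)
        if fix_gamma is not None:
            free[1] = False
        x0 = np.asarray(start_params, float) if start_params is not None \
            else self._start_params(gamma0=fix_gamma if fix_gamma is not None else 0.09)
        if fix_gamma is not None:
            x0[1] = fix_gamma

        def pack(full):
            return full[free]

        def unpack(sub):
            full = x0.copy()
            full[free] = sub
            if fix_gamma is not None:
                full[1] = fix_gamma
            return full

        def nll(sub):
            return -self.loglike(unpack(sub))

        def njac(sub):
            return -self.score(unpack(sub))[free]

        res = optimize.minimize(nll, pack(x0), jac=njac, method="BFGS",
                                options={"gtol": 1e-5, "maxiter": maxiter})
        params = unpack(res.x)
        niter = int(res.nit)
        # Newton polish: quadratic convergence to the stated gradient tolerance
        for _ in range(50):
            grad = self.score(params)[free]
            if np.max(np.abs(grad)) <= gtol:
                break
            H = self.hessian(params)[np.ix_(free, free)]
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, -grad, rcond=None)[0]
            ll0 = self.loglike(params)
            scale = 1.0
            for _ in range(30):
                cand = params.copy()
                cand[free] = params[free] + scale * step
                if np.isfinite(self.loglike(cand)) and self.loglike(cand) >= ll0 - 1e-10:
                    break
                scale *= 0.5
            params = cand
            niter += 1
        else:
            raise ConvergenceError(
                f"Gompertz PH fit did not converge for stratum {self.label!r}")
        grad = self.score(params)[free]
        if np.max(np.abs(grad)) > gtol:
            raise ConvergenceError(
                f"Gompertz PH fit did not converge for stratum {self.label!r} "
                f"(gradient max-norm {np.max(np.abs(grad)):.2e})")

        H = self.hessian(params)[np.ix_(free, free)]
        try:
            cov_free = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov_free = np.linalg.pinv(-H)
        cov = np.zeros((params.size, params.size))
        cov[np.ix_(free, free)] = cov_free

        if params[1] < 0 and fix_gamma is None:
            warnings.warn(
                f"fitted gamma < 0 in stratum {self.label!r}: defective survival, "
                "implausible for adult mortality", RuntimeWarning, stacklevel=2)
        betas = params[2:]
        if betas.size and np.max(np.abs(betas)) > 10:
            warnings.warn(
                f"very large |beta| in stratum {self.label!r}: possible separation "
                "(a covariate level with no events)", RuntimeWarning, stacklevel=2)
        return GompertzPHResults(self, params, cov, free,
                                 loglik=self.loglike(params), niter=niter)

    def fit_bayes(self, priors: dict | None = None, method: str = "laplace",
                  draws: int = 1000, seed: int = 0, scale: float = 1.0,
                  burn: int = 1000) -> "GompertzPHBayesResults":
        """Bayesian fit with independent normal priors.

        Default priors: Normal(0, 10) on log lambda and each beta,
        Normal(0, 1) on gamma.  ``method='laplace'`` (default) draws from
        the multivariate-normal approximation at the posterior mode;
        ``method='metropolis'`` runs a random-walk sampler whose proposal
        is calibrated from the Laplace covariance.  Deterministic given
        ``seed``.  ``scale=0`` suppresses Laplace noise (every draw is
        the MAP), useful for degenerate-configuration checks.
        """
        p = 2 + self.exog.shape[1]
        sd = np.full(p, 10.0)
        sd[1] = 1.0
        mu = np.zeros(p)
        if priors:
            for i, name in enumerate(self.param_names):
                if name in priors:
                    m, s = priors[name]
                    mu[i], sd[i] = float(m), float(s)

        def logpost(params):
            lp = self.loglike(params)
            lp += float(np.sum(norm.logpdf(params, loc=mu, scale=sd)))
            if not np.isfinite(lp):
                raise ValueError("non-finite posterior")
            return lp

        def grad(params):
            return self.score(params) - (params - mu) / sd**2

        x0 = self.fit().params
        res = optimize.minimize(lambda x: -logpost(x), x0, jac=lambda x: -grad(x),
                                method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
        map_params = res.x
        H = self.hessian(map_params) - np.diag(1.0 / sd**2)
        cov = np.linalg.inv(-H)
        L = np.linalg.cholesky(0.5 * (cov + cov.T))
        rng = np.random.default_rng(seed)
        acceptance = None
        if method == "laplace":
            z = rng.standard_normal((draws, p))
            smp = map_params + scale * z @ L.T
        elif method == "metropolis":
            step = (2.38 / np.sqrt(p)) * L
            cur = map_params.copy()
            cur_lp = logpost(cur)
            smp = np.empty((draws, p))
            accepted = 0
            for i in range(burn + draws):
                prop = cur + step @ rng.standard_normal(p)
                lp = logpost(prop)
                if np.log(rng.uniform()) < lp - cur_lp:
                    cur, cur_lp = prop, lp
                    if i >= burn:
                        accepted += 1
                if i >= burn:
                    smp[i - burn] = cur
            acceptance = accepted / draws
            if not 0.1 <= acceptance <= 0.6:
                warnings.warn(f"Metropolis acceptance rate {acceptance:.2f} outside "
                              "[0.1, 0.6]", RuntimeWarning, stacklevel=2)
        else:
            raise ValueError(f"unknown method {method!r}")
        if not np.all(np.isfinite(smp)):
            raise ValueError("non-finite posterior draws")
        return GompertzPHBayesResults(self, smp, map_params, cov,
                                      method=method, seed=seed,
                                      acceptance=acceptance)


# ---------------------------------------------------------------------------
# results


class GompertzPHResults:
    """MLE results: parameters, covariance and derived summaries."""

    def __init__(self, model, params, cov, free=None, loglik=np.nan, niter=0):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.free = np.ones(self.params.size, bool) if free is None else np.asarray(free, bool)
        self.loglik = float(loglik)
        self.niter = niter
        if model is not None:
            self.param_names = list(model.param_names)
            self.nobs = model.nobs
            self.n_events = model.n_events
            self.age_origin = model.age_origin
            self.label = model.label
        # from_json fills these attributes directly otherwise

    # -- basic accessors ----------------------------------------------

    @property
    def lambda_(self) -> float:
        return float(np.exp(self.params[0]))

    @property
    def gamma(self) -> float:
        return float(self.params[1])

    @property
    def betas(self) -> dict[str, float]:
        return dict(zip(self.param_names[2:], self.params[2:]))

    def cov_params(self) -> np.ndarray:
        return self.cov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    # -- hazard ratios ------------------------------------------------

    def hazard_ratios(self, adjustment: str = "multivariable",
                      alpha: float = 0.05) -> pd.DataFrame:
        """Wald hazard ratios exp(beta) with level-(1-alpha) CIs.

        Age adjustment is intrinsic to the age time-scale; the
        ``adjustment`` label records whether the fitted model contained
        a single component ('age_only') or the full covariate set.
        """
        if self.cov is None or not np.all(np.isfinite(self.cov)):
            raise ValueError("missing covariance matrix")
        ci = self.conf_int(alpha)[2:]
        rows = []
        for i, name in enumerate(self.param_names[2:]):
            b = self.params[2 + i]
            rows.append({"covariate": name, "hr": float(np.exp(b)),
                         "ci_low": float(np.exp(ci[i, 0])),
                         "ci_high": float(np.exp(ci[i, 1])),
                         "adjustment": adjustment})
        return pd.DataFrame(rows)

    # -- derived life quantities --------------------------------------

    def linear_predictor(self, profile: dict | None = None) -> float:
        """x'beta for a covariate profile given as {name: value}; absent names are 0."""
        profile = profile or {}
        unknown = set(profile) - set(self.param_names[2:])
        if unknown:
            raise KeyError(f"profile names not in model: {sorted(unknown)}")
        return float(sum(self.betas[k] * v for k, v in profile.items()))

    def expectancy(self, age: float, profile: dict | None = None) -> float:
        """Closed-form remaining life expectancy at ``age`` for a profile."""
        from .lifetable import closed_form_expectancy
        return closed_form_expectancy(self.lambda_, self.gamma,
                                      linpred=self.linear_predictor(profile),
                                      age=age, origin=self.age_origin)

    def life_table(self, profile: dict | None = None, **kwargs):
        """Single-year life table for a covariate profile (see lifetable module)."""
        from .lifetable import gompertz_life_table
        kwargs.setdefault("label", self.label)
        return gompertz_life_table(self.lambda_, self.gamma,
                                   linpred=self.linear_predictor(profile),
                                   origin=self.age_origin, **kwargs)

    def survival(self, age, profile: dict | None = None, given_alive_at=None):
        """S(age | alive at ``given_alive_at``) under the fitted hazard."""
        e = self.age_origin if given_alive_at is None else given_alive_at
        theta = self.lambda_ * np.exp(self.linear_predictor(profile))
        g = cumhaz_factor(self.gamma, e - self.age_origin,
                          np.asarray(age, float) - self.age_origin)
        return np.exp(-theta * g)

    def sample_params(self, size: int, seed: int = 0) -> np.ndarray:
        """Draws from the normal approximation N(estimate, vcov).

        Fixed parameters stay at their fixed value.  This is the
        parameter-draw Monte-Carlo engine used for fast interval
        construction.
        """
        rng = np.random.default_rng(seed)
        sub = self.cov[np.ix_(self.free, self.free)]
        L = np.linalg.cholesky(0.5 * (sub + sub.T) + 1e-12 * np.eye(sub.shape[0]))
        z = rng.standard_normal((size, sub.shape[0]))
        out = np.tile(self.params, (size, 1))
        out[:, self.free] = self.params[self.free] + z @ L.T
        return out

    # -- reporting ----------------------------------------------------

    def summary(self) -> str:
        z = self.params[self.free] / np.where(self.bse[self.free] > 0,
                                              self.bse[self.free], np.nan)
        lines = [
            "Gompertz proportional-hazards regression (delayed entry)",
            f"Stratum: {self.label or '-'}   n = {self.nobs}   events = {self.n_events}",
            f"Age origin: {self.age_origin:.0f}   log-likelihood = {self.loglik:.3f}",
            "-" * 64,
            f"{'parameter':<22}{'estimate':>10}{'std err':>10}{'z':>9}{'HR':>9}",
        ]
        k = 0
        for i, name in enumerate(self.param_names):
            if not self.free[i]:
                lines.append(f"{name:<22}{self.params[i]:>10.4f}{'(fixed)':>10}")
                continue
            hr = f"{np.exp(self.params[i]):.3f}" if i >= 2 else ""
            lines.append(f"{name:<22}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                         f"{z[k]:>9.2f}{hr:>9}")
            k += 1
        lines.append("-" * 64)
        lines.append(f"lambda (hazard at {self.age_origin:.0f}) = {self.lambda_:.6g}"
                     f"   gamma = {self.gamma:.4f} /yr")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "param_names": self.param_names,
            "params": self.params.tolist(),
            "cov": self.cov.tolist(),
            "free": self.free.astype(int).tolist(),
            "loglik": self.loglik,
            "nobs": self.nobs,
            "n_events": self.n_events,
            "age_origin": self.age_origin,
            "label": self.label,
        })

    @classmethod
    def from_json(cls, text: str) -> "GompertzPHResults":
        d = json.loads(text)
        obj = cls(None, np.array(d["params"]), np.array(d["cov"]),
                  free=np.array(d["free"], bool), loglik=d["loglik"])
        obj.param_names = d["param_names"]
        obj.nobs = d["nobs"]
        obj.n_events = d["n_events"]
        obj.age_origin = d["age_origin"]
        obj.label = d["label"]
        return obj


@dataclass
class GompertzPHBayesResults:
    """Posterior draws over (log lambda, gamma, beta...)."""

    model: GompertzPH
    draws: np.ndarray
    map_params: np.ndarray
    cov: np.ndarray
    method: str = "laplace"
    seed: int = 0
    acceptance: float | None = None

    @property
    def param_names(self) -> list[str]:
        return list(self.model.param_names)

    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        lo = 50 * (1 - level)
        return np.percentile(self.draws, [lo, 100 - lo], axis=0).T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.param_names)
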