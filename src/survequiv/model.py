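"""Censored-data maximum likelihood for parametric survival models.

The central objects follow the Model/Results convention: a
:class:`ParametricSurvivalModel` is built from one arm's right-censored
observations and a family name; its :meth:`fit` returns a
:class:`FittedSurvivalModel` carrying the MLE, its log-likelihood, the
observed information (negative Hessian of the log-likelihood at the
optimum) and the AIC.

The log-likelihood is the event factor of the full random-censoring
likelihood,

    l(theta) = sum_j [ delta_j log f(t_j, theta) + (1-delta_j) log S(t_j, theta) ],

which is all the event model needs because the event and censoring
parameters are variation independent. The censoring model is fitted by
maximizing the censoring factor, which is literally the same objective
with the event indicators flipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools import numdiff

from .data import CensoredSample
from .families import Family, get_family

__all__ = [
    "censored_loglik",
    "ParametricSurvivalModel",
    "FittedSurvivalModel",
    "fit_event_model",
    "fit_censoring_model",
    "model_selection_aic",
    "FitError",
    "ConvergenceError",
]


class FitError(RuntimeError):
    pass


class ConvergenceError(FitError):
    pass


def censored_loglik(sample: CensoredSample, family, theta) -> float:
    """Right-censored log-likelihood sum(delta*log f + (1-delta)*log S)."""
    fam = get_family(family)
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = fam.logpdf(sample.times, theta)
        logs = fam.logsf(sample.times, theta)
        ll = np.where(sample.events == 1, logf, logs).sum()
    return float(ll) if np.isfinite(ll) else -np.inf


# ---------------------------------------------------------------------------
# fast closed-form / profile paths
# ---------------------------------------------------------------------------


def _fit_exponential(times, events):
    d = events.sum()
    rate = d / times.sum()
    return np.array([rate])


def _weibull_profile_score(k, times, events, d, mean_log_t_events):
    tk = times**k
    logt = np.log(times)
    return 1.0 / k + mean_log_t_events - (tk * logt).sum() / tk.sum()


def _fit_weibull_profile(times, events):
    """Profile-likelihood Weibull MLE.

    For fixed shape k the scale MLE is closed form,
    lam(k) = (sum t_j^k / d)^(1/k); substituting it leaves a monotone
    1-d score in k solved by bracketing.
    """
    d = events.sum()
    mean_log_t_events = np.log(times[events == 1]).mean()
    lo, hi = 1e-3, 64.0
    f_lo = _weibull_profile_score(lo, times, events, d, mean_log_t_events)
    f_hi = _weibull_profile_score(hi, times, events, d, mean_log_t_events)
    while f_hi > 0 and hi < 1e5:  # extremely concentrated data
        hi *= 4
        f_hi = _weibull_profile_score(hi, times, events, d, mean_log_t_events)
    if f_lo < 0 or f_hi > 0:
        raise ConvergenceError("Weibull profile score could not be bracketed")
    k = optimize.brentq(
        _weibull_profile_score,
        lo,
        hi,
        args=(times, events, d, mean_log_t_events),
        xtol=1e-12,
    )
    lam = ((times**k).sum() / d) ** (1.0 / k)
    return np.array([k, lam])


def _weibull_observed_information(theta, times, events):
    """Analytic negative Hessian of the Weibull censored log-likelihood."""
    k, lam = theta
    d = events.sum()
    u = (times / lam) ** k
    logr = np.log(times / lam)
    d2_kk = -d / k**2 - (u * logr**2).sum()
    d2_ll = d * k / lam**2 - (k * (1 + k) / lam**2) * u.sum()
    d2_kl = -d / lam + (u * (k * logr + 1)).sum() / lam
    return -np.array([[d2_kk, d2_kl], [d2_kl, d2_ll]])


def _fit_uniform_censoring(times, events):
    """MLE of the upper endpoint c for a uniform-[0, c] model.

    In the working-sample convention (events carry the density term,
    censorings the survival term) the log-likelihood is
    sum_j [ e_j (-log c) + (1-e_j) log(1 - t_j/c) ], maximized over
    c > max(t).
    """
    t_top = times.max()

    def nll(c):
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(events == 1, -np.log(c), np.log1p(-times / c))
        s = terms.sum()
        return -s if np.isfinite(s) else np.inf

    res = optimize.minimize_scalar(
        nll, bounds=(t_top * (1 + 1e-9), t_top * 1e4), method="bounded",
        options={"xatol": 1e-10 * t_top},
    )
    return np.array([res.x])


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


_START_JITTER_SD = 0.3
_MAX_RESTARTS = 5


class ParametricSurvivalModel:
    """One arm's parametric survival model under right censoring.

    Parameters
    ----------
    sample : CensoredSample
        Observations (t_j, delta_j) for one arm.
    family : str or Family
        Distribution family; see :mod:`survequiv.families`.
    role : {"event", "censoring"}
        A censoring model maximizes the censoring factor of the full
        likelihood, i.e. the event-model objective on the flipped sample.
    """

    def __init__(self, sample: CensoredSample, family="weibull", role="event"):
        if role not in ("event", "censoring"):
            raise ValueError("role must be 'event' or 'censoring'")
        self.family: Family = get_family(family)
        self.role = role
        self.sample = sample
        self._work = sample if role == "event" else sample.flip()
        if self._work.n_events == 0:
            what = "events" if role == "event" else "censored observations"
            raise FitError(f"cannot fit a {role} model: sample has no {what}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group, family="weibull", role="event"):
        sub = df[df["group"] == group]
        sample = CensoredSample(
            sub["time"].to_numpy(), sub["event"].to_numpy(), group
        )
        return cls(sample, family=family, role=role)

    # objective on the working (possibly flipped) sample
    def loglike(self, theta) -> float:
        return censored_loglik(self._work, self.family, theta)

    def _start_values(self):
        t, e = self._work.times, self._work.events
        name = self.family.name
        if name == "log_normal":
            return np.array([np.log(t).mean(), max(np.log(t).std(), 1e-2)])
        if name in ("gaussian", "logistic"):
            return np.array([t.mean(), max(t.std(), 1e-2)])
        if name == "log_logistic":
            return np.array([np.median(t), 1.0])
        if name == "weibull":
            return np.array([1.0, t.sum() / max(e.sum(), 1)])
        if name == "exponential":
            return np.array([e.sum() / t.sum()])
        if name == "uniform":
            return np.array([t.max() * 1.5])
        raise KeyError(name)

    def fit(self, rng: np.random.Generator | None = None) -> "FittedSurvivalModel":
        t, e = self._work.times, self._work.events
        name = self.family.name
        # closed-form / profile fast paths
        if name == "exponential":
            theta = _fit_exponential(t, e)
        elif name == "weibull":
            theta = _fit_weibull_profile(t, e)
        elif name == "uniform":
            theta = _fit_uniform_censoring(t, e)
        else:
            theta = self._fit_numeric(rng)
        return FittedSurvivalModel(self, theta)

    def _fit_numeric(self, rng):
        # unconstrained optimization: log-transform positive parameters
        mask = self.family._positivity_mask()

        def to_eta(theta):
            eta = np.array(theta, dtype=float)
            eta[mask] = np.log(eta[mask])
            return eta

        def to_theta(eta):
            theta = np.array(eta, dtype=float)
            theta[mask] = np.exp(theta[mask])
            return theta

        def nll(eta):
            v = self.loglike(to_theta(eta))
            return -v if np.isfinite(v) else 1e300

        eta0 = to_eta(self._start_values())
        rng = rng or np.random.default_rng(0)
        best = None
        for attempt in range(_MAX_RESTARTS + 1):
            start = eta0 if attempt == 0 else eta0 + rng.normal(
                0, _START_JITTER_SD, eta0.shape
            )
            res = optimize.minimize(nll, start, method="BFGS")
            if best is None or res.fun < best.fun:
                best = res
            grad_ok = np.max(np.abs(best.jac)) < 1e-4 * max(1.0, abs(best.fun))
            if np.isfinite(best.fun) and grad_ok:
                break
        else:
            if not np.isfinite(best.fun):
                raise ConvergenceError(
                    f"{self.family.name} fit failed after {_MAX_RESTARTS} restarts: "
                    f"{best.message}"
                )
            warnings.warn(
                f"{self.family.name} fit: gradient norm {np.max(np.abs(best.jac)):.2e} "
                "above tolerance; returning best point found"
            )
        return to_theta(best.x)


@dataclass(frozen=True)
class FittedSurvivalModel:
    """MLE results for one arm: theta-hat, log-likelihood, information, AIC."""

    model: ParametricSurvivalModel
    params: np.ndarray

    @property
    def family(self) -> Family:
        return self.model.family

    @property
    def sample(self) -> CensoredSample:
        return self.model.sample

    @property
    def nobs(self) -> int:
        return self.model.sample.n

    @cached_property
    def llf(self) -> float:
        return self.model.loglike(self.params)

    @property
    def df_model(self) -> int:
        return self.family.arity

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    @cached_property
    def observed_information(self) -> np.ndarray:
        """Full-sample observed information: -Hessian of loglik at theta-hat.

        The asymptotic covariance of theta-hat is its inverse directly:
        the 1/n of the textbook per-observation scaling is already carried
        by the full-sample Hessian.
        """
        if self.family.name == "weibull":
            w = self.model._work
            return _weibull_observed_information(self.params, w.times, w.events)
        if self.family.name == "exponential":
            d = self.model._work.n_events
            return np.array([[d / self.params[0] ** 2]])
        hess = numdiff.approx_hess3(self.params, self.model.loglike)
        return -np.asarray(hess)

    @cached_property
    def cov_params(self) -> np.ndarray:
        info = self.observed_information
        cond = np.linalg.cond(info)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"observed information is numerically singular "
                f"(condition number {cond:.2e})"
            )
        return np.linalg.inv(info)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    # convenience evaluations at the fitted parameters
    def sf(self, t):
        return self.family.sf(t, self.params)

    def hazard(self, t):
        return self.family.hazard(t, self.params)

    def cumhaz(self, t):
        return self.family.cumhaz(t, self.params)

    def summary(self) -> str:
        lines = [
            f"Parametric survival model ({self.model.role})",
            f"  family: {self.family.name}   n = {self.nobs} "
            f"({self.sample.n_events} events, {self.sample.n_censored} censored)",
            f"  log-likelihood = {self.llf:.3f}   AIC = {self.aic:.1f}",
            "",
            f"  {'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(self.family.param_names, self.params, self.bse):
            lines.append(f"  {name:<10}{est:>12.5g}{se:>12.5g}")
        return "\n".join(lines)


def fit_event_model(sample: CensoredSample, family) -> FittedSurvivalModel:
    return ParametricSurvivalModel(sample, family, role="event").fit()


def fit_censoring_model(sample: CensoredSample, family) -> FittedSurvivalModel:
    return ParametricSurvivalModel(sample, family, role="censoring").fit()


def model_selection_aic(sample: CensoredSample, families) -> pd.DataFrame:
    """Fit each candidate family and rank by AIC (ties: fewer parameters).

    Families that fail to fit are kept in the table with the error message
    rather than silently dropped.
    """
    families = list(families)
    if len(families) < 1:
        raise ValueError("need at least one candidate family")
    rows = []
    for name in families:
        fam = get_family(name)
        try:
            fitted = fit_event_model(sample, fam)
            rows.append(
                {
                    "family": fam.name,
                    "n_params": fam.arity,
                    "loglik": fitted.llf,
                    "aic": fitted.aic,
                    "params": tuple(np.round(fitted.params, 6)),
                    "error": "",
                }
            )
        except Exception as exc:  # report, don't drop
            rows.append(
                {
                    "family": fam.name,
                    "n_params": fam.arity,
                    "loglik": np.nan,
                    "aic": np.inf,
                    "params": (),
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["aic", "n_params"], kind="stable", ignore_index=True
    )
    return table
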