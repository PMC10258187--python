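"""Parametric survival families.

Each family wraps a :mod:`scipy.stats` distribution in the shape/scale
parameterization used throughout the package:

================  ==========================  =============================================
name              parameters (theta)          survival function
================  ==========================  =============================================
weibull           (shape k, scale lam)        S(t) = exp{-(t/lam)^k}
exponential       (rate lam,)                 S(t) = exp{-lam t}
log_logistic      (scale alpha, shape beta)   S(t) = 1 / (1 + (t/alpha)^beta)
log_normal        (mu, sigma)                 S(t) = 1 - Phi((log t - mu)/sigma)
gaussian          (mu, sigma)                 support on all reals
logistic          (loc, scale)                support on all reals
================  ==========================  =============================================

All probability computations run on the log scale (``logsf``/``logpdf``)
so that tails do not underflow; the hazard is ``exp(logpdf - logsf)`` and
the cumulative hazard is ``-logsf``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "Family",
    "get_family",
    "FAMILIES",
    "evaluate",
    "quantile",
    "sample_times",
]


class DomainError(ValueError):
    """Parameter vector outside the family's domain."""


@dataclass(frozen=True)
class Family:
    """A named parametric lifetime distribution.

    Parameters are handed around as plain tuples/arrays in the order given
    by :attr:`param_names`. ``frozen(theta)`` returns the corresponding
    scipy frozen distribution; everything else derives from it.
    """

    name: str
    param_names: tuple[str, ...]
    positive_support: bool
    _frozen: Callable[[np.ndarray], stats.rv_continuous]

    @property
    def arity(self) -> int:
        return len(self.param_names)

    def check_params(self, theta) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.shape != (self.arity,):
            raise DomainError(
                f"{self.name} expects {self.arity} parameters "
                f"{self.param_names}, got {theta.shape}"
            )
        if not np.all(np.isfinite(theta)):
            raise DomainError(f"non-finite parameters {theta} for {self.name}")
        # scale-type parameters must be positive; Gaussian/logistic location free
        lower = self._positivity_mask()
        if np.any(theta[lower] <= 0):
            raise DomainError(
                f"parameters {theta} violate positivity for {self.name}"
            )
        return theta

    def _positivity_mask(self) -> np.ndarray:
        if self.name in ("gaussian", "logistic", "log_normal"):
            # location/mu may be any real; the dispersion must be positive
            return np.array([False, True])
        return np.ones(self.arity, dtype=bool)

    def frozen(self, theta):
        return self._frozen(self.check_params(theta))

    def _check_t(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.positive_support and np.any(t < 0):
            raise ValueError(f"negative time for positive-support family {self.name}")
        return t

    # -- survival quantities -------------------------------------------------

    def logsf(self, t, theta):
        return self.frozen(theta).logsf(self._check_t(t))

    def sf(self, t, theta):
        return np.exp(self.logsf(t, theta))

    def logpdf(self, t, theta):
        return self.frozen(theta).logpdf(self._check_t(t))

    def pdf(self, t, theta):
        return np.exp(self.logpdf(t, theta))

    def hazard(self, t, theta):
        d = self.frozen(theta)
        t = self._check_t(t)
        return np.exp(d.logpdf(t) - d.logsf(t))

    def cumhaz(self, t, theta):
        return -self.logsf(t, theta)

    def ppf(self, p, theta):
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p >= 1)):
            raise ValueError("probability must lie in [0, 1)")
        return self.frozen(theta).ppf(p)

    def rvs(self, theta, size, rng: np.random.Generator):
        return self.frozen(theta).rvs(size=size, random_state=rng)


def _weibull(theta):
    return stats.weibull_min(c=theta[0], scale=theta[1])


def _exponential(theta):
    return stats.expon(scale=1.0 / theta[0])


def _log_logistic(theta):
    # scipy's fisk: sf(t) = 1/(1+(t/scale)^c)
    return stats.fisk(c=theta[1], scale=theta[0])


def _log_normal(theta):
    return stats.lognorm(s=theta[1], scale=np.exp(theta[0]))


def _gaussian(theta):
    return stats.norm(loc=theta[0], scale=theta[1])


def _logistic(theta):
    return stats.logistic(loc=theta[0], scale=theta[1])


def _uniform(theta):
    # censoring-only family: uniform on [0, c]
    return stats.uniform(loc=0.0, scale=theta[0])


FAMILIES: dict[str, Family] = {
    f.name: f
    for f in (
        Family("weibull", ("shape", "scale"), True, _weibull),
        Family("exponential", ("rate",), True, _exponential),
        Family("log_logistic", ("scale", "shape"), True, _log_logistic),
        Family("log_normal", ("mu", "sigma"), True, _log_normal),
        Family("gaussian", ("mu", "sigma"), False, _gaussian),
        Family("logistic", ("loc", "scale"), False, _logistic),
        Family("uniform", ("upper",), True, _uniform),
    )
}

#: families sensible as event-time models (uniform is censoring-only)
EVENT_FAMILIES = (
    "weibull",
    "exponential",
    "log_logistic",
    "log_normal",
    "gaussian",
    "logistic",
)


def get_family(name: str | Family) -> Family:
    if isinstance(name, Family):
        return name
    try:
        return FAMILIES[name]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None


def evaluate(family, theta, t) -> dict[str, np.ndarray]:
    """Survival S, density f, hazard h and cumulative hazard H at ``t``."""
    fam = get_family(family)
    logs = fam.logsf(t, theta)
    logf = fam.logpdf(t, theta)
    return {
        "S": np.exp(logs),
        "f": np.exp(logf),
        "h": np.exp(logf - logs),
        "H": -logs,
    }


def quantile(family, theta, p):
    """Time t with F(t) = p (equivalently S(t) = 1 - p)."""
    return get_family(family).ppf(p, theta)


def sample_times(family, theta, n: int, rng: np.random.Generator):
    """Draw ``n`` event (or censoring) times; reproducible under ``rng``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return get_family(family).rvs(theta, size=n, rng=rng)
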