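"""Scenario generator and Monte-Carlo harness for operating characteristics.

Three built-in two-arm scenarios drive the coverage, type-I-error and
power studies (time unit: months, administrative follow-up cap t_max):

* ``ph-type1`` / ``ph-power`` — both arms Weibull with common shape 1.5
  (proportional hazards). Reference arm Weibull(1.5, 3.4) with Exp(0.1)
  censoring; test arm scale 4.9 (type-I, Exp(0.09) censoring) or 3.7
  (power, Exp(0.05) censoring); t_max = 9. Rates give ~25% censoring.
* ``nph-type1`` / ``nph-power`` — test arm Weibull shape 2 (crossing
  curves, non-proportional hazards), scale 2.5 (type-I, test-arm
  censoring rate 0.14) or 3.4 (power, rate 0.1); reference arm as above.
* ``ll-misspec`` — both arms log-logistic (reference scale 2.6 / shape
  1.5, test scale 3.9 / shape 2.1; the hazard ratio then falls from
  about 2.5 to 0.8 across t in [1, 5]) with uniform-[0, c] censoring, c
  calibrated at build time to ~20% censoring; t_max = 12. Fitting a
  Weibull to these data probes robustness to event-model
  misspecification.

Each scenario carries the evaluation grid its operating characteristics
are tabulated on. One master seed spawns independent per-trial
substreams, so results are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, optimize

from .bands import pointwise_bands
from .data import CensoredSample
from .equivalence import TestSpec, pointwise_test
from .families import get_family
from .model import fit_censoring_model, fit_event_model, FitError, ConvergenceError
from .nonparam import np_diff_bands

__all__ = [
    "ArmSpec",
    "ScenarioConfig",
    "SimulationSummary",
    "get_scenario",
    "load_scenario_yaml",
    "dump_scenario_yaml",
    "SCENARIOS",
    "generate_trial",
    "censoring_fraction",
    "estimate_operating_characteristics",
    "simulate_coverage",
]


@dataclass(frozen=True)
class ArmSpec:
    event_family: str
    event_params: tuple
    censor_family: str
    censor_params: tuple


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    arm1: ArmSpec
    arm2: ArmSpec
    t_max: float
    n1: int = 50
    n2: int = 50
    grid: tuple = ()
    fit_family: str = "weibull"  # event model fitted in the analysis
    censor_fit_family: str = "exponential"  # censoring model for the bootstrap

    def with_n(self, n1, n2=None):
        return replace(self, n1=n1, n2=n2 if n2 is not None else n1)


def load_scenario_yaml(path) -> "ScenarioConfig":
    """Read a ScenarioConfig from a structured-text (YAML) file.

    Keys mirror the dataclass: name, t_max, n1, n2, grid, fit_family,
    censor_fit_family, and per-arm blocks arm1/arm2 with event_family,
    event_params, censor_family, censor_params.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    arms = {
        key: ArmSpec(
            raw[key]["event_family"],
            tuple(raw[key]["event_params"]),
            raw[key]["censor_family"],
            tuple(raw[key]["censor_params"]),
        )
        for key in ("arm1", "arm2")
    }
    return ScenarioConfig(
        name=raw.get("name", "custom"),
        arm1=arms["arm1"],
        arm2=arms["arm2"],
        t_max=float(raw["t_max"]),
        n1=int(raw.get("n1", 50)),
        n2=int(raw.get("n2", 50)),
        grid=tuple(raw.get("grid", ())),
        fit_family=raw.get("fit_family", "weibull"),
        censor_fit_family=raw.get("censor_fit_family", "exponential"),
    )


def dump_scenario_yaml(config: "ScenarioConfig", path) -> None:
    import dataclasses

    import yaml

    raw = dataclasses.asdict(config)
    raw["grid"] = [float(g) for g in config.grid]
    for key in ("arm1", "arm2"):
        raw[key]["event_params"] = [float(v) for v in raw[key]["event_params"]]
        raw[key]["censor_params"] = [float(v) for v in raw[key]["censor_params"]]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def _uniform_censor_bound(event_family, event_params, t_max, target_rate):
    """Upper endpoint c of uniform-[0, c] censoring giving the target
    censoring fraction under the administrative cap.

    The censoring probability is 1 - E[F_Y(min(C, t_max))].
    """
    fam = get_family(event_family)

    def rate(c):
        top = min(c, t_max)
        integral, _ = integrate.quad(
            lambda u: 1.0 - fam.sf(u, event_params), 0, top
        )
        p_event = integral / c
        if c > t_max:
            p_event += (1.0 - fam.sf(t_max, event_params)) * (c - t_max) / c
        return 1.0 - p_event

    return optimize.brentq(lambda c: rate(c) - target_rate, t_max * 0.2, t_max * 50)


def _weibull_arm(scale, censor_rate, shape=1.5):
    return ArmSpec("weibull", (shape, scale), "exponential", (censor_rate,))


def _build_scenarios():
    ph_grid = tuple(np.linspace(1.5, 6, 23))
    nph_grid = tuple(np.linspace(1.5, 4, 14))
    mis_grid = tuple(np.linspace(1, 5, 21))
    ref = _weibull_arm(3.4, 0.1)
    scen = {
        "ph-type1": ScenarioConfig(
            "ph-type1", ref, _weibull_arm(4.9, 0.09), t_max=9, grid=ph_grid
        ),
        "ph-power": ScenarioConfig(
            "ph-power", ref, _weibull_arm(3.7, 0.05), t_max=9, grid=ph_grid
        ),
        "nph-type1": ScenarioConfig(
            "nph-type1", ref, _weibull_arm(2.5, 0.14, shape=2), t_max=9,
            grid=nph_grid,
        ),
        "nph-power": ScenarioConfig(
            "nph-power", ref, _weibull_arm(3.4, 0.1, shape=2), t_max=9,
            grid=nph_grid,
        ),
    }
    ll1, ll2 = (2.6, 1.5), (3.9, 2.1)  # (scale, shape)
    c1 = _uniform_censor_bound("log_logistic", ll1, 12, 0.20)
    c2 = _uniform_censor_bound("log_logistic", ll2, 12, 0.20)
    scen["ll-misspec"] = ScenarioConfig(
        "ll-misspec",
        ArmSpec("log_logistic", ll1, "uniform", (c1,)),
        ArmSpec("log_logistic", ll2, "uniform", (c2,)),
        t_max=12,
        grid=mis_grid,
    )
    return scen


_SCENARIO_CACHE: dict[str, ScenarioConfig] = {}


def get_scenario(name: str) -> ScenarioConfig:
    if not _SCENARIO_CACHE:
        _SCENARIO_CACHE.update(_build_scenarios())
    try:
        return _SCENARIO_CACHE[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIO_CACHE)}"
        ) from None


SCENARIOS = ("ph-type1", "ph-power", "nph-type1", "nph-power", "ll-misspec")


def _draw_arm(arm: ArmSpec, n, t_max, rng, group):
    efam = get_family(arm.event_family)
    cfam = get_family(arm.censor_family)
    y = efam.rvs(arm.event_params, n, rng)
    c = cfam.rvs(arm.censor_params, n, rng)
    obs = np.minimum(np.minimum(y, c), t_max)
    delta = (y <= np.minimum(c, t_max)).astype(int)
    return CensoredSample(obs, delta, group=group, t_max=t_max)


def generate_trial(config: ScenarioConfig, rng, n1=None, n2=None):
    """One simulated two-arm trial: event time vs random censoring vs cap."""
    n1 = n1 if n1 is not None else config.n1
    n2 = n2 if n2 is not None else config.n2
    return (
        _draw_arm(config.arm1, n1, config.t_max, rng, group=1),
        _draw_arm(config.arm2, n2, config.t_max, rng, group=2),
    )


def censoring_fraction(config: ScenarioConfig, arm: int, n: int, rng) -> float:
    """Empirical censored fraction for one arm at sample size n."""
    spec = config.arm1 if arm == 1 else config.arm2
    sample = _draw_arm(spec, n, config.t_max, rng, group=arm)
    return sample.censoring_rate


def true_contrast(config: ScenarioConfig, t, contrast="surv_diff"):
    """Delta(t) or r(t) under the generating models (the estimand)."""
    t = np.asarray(t, dtype=float)
    f1, f2 = get_family(config.arm1.event_family), get_family(config.arm2.event_family)
    if contrast == "surv_diff":
        return f1.sf(t, config.arm1.event_params) - f2.sf(t, config.arm2.event_params)
    h1 = f1.hazard(t, config.arm1.event_params)
    h2 = f2.hazard(t, config.arm2.event_params)
    return np.log(h1 / h2)


@dataclass(frozen=True)
class SimulationSummary:
    """Monte-Carlo estimate of a test's or band's operating characteristic."""

    metric: str  # "rejection" (type I error or power) | "coverage"
    values: np.ndarray  # scalar (rejection) or per-grid-point (coverage)
    n_sim: int
    method: str
    grid: np.ndarray | None = None
    n_failures: int = 0
    true_value: np.ndarray | None = None  # signed true contrast at t0/grid

    @property
    def mc_se(self) -> np.ndarray:
        p = np.asarray(self.values, dtype=float)
        return np.sqrt(p * (1 - p) / self.n_sim)


_MAX_FAILURE_FRACTION = 0.05


class HarnessError(RuntimeError):
    pass


def _fit_arms(config, s1, s2, need_censoring):
    f1 = fit_event_model(s1, config.fit_family)
    f2 = fit_event_model(s2, config.fit_family)
    if not need_censoring:
        return f1, f2, None, None
    c1 = fit_censoring_model(s1, config.censor_fit_family)
    c2 = fit_censoring_model(s2, config.censor_fit_family)
    return f1, f2, c1, c2


_TRIAL_ERRORS = (FitError, ConvergenceError, np.linalg.LinAlgError, ValueError)


def estimate_operating_characteristics(
    config: ScenarioConfig,
    spec: TestSpec,
    n_sim: int,
    seed: int,
    method: str = "asymptotic",
    n1=None,
    n2=None,
    n_boot: int = 500,
    contrast: str = "surv_diff",
) -> SimulationSummary:
    """Rejection fraction of the pointwise test across simulated trials.

    Whether the fraction is a type-I error or a power depends only on
    where the scenario's true contrast at t0 sits relative to the margin.
    """
    if spec.t0 is None:
        raise ValueError("spec must carry a time point t0")
    if method not in ("asymptotic", "bootstrap", "nonparametric"):
        raise ValueError(f"unknown method {method!r}")
    streams = np.random.SeedSequence(seed).spawn(n_sim)
    grid = np.array([spec.t0])
    rejections = 0
    failures = 0
    done = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        s1, s2 = generate_trial(config, rng, n1, n2)
        try:
            if method == "nonparametric":
                band = np_diff_bands(s1, s2, grid, alpha=spec.alpha)
            else:
                f1, f2, c1, c2 = _fit_arms(config, s1, s2, method == "bootstrap")
                band = pointwise_bands(
                    f1, f2, grid, alpha=spec.alpha, contrast=contrast,
                    method="asymptotic" if method == "asymptotic" else "bootstrap",
                    censor_fit1=c1, censor_fit2=c2, n_boot=n_boot,
                    t_max=config.t_max, rng=rng,
                )
            result = pointwise_test(band, spec.t0, spec)
        except _TRIAL_ERRORS:
            failures += 1
            if failures > _MAX_FAILURE_FRACTION * n_sim:
                raise HarnessError(
                    f"more than {_MAX_FAILURE_FRACTION:.0%} of trials failed"
                )
            continue
        done += 1
        rejections += result.reject
    return SimulationSummary(
        metric="rejection",
        values=np.array(rejections / done),
        n_sim=done,
        method=method,
        n_failures=failures,
        true_value=true_contrast(config, spec.t0, contrast),
    )


def simulate_coverage(
    config: ScenarioConfig,
    n_sim: int,
    seed: int,
    method: str = "asymptotic",
    contrast: str = "surv_diff",
    alpha: float = 0.05,
    n1=None,
    n2=None,
    n_boot: int = 500,
    grid=None,
) -> SimulationSummary:
    """Pointwise two-sided coverage of the true contrast on the grid.

    Counts, per grid point, how often L(t) <= true contrast <= U(t)
    across simulated trials, for two-sided (1 - alpha) intervals: the
    bands are built one-sided at level alpha/2 each so that their joint
    containment has nominal probability 1 - alpha (0.95 by default).
    """
    band_alpha = alpha / 2.0
    grid = np.asarray(grid if grid is not None else config.grid, dtype=float)
    truth = true_contrast(config, grid, contrast)
    streams = np.random.SeedSequence(seed).spawn(n_sim)
    hits = np.zeros(grid.size)
    failures = 0
    done = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        s1, s2 = generate_trial(config, rng, n1, n2)
        try:
            if method == "nonparametric":
                band = np_diff_bands(s1, s2, grid, alpha=band_alpha)
            else:
                f1, f2, c1, c2 = _fit_arms(config, s1, s2, method == "bootstrap")
                band = pointwise_bands(
                    f1, f2, grid, alpha=band_alpha, contrast=contrast,
                    method="asymptotic" if method == "asymptotic" else "bootstrap",
                    censor_fit1=c1, censor_fit2=c2, n_boot=n_boot,
                    t_max=config.t_max, rng=rng,
                )
        except _TRIAL_ERRORS:
            failures += 1
            if failures > _MAX_FAILURE_FRACTION * n_sim:
                raise HarnessError(
                    f"more than {_MAX_FAILURE_FRACTION:.0%} of trials failed"
                )
            continue
        done += 1
        hits += (band.lower <= truth) & (truth <= band.upper)
    return SimulationSummary(
        metric="coverage",
        values=hits / done,
        n_sim=done,
        method=method,
        grid=grid,
        n_failures=failures,
        true_value=truth,
    )
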