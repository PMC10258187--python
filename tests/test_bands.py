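import numpy as np
import pytest

from survequiv import (
    CensoredSample,
    bootstrap_variance,
    contrast_at,
    delta_variance,
    fit_censoring_model,
    fit_event_model,
    pointwise_bands,
)
from survequiv.bands import contrast_gradient
from .conftest import make_censored_weibull

GRID = np.linspace(0.5, 6.0, 12)


def test_identical_fits_give_zero_contrast(ph_arms):
    _, _, f1, _ = ph_arms
    assert np.allclose(contrast_at(f1, f1, GRID, "surv_diff"), 0.0)
    assert np.allclose(contrast_at(f1, f1, GRID, "log_hr"), 0.0)


def test_surv_diff_bounded(ph_arms):
    _, _, f1, f2 = ph_arms
    d = contrast_at(f1, f2, GRID, "surv_diff")
    assert np.all(np.abs(d) <= 1.0)


def test_common_shape_weibull_log_hr_is_constant(ph_arms):
    """With a shared Weibull shape k the log hazard ratio is the constant
    k*log(lambda2/lambda1) — the proportional-hazards special case."""
    s1 = make_censored_weibull((1.5, 3.4), 100, 0.0, np.inf, seed=31)
    f1 = fit_event_model(s1, "weibull")
    # second arm: same fitted shape, different scale, by construction
    from survequiv.model import FittedSurvivalModel, ParametricSurvivalModel

    k, lam1 = f1.params
    lam2 = lam1 * 1.4
    f2 = FittedSurvivalModel(
        ParametricSurvivalModel(s1, "weibull"), np.array([k, lam2])
    )
    r = contrast_at(f1, f2, GRID, "log_hr")
    np.testing.assert_allclose(r, k * np.log(lam2 / lam1), rtol=1e-10)


@pytest.mark.parametrize("contrast", ["surv_diff", "log_hr"])
@pytest.mark.parametrize("family,theta", [
    ("weibull", (1.5, 3.4)),
    ("exponential", (0.3,)),
])
def test_analytic_gradients_match_finite_differences(family, theta, contrast):
    sample = make_censored_weibull((1.5, 3.4), 150, 0.1, 9, seed=32)
    from survequiv.model import FittedSurvivalModel, ParametricSurvivalModel

    fitted = FittedSurvivalModel(
        ParametricSurvivalModel(sample, family), np.asarray(theta, float)
    )
    t = np.linspace(0.5, 6, 9)
    g_analytic = contrast_gradient(fitted, t, contrast, numeric=False)
    g_numeric = contrast_gradient(fitted, t, contrast, numeric=True)
    np.testing.assert_allclose(g_analytic, g_numeric, rtol=1e-6, atol=1e-9)


def test_delta_variance_zero_at_time_origin(ph_arms):
    _, _, f1, f2 = ph_arms
    assert delta_variance(f1, f2, [0.0], "surv_diff")[0] == pytest.approx(0.0)


def test_duplicating_observations_halves_variance(ph_arms):
    """Doubling every observation doubles the information, halving the
    delta-method variance — checked by refitting the duplicated data."""
    s1, s2, f1, f2 = ph_arms
    dup = lambda s: CensoredSample(
        np.concatenate([s.times, s.times]),
        np.concatenate([s.events, s.events]),
        s.group,
    )
    f1d = fit_event_model(dup(s1), "weibull")
    f2d = fit_event_model(dup(s2), "weibull")
    t = np.array([1.0, 2.5, 4.0])
    v = delta_variance(f1, f2, t)
    vd = delta_variance(f1d, f2d, t)
    np.testing.assert_allclose(vd, v / 2, rtol=1e-6)


def test_bands_centered_with_correct_halfwidth(ph_arms):
    from scipy import stats

    _, _, f1, f2 = ph_arms
    band = pointwise_bands(f1, f2, GRID, alpha=0.05)
    z = stats.norm.ppf(0.95)
    np.testing.assert_allclose(band.upper - band.lower,
                               2 * z * np.sqrt(band.variance), rtol=1e-12)
    assert np.all(band.lower <= band.estimate)
    assert np.all(band.estimate <= band.upper)


def test_band_monotone_in_alpha_and_degenerate_at_half(ph_arms):
    _, _, f1, f2 = ph_arms
    tight = pointwise_bands(f1, f2, GRID, alpha=0.1)
    wide = pointwise_bands(f1, f2, GRID, alpha=0.01)
    assert np.all(wide.lower < tight.lower)
    assert np.all(wide.upper > tight.upper)
    degenerate = pointwise_bands(f1, f2, GRID, alpha=0.5)
    np.testing.assert_allclose(degenerate.lower, degenerate.estimate)
    np.testing.assert_allclose(degenerate.upper, degenerate.estimate)
    with pytest.raises(ValueError):
        pointwise_bands(f1, f2, GRID, alpha=0.7)


def test_swapping_arms_reflects_bands(ph_arms):
    _, _, f1, f2 = ph_arms
    band = pointwise_bands(f1, f2, GRID, alpha=0.05)
    swapped = pointwise_bands(f2, f1, GRID, alpha=0.05)
    np.testing.assert_allclose(swapped.lower, -band.upper, rtol=1e-10)
    np.testing.assert_allclose(swapped.upper, -band.lower, rtol=1e-10)


def test_band_serialization_round_trip(tmp_path, ph_arms):
    import pandas as pd

    _, _, f1, f2 = ph_arms
    band = pointwise_bands(f1, f2, GRID, alpha=0.05)
    path = tmp_path / "band.csv"
    band.to_csv(path)
    df = pd.read_csv(path)
    np.testing.assert_allclose(df["t"], band.grid)
    np.testing.assert_allclose(df["lower"], band.lower)
    np.testing.assert_allclose(df["upper"], band.upper)


def test_bootstrap_requires_rng_and_censoring_models(ph_arms):
    s1, s2, f1, f2 = ph_arms
    c1 = fit_censoring_model(s1, "exponential")
    c2 = fit_censoring_model(s2, "exponential")
    with pytest.raises(ValueError, match="rng"):
        bootstrap_variance(f1, f2, c1, c2, [2.0], n_boot=50, rng=None)
    with pytest.raises(ValueError, match="n_boot"):
        bootstrap_variance(f1, f2, c1, c2, [2.0], n_boot=1,
                           rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="censoring"):
        pointwise_bands(f1, f2, [2.0], method="bootstrap")


def test_bootstrap_variance_reproducible(ph_arms):
    s1, s2, f1, f2 = ph_arms
    c1 = fit_censoring_model(s1, "exponential")
    c2 = fit_censoring_model(s2, "exponential")
    v1 = bootstrap_variance(f1, f2, c1, c2, GRID, n_boot=40, t_max=9,
                            rng=np.random.default_rng(5))
    v2 = bootstrap_variance(f1, f2, c1, c2, GRID, n_boot=40, t_max=9,
                            rng=np.random.default_rng(5))
    np.testing.assert_array_equal(v1, v2)
    v3 = bootstrap_variance(f1, f2, c1, c2, GRID, n_boot=40, t_max=9,
                            rng=np.random.default_rng(6))
    assert not np.array_equal(v1, v3)


def test_bootstrap_agrees_with_delta_method():
    """On a well-specified proportional-hazards dataset (n=500/arm) the
    parametric-bootstrap variance converges to the delta-method value."""
    s1 = make_censored_weibull((1.5, 3.4), 500, 0.1, 9, seed=41, group=1)
    s2 = make_censored_weibull((1.5, 4.9), 500, 0.09, 9, seed=42, group=2)
    f1, f2 = fit_event_model(s1, "weibull"), fit_event_model(s2, "weibull")
    c1 = fit_censoring_model(s1, "exponential")
    c2 = fit_censoring_model(s2, "exponential")
    t = np.array([1.6, 2.3, 4.0])
    vd = delta_variance(f1, f2, t)
    vb = bootstrap_variance(f1, f2, c1, c2, t, n_boot=2000, t_max=9,
                            rng=np.random.default_rng(43))
    np.testing.assert_allclose(vb, vd, rtol=0.10)


def test_veteran_asymptotic_interval_at_day_80(veteran):
    """Survival difference 0.047 at day 80 with two-sided 90% interval
    [-0.068, 0.163] under Weibull models for both arms."""
    ref, test_arm = veteran
    f1 = fit_event_model(ref, "weibull")
    f2 = fit_event_model(test_arm, "weibull")
    band = pointwise_bands(f1, f2, [80.0], alpha=0.05)
    assert band.estimate[0] == pytest.approx(0.047, abs=1e-3)
    assert band.lower[0] == pytest.approx(-0.068, abs=1e-3)
    assert band.upper[0] == pytest.approx(0.163, abs=1e-3)
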