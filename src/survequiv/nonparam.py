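"""Kaplan-Meier estimation with Greenwood variance, and difference bands.

This is the distribution-free comparator the parametric approach is
benchmarked against: the product-limit estimate per arm, Greenwood's
variance, the normal-approximation band for S1-S2 with variance
Var1 + Var2, and the very same decision rules applied to it. Emitting a
:class:`~survequiv.bands.BandResult` keeps the test code path identical
for the two approaches.

Ties between events and censorings at the same time are resolved the
standard way: events happen first, so tied censored subjects still count
as at risk for that event time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandResult, make_band
from .data import CensoredSample

__all__ = ["KMEstimate", "km_with_greenwood", "np_diff_bands"]


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate with Greenwood variance."""

    event_times: np.ndarray  # distinct times with >= 1 event
    survival: np.ndarray  # S-hat just after each event time
    variance: np.ndarray  # Greenwood variance at each event time
    n_risk: np.ndarray
    n_event: np.ndarray
    t_last: float  # largest observed time (event or censored)

    def survival_at(self, t):
        """Right-continuous step function; 1 before the first event."""
        idx = np.searchsorted(self.event_times, np.asarray(t, float), side="right")
        return np.concatenate([[1.0], self.survival])[idx]

    def variance_at(self, t):
        idx = np.searchsorted(self.event_times, np.asarray(t, float), side="right")
        return np.concatenate([[0.0], self.variance])[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.event_times,
                "survival": self.survival,
                "variance": self.variance,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
            }
        )


def km_with_greenwood(sample: CensoredSample) -> KMEstimate:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i) with
    Greenwood variance S(t)^2 sum_{t_i <= t} d_i / (n_i (n_i - d_i))."""
    order = np.argsort(sample.times, kind="stable")
    times = sample.times[order]
    events = sample.events[order]
    uniq = np.unique(times)
    # at-risk at t: all with observed time >= t (ties: events first)
    n_risk = sample.n - np.searchsorted(times, uniq, side="left")
    d = np.array([events[times == u].sum() for u in uniq])
    keep = d > 0
    uniq, n_risk, d = uniq[keep], n_risk[keep], d[keep]
    surv = np.cumprod(1.0 - d / n_risk)
    with np.errstate(divide="ignore"):
        terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), 0.0)
    var = np.where(surv > 0, surv**2 * np.cumsum(terms), 0.0)
    return KMEstimate(
        event_times=uniq,
        survival=surv,
        variance=var,
        n_risk=n_risk,
        n_event=d,
        t_last=float(sample.times.max()),
    )


def np_diff_bands(
    sample1: CensoredSample, sample2: CensoredSample, grid, alpha=0.05
) -> BandResult:
    """Normal-approximation bands for the Kaplan-Meier difference S1 - S2.

    Grid points beyond the last observed time of either arm carry an
    extrapolated (frozen) estimate and are flagged unreliable.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    km1 = km_with_greenwood(sample1)
    km2 = km_with_greenwood(sample2)
    estimate = km1.survival_at(grid) - km2.survival_at(grid)
    variance = km1.variance_at(grid) + km2.variance_at(grid)
    reliable = grid <= min(km1.t_last, km2.t_last)
    return make_band(
        "surv_diff", grid, estimate, variance, alpha,
        method="nonparametric", reliable=reliable,
    )
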