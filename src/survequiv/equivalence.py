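"""Non-inferiority and equivalence decisions from confidence bands.

The one-sided non-inferiority null H0: Delta(t0) >= delta is rejected
when the upper (1-alpha) band lies at or below the margin,
U(t0) <= delta. The two-sided equivalence null |Delta(t0)| >= delta is
rejected when additionally L(t0) >= -delta. By the intersection-union
principle the *same* (1-alpha) bands serve both tests and the
equivalence test is still asymptotically level alpha — no alpha
splitting, no simultaneous bands.

Over an interval [t1, t2] the union null max_t |Delta(t)| >= delta is
rejected when every pointwise test on the evaluation grid rejects,
equivalently when -delta <= min L and max U <= delta on the grid. The
grid is a finite approximation of the continuum; its density is the
caller's choice.

Hazard-ratio tests are the identical machinery with (r, epsilon)
replacing (Delta, delta): pass a ``log_hr`` band and the margin epsilon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .bands import BandResult

__all__ = ["TestSpec", "TestResult", "pointwise_test", "interval_test"]

_KINDS = ("noninferiority", "equivalence")


@dataclass(frozen=True)
class TestSpec:
    """What is being tested: kind, margin and scope."""

    __test__ = False  # dataclass, not a pytest case

    kind: str  # "noninferiority" | "equivalence"
    margin: float  # delta (surv_diff) or epsilon (log_hr)
    alpha: float = 0.05
    t0: float | None = None  # pointwise scope
    interval: tuple[float, float] | None = None  # interval scope

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if not 0 < self.alpha <= 0.5:
            raise ValueError("alpha must lie in (0, 0.5]")


@dataclass(frozen=True)
class TestResult:
    """Decision plus the evaluated band bounds that produced it."""

    __test__ = False  # dataclass, not a pytest case

    reject: bool
    kind: str
    margin: float
    alpha: float
    contrast: str
    lower: float  # L(t0), or min L over the grid
    upper: float  # U(t0), or max U over the grid
    t0: float | None = None
    interval: tuple[float, float] | None = None
    first_rejection_time: float | None = None

    def to_record(self) -> str:
        d = {
            "reject": int(self.reject),
            "kind": self.kind,
            "contrast": self.contrast,
            "margin": self.margin,
            "alpha": self.alpha,
            "lower": self.lower,
            "upper": self.upper,
        }
        if self.t0 is not None:
            d["t0"] = self.t0
        if self.interval is not None:
            d["t1"], d["t2"] = self.interval
        if self.first_rejection_time is not None:
            d["first_rejection_time"] = self.first_rejection_time
        return json.dumps(d)

    def report(self) -> str:
        scope = (
            f"at t0 = {self.t0:g}"
            if self.t0 is not None
            else f"on [{self.interval[0]:g}, {self.interval[1]:g}]"
        )
        verdict = "REJECTED" if self.reject else "not rejected"
        lines = [
            f"{self.kind} test ({self.contrast}) {scope}, "
            f"margin = {self.margin:g}, alpha = {self.alpha:g}",
            f"  evaluated bounds: L = {self.lower:.4f}, U = {self.upper:.4f}",
            f"  H0 {verdict} -> {self.kind} "
            f"{'claimed' if self.reject else 'cannot be claimed'}",
        ]
        if self.first_rejection_time is not None:
            lines.append(
                f"  pointwise rejection holds from t = "
                f"{self.first_rejection_time:g} onward"
            )
        return "\n".join(lines)


def _decide(kind, lower, upper, margin):
    # boundary inclusive, as defined
    noninf = upper <= margin
    if kind == "noninferiority":
        return bool(noninf)
    return bool(noninf and lower >= -margin)


def pointwise_test(band: BandResult, t0: float, spec: TestSpec) -> TestResult:
    """Test at a single grid time t0 (must lie exactly on the band's grid)."""
    if spec.alpha != band.alpha:
        raise ValueError(
            f"spec alpha {spec.alpha} differs from the band's {band.alpha}; "
            "rebuild the band at the test level"
        )
    i = band.locate(t0)
    lo, up = float(band.lower[i]), float(band.upper[i])
    return TestResult(
        reject=_decide(spec.kind, lo, up, spec.margin),
        kind=spec.kind,
        margin=spec.margin,
        alpha=spec.alpha,
        contrast=band.contrast,
        lower=lo,
        upper=up,
        t0=float(t0),
    )


def interval_test(band: BandResult, spec: TestSpec) -> TestResult:
    """Intersection-union test over [t1, t2] on the band's grid.

    Rejects iff every pointwise test on the grid inside the interval
    rejects. Also reports the earliest grid time from which the pointwise
    condition holds through t2 (useful for "non-inferior from day X
    onward" statements); None if it fails at t2 itself.
    """
    if spec.alpha != band.alpha:
        raise ValueError("spec alpha differs from the band's alpha")
    t1, t2 = spec.interval if spec.interval is not None else (
        band.grid[0], band.grid[-1]
    )
    mask = (band.grid >= t1 - 1e-12) & (band.grid <= t2 + 1e-12)
    if not mask.any():
        raise ValueError(f"band grid has no points inside [{t1}, {t2}]")
    lo = band.lower[mask]
    up = band.upper[mask]
    times = band.grid[mask]
    point_ok = up <= spec.margin
    if spec.kind == "equivalence":
        point_ok = point_ok & (lo >= -spec.margin)
    # earliest time from which rejection holds through t2
    holds_to_end = np.flip(np.cumprod(np.flip(point_ok))).astype(bool)
    first = float(times[holds_to_end][0]) if holds_to_end.any() else None
    return TestResult(
        reject=bool(point_ok.all()),
        kind=spec.kind,
        margin=spec.margin,
        alpha=spec.alpha,
        contrast=band.contrast,
        lower=float(lo.min()),
        upper=float(up.max()),
        interval=(float(t1), float(t2)),
        first_rejection_time=first,
    )
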