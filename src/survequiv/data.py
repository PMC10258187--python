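"""Two-arm right-censored samples and their delimited-text representation.

The on-disk schema is fixed: a header row and columns ``time`` (positive
real), ``event`` (1 = event observed, 0 = right-censored) and ``group``
(arm label, 1 = reference, 2 = test). Survival-data dialects vary, so the
schema is validated explicitly on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CensoredSample", "read_two_arm", "write_two_arm"]


@dataclass(frozen=True)
class CensoredSample:
    """One arm's right-censored observations (t_j, delta_j)."""

    times: np.ndarray
    events: np.ndarray
    group: int | str = 1
    t_max: float | None = field(default=None, compare=False)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        if times.shape != events.shape or times.ndim != 1:
            raise ValueError("times and events must be equal-length 1-d arrays")
        if times.size == 0:
            raise ValueError("empty sample")
        if np.any(times <= 0) or not np.all(np.isfinite(times)):
            raise ValueError("all observation times must be positive and finite")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("event indicators must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_censored(self) -> int:
        return self.n - self.n_events

    @property
    def censoring_rate(self) -> float:
        return self.n_censored / self.n

    def flip(self) -> "CensoredSample":
        """Swap the roles of events and censorings.

        Fitting an event model to the flipped sample is exactly fitting a
        censoring model to the original one: the censoring factor of the
        full likelihood has the two indicator exponents exchanged.
        """
        return CensoredSample(self.times, 1 - self.events, self.group, self.t_max)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "event": self.events, "group": self.group}
        )


def _validate(df: pd.DataFrame, path) -> None:
    missing = {"time", "event", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df.index[~df["event"].isin((0, 1))]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0] + 2}: event must be 0 or 1")
    bad = df.index[~(df["time"] > 0)]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0] + 2}: time must be > 0")


def read_two_arm(path, sep=",") -> tuple[CensoredSample, CensoredSample]:
    """Read a (time, event, group) file into (reference, test) samples.

    The two distinct group labels are ordered; the smaller one is the
    reference arm.
    """
    df = pd.read_csv(path, sep=sep)
    _validate(df, path)
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"{path}: expected exactly 2 groups, found {labels}")
    arms = []
    for lab in labels:
        sub = df[df["group"] == lab]
        arms.append(
            CensoredSample(sub["time"].to_numpy(), sub["event"].to_numpy(), lab)
        )
    return tuple(arms)


def write_two_arm(path, sample1: CensoredSample, sample2: CensoredSample, sep=","):
    pd.concat([sample1.to_frame(), sample2.to_frame()]).to_csv(
        path, sep=sep, index=False
    )
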