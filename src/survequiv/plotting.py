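"""Basic line plots for bands and survival-curve comparisons."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_band", "plot_survival_curves"]


def plot_band(band, margin=None, ax=None):
    """Contrast estimate with its pointwise bands; optional margin lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(band.grid, band.estimate, color="black", label="estimate")
    ax.fill_between(band.grid, band.lower, band.upper, alpha=0.25,
                    label=f"pointwise bands ({band.method})")
    if margin is not None:
        ax.axhline(margin, ls="--", color="grey")
        ax.axhline(-margin, ls="--", color="grey")
    ax.axhline(0.0, lw=0.5, color="grey")
    ax.set_xlabel("time")
    label = "S1(t) - S2(t)" if band.contrast == "surv_diff" else "log h1/h2"
    ax.set_ylabel(label)
    ax.legend()
    return ax


def plot_survival_curves(fitted1, fitted2, km1=None, km2=None, ax=None):
    """Fitted parametric curves, optionally overlaid on Kaplan-Meier steps."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    top = max(fitted1.sample.times.max(), fitted2.sample.times.max())
    t = np.linspace(0, top, 300)
    ax.plot(t, fitted1.sf(t), label=f"arm {fitted1.sample.group} (fit)")
    ax.plot(t, fitted2.sf(t), label=f"arm {fitted2.sample.group} (fit)")
    for km, style in ((km1, "C0"), (km2, "C1")):
        if km is not None:
            ax.step(km.event_times, km.survival, where="post", color=style,
                    alpha=0.5, lw=0.8)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
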