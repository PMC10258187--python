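"""Two-arm comparison object tying fitting, bands and tests together.

:class:`SurvivalContrast` is the front door for a complete analysis: fit
an event model per arm (plus censoring models when the bootstrap is
used), then ask for bands on a grid and for non-inferiority or
equivalence decisions against a margin.
"""

from __future__ import annotations

from .bands import BandResult, pointwise_bands
from .data import CensoredSample, read_two_arm
from .equivalence import TestSpec, TestResult, interval_test, pointwise_test
from .model import fit_censoring_model, fit_event_model

__all__ = ["SurvivalContrast"]


class SurvivalContrast:
    """Fitted parametric comparison of a reference and a test arm."""

    def __init__(
        self,
        sample1: CensoredSample,
        sample2: CensoredSample,
        family="weibull",
        family2=None,
        censoring_family="exponential",
    ):
        self.sample1, self.sample2 = sample1, sample2
        self.censoring_family = censoring_family
        self.fitted1 = fit_event_model(sample1, family)
        self.fitted2 = fit_event_model(sample2, family2 or family)
        self._censor_fits = None

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SurvivalContrast":
        s1, s2 = read_two_arm(path)
        return cls(s1, s2, **kwargs)

    @property
    def censor_fits(self):
        if self._censor_fits is None:
            self._censor_fits = (
                fit_censoring_model(self.sample1, self.censoring_family),
                fit_censoring_model(self.sample2, self.censoring_family),
            )
        return self._censor_fits

    def bands(
        self,
        grid,
        alpha=0.05,
        contrast="surv_diff",
        method="asymptotic",
        n_boot=500,
        t_max=None,
        rng=None,
    ) -> BandResult:
        censor1 = censor2 = None
        if method == "bootstrap":
            censor1, censor2 = self.censor_fits
        return pointwise_bands(
            self.fitted1,
            self.fitted2,
            grid,
            alpha=alpha,
            contrast=contrast,
            method=method,
            censor_fit1=censor1,
            censor_fit2=censor2,
            n_boot=n_boot,
            t_max=t_max,
            rng=rng,
        )

    def test(self, band: BandResult, spec: TestSpec) -> TestResult:
        if spec.t0 is not None:
            return pointwise_test(band, spec.t0, spec)
        return interval_test(band, spec)

    def summary(self) -> str:
        parts = [
            f"Two-arm survival contrast (reference group "
            f"{self.sample1.group}, test group {self.sample2.group})",
            "",
            self.fitted1.summary(),
            "",
            self.fitted2.summary(),
        ]
        return "\n".join(parts)
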