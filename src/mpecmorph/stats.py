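"""Replicate-level statistics shared by the morphometric and metabolic stages.

Two primitives cover everything the pipeline reports: a mean/SD/confidence
band summary of a replicate sample (Student-t band, default α = 0.05), and
a two-sided Welch t-test p-value for treatment-vs-control comparisons.
Welch's unequal-variance form is used because group sizes and variances
differ across cultivation conditions; a pooled-variance variant is
available through ``equal_var=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = ["SampleSummary", "mean_sd_ci", "t_test_p"]

# variances below this (relative to the squared scale of the data) are
# treated as exactly zero for the degenerate-sample conventions
_ZERO_VAR_RTOL = 1e-24


@dataclass(frozen=True)
class SampleSummary:
    """Mean, n−1 standard deviation and a Student-t confidence band.

    ``sd``, ``ci_low`` and ``ci_high`` are ``None`` for a single
    observation, where dispersion is undefined.
    """

    n: int
    mean: float
    sd: float | None
    ci_low: float | None
    ci_high: float | None
    alpha: float = 0.05

    @property
    def half_width(self) -> float | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return 0.5 * (self.ci_high - self.ci_low)


def mean_sd_ci(values: Sequence[float], alpha: float = 0.05) -> SampleSummary:
    """Summarise a replicate sample.

    The band is ``mean ± t(1−α/2, n−1) · SD/√n`` with the n−1 standard
    deviation. Raises on an empty sample; for ``n == 1`` the mean is
    returned with SD and band unavailable.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        raise ValueError("cannot summarise an empty sample")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    mean = float(x.mean())
    if x.size == 1:
        return SampleSummary(n=1, mean=mean, sd=None, ci_low=None, ci_high=None, alpha=alpha)
    sd = float(x.std(ddof=1))
    half = float(_st.t.ppf(1 - alpha / 2, x.size - 1) * sd / np.sqrt(x.size))
    return SampleSummary(
        n=int(x.size), mean=mean, sd=sd,
        ci_low=mean - half, ci_high=mean + half, alpha=alpha,
    )


def t_test_p(a: Sequence[float], b: Sequence[float], *, equal_var: bool = False) -> float:
    """Two-sided t-test p-value between two replicate samples.

    Defaults to Welch's unequal-variance form. Both samples need at least
    two observations. When both samples are exactly constant the test
    statistic is undefined; the documented convention is p = 1 for equal
    means and p = 0 for different means.
    """
    xa = np.asarray(a, dtype=float).ravel()
    xb = np.asarray(b, dtype=float).ravel()
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs at least two observations")
    va = xa.var(ddof=1)
    vb = xb.var(ddof=1)
    scale = max(xa.mean() ** 2, xb.mean() ** 2, 1.0)
    if va <= _ZERO_VAR_RTOL * scale and vb <= _ZERO_VAR_RTOL * scale:
        return 1.0 if np.isclose(xa.mean(), xb.mean(), rtol=0, atol=0) else 0.0
    res = _st.ttest_ind(xa, xb, equal_var=equal_var)
    return float(res.pvalue)
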