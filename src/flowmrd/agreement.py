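"""Method-comparison statistics for automated vs manual MRD percentages.

Implements the three analyses used to validate an automated gating method
against conventional manual analysis over paired per-specimen MRD
percentages: the two-tailed paired Student t-test, the Pearson
product-moment correlation, and Bland–Altman 95% limits of agreement
(bias ± 1.96 · SD of the paired differences, the large-sample normal
quantile without a small-sample t correction).

Differences are computed as (method_a − method_b) in the order the pairs
are given; pass (manual, automated) for the conventional report
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PairedResults:
    """Paired MRD percentages from two methods, one pair per specimen."""

    a: tuple[float, ...]
    b: tuple[float, ...]
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("paired columns must have equal length")
        if self.ids is not None and len(self.ids) != len(self.a):
            raise ValueError("ids must match pair count")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("paired values must be finite")

    @classmethod
    def from_arrays(cls, a: Sequence[float], b: Sequence[float],
                    ids: Sequence[str] | None = None) -> "PairedResults":
        return cls(a=tuple(float(x) for x in a), b=tuple(float(x) for x in b),
                   ids=tuple(ids) if ids is not None else None)

    @property
    def n(self) -> int:
        return len(self.a)

    def differences(self) -> np.ndarray:
        return np.asarray(self.a) - np.asarray(self.b)


def paired_t_test(pr: PairedResults) -> tuple[float, int, float]:
    """Two-tailed paired Student t-test; returns (t, df, p).

    ``t = mean(d) / (sd(d)/sqrt(n))`` with the sample (n−1) standard
    deviation and ``df = n − 1``.  All-identical differences carry zero
    variance, for which no t statistic exists; that degenerate input raises
    rather than fabricating a p-value.
    """
    if pr.n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = pr.differences()
    if np.ptp(d) == 0:
        raise ValueError("all paired differences identical: zero variance, t undefined")
    res = stats.ttest_rel(pr.a, pr.b)
    return float(res.statistic), pr.n - 1, float(res.pvalue)


def pearson_correlation(pr: PairedResults) -> float:
    """Pearson product-moment correlation between the two methods."""
    if pr.n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    a, b = np.asarray(pr.a), np.asarray(pr.b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant column")
    return float(stats.pearsonr(a, b).statistic)


@dataclass(frozen=True)
class BlandAltman:
    """Bland–Altman summary plus per-pair plotting coordinates."""

    bias: float
    loa_low: float
    loa_high: float
    n_outside: int
    means: tuple[float, ...]
    diffs: tuple[float, ...]


def bland_altman(pr: PairedResults) -> BlandAltman:
    """Bland–Altman limits of agreement: bias ± 1.96 · sample SD of differences.

    ``n_outside`` counts strict exceedances — a difference exactly on a
    limit is inside.  Per-pair (mean, difference) coordinates are returned
    for the conventional plot.
    """
    if pr.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = pr.differences()
    m = (np.asarray(pr.a) + np.asarray(pr.b)) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    low, high = bias - 1.96 * sd, bias + 1.96 * sd
    outside = int(np.sum((d < low) | (d > high)))
    return BlandAltman(bias=bias, loa_low=low, loa_high=high, n_outside=outside,
                       means=tuple(m), diffs=tuple(d))


@dataclass(frozen=True)
class AgreementReport:
    """Combined paired-t, correlation and Bland–Altman comparison."""

    t_statistic: float
    df: int
    p_value: float
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    n_outside: int
    n: int


def compare_methods(pr: PairedResults) -> AgreementReport:
    """Run all three agreement analyses over one set of paired results."""
    t, df, p = paired_t_test(pr)
    r = pearson_correlation(pr)
    ba = bland_altman(pr)
    return AgreementReport(t_statistic=t, df=df, p_value=p, pearson_r=r,
                           bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
                           n_outside=ba.n_outside, n=pr.n)
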