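"""Hypothesis tests on normalized FA differences.

The sampling unit is one normalized difference per matched fragment channel.
Replicate comparisons of a single analyte establish how large the observed
mean is under instrument noise alone; a comparison is called *different*
when a one-sample, one-tailed t-test rejects the hypothesized mean built
from that replicate variation.  All tests are one-sided in the "greater"
direction only — two spectra cannot be meaningfully more similar than
replicates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diffs import DifferenceSet

VERDICT_DIFFERENT = "different"
VERDICT_NOT_DISTINGUISHED = "not_distinguished"


def assign_stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else empty."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class HypothesizedMean:
    """Null threshold for the observed mean, with provenance.

    rule ``mean_plus_3sd``: mean of the replicate observed means plus
    ``k_sd`` sample standard deviations (conservatively high, so that
    ordinary replicate variation is almost never called significant).
    rule ``upper_quartile``: 75th percentile of the supplied means, used for
    complex LC-MS data where some nominally single peaks may hide isomers.
    """

    value: float
    rule: str = "manual"
    replicate_means: list[float] = field(default_factory=list)
    k_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("hypothesized mean must be non-negative")

    @classmethod
    def manual(cls, value: float) -> "HypothesizedMean":
        return cls(value=float(value), rule="manual")


def hypothesized_mean_from_replicates(
    replicate_means: list[float] | np.ndarray, k_sd: float = 3.0
) -> HypothesizedMean:
    """Mean of the replicate observed means plus ``k_sd`` sample SDs (n-1)."""
    means = np.asarray(replicate_means, dtype=float)
    if means.size < 2:
        raise ValueError("cannot estimate SD from fewer than 2 replicate means")
    if np.any(means < 0):
        raise ValueError("observed means must be non-negative")
    value = float(means.mean() + k_sd * means.std(ddof=1))
    return HypothesizedMean(
        value=value,
        rule="mean_plus_3sd",
        replicate_means=[float(m) for m in means],
        k_sd=float(k_sd),
    )


@dataclass
class ComparisonResult:
    """Outcome of testing one spectrum pair against a hypothesized mean."""

    observed_mean: float
    hypothesized_mean: HypothesizedMean
    t_statistic: float
    degrees_freedom: float
    p_value_t: float
    n_channels: int
    verdict: str
    stars: str
    p_value_nonparametric: float | None = None
    flags: list[str] = field(default_factory=list)
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "observed_mean": self.observed_mean,
            "hypothesized_mean": self.hypothesized_mean.value,
            "hypothesized_rule": self.hypothesized_mean.rule,
            "t_statistic": self.t_statistic,
            "degrees_freedom": self.degrees_freedom,
            "p_value_t": self.p_value_t,
            "p_value_nonparametric": self.p_value_nonparametric,
            "n_channels": self.n_channels,
            "verdict": self.verdict,
            "stars": self.stars,
            "flags": self.flags,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv_record(self) -> str:
        f = self.to_dict()
        cols = (
            "label observed_mean hypothesized_mean t_statistic degrees_freedom "
            "p_value_t stars verdict"
        ).split()
        return "\t".join(str(f[c]) for c in cols)


def _as_mu0(mu0: "HypothesizedMean | float") -> HypothesizedMean:
    if isinstance(mu0, HypothesizedMean):
        return mu0
    return HypothesizedMean.manual(mu0)


def one_sample_test(
    diffs: DifferenceSet,
    mu0: HypothesizedMean | float,
    alpha: float = 0.05,
    label: str = "",
) -> ComparisonResult:
    """One-sample, one-tailed t-test of the normalized differences vs. ``mu0``.

    ``t = (observed_mean - mu0) / (s / sqrt(n))`` over the n per-channel
    normalized values, with n-1 degrees of freedom; p is the upper tail.
    Verdict is ``different`` when p < ``alpha``.
    """
    mu0 = _as_mu0(mu0)
    x = np.asarray(diffs.normalized, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 channels for a one-sample t-test")
    flags = []
    s = x.std(ddof=1)
    if s == 0.0:
        flags.append("degenerate variance")
        if x.mean() > mu0.value:
            t, p = math.inf, 0.0
        elif x.mean() < mu0.value:
            t, p = -math.inf, 1.0
        else:
            t, p = 0.0, 0.5
    else:
        res = stats.ttest_1samp(x, mu0.value, alternative="greater")
        t, p = float(res.statistic), float(res.pvalue)
    p_t = min(max(p, 0.0), 1.0)
    return ComparisonResult(
        observed_mean=float(diffs.observed_mean),
        hypothesized_mean=mu0,
        t_statistic=t,
        degrees_freedom=n - 1,
        p_value_t=p_t,
        n_channels=n,
        verdict=VERDICT_DIFFERENT if p_t < alpha else VERDICT_NOT_DISTINGUISHED,
        stars=assign_stars(p_t),
        flags=flags,
        label=label,
    )


def two_sample_test(
    diffs_isomer: DifferenceSet,
    diffs_replicate: DifferenceSet,
    alpha: float = 0.05,
    label: str = "",
) -> ComparisonResult:
    """Welch one-sided t-test: isomer normalized differences exceed replicate ones.

    Uses the unequal-variance form with the Welch-Satterthwaite degrees of
    freedom.  Appropriate when a matched replicate comparison is available
    for one member of the candidate isomer pair.
    """
    x = np.asarray(diffs_isomer.normalized, dtype=float)
    y = np.asarray(diffs_replicate.normalized, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 channels in each set")
    flags = []
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        flags.append("degenerate variance")
        if x.mean() > y.mean():
            t, p, df = math.inf, 0.0, x.size + y.size - 2
        elif x.mean() < y.mean():
            t, p, df = -math.inf, 1.0, x.size + y.size - 2
        else:
            t, p, df = 0.0, 0.5, x.size + y.size - 2
    else:
        res = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    p = min(max(p, 0.0), 1.0)
    mu0 = HypothesizedMean(
        value=float(y.mean()), rule="manual", replicate_means=[float(y.mean())]
    )
    return ComparisonResult(
        observed_mean=float(diffs_isomer.observed_mean),
        hypothesized_mean=mu0,
        t_statistic=t,
        degrees_freedom=df,
        p_value_t=p,
        n_channels=x.size,
        verdict=VERDICT_DIFFERENT if p < alpha else VERDICT_NOT_DISTINGUISHED,
        stars=assign_stars(p),
        flags=flags,
        label=label,
    )


def nonparametric_test(
    diffs: DifferenceSet, mu0: HypothesizedMean | float, method: str = "wilcoxon"
) -> float:
    """One-sided Wilcoxon signed-rank p-value of the normalized values vs. ``mu0``.

    The exact null distribution is used for n <= 25 differences; larger
    panels use the normal approximation with continuity correction.  A sign
    test (``method="sign"``) is available for heavily tied data.
    """
    mu0 = _as_mu0(mu0)
    x = np.asarray(diffs.normalized, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 channels for a non-parametric test")
    d = x - mu0.value
    nz = d[d != 0.0]
    if nz.size == 0:
        raise ValueError("no nonzero differences from the hypothesized mean")
    if method == "sign":
        n_pos = int((nz > 0).sum())
        return float(stats.binomtest(n_pos, nz.size, 0.5, alternative="greater").pvalue)
    if method != "wilcoxon":
        raise ValueError("method must be 'wilcoxon' or 'sign'")
    if nz.size <= 25:
        try:
            res = stats.wilcoxon(nz, alternative="greater", method="exact")
        except ValueError:  # ties prevent the exact distribution
            res = stats.wilcoxon(nz, alternative="greater", method="approx", correction=True)
    else:
        res = stats.wilcoxon(nz, alternative="greater", method="approx", correction=True)
    return float(res.pvalue)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values for optional control over all-vs-all LC comparisons."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
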