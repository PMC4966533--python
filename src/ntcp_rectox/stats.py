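"""Cohort-level statistics: 2x2 contingency analyses, two-sample
comparisons, and the population prevalence-shift projection.

These are the unprocessed-data summaries behind the headline clinical
findings: the toxicity rate split by a binary exposure (e.g. statin use)
with odds ratio and chi-square / Fisher tests, the comparison of a
continuous covariate (e.g. pre-treatment PSA) between toxicity groups
(Welch t and Mann-Whitney), and the expected change in population
toxicity incidence when the prevalence of a protective exposure shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dvh import ConfigurationError

__all__ = [
    "ContingencyResult",
    "TwoSampleResult",
    "contingency_2x2",
    "two_sample_compare",
    "prevalence_shift_factor",
]


@dataclass
class ContingencyResult:
    """2x2 exposure-by-outcome table with rates, odds ratio and tests.

    Table layout: a = exposed events, b = exposed non-events,
    c = unexposed events, d = unexposed non-events.
    """

    a: int
    b: int
    c: int
    d: int
    exposure: str
    outcome: str
    rate_exposed: float        # percent, events / exposed * 100
    rate_unexposed: float      # percent
    odds_ratio: float
    or_ci95: tuple | None
    or_ci_unbounded: bool
    chi2: float
    chi2_p: float
    chi2_corrected: float
    chi2_corrected_p: float
    fisher_p: float


def contingency_2x2(cohort: pd.DataFrame, exposure_name: str, outcome_name: str) -> ContingencyResult:
    """Tabulate a binary exposure against a binary outcome.

    Reports per-group event rates (percent), the odds ratio
    OR = (a*d)/(b*c) with a Woolf (log-scale) 95% CI, Pearson chi-square
    with and without Yates continuity correction, and Fisher's exact p.
    A zero cell leaves the OR defined by convention (inf or 0) with the
    CI flagged unbounded.
    """
    for name in (exposure_name, outcome_name):
        if name not in cohort.columns:
            raise ConfigurationError(f"{name}: not present in cohort")
        vals = set(pd.unique(cohort[name]))
        if not vals <= {0, 1}:
            raise ConfigurationError(f"{name}: must be binary 0/1, got values {sorted(vals)}")
    e = cohort[exposure_name].to_numpy(int)
    y = cohort[outcome_name].to_numpy(int)
    if e.sum() == 0 or e.sum() == e.size:
        raise ConfigurationError(f"{exposure_name}: one exposure group is empty")
    a = int(np.sum((e == 1) & (y == 1)))
    b = int(np.sum((e == 1) & (y == 0)))
    c = int(np.sum((e == 0) & (y == 1)))
    d = int(np.sum((e == 0) & (y == 0)))
    table = np.array([[a, b], [c, d]])
    rate_exp = 100.0 * a / (a + b)
    rate_unexp = 100.0 * c / (c + d)
    unbounded = min(a, b, c, d) == 0
    if b * c == 0:
        odds_ratio = np.inf if a * d > 0 else 0.0
        or_ci = None
    else:
        odds_ratio = (a * d) / (b * c)
        if unbounded:
            or_ci = None
        else:
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            or_ci = (float(odds_ratio * np.exp(-1.96 * se)),
                     float(odds_ratio * np.exp(1.96 * se)))
    chi2, chi2_p = sps.chi2_contingency(table, correction=False)[:2]
    chi2c, chi2c_p = sps.chi2_contingency(table, correction=True)[:2]
    fisher_p = float(sps.fisher_exact(table)[1])
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        exposure=exposure_name, outcome=outcome_name,
        rate_exposed=float(rate_exp), rate_unexposed=float(rate_unexp),
        odds_ratio=float(odds_ratio), or_ci95=or_ci, or_ci_unbounded=unbounded,
        chi2=float(chi2), chi2_p=float(chi2_p),
        chi2_corrected=float(chi2c), chi2_corrected_p=float(chi2c_p),
        fisher_p=fisher_p,
    )


@dataclass
class TwoSampleResult:
    """Group summaries and tests for a continuous variable across two groups."""

    n1: int
    n0: int
    mean1: float
    mean0: float
    sd1: float | None          # sample SD (n-1); None when n = 1
    sd0: float | None
    mean_difference: float     # mean1 - mean0
    welch_t: float | None
    welch_p: float | None
    ranksum_u: float
    ranksum_p: float
    sd_undefined: bool = False


def two_sample_compare(values, groups) -> TwoSampleResult:
    """Compare a continuous variable between groups coded 1 and 0.

    Reports means, sample SDs, the mean difference (group 1 minus
    group 0), the Welch t-test and the Mann-Whitney rank-sum test.  A
    group of size one leaves the SD undefined and the Welch test flagged.
    """
    v = np.asarray(values, float)
    g = np.asarray(groups, int)
    if v.shape != g.shape:
        raise ConfigurationError("values/groups: shape mismatch")
    v1, v0 = v[g == 1], v[g == 0]
    if v1.size == 0 or v0.size == 0:
        raise ConfigurationError("groups: both groups must be nonempty")
    sd_undefined = v1.size < 2 or v0.size < 2
    sd1 = float(np.std(v1, ddof=1)) if v1.size > 1 else None
    sd0 = float(np.std(v0, ddof=1)) if v0.size > 1 else None
    if sd_undefined:
        welch_t = welch_p = None
    else:
        t, p = sps.ttest_ind(v1, v0, equal_var=False)
        welch_t, welch_p = float(t), float(p)
    u, up = sps.mannwhitneyu(v1, v0, alternative="two-sided")
    return TwoSampleResult(
        n1=int(v1.size), n0=int(v0.size),
        mean1=float(v1.mean()), mean0=float(v0.mean()),
        sd1=sd1, sd0=sd0,
        mean_difference=float(v1.mean() - v0.mean()),
        welch_t=welch_t, welch_p=welch_p,
        ranksum_u=float(u), ranksum_p=float(up),
        sd_undefined=sd_undefined,
    )


def prevalence_shift_factor(
    relative_risk: float,
    prevalence_before: float,
    prevalence_after: float,
) -> float:
    """Ratio of expected population incidence after vs before an exposure
    prevalence shift.

    With exposed-vs-unexposed risk ratio ``r`` and exposed fraction moving
    from ``p_before`` to ``p_after``, the population incidence scales by

        (1 - p_after * (1 - r)) / (1 - p_before * (1 - r)).

    For a protective exposure (r < 1) that becomes more prevalent, the
    factor is below one (e.g. r = 1/3 with prevalence rising from 20% to
    50% gives 0.77: a 23% decline attributable to the exposure shift).
    """
    if not relative_risk > 0:
        raise ConfigurationError("relative_risk: must be > 0")
    for name, p in (("prevalence_before", prevalence_before),
                    ("prevalence_after", prevalence_after)):
        if not 0 <= p <= 1:
            raise ConfigurationError(f"{name}: must be in [0, 1]")
    return (1.0 - prevalence_after * (1.0 - relative_risk)) / (
        1.0 - prevalence_before * (1.0 - relative_risk)
    )
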