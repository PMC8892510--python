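"""Cohort-level statistics: Kaplan–Meier survival, log-rank contrasts,
and balancer-cross developmental genetics.

Survival estimation is delegated to :mod:`lifelines`; the genetics side
(gamete enumeration, balancer lethality, homozygosity ratios) is computed
here from first principles because it is the quantity of interest rather
than a standard fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .types import (
    BALANCER_ALLELES,
    CrossSpec,
    GenotypeCounts,
    ParameterError,
    SurvivalCohort,
    genotype_label,
    is_homozygote,
)

__all__ = [
    "SurvivalCurve",
    "TestResult",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "expected_cross_frequencies",
    "homozygosity_ratio",
    "chi2_homogeneity",
    "dominance_contrast",
    "wilson_interval",
    "bonferroni",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """A right-continuous Kaplan–Meier step function.

    ``median`` is the first time at which survival drops to 0.5 or below,
    or ``None`` if the curve never reaches 0.5 (no extrapolation).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None

    def __call__(self, t: float) -> float:
        return survival_at(self, t)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


def km_estimate(cohort: SurvivalCohort) -> SurvivalCurve:
    """Product-limit (Kaplan–Meier) survival estimate with right censoring."""
    if len(cohort) == 0:
        raise ParameterError("cannot estimate survival from an empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.days, event_observed=cohort.events)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index)
        .to_numpy(dtype=float)
    )
    median = float(kmf.median_survival_time_)
    return SurvivalCurve(
        event_times=times,
        survival=surv,
        at_risk=at_risk,
        median=None if not np.isfinite(median) else median,
    )


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Step-function value S(t); S(t) = 1 before the first event time."""
    if t < 0:
        raise ParameterError("t must be non-negative")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def logrank_test(a: SurvivalCohort, b: SurvivalCohort) -> TestResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both cohorts must be non-empty")
    res = _ll_logrank(a.days, b.days, event_observed_A=a.events, event_observed_B=b.events)
    return TestResult(
        statistic=float(res.test_statistic), df=1, p_value=float(res.p_value)
    )


def expected_cross_frequencies(cross: CrossSpec) -> dict[str, float]:
    """Mendelian offspring class probabilities for a two-parent cross.

    Enumerates the four equally likely gamete combinations, removes
    balancer homozygotes, applies per-genotype viability coefficients,
    and renormalises over the surviving classes.
    """
    raw: dict[str, float] = {}
    for ga in cross.parent_a:
        for gb in cross.parent_b:
            label = genotype_label(ga, gb)
            raw[label] = raw.get(label, 0.0) + 0.25
    weighted: dict[str, float] = {}
    for label, p in raw.items():
        a, _, b = label.partition("/")
        if a == b and a in BALANCER_ALLELES:
            continue  # balancer homozygotes are inviable
        v = float(cross.viability.get(label, 1.0))
        if p * v > 0:
            weighted[label] = p * v
    total = sum(weighted.values())
    if total <= 0:
        raise ParameterError("all offspring classes are inviable")
    return {label: p / total for label, p in sorted(weighted.items())}


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score 95% (by default) confidence interval for a proportion."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def homozygosity_ratio(
    counts: GenotypeCounts, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Fraction of knock-in homozygotes among all scored offspring.

    Returns the point estimate and its Wilson confidence interval.
    """
    total = counts.total
    if total <= 0:
        raise ParameterError("cannot compute a ratio from zero offspring")
    hom = sum(c for label, c in counts.counts.items() if is_homozygote(label))
    return hom / total, wilson_interval(hom, total, alpha=alpha)


def chi2_homogeneity(
    test: GenotypeCounts, reference: GenotypeCounts, correction: bool = False
) -> TestResult:
    """Pearson chi-square test of homogeneity of the homozygote proportion.

    Builds the 2x2 table (homozygote, non-homozygote) x (test, reference).
    Continuity correction is off by default.
    """

    def split(c: GenotypeCounts) -> tuple[int, int]:
        hom = sum(v for label, v in c.counts.items() if is_homozygote(label))
        return hom, c.total - hom

    t_hom, t_other = split(test)
    r_hom, r_other = split(reference)
    table = np.array([[t_hom, t_other], [r_hom, r_other]], dtype=float)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ParameterError("chi-square table has an empty margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
    return TestResult(statistic=float(chi2), df=int(df), p_value=float(p))


def dominance_contrast(
    het_with_mutant: SurvivalCohort, het_with_deletion: SurvivalCohort
) -> tuple[TestResult, float | None, str]:
    """Contrast survival of mutant-over-WT heterozygotes against
    deletion-over-WT hemizygotes.

    If the mutant allele merely removes one functional gene dose
    (haploinsufficiency) the two cohorts should survive alike; a mutant
    heterozygote doing *worse* than the deletion heterozygote indicates a
    dominant-negative interaction (e.g. poisoning of WT subunits in an
    obligate dimer).  Returns the log-rank result, the KM median
    difference (mutant minus deletion; ``None`` if either median is
    undefined), and an interpretive flag string.
    """
    lr = logrank_test(het_with_mutant, het_with_deletion)
    m_mut = km_estimate(het_with_mutant).median
    m_del = km_estimate(het_with_deletion).median
    diff = None if (m_mut is None or m_del is None) else m_mut - m_del
    if diff is None or diff == 0:
        flag = "no median difference"
    elif diff < 0:
        flag = "consistent with dominant-negative"
    else:
        flag = "consistent with haploinsufficiency-only"
    return lr, diff, flag


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni-adjusted p-values (clipped at 1) and rejection flags."""
    p = np.asarray(list(p_values), dtype=float)
    adj = np.minimum(p * p.size, 1.0)
    return adj, adj < alpha
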