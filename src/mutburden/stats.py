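"""Auxiliary cohort statistics.

Welch's t test, Pearson correlation, simple-linear-fit R^2, modified
Z-score outlier detection, comparison of an observed burden against the
trio-expected paternal germline accumulation (fold change and
years-to-accumulate), and cross-sample mutation overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str


@dataclass
class TrioModel:
    """Expected paternal-germline mutation accumulation from trio studies.

    ``expected(age) = intercept + slope * age`` in mutations per (haploid)
    genome. Defaults (1.5 mutations/year, 7 at age 0) are illustrative
    stand-ins for external trio fits and are configuration, not assertions.
    """

    slope: float = 1.5
    intercept: float = 7.0
    genome_equivalent: float = 2.91e9

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("trio slope must be positive")

    def expected(self, age: float) -> float:
        return self.intercept + self.slope * age


@dataclass
class TrioComparison:
    expected: float
    fold_change: float
    excess: float
    years_equivalent: float


def welch_t_test(x, y) -> TestResult:
    """Two-sided Welch's t test (unequal variances, Welch-Satterthwaite df).

    Both samples entirely constant and equal is reported as t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, None, 1.0, "welch_t")
        raise ValueError("both samples constant with different means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "welch_t")


def pearson_correlation(x, y) -> TestResult:
    """Sample Pearson r with the exact t-based two-sided p-value (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), float(len(x) - 2), float(res.pvalue), "pearson")


def linear_r_squared(x, y) -> float:
    """R^2 of the simple linear fit of y on x (squared Pearson r)."""
    return pearson_correlation(x, y).statistic ** 2


def modified_z_scores(values, threshold: float = 3.5) -> tuple[np.ndarray, np.ndarray]:
    """Robust outlier scores z_i = 0.6745 (v_i - median) / MAD.

    MAD is the unscaled median absolute deviation. When MAD is 0 with all
    values equal, all scores are 0; when MAD is 0 otherwise, off-median
    values get +/-inf sentinels. Returns (scores, outlier flags at
    |z| > threshold).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        dev = v - med
        scores = np.where(dev == 0, 0.0, np.where(dev > 0, np.inf, -np.inf))
    else:
        scores = 0.6745 * (v - med) / mad
    return scores, np.abs(scores) > threshold


def trio_comparison(
    observed_mutations: float, age: float, model: TrioModel | None = None
) -> TrioComparison:
    """Compare an observed per-genome burden against the trio expectation.

    years_equivalent answers "how long would normal germline accumulation
    take to produce the excess": excess / slope.
    """
    model = model or TrioModel()
    if age < 0:
        raise ValueError("age must be non-negative")
    expected = model.expected(age)
    if expected <= 0:
        raise ValueError("expected burden must be positive")
    excess = observed_mutations - expected
    return TrioComparison(
        expected=expected,
        fold_change=observed_mutations / expected,
        excess=excess,
        years_equivalent=excess / model.slope,
    )


def shared_mutation_count(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Number of distinct (chrom, pos, ref, alt) present in both tables.

    Used e.g. to confirm that mutations called in sperm are absent from the
    same participant's saliva.
    """
    keys = ["chrom", "pos", "ref", "alt"]
    if len(a) == 0 or len(b) == 0:
        return 0
    ka = a[keys].drop_duplicates()
    kb = b[keys].drop_duplicates()
    return int(len(ka.merge(kb, on=keys)))
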