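"""Cohort-level statistics: age regressions, group comparisons, and
per-sample signature-signature correlations.

Each clonal lineage is one observation (multiple clones from one donor count
separately, matching the per-sample points of the figures this mirrors).
Regressions are ordinary least squares with t-based 95% confidence
intervals; group comparisons use the two-sided Mann-Whitney U test, exact
for small tie-free samples, with an explicit Bonferroni family size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]  # 95% CI
    p: float  # p-value for slope != 0
    n: int
    r_squared: float = float("nan")

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    medians: tuple[float, float]
    u_statistic: float
    p: float
    p_bonferroni: float
    method: str  # exact / asymptotic


def _ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        p=float(model.pvalues[1]),
        n=int(x.size),
        r_squared=float(model.rsquared),
    )


def regress_vs_age(values: Sequence[float], ages: Sequence[float]) -> RegressionFit:
    """OLS of a per-sample quantity on donor age (slope in units per year)."""
    return _ols_fit(ages, values)


def correlate(x_values: Sequence[float], y_values: Sequence[float]) -> RegressionFit:
    """OLS of y on x for two per-sample quantities."""
    return _ols_fit(x_values, y_values)


def compare_groups(values: Sequence[float], labels: Sequence[str],
                   family_size: int = 1,
                   exclude: Optional[Sequence[bool]] = None) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of a quantity between two groups.

    The exact null distribution is used for combined n <= 25 without ties,
    the tie-corrected normal approximation otherwise.  ``family_size``
    controls the Bonferroni correction (min(1, p * family_size)).
    ``exclude`` drops flagged observations first (e.g. the
    melanocyte-exclusion sensitivity analysis).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if exclude is not None:
        mask = ~np.asarray(exclude, dtype=bool)
        values, labels = values[mask], labels[mask]
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(values).size < values.size
    method = "exact" if (a.size + b.size <= 25 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return GroupComparison(
        labels=(groups[0], groups[1]),
        n=(int(a.size), int(b.size)),
        medians=(float(np.median(a)), float(np.median(b))),
        u_statistic=float(res.statistic),
        p=p,
        p_bonferroni=min(1.0, p * family_size),
        method=method,
    )
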