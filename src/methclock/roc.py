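"""Per-site rate of change (ROC) of methylation with age.

Each site gets an ordinary least-squares regression of methylation level
(in percent) on age (in weeks); the slope is the site's ROC in % per week.
Sites whose model passes a p-value and an R-squared filter are averaged to
a mean ROC.  The R-squared cutoff is configurable (default 0.65; 0.5 is
the other convention in circulation) and both are worth reporting when the
choice matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import MethylationMatrix, SiteKey

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_R2_THRESHOLD = 0.65


@dataclass(frozen=True)
class SiteROC:
    key: SiteKey | None
    slope: float                # % methylation per week
    intercept: float
    p_value: float
    r_squared: float


@dataclass(frozen=True)
class MeanROC:
    mean_slope: float
    sd_slope: float
    n_retained: int

    @property
    def defined(self) -> bool:
        return self.n_retained > 0


def site_regression(
    ages_weeks: Sequence[float],
    fractions: Sequence[float],
    key: SiteKey | None = None,
) -> SiteROC:
    """OLS of 100 x fraction on age in weeks for one site.

    Constant methylation yields slope 0, R-squared 0 and p 1 (the site can
    never be retained).  Fewer than 3 points or a single distinct age is an
    error.
    """
    x = np.asarray(ages_weeks, dtype=float)
    y = 100.0 * np.asarray(fractions, dtype=float)
    if x.size != y.size:
        raise ValueError("ages and fractions differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all ages identical: slope is unidentifiable")
    if np.ptp(y) == 0:
        return SiteROC(key, 0.0, float(y[0]), 1.0, 0.0)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return SiteROC(key, float(res.slope), float(res.intercept), p, r2)


def site_roc_table(
    matrix: MethylationMatrix, sites: Sequence[SiteKey] | None = None
) -> list[SiteROC]:
    """Per-site regressions against the manifest ages (days -> weeks)."""
    ages_weeks = matrix.ages_days / 7.0
    if sites is None:
        rows = range(matrix.n_sites)
        keys = matrix.sites
    else:
        index = matrix.site_index()
        keys = list(sites)
        rows = [index[k] for k in keys]
    return [
        site_regression(ages_weeks, matrix.fractions[i, :], key=k)
        for i, k in zip(rows, keys)
    ]


def mean_roc(
    site_rocs: Sequence[SiteROC],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> MeanROC:
    """Mean and SD of slopes over sites passing both filters.

    An empty retained set gives ``n_retained = 0`` with NaN summaries
    (``defined`` is False) rather than a silent zero.
    """
    if not (0 < p_threshold < 1 and 0 < r2_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    slopes = np.array(
        [r.slope for r in site_rocs
         if r.p_value < p_threshold and r.r_squared > r2_threshold]
    )
    if slopes.size == 0:
        return MeanROC(float("nan"), float("nan"), 0)
    sd = float(np.std(slopes, ddof=1)) if slopes.size > 1 else float("nan")
    return MeanROC(float(np.mean(slopes)), sd, int(slopes.size))


def retained_slopes(
    site_rocs: Sequence[SiteROC],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> np.ndarray:
    return np.array(
        [r.slope for r in site_rocs
         if r.p_value < p_threshold and r.r_squared > r2_threshold]
    )


def compare_roc(
    slopes_a: Sequence[float], slopes_b: Sequence[float]
) -> tuple[float, float]:
    """Compare two slope collections: location and spread.

    Returns ``(wilcoxon_p, levene_p)``: a two-sided Wilcoxon rank-sum test
    on the slopes and a mean-centered Levene test on their variances.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 slopes per collection")
    w_p = float(stats.ranksums(a, b).pvalue)
    l_p = float(stats.levene(a, b, center="mean").pvalue)
    return w_p, l_p
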