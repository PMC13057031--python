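"""Group-comparison, concordance and variability statistics.

Two-group comparisons follow a normality-gated protocol: both groups are
tested with Shapiro-Wilk; if both pass at the gate alpha the two-tailed
Welch's t-test is used, otherwise the two-tailed Mann-Whitney U test (exact
enumeration for small samples, tie-corrected normal approximation
otherwise).  Method-comparison concordance is Pearson correlation plus
ordinary least-squares regression on paired values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigError

#: largest combined sample size for which the Mann-Whitney null distribution
#: is enumerated exactly (C(16, 8) = 12,870 partitions)
EXACT_MW_MAX_N = 16


@dataclass
class GroupTestResult:
    method: str                  # welch_t | mann_whitney_u | mann_whitney_exact
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    shapiro_p: tuple[float | None, float | None] = (None, None)


@dataclass
class ConcordanceResult:
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float               # regression/correlation p (identical for OLS)
    n: int


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled)


def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-tailed Mann-Whitney U by full enumeration.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes (midranks, so ties are handled exactly) and reports the
    probability of a U at least as far from its null mean n_a·n_b/2 as the
    observed one.  Returns ``(U, p)`` with U computed for the first group.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ConfigError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_obs = _u_from_ranks(ranks[:n_a], n_a)
    centre = n_a * n_b / 2.0
    d_obs = abs(u_obs - centre)
    total = math.comb(n_a + n_b, n_a)
    count = 0
    for idx in itertools.combinations(range(n_a + n_b), n_a):
        u = _u_from_ranks(ranks[list(idx)], n_a)
        if abs(u - centre) >= d_obs - 1e-9:
            count += 1
    return u_obs, count / total


def compare_groups(a, b, alpha_normality: float = 0.05) -> GroupTestResult:
    """Normality-gated two-group comparison (two-tailed throughout).

    Groups of fewer than 3 observations cannot be Shapiro-Wilk tested and
    route directly to the exact Mann-Whitney test.  Identical constant
    groups fall through the exact route to p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigError("both groups must be non-empty")
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each group needs at least 2 observations")

    base = dict(mean_a=float(a.mean()), mean_b=float(b.mean()),
                median_a=float(np.median(a)), median_b=float(np.median(b)),
                n_a=len(a), n_b=len(b))

    sw_p: list[float | None] = [None, None]
    normal = len(a) >= 3 and len(b) >= 3
    if normal:
        for i, g in enumerate((a, b)):
            if np.ptp(g) == 0:          # constant group: not normal
                sw_p[i] = 0.0
                normal = False
            else:
                sw_p[i] = float(sps.shapiro(g).pvalue)
                if sw_p[i] < alpha_normality:
                    normal = False

    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        return GroupTestResult(method="welch_t", statistic=float(res.statistic),
                               p_value=float(res.pvalue),
                               shapiro_p=(sw_p[0], sw_p[1]), **base)
    if len(a) + len(b) <= EXACT_MW_MAX_N:
        u, p = mann_whitney_exact(a, b)
        return GroupTestResult(method="mann_whitney_exact", statistic=u,
                               p_value=p, shapiro_p=(sw_p[0], sw_p[1]), **base)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupTestResult(method="mann_whitney_u",
                           statistic=float(res.statistic),
                           p_value=float(res.pvalue),
                           shapiro_p=(sw_p[0], sw_p[1]), **base)


# ---------------------------------------------------------------------------
# concordance and CV
# ---------------------------------------------------------------------------

def concordance(paired) -> ConcordanceResult:
    """Pearson correlation + OLS regression on paired measurements."""
    arr = np.asarray(paired, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ConfigError("paired must be an (n, 2) array of (x, y)")
    if len(arr) < 3:
        raise ConfigError("need at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ConfigError("x is constant; regression undefined")
    reg = sps.linregress(x, y)
    r = float(reg.rvalue)
    return ConcordanceResult(pearson_r=r, r_squared=r * r,
                             slope=float(reg.slope),
                             intercept=float(reg.intercept),
                             p_value=float(reg.pvalue), n=len(arr))


def coefficient_of_variation(values) -> float:
    """CV (%): 100 × sample sd (n−1 denominator) / mean.

    Returns NaN (undefined) when the mean is zero.
    """
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ConfigError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def kruskal_wallis(*groups):
    """Multi-group rank test; thin pass-through returning (H, p)."""
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
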