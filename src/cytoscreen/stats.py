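"""Statistical layer for screening results.

Covers the tests a plate experiment needs: a Kolmogorov-Smirnov normality
check (with the estimated-parameters caveat flagged), Bonferroni
correction, Tukey-Kramer HSD all-pairs comparisons via the studentized
range distribution, and the OLS agreement model used to validate software
counts against manual counts (``manual ~ software``).

Significance convention: p < 0.05; figure annotations map * / ** / *** to
the 0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = ["KSResult", "HSDResult", "AgreementResult", "ks_normality",
           "bonferroni", "tukey_hsd", "agreement_model",
           "relative_difference", "significance_stars"]


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    mean: float
    sd: float
    n: int
    # p-value is anti-conservative when mean/sd come from the same sample
    # (the Lilliefors situation); reports must carry this caveat.
    estimated_parameters: bool = True


def ks_normality(sample: Sequence[float]) -> KSResult:
    """One-sample KS test against a normal with sample-estimated mean/sd."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("KS normality test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    mean = x.mean()
    res = sps.kstest(x, "norm", args=(mean, sd))
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                    mean=float(mean), sd=float(sd), n=x.size)


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p.size * p)


@dataclass(frozen=True)
class HSDResult:
    """All pairwise group comparisons with family-wise 95% intervals."""

    comparisons: pd.DataFrame  # group_i, group_j, diff, se, q, p_adj, ci_low, ci_high
    n_groups: int
    df_within: int
    pooled_variance: float
    q_critical: float
    alpha: float = 0.05


def _pairwise_q(groups: List[np.ndarray]):
    """Tukey-Kramer q statistics with pooled within-group variance.

    Returns (pairs, diffs, ses, qs, df, s2) where q = |diff| / se and
    se = sqrt(s2/2 * (1/n_i + 1/n_j)) (the Kramer unequal-n form).
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df = int(ns.sum() - k)
    s2 = float(sum((len(g) - 1) * g.var(ddof=1) for g in groups) / df)
    if s2 <= 0:
        raise ValueError("zero pooled within-group variance: HSD undefined")
    pairs, diffs, ses = [], [], []
    for i, j in combinations(range(k), 2):
        pairs.append((i, j))
        diffs.append(means[i] - means[j])
        ses.append(math.sqrt(s2 / 2.0 * (1.0 / ns[i] + 1.0 / ns[j])))
    diffs = np.array(diffs)
    ses = np.array(ses)
    qs = np.abs(diffs) / ses
    return pairs, diffs, ses, qs, df, s2


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05,
              labels: Sequence[str] | None = None) -> HSDResult:
    """Tukey-Kramer HSD over all group pairs.

    Adjusted p-values come from the studentized range distribution with
    ``k`` groups and the pooled within-group degrees of freedom; the
    family-wise interval uses the same distribution's 1-alpha quantile.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    pairs, diffs, ses, qs, df, s2 = _pairwise_q(arrays)
    k = len(arrays)
    p_adj = sps.studentized_range.sf(qs, k, df)
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df))
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    rows = []
    for (i, j), diff, se, q, p in zip(pairs, diffs, ses, qs, p_adj):
        rows.append({"group_i": labels[i], "group_j": labels[j],
                     "diff": float(diff), "se": float(se), "q": float(q),
                     "p_adj": float(np.clip(p, 0.0, 1.0)),
                     "ci_low": float(diff - q_crit * se),
                     "ci_high": float(diff + q_crit * se)})
    return HSDResult(comparisons=pd.DataFrame(rows), n_groups=k,
                     df_within=df, pooled_variance=s2, q_critical=q_crit,
                     alpha=alpha)


@dataclass(frozen=True)
class AgreementResult:
    """OLS agreement between manual and software counts (manual ~ software)."""

    slope: float
    slope_ci: Tuple[float, float]
    intercept: float
    intercept_ci: Tuple[float, float]
    t_slope: float
    t_intercept: float
    p_slope: float
    p_intercept: float
    r_squared: float
    adj_r_squared: float
    std_beta: float
    std_beta_ci: Tuple[float, float]
    df: int
    n: int


def agreement_model(manual_counts: Sequence[float],
                    software_counts: Sequence[float]) -> AgreementResult:
    """Fit ``manual ~ software`` by OLS and report agreement diagnostics.

    The standardized beta is obtained by refitting on z-scored variables.
    """
    y = np.asarray(manual_counts, dtype=float)
    x = np.asarray(software_counts, dtype=float)
    if y.shape != x.shape:
        raise ValueError("manual and software vectors must have equal length")
    n = y.size
    if n < 3:
        raise ValueError("agreement model needs n >= 3 pairs")
    if x.std(ddof=1) == 0:
        raise ValueError("software counts have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)

    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    zres = sm.OLS(zy, sm.add_constant(zx)).fit()
    zci = zres.conf_int(alpha=0.05)

    return AgreementResult(
        slope=float(res.params[1]), slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(res.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        t_slope=float(res.tvalues[1]), t_intercept=float(res.tvalues[0]),
        p_slope=float(res.pvalues[1]), p_intercept=float(res.pvalues[0]),
        r_squared=float(res.rsquared), adj_r_squared=float(res.rsquared_adj),
        std_beta=float(zres.params[1]),
        std_beta_ci=(float(zci[1][0]), float(zci[1][1])),
        df=int(res.df_resid), n=n)


def relative_difference(a: float, b: float) -> Tuple[float, int]:
    """Percent difference of b relative to a: 100 |b - a| / a.

    Returns (raw percent, integer-rounded presentation value).
    """
    if a <= 0:
        raise ValueError("reference count must be > 0")
    pct = 100.0 * abs(b - a) / a
    return pct, int(round(pct))


def significance_stars(p: float) -> str:
    """Conventional star annotation: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
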