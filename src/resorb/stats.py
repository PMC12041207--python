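"""Inferential toolkit: t-tests with effect sizes, power, assumption checks.

Significance throughout the package follows a joint rule: a comparison is
called significant only when its p-value falls below alpha *and* the
magnitude of Cohen's d exceeds a minimum effect size (defaults 0.05 and
0.2), so trivially small but precisely estimated differences are not
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

DEFAULT_ALPHA = 0.05
DEFAULT_D_MIN = 0.2


@dataclass(frozen=True)
class ComparisonResult:
    estimate: float       # mean difference, units of the input
    t_stat: float
    df: float
    p_two_sided: float
    cohen_d: float
    ci_low: float
    ci_high: float
    significant: bool
    power: float | None = None
    degenerate: bool = False   # zero-variance input; t/p/d conventions applied


def joint_significance(p: float, d: float, alpha: float = DEFAULT_ALPHA,
                       d_min: float = DEFAULT_D_MIN) -> bool:
    """Significant iff p < alpha and |d| > d_min."""
    if not (0 <= p <= 1):
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    return bool(p < alpha and abs(d) > d_min)


def paired_t(a, b, alpha: float = DEFAULT_ALPHA, d_min: float = DEFAULT_D_MIN) -> ComparisonResult:
    """Paired-samples t-test on a - b with Cohen's d = mean(diff)/sd(diff).

    The 95% CI on the mean difference uses the t quantile with n-1 degrees
    of freedom.  Zero-variance differences are degenerate: t=0/p=1/d=0 when
    the mean difference is zero, otherwise an infinite t reported as p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    diff = a - b
    md = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    df = n - 1
    if sd == 0:
        if md == 0:
            return ComparisonResult(0.0, 0.0, df, 1.0, 0.0, 0.0, 0.0,
                                    significant=False, degenerate=True)
        t = float(np.sign(md) * np.inf)
        return ComparisonResult(md, t, df, 0.0, t, md, md,
                                significant=joint_significance(0.0, t, alpha, d_min),
                                degenerate=True)
    se = sd / np.sqrt(n)
    t = md / se
    p = float(2 * stats.t.sf(abs(t), df))
    d = md / sd
    tq = stats.t.ppf(0.975, df)
    return ComparisonResult(
        estimate=md, t_stat=float(t), df=df, p_two_sided=p, cohen_d=float(d),
        ci_low=float(md - tq * se), ci_high=float(md + tq * se),
        significant=joint_significance(p, d, alpha, d_min),
    )


def independent_t(a, b, welch: bool = True, alpha: float = DEFAULT_ALPHA,
                  d_min: float = DEFAULT_D_MIN) -> ComparisonResult:
    """Independent-samples t-test (Welch by default; pooled optional).

    Cohen's d always uses the pooled standard deviation, the conventional
    standardiser, regardless of which t variant is chosen.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 observations")
    md = float(np.mean(a) - np.mean(b))
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    d = md / np.sqrt(sp2) if sp2 > 0 else (0.0 if md == 0 else float(np.sign(md) * np.inf))
    if v1 == 0 and v2 == 0:
        if md == 0:
            return ComparisonResult(0.0, 0.0, n1 + n2 - 2, 1.0, 0.0, 0.0, 0.0,
                                    significant=False, degenerate=True)
        t = float(np.sign(md) * np.inf)
        return ComparisonResult(md, t, n1 + n2 - 2, 0.0, d, md, md,
                                significant=joint_significance(0.0, d, alpha, d_min),
                                degenerate=True)
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = n1 + n2 - 2
    se = np.sqrt(se2)
    t = md / se
    p = float(2 * stats.t.sf(abs(t), df))
    tq = stats.t.ppf(0.975, df)
    return ComparisonResult(
        estimate=md, t_stat=float(t), df=float(df), p_two_sided=p, cohen_d=float(d),
        ci_low=float(md - tq * se), ci_high=float(md + tq * se),
        significant=joint_significance(p, d, alpha, d_min),
    )


def power_two_sample(d: float, n1: int, n2: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Power of a two-sided two-sample t-test at effect size d.

    Uses the noncentral t distribution with noncentrality
    d * sqrt(n1 n2 / (n1 + n2)) and n1 + n2 - 2 degrees of freedom.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    nc = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    return float(power)


def check_assumptions(*groups) -> dict:
    """Advisory normality and homoscedasticity report for one or more groups.

    Levene's test (mean-centred) assesses homoscedasticity across groups;
    Shapiro-Wilk assesses normality per group.  Advisory only — the report
    never gates downstream tests.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 3:
            raise ValidationError("each group needs at least 3 observations")
    report: dict = {"normality": []}
    for g in arrays:
        if np.ptp(g) == 0:
            report["normality"].append({"statistic": float("nan"), "p": float("nan"),
                                        "constant": True})
        else:
            stat, p = stats.shapiro(g)
            report["normality"].append({"statistic": float(stat), "p": float(p),
                                        "constant": False})
    if len(arrays) >= 2:
        stat, p = stats.levene(*arrays, center="mean")
        report["levene"] = {"statistic": float(stat), "p": float(p)}
    else:
        report["levene"] = {"statistic": float("nan"), "p": float("nan")}
    return report
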