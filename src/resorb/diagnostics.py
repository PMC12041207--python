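"""Diagnostics for the three nutrient-resorption control strategies.

The senesced-versus-mature concentration relation is modelled as a power law

    Nu_sen = a * Nu_mat^b,

fitted as a straight line after log10 transformation.  Substituting into the
efficiency definition gives NuRE = (1 - a * Nu_mat^(b-1)) * 100%, so b > 1
means resorption is more efficient where mature leaves are nutrient-poor
(*concentration control*).  Analogously, the resorbed N:P ratio is modelled
against the mature-leaf N:P ratio,

    resorbed N:P = eps * (leaf N:P)^lambda,

whence the efficiency ratio NRE:PRE scales as (leaf N:P)^(lambda-1): a slope
lambda significantly below 1 means the scarcer nutrient is resorbed
preferentially (*limitation control*).  *Stoichiometry control* — nutrients
withdrawn in proportion to their mature-leaf ratio — is judged from a
positive NRE-PRE correlation together with a positive resorbed-N:P versus
mature-N:P regression.

Fits default to ordinary least squares on site means (the transparent
estimator at the 30-site scale); a replicate-aware mixed mode with a random
site intercept is available and yields the same fixed-effect slope when each
site has a single observation.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

MODES = ("site_means", "mixed")


@dataclass(frozen=True)
class RegressionFit:
    """A simple linear fit with a slope test against an arbitrary null value."""

    slope: float
    intercept: float
    slope_se: float
    r2: float
    n: int
    df: int
    p_slope_zero: float
    p_slope_vs_null: float | None = None
    null_slope: float | None = None
    mode: str = "site_means"


@dataclass(frozen=True)
class StrategyVerdict:
    strategy: str
    nutrient_context: str
    supported: bool
    evidence: dict
    criterion: str


def _ols_line(lx: np.ndarray, ly: np.ndarray, mode: str) -> RegressionFit:
    res = stats.linregress(lx, ly)
    n = lx.size
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r2=float(res.rvalue**2),
        n=int(n),
        df=int(n - 2),
        p_slope_zero=float(res.pvalue),
        mode=mode,
    )


def _mixed_line(lx: np.ndarray, ly: np.ndarray, groups: np.ndarray) -> RegressionFit:
    import statsmodels.api as sm

    data = pd.DataFrame({"x": lx, "y": ly, "g": groups})
    sizes = data.groupby("g").size()
    if (sizes == 1).all():
        # singleton groups: the random intercept is unidentified and the
        # fixed-effect line reduces exactly to OLS
        return dataclasses.replace(_ols_line(lx, ly, "site_means"), mode="mixed")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(data["y"], sm.add_constant(data["x"]), groups=data["g"])
        fit = model.fit(reml=True)
    slope = float(fit.params["x"])
    se = float(fit.bse["x"])
    n_groups = sizes.size
    df = max(n_groups - 2, 1)
    resid = fit.resid
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((data["y"] - data["y"].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    t0 = slope / se
    return RegressionFit(
        slope=slope,
        intercept=float(fit.params["const"]),
        slope_se=se,
        r2=r2,
        n=int(len(data)),
        df=int(df),
        p_slope_zero=float(2 * stats.t.sf(abs(t0), df)),
        mode="mixed",
    )


def fit_loglog(x, y, mode: str = "site_means", groups=None) -> RegressionFit:
    """Fit log10(y) on log10(x).

    Parameters
    ----------
    x, y
        Strictly positive observations.
    mode
        ``"site_means"`` for OLS on the given vectors, ``"mixed"`` for a
        random-site-intercept model on replicate-level data (``groups``
        required and aligned with ``x``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    bad = np.nonzero(~((x > 0) & (y > 0)))[0]
    if bad.size:
        raise ValidationError(f"non-positive value at index {bad[0]}; log10 undefined")
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 points, got {x.size}")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0:
        raise DegenerateFitError("constant predictor: slope is unidentified")
    if mode == "site_means":
        return _ols_line(lx, ly, mode)
    if mode == "mixed":
        if groups is None:
            raise ValidationError("mixed mode requires groups")
        return _mixed_line(lx, ly, np.asarray(groups))
    raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")


def fit_linear(x, y, mode: str = "site_means", groups=None) -> RegressionFit:
    """Untransformed analogue of :func:`fit_loglog` (used for ratio fits)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor: slope is unidentified")
    if mode == "site_means":
        return _ols_line(x, y, mode)
    if mode == "mixed":
        if groups is None:
            raise ValidationError("mixed mode requires groups")
        return _mixed_line(x, y, np.asarray(groups))
    raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")


def test_slope_against(fit: RegressionFit, null_slope: float) -> RegressionFit:
    """Attach a two-sided t-test of the slope against ``null_slope``.

    t = (slope - null) / SE with the fit's residual degrees of freedom.
    """
    if not (fit.slope_se > 0):
        raise DegenerateFitError("slope standard error is zero; t-test undefined")
    t = (fit.slope - null_slope) / fit.slope_se
    p = float(2 * stats.t.sf(abs(t), fit.df))
    return dataclasses.replace(fit, p_slope_vs_null=p, null_slope=float(null_slope))


# not a pytest case, despite the conventional statistics name
test_slope_against.__test__ = False  # type: ignore[attr-defined]


def one_sided_slope_p(fit: RegressionFit, null_slope: float, direction: str) -> float:
    """One-sided p for slope > null (``"greater"``) or slope < null (``"less"``)."""
    if not (fit.slope_se > 0):
        raise DegenerateFitError("slope standard error is zero; t-test undefined")
    t = (fit.slope - null_slope) / fit.slope_se
    if direction == "greater":
        return float(stats.t.sf(t, fit.df))
    if direction == "less":
        return float(stats.t.cdf(t, fit.df))
    raise ValidationError("direction must be 'greater' or 'less'")


def _fit_as_dict(fit: RegressionFit) -> dict:
    return dataclasses.asdict(fit)


def _attach_null_test(fit: RegressionFit, null_slope: float) -> RegressionFit:
    """As :func:`test_slope_against`, but treating a perfect fit (zero slope
    SE) as the limit p -> 0 for a slope away from the null, p = 1 at it."""
    if fit.slope_se == 0:
        at_null = np.isclose(fit.slope, null_slope, rtol=1e-9, atol=1e-12)
        p = 1.0 if at_null else 0.0
        return dataclasses.replace(fit, p_slope_vs_null=p, null_slope=float(null_slope))
    return test_slope_against(fit, null_slope)


def _directional_p(fit: RegressionFit, null_slope: float, direction: str) -> float:
    """One-sided slope p-value with the same zero-SE limiting convention."""
    if fit.slope_se == 0:
        if np.isclose(fit.slope, null_slope, rtol=1e-9, atol=1e-12):
            return 1.0
        exceeds = fit.slope > null_slope if direction == "greater" else fit.slope < null_slope
        return 0.0 if exceeds else 1.0
    return one_sided_slope_p(fit, null_slope, direction)


def concentration_control_test(
    site_df: pd.DataFrame,
    nutrient: str,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "site_means",
    replicate_df: pd.DataFrame | None = None,
) -> StrategyVerdict:
    """Test concentration control: senesced~mature power-law exponent b > 1.

    Supported when the log-log regression is itself significant at ``alpha``
    and the slope is significantly greater than 1 (one-sided).
    ``site_df``/``replicate_df`` are the outputs of ``pair_site_periods``.
    """
    cols = {"N": ("mature_n", "sen_n"), "P": ("mature_p", "sen_p")}
    try:
        mat_col, sen_col = cols[nutrient]
    except KeyError:
        raise ValidationError(f"nutrient must be N or P, got {nutrient!r}") from None
    if mode == "mixed":
        if replicate_df is None:
            raise ValidationError("mixed mode requires replicate_df")
        fit = fit_loglog(
            replicate_df[mat_col], replicate_df[sen_col],
            mode="mixed", groups=replicate_df["site_id"],
        )
    else:
        fit = fit_loglog(site_df[mat_col], site_df[sen_col], mode=mode)
    fit = _attach_null_test(fit, 1.0)
    p_gt1 = _directional_p(fit, 1.0, "greater")
    supported = (fit.p_slope_zero < alpha) and (p_gt1 < alpha)
    return StrategyVerdict(
        strategy="concentration_control",
        nutrient_context=nutrient,
        supported=bool(supported),
        evidence={"fit": _fit_as_dict(fit), "p_slope_gt_1": p_gt1},
        criterion=(
            f"log10(senesced)~log10(mature) regression p < {alpha} "
            f"and slope > 1 (one-sided p < {alpha})"
        ),
    )


def _valid_ratio_rows(site_resorption: pd.DataFrame) -> pd.DataFrame:
    valid = site_resorption.dropna(subset=["resorbed_np", "mature_np"])
    valid = valid[(valid["resorbed_np"] > 0) & (valid["mature_np"] > 0)]
    n_excluded = len(site_resorption) - len(valid)
    if n_excluded:
        logger.info(
            "excluded %d site(s) with undefined or non-positive resorbed N:P",
            n_excluded,
        )
    if len(valid) < 3:
        raise InsufficientDataError(
            f"only {len(valid)} site(s) with defined ratios; need at least 3"
        )
    return valid


def stoichiometry_control_test(
    site_resorption: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> StrategyVerdict:
    """Test stoichiometry control: N and P resorbed in their mature-leaf proportion.

    Supported when NRE and PRE correlate positively and significantly, and
    the resorbed N:P ratio regresses on the mature-leaf N:P ratio with a
    positive significant slope.
    """
    valid = _valid_ratio_rows(site_resorption)
    r, p_corr = stats.pearsonr(valid["nre"], valid["pre"])
    ratio_fit = fit_linear(valid["mature_np"], valid["resorbed_np"])
    supported = (
        (r > 0) and (p_corr < alpha)
        and (ratio_fit.slope > 0) and (ratio_fit.p_slope_zero < alpha)
    )
    return StrategyVerdict(
        strategy="stoichiometry_control",
        nutrient_context="N:P",
        supported=bool(supported),
        evidence={
            "nre_pre_r": float(r),
            "nre_pre_p": float(p_corr),
            "ratio_fit": _fit_as_dict(ratio_fit),
            "n_sites": int(len(valid)),
        },
        criterion=(
            f"corr(NRE, PRE) > 0 with p < {alpha} and resorbed N:P ~ mature N:P "
            f"slope > 0 with p < {alpha}"
        ),
    )


def limitation_control_test(
    site_resorption: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "site_means",
    replicate_resorption: pd.DataFrame | None = None,
) -> StrategyVerdict:
    """Test limitation control: resorbed-ratio exponent lambda < 1.

    Fits log10(resorbed N:P) on log10(mature-leaf N:P); supported when the
    slope is significantly below 1 (one-sided).
    """
    valid = _valid_ratio_rows(site_resorption)
    if mode == "mixed":
        if replicate_resorption is None:
            raise ValidationError("mixed mode requires replicate_resorption")
        rep = _valid_ratio_rows(replicate_resorption)
        fit = fit_loglog(
            rep["mature_np"], rep["resorbed_np"], mode="mixed", groups=rep["site_id"]
        )
    else:
        fit = fit_loglog(valid["mature_np"], valid["resorbed_np"], mode=mode)
    fit = _attach_null_test(fit, 1.0)
    p_lt1 = _directional_p(fit, 1.0, "less")
    supported = p_lt1 < alpha
    return StrategyVerdict(
        strategy="limitation_control",
        nutrient_context="N:P",
        supported=bool(supported),
        evidence={"fit": _fit_as_dict(fit), "p_slope_lt_1": p_lt1, "n_sites": int(fit.n)},
        criterion=f"log-log resorbed-ratio slope < 1 (one-sided p < {alpha})",
    )
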