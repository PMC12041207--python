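"""Resorption-versus-mineralization trade-off fits.

A cross-site trade-off is a negative linear association between a leaf
resorption quantity (NRE, PRE, or the NRE:PRE ratio) and a soil nutrient
supply quantity (net N or P mineralization rate, or their ratio).  Fits are
Gaussian identity-link linear models on site-level values; the mixed mode
adds a random site intercept over replicate-level responses.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import DEFAULT_ALPHA, RegressionFit, fit_linear
from .errors import InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TradeoffFit:
    response: str
    predictor: str
    fit: RegressionFit
    negative_tradeoff: bool  # slope < 0 and regression significant at alpha


def fit_tradeoff(response, predictor, mode: str = "site_means", groups=None,
                 alpha: float = DEFAULT_ALPHA,
                 response_name: str = "response",
                 predictor_name: str = "predictor") -> TradeoffFit:
    """Linear fit of a resorption response on a mineralization predictor.

    ``negative_tradeoff`` is True when the slope is negative and the
    regression is significant at ``alpha`` (two-sided slope-vs-zero test).
    """
    fit = fit_linear(predictor, response, mode=mode, groups=groups)
    negative = (fit.slope < 0) and (fit.p_slope_zero < alpha)
    return TradeoffFit(
        response=response_name,
        predictor=predictor_name,
        fit=fit,
        negative_tradeoff=bool(negative),
    )


def ratio_tradeoff(nre_pre_ratio, min_ratio, alpha: float = DEFAULT_ALPHA) -> TradeoffFit:
    """Trade-off fit of the NRE:PRE ratio on the N:P mineralization-rate ratio.

    Pairs with an undefined ratio (NaN or non-finite) are excluded with a
    logged count; fewer than 3 remaining pairs is an error.
    """
    x = np.asarray(min_ratio, dtype=float)
    y = np.asarray(nre_pre_ratio, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluded %d pair(s) with undefined ratios", n_excluded)
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"only {int(ok.sum())} valid ratio pair(s); need at least 3"
        )
    return fit_tradeoff(
        y[ok], x[ok], alpha=alpha,
        response_name="nre_pre_ratio", predictor_name="nmin_pmin_ratio",
    )


def tradeoff_suite(site_resorption: pd.DataFrame, site_rates: pd.DataFrame,
                   alpha: float = DEFAULT_ALPHA) -> list[TradeoffFit]:
    """The five standard trade-off fits on merged site tables.

    NRE~Nmin, PRE~Pmin, NRE:PRE~Nmin, NRE:PRE~Pmin, NRE:PRE~Nmin:Pmin.
    """
    merged = site_resorption.merge(site_rates, on="site_id", how="inner")
    if len(merged) < 3:
        raise InsufficientDataError(
            f"only {len(merged)} site(s) with both resorption and rates"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        eff_ratio = merged["nre"] / merged["pre"]
    eff_ratio = eff_ratio.where(merged["pre"] > 0)
    fits = [
        fit_tradeoff(merged["nre"], merged["n_rate"], alpha=alpha,
                     response_name="nre", predictor_name="n_min_rate"),
        fit_tradeoff(merged["pre"], merged["p_rate"], alpha=alpha,
                     response_name="pre", predictor_name="p_min_rate"),
        fit_tradeoff(eff_ratio, merged["n_rate"], alpha=alpha,
                     response_name="nre_pre_ratio", predictor_name="n_min_rate"),
        fit_tradeoff(eff_ratio, merged["p_rate"], alpha=alpha,
                     response_name="nre_pre_ratio", predictor_name="p_min_rate"),
        ratio_tradeoff(eff_ratio, merged["np_rate_ratio"], alpha=alpha),
    ]
    return fits


def tradeoff_frame(fits: list[TradeoffFit]) -> pd.DataFrame:
    """Flatten trade-off fits into one row per relationship."""
    rows = []
    for tf in fits:
        row = {"response": tf.response, "predictor": tf.predictor,
               "negative_tradeoff": tf.negative_tradeoff}
        row.update({k: v for k, v in dataclasses.asdict(tf.fit).items()
                    if k not in ("mode",)})
        rows.append(row)
    return pd.DataFrame(rows)
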