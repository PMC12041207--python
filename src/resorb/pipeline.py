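"""End-to-end pipeline: resorption -> strategies -> mineralization -> trade-off.

``run_pipeline`` executes every stage on a pair of input CSVs, writes one
CSV per stage plus a key/value summary report into the output directory, and
returns the in-memory results.  Identical inputs and config produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diagnostics import (
    concentration_control_test,
    limitation_control_test,
    stoichiometry_control_test,
)
from .errors import ConfigurationError, ResorbError
from .io import (
    DEFAULT_MLCF,
    pair_site_periods,
    read_incubation_table,
    read_leaf_table,
    write_results,
)
from .mineralization import aggregate_rates, rates_table
from .resorption import replicate_resorption_table, site_resorption_table
from .stats import paired_t
from .tradeoff import tradeoff_frame, tradeoff_suite

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    leaf_path: str | None = None
    incubation_path: str | None = None
    out_dir: str = "."
    alpha: float = 0.05
    d_min: float = 0.2
    mode: str = "site_means"
    mlcf: dict = field(default_factory=lambda: dict(DEFAULT_MLCF))
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.d_min < 0:
            raise ConfigurationError(f"d_min must be >= 0, got {self.d_min}")


class StageError(ResorbError):
    """An error in one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _verdict_row(v) -> dict:
    row = {
        "strategy": v.strategy,
        "nutrient_context": v.nutrient_context,
        "supported": v.supported,
        "criterion": v.criterion,
    }
    fit = v.evidence.get("fit") or v.evidence.get("ratio_fit")
    if fit:
        row.update(
            slope=fit["slope"], slope_se=fit["slope_se"], r2=fit["r2"],
            p_slope_zero=fit["p_slope_zero"], p_slope_vs_null=fit["p_slope_vs_null"],
        )
    for key in ("p_slope_gt_1", "p_slope_lt_1", "nre_pre_r", "nre_pre_p"):
        if key in v.evidence:
            row[key] = v.evidence[key]
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write per-stage CSVs plus ``summary.txt``."""
    config.validate()
    if config.leaf_path is None:
        raise ConfigurationError("leaf_path is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    try:
        records = read_leaf_table(config.leaf_path)
        site_df, replicate_df = pair_site_periods(records)
        site_res = site_resorption_table(site_df)
        rep_res = replicate_resorption_table(replicate_df)
        write_results(site_res, out / "resorption.csv")
        results["site_resorption"] = site_res
        results["replicate_resorption"] = rep_res
        logger.info("resorption: %d sites", len(site_res))
    except Exception as exc:
        raise StageError("compute-resorption", exc) from exc

    try:
        verdicts = [
            concentration_control_test(site_df, "N", alpha=config.alpha,
                                       mode=config.mode, replicate_df=replicate_df),
            concentration_control_test(site_df, "P", alpha=config.alpha,
                                       mode=config.mode, replicate_df=replicate_df),
            stoichiometry_control_test(site_res, alpha=config.alpha),
            limitation_control_test(site_res, alpha=config.alpha, mode=config.mode,
                                    replicate_resorption=rep_res),
        ]
        strategies = pd.DataFrame([_verdict_row(v) for v in verdicts])
        write_results(strategies, out / "strategies.csv")
        results["strategies"] = strategies
        logger.info("strategies: %d verdicts (%d supported)",
                    len(strategies), int(strategies["supported"].sum()))
    except Exception as exc:
        raise StageError("diagnose-strategies", exc) from exc

    if config.incubation_path is None:
        raise StageError(
            "mineralization",
            ConfigurationError("incubation_path is required for the "
                               "mineralization and trade-off stages"),
        )
    try:
        inc = read_incubation_table(config.incubation_path)
        site_rates = aggregate_rates(rates_table(inc))
        write_results(site_rates, out / "mineralization.csv")
        results["site_rates"] = site_rates
        logger.info("mineralization: %d sites", len(site_rates))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("mineralization", exc) from exc

    try:
        fits = tradeoff_suite(site_res, site_rates, alpha=config.alpha)
        tf = tradeoff_frame(fits)
        write_results(tf, out / "tradeoff.csv")
        results["tradeoff"] = tf
        logger.info("tradeoff: %d fits (%d negative)",
                    len(tf), int(tf["negative_tradeoff"].sum()))
    except Exception as exc:
        raise StageError("tradeoff", exc) from exc

    try:
        cmp_res = paired_t(site_res["nre"], site_res["pre"],
                           alpha=config.alpha, d_min=config.d_min)
        comparisons = pd.DataFrame([{"comparison": "nre_vs_pre_paired",
                                     **dataclasses.asdict(cmp_res)}])
        write_results(comparisons, out / "comparisons.csv")
        results["comparisons"] = comparisons
    except Exception as exc:
        raise StageError("compare", exc) from exc

    _write_summary(out / "summary.txt", config, results)
    return results


def _write_summary(path: Path, config: RunConfig, results: dict) -> None:
    import numpy
    import scipy
    import statsmodels

    site_res = results["site_resorption"]
    strategies = results["strategies"]
    tf = results["tradeoff"]
    cmp_row = results["comparisons"].iloc[0]
    lines = [
        f"resorb_version = {__version__}",
        f"numpy_version = {numpy.__version__}",
        f"scipy_version = {scipy.__version__}",
        f"statsmodels_version = {statsmodels.__version__}",
        f"alpha = {config.alpha}",
        f"d_min = {config.d_min}",
        f"mode = {config.mode}",
        f"n_sites = {len(site_res)}",
        f"mean_nre_percent = {site_res['nre'].mean():.6g}",
        f"mean_pre_percent = {site_res['pre'].mean():.6g}",
        f"mean_senesced_p_g_kg = {site_res['sen_p'].mean():.6g}",
        f"nre_vs_pre_p = {cmp_row['p_two_sided']:.6g}",
        f"nre_vs_pre_cohen_d = {cmp_row['cohen_d']:.6g}",
        f"nre_vs_pre_significant = {bool(cmp_row['significant'])}",
    ]
    for _, row in strategies.iterrows():
        key = f"strategy_{row['strategy']}_{row['nutrient_context'].replace(':', '')}"
        lines.append(f"{key}_supported = {bool(row['supported'])}")
    for _, row in tf.iterrows():
        lines.append(
            f"tradeoff_{row['response']}_vs_{row['predictor']}_negative = "
            f"{bool(row['negative_tradeoff'])}"
        )
    path.write_text("\n".join(lines) + "\n")
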