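"""Leaf nutrient resorption: efficiency, absolute resorption, proficiency.

Resorption efficiency (NuRE) is the fraction of a nutrient withdrawn from
leaves before abscission,

    NuRE = (Nu_mat - Nu_sen) / Nu_mat * 100%,

computed from community-level mature and senesced leaf concentrations
(g kg^-1).  Absolute resorption is the concentration difference itself.
Proficiency is judged from the senesced concentration alone against a
complete-resorption boundary (Killingbeck's criterion; the default boundary
of 0.4 g kg^-1 applies to P only).  Mass-based efficiencies from litter
studies are converted to the concentration basis with a growth-form specific
mass loss correction factor (MLCF):

    NuRE = (1 - (1 - NuRE_m) * MLCF) * 100%.

The canonical efficiency scale is percent throughout; mass-based inputs are
fractions in [0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import DEFAULT_MLCF

#: Senesced-leaf P concentration (g kg^-1) below which P resorption is
#: considered complete.  No equivalent default is adopted for N.
P_COMPLETE_BOUNDARY = 0.4


@dataclass(frozen=True)
class ProficiencyVerdict:
    nutrient: str
    sen_conc: float
    boundary: float
    complete: bool


@dataclass(frozen=True)
class MassBasedRecord:
    """A literature-style mass-based resorption efficiency observation."""

    growth_form: str
    nure_m: float
    nutrient: str

    def __post_init__(self) -> None:
        if not (0 <= self.nure_m < 1):
            raise ValidationError(f"nure_m must lie in [0, 1), got {self.nure_m}")


def resorption_efficiency(nu_mat, nu_sen):
    """Percent of a nutrient resorbed between the mature and senesced stage.

    Accepts scalars or arrays.  A negative result (senesced exceeding mature,
    possible under measurement noise) is permitted with a warning rather than
    clamped, so that downstream diagnostics see the unmodified value.
    """
    nu_mat = np.asarray(nu_mat, dtype=float)
    nu_sen = np.asarray(nu_sen, dtype=float)
    if np.any(nu_mat <= 0):
        raise ValidationError("mature concentration must be positive")
    if np.any(nu_sen < 0):
        raise ValidationError("senesced concentration must be non-negative")
    eff = (nu_mat - nu_sen) / nu_mat * 100.0
    if np.any(eff < 0):
        warnings.warn(
            "negative resorption efficiency: senesced concentration exceeds "
            "mature concentration",
            stacklevel=2,
        )
    return eff if eff.ndim else float(eff)


def absolute_resorption(nu_mat, nu_sen):
    """Absolute resorbed amount, g kg^-1 (mature minus senesced)."""
    nu_mat = np.asarray(nu_mat, dtype=float)
    nu_sen = np.asarray(nu_sen, dtype=float)
    if np.any(nu_mat <= 0):
        raise ValidationError("mature concentration must be positive")
    if np.any(nu_sen < 0):
        raise ValidationError("senesced concentration must be non-negative")
    out = nu_mat - nu_sen
    return out if out.ndim else float(out)


def proficiency_class(nutrient: str, sen_conc: float, boundary: float | None = None) -> ProficiencyVerdict:
    """Classify resorption as complete or incomplete from senesced concentration.

    ``complete`` uses the strict inequality ``sen_conc < boundary``.  For P
    the boundary defaults to 0.4 g kg^-1; for N a boundary must be supplied.
    """
    if sen_conc < 0:
        raise ValidationError("senesced concentration must be non-negative")
    if boundary is None:
        if nutrient == "P":
            boundary = P_COMPLETE_BOUNDARY
        else:
            raise ConfigurationError(
                f"no default complete-resorption boundary for nutrient {nutrient!r}; "
                "supply one explicitly"
            )
    return ProficiencyVerdict(
        nutrient=nutrient,
        sen_conc=float(sen_conc),
        boundary=float(boundary),
        complete=bool(sen_conc < boundary),
    )


def mass_to_concentration_basis(record: MassBasedRecord, table: Mapping[str, float] = DEFAULT_MLCF) -> float:
    """Convert a mass-based efficiency (fraction) to concentration basis (percent)."""
    try:
        mlcf = table[record.growth_form]
    except KeyError:
        raise ConfigurationError(
            f"growth form {record.growth_form!r} not present in the MLCF table"
        ) from None
    return (1.0 - (1.0 - record.nure_m) * mlcf) * 100.0


def concentration_to_mass_basis(nure_pct: float, growth_form: str, table: Mapping[str, float] = DEFAULT_MLCF) -> float:
    """Algebraic inverse of :func:`mass_to_concentration_basis` (returns a fraction)."""
    try:
        mlcf = table[growth_form]
    except KeyError:
        raise ConfigurationError(
            f"growth form {growth_form!r} not present in the MLCF table"
        ) from None
    return 1.0 - (1.0 - nure_pct / 100.0) / mlcf


def site_resorption_table(site_df: pd.DataFrame) -> pd.DataFrame:
    """Build the per-site resorption summary from paired site means.

    Input is the site-level output of ``pair_site_periods``.  Output columns:
    ``site_id, nre, pre, resorbed_n, resorbed_p, resorbed_np, mature_np,
    sen_p`` — efficiencies in percent, absolute amounts in g kg^-1, ratios
    dimensionless.  ``resorbed_np`` is NaN where resorbed P is non-positive.
    """
    out = pd.DataFrame({"site_id": site_df["site_id"]})
    out["nre"] = resorption_efficiency(site_df["mature_n"], site_df["sen_n"])
    out["pre"] = resorption_efficiency(site_df["mature_p"], site_df["sen_p"])
    out["resorbed_n"] = absolute_resorption(site_df["mature_n"], site_df["sen_n"])
    out["resorbed_p"] = absolute_resorption(site_df["mature_p"], site_df["sen_p"])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["resorbed_n"] / out["resorbed_p"]
    out["resorbed_np"] = ratio.where(out["resorbed_p"] > 0)
    out["mature_np"] = site_df["mature_n"] / site_df["mature_p"]
    out["sen_p"] = site_df["sen_p"]
    return out


def replicate_resorption_table(replicate_df: pd.DataFrame) -> pd.DataFrame:
    """Replicate-level analogue of :func:`site_resorption_table` for mixed fits."""
    out = pd.DataFrame(
        {"site_id": replicate_df["site_id"], "pair_index": replicate_df["pair_index"]}
    )
    out["nre"] = resorption_efficiency(replicate_df["mature_n"], replicate_df["sen_n"])
    out["pre"] = resorption_efficiency(replicate_df["mature_p"], replicate_df["sen_p"])
    out["resorbed_n"] = absolute_resorption(replicate_df["mature_n"], replicate_df["sen_n"])
    out["resorbed_p"] = absolute_resorption(replicate_df["mature_p"], replicate_df["sen_p"])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["resorbed_n"] / out["resorbed_p"]
    out["resorbed_np"] = ratio.where(out["resorbed_p"] > 0)
    out["mature_np"] = replicate_df["mature_n"] / replicate_df["mature_p"]
    out["sen_p"] = replicate_df["sen_p"]
    return out
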