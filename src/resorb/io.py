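"""Tabular input/output and the shared record types.

All stages exchange plain CSV (UTF-8, one header row, comma separated).
Column names are fixed:

* leaf chemistry:  ``site_id, quadrat_id, period, n_conc_g_kg, p_conc_g_kg``
* incubation:      ``site_id, replicate_id, nutrient, pre_soil_ng,
  post_soil_ng, resin_ng, tube_diameter_cm, days``

Missing values are encoded as empty cells and any required empty cell is an
error; nothing is imputed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PairingError, SchemaError, ValidationError

PERIODS = ("mature", "senesced")
NUTRIENTS = ("N", "P")

LEAF_COLUMNS = ["site_id", "quadrat_id", "period", "n_conc_g_kg", "p_conc_g_kg"]
INCUBATION_COLUMNS = [
    "site_id",
    "replicate_id",
    "nutrient",
    "pre_soil_ng",
    "post_soil_ng",
    "resin_ng",
    "tube_diameter_cm",
    "days",
]

#: Growth-form specific mass loss correction factors used to convert
#: mass-based resorption efficiencies to a concentration basis.
DEFAULT_MLCF: Mapping[str, float] = {
    "evergreen_broadleaf": 0.780,
    "deciduous_broadleaf": 0.784,
    "conifer": 0.745,
    "forb": 0.640,
    "graminoid": 0.713,
}

GROWTH_FORMS = tuple(DEFAULT_MLCF)


@dataclass(frozen=True)
class LeafChemistryRecord:
    """One quadrat-period measurement of community leaf chemistry.

    Concentrations are in g kg^-1 dry mass; ``period`` is ``"mature"`` (peak
    growing season) or ``"senesced"`` (wilting period).
    """

    site_id: str
    quadrat_id: str
    period: str
    n_conc: float
    p_conc: float

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValidationError(
                f"period must be one of {PERIODS}, got {self.period!r}"
            )
        if not (self.n_conc > 0 and self.p_conc > 0):
            raise ValidationError(
                f"concentrations must be positive (site {self.site_id}: "
                f"N={self.n_conc}, P={self.p_conc})"
            )


@dataclass(frozen=True)
class IncubationRecord:
    """Inorganic-nutrient budget of one resin-core incubation tube.

    Masses are total inorganic N (ammonium + nitrate) or inorganic P in ng;
    ``resin_mass`` is the capture summed over all monthly resin bags.
    """

    site_id: str
    replicate_id: str
    nutrient: str
    pre_soil_mass: float
    post_soil_mass: float
    resin_mass: float
    tube_diameter: float
    incubation_days: float

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENTS:
            raise ValidationError(f"nutrient must be N or P, got {self.nutrient!r}")
        if self.tube_diameter <= 0 or self.incubation_days <= 0:
            raise ValidationError(
                f"tube diameter and incubation days must be positive "
                f"(site {self.site_id}, replicate {self.replicate_id})"
            )
        if min(self.pre_soil_mass, self.post_soil_mass, self.resin_mass) < 0:
            raise ValidationError(
                f"masses must be non-negative (site {self.site_id}, "
                f"replicate {self.replicate_id})"
            )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_leaf_table(path, column_map: Mapping[str, str] | None = None) -> list[LeafChemistryRecord]:
    """Read a leaf-chemistry CSV into records.

    Parameters
    ----------
    path
        CSV file with a header row.  Unknown columns are ignored.
    column_map
        Optional mapping from the file's column names to the canonical ones,
        so externally deposited tables with different headers can be loaded
        without rewriting the file.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    _require_columns(df, LEAF_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        for col in LEAF_COLUMNS:
            if pd.isna(row[col]):
                raise ValidationError(f"{path}: row {i}: empty required cell {col!r}")
        try:
            rec = LeafChemistryRecord(
                site_id=str(row["site_id"]),
                quadrat_id=str(row["quadrat_id"]),
                period=str(row["period"]),
                n_conc=float(row["n_conc_g_kg"]),
                p_conc=float(row["p_conc_g_kg"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    return records


def read_incubation_table(path, column_map: Mapping[str, str] | None = None) -> list[IncubationRecord]:
    """Read an incubation-budget CSV into records."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    _require_columns(df, INCUBATION_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        for col in INCUBATION_COLUMNS:
            if pd.isna(row[col]):
                raise ValidationError(f"{path}: row {i}: empty required cell {col!r}")
        try:
            rec = IncubationRecord(
                site_id=str(row["site_id"]),
                replicate_id=str(row["replicate_id"]),
                nutrient=str(row["nutrient"]),
                pre_soil_mass=float(row["pre_soil_ng"]),
                post_soil_mass=float(row["post_soil_ng"]),
                resin_mass=float(row["resin_ng"]),
                tube_diameter=float(row["tube_diameter_cm"]),
                incubation_days=float(row["days"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    return records


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Convert a sequence of dataclass records into a DataFrame."""
    records = list(records)
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def leaf_records(df: pd.DataFrame) -> list[LeafChemistryRecord]:
    """Convert a canonical leaf-chemistry DataFrame into validated records."""
    return [
        LeafChemistryRecord(
            site_id=str(r.site_id), quadrat_id=str(r.quadrat_id), period=str(r.period),
            n_conc=float(r.n_conc_g_kg), p_conc=float(r.p_conc_g_kg),
        )
        for r in df.itertuples(index=False)
    ]


def incubation_records(df: pd.DataFrame) -> list[IncubationRecord]:
    """Convert a canonical incubation DataFrame into validated records."""
    return [
        IncubationRecord(
            site_id=str(r.site_id), replicate_id=str(r.replicate_id),
            nutrient=str(r.nutrient), pre_soil_mass=float(r.pre_soil_ng),
            post_soil_mass=float(r.post_soil_ng), resin_mass=float(r.resin_ng),
            tube_diameter=float(r.tube_diameter_cm), incubation_days=float(r.days),
        )
        for r in df.itertuples(index=False)
    ]


def write_results(records, path, columns: Sequence[str] | None = None) -> None:
    """Write a result collection (records or DataFrame) as CSV.

    An empty collection produces a header-only file when ``columns`` is given,
    otherwise an empty file with no rows.  The parent directory must exist;
    a nonexistent directory raises ``OSError`` rather than being created
    silently.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
        if df.empty and columns is not None:
            df = pd.DataFrame(columns=list(columns))
    parent = Path(path).parent
    if not parent.is_dir():
        raise OSError(f"directory does not exist: {parent}")
    df.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    return pd.read_csv(path)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def pair_site_periods(records: Iterable[LeafChemistryRecord]):
    """Pair mature and senesced chemistry within each site.

    Periods are matched by site only: senesced quadrats in the field design
    sit adjacent to, not on top of, the mature quadrats, so quadrats carry no
    physical identity across periods.  Replicate-level pairs are formed
    positionally by sorted quadrat id (up to the smaller replicate count) and
    retained for replicate-aware (mixed) model fitting.

    Returns
    -------
    site_df : DataFrame
        One row per site with mean and SE of mature/senesced N and P.
    replicate_df : DataFrame
        One row per positional replicate pair.
    """
    df = records_to_frame(records)
    if df.empty:
        return (
            pd.DataFrame(
                columns=[
                    "site_id",
                    "mature_n", "mature_p", "sen_n", "sen_p",
                    "mature_n_se", "mature_p_se", "sen_n_se", "sen_p_se",
                ]
            ),
            pd.DataFrame(
                columns=["site_id", "pair_index", "mature_n", "mature_p", "sen_n", "sen_p"]
            ),
        )

    missing = []
    site_rows = []
    rep_rows = []
    for site_id, g in df.groupby("site_id", sort=True):
        mat = g[g["period"] == "mature"].sort_values("quadrat_id")
        sen = g[g["period"] == "senesced"].sort_values("quadrat_id")
        if mat.empty or sen.empty:
            missing.append(str(site_id))
            continue
        site_rows.append(
            {
                "site_id": site_id,
                "mature_n": mat["n_conc"].mean(),
                "mature_p": mat["p_conc"].mean(),
                "sen_n": sen["n_conc"].mean(),
                "sen_p": sen["p_conc"].mean(),
                "mature_n_se": _sem(mat["n_conc"].to_numpy()),
                "mature_p_se": _sem(mat["p_conc"].to_numpy()),
                "sen_n_se": _sem(sen["n_conc"].to_numpy()),
                "sen_p_se": _sem(sen["p_conc"].to_numpy()),
            }
        )
        k = min(len(mat), len(sen))
        for j in range(k):
            rep_rows.append(
                {
                    "site_id": site_id,
                    "pair_index": j,
                    "mature_n": mat["n_conc"].iloc[j],
                    "mature_p": mat["p_conc"].iloc[j],
                    "sen_n": sen["n_conc"].iloc[j],
                    "sen_p": sen["p_conc"].iloc[j],
                }
            )
    if missing:
        raise PairingError(
            "sites missing one sampling period: " + ", ".join(sorted(missing))
        )
    return pd.DataFrame(site_rows), pd.DataFrame(rep_rows)
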