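"""Reading, validation and normalisation of OMOP-style longitudinal tables.

Three tables describe a cohort: drug exposures, condition occurrences and
observation periods.  Externally they carry OMOP CDM column names and ISO-8601
calendar dates; internally dates are integer days since 1970-01-01 so that all
day-offset arithmetic is exact.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError

logger = logging.getLogger(__name__)

# External (on-disk) schemas: OMOP CDM column names.
EXPOSURE_COLUMNS = ["person_id", "drug_concept_id", "drug_exposure_start_date"]
CONDITION_COLUMNS = ["person_id", "condition_concept_id", "condition_start_date"]
OBSERVATION_COLUMNS = [
    "person_id",
    "observation_period_start_date",
    "observation_period_end_date",
]

# Internal (in-memory) schemas: integer day offsets since the Unix epoch.
EXPOSURE_INTERNAL = ["person_id", "drug_id", "day"]
CONDITION_INTERNAL = ["person_id", "condition_id", "day"]
OBSERVATION_INTERNAL = ["person_id", "start_day", "end_day"]

FILE_NAMES = {
    "exposures": "drug_exposure",
    "conditions": "condition_occurrence",
    "observation": "observation_period",
}


def dates_to_days(dates: pd.Series, table: str, column: str) -> np.ndarray:
    """Parse ISO-8601 dates into integer days since 1970-01-01.

    Raises :class:`SchemaError` naming the first offending row if any value
    does not parse.
    """
    parsed = pd.to_datetime(dates, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & dates.notna()
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna().to_numpy())[0])
        raise SchemaError(f"{table}: missing {column} at row {row}")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{table}: unparseable date {dates.iloc[row]!r} in {column} at row {row}"
        )
    return parsed.to_numpy().astype("datetime64[D]").astype("int64")


def days_to_dates(days: pd.Series | np.ndarray) -> pd.Series:
    """Format integer epoch days as ISO-8601 date strings."""
    arr = np.asarray(days, dtype="int64").astype("datetime64[D]")
    return pd.Series(arr.astype(str))


@dataclass
class DropReport:
    """Counts of records removed during cohort validation."""

    exposures_no_observation: int = 0
    conditions_no_observation: int = 0
    exposures_outside_period: int = 0
    conditions_outside_period: int = 0
    extra_observation_periods: int = 0

    @property
    def total(self) -> int:
        return (
            self.exposures_no_observation
            + self.conditions_no_observation
            + self.exposures_outside_period
            + self.conditions_outside_period
            + self.extra_observation_periods
        )


@dataclass
class Cohort:
    """A validated longitudinal cohort.

    Attributes
    ----------
    exposures : DataFrame with columns person_id, drug_id, day
    conditions : DataFrame with columns person_id, condition_id, day
    observation : DataFrame with columns person_id, start_day, end_day
        One row per person; the observation interval is closed at both ends.
    """

    exposures: pd.DataFrame
    conditions: pd.DataFrame
    observation: pd.DataFrame
    drop_report: DropReport = field(default_factory=DropReport)

    @property
    def n_persons(self) -> int:
        return int(self.observation["person_id"].nunique())

    def equals(self, other: "Cohort") -> bool:
        def _eq(a: pd.DataFrame, b: pd.DataFrame, cols: list[str]) -> bool:
            a = a[cols].sort_values(cols).reset_index(drop=True)
            b = b[cols].sort_values(cols).reset_index(drop=True)
            if a.empty and b.empty:  # dtype of an empty column is immaterial
                return True
            return a.equals(b)

        return (
            _eq(self.exposures, other.exposures, EXPOSURE_INTERNAL)
            and _eq(self.conditions, other.conditions, CONDITION_INTERNAL)
            and _eq(self.observation, other.observation, OBSERVATION_INTERNAL)
        )


def validate_cohort(
    exposures: pd.DataFrame,
    conditions: pd.DataFrame,
    observation: pd.DataFrame,
) -> Cohort:
    """Normalise raw internal-schema frames into a valid :class:`Cohort`.

    Enforces one observation period per person (keeping the longest), drops
    exposure/condition records for persons without an observation period, and
    drops records dated outside the person's closed observation interval.
    All drop counts are logged and returned in ``Cohort.drop_report``.
    """
    report = DropReport()

    obs = observation.copy()
    if (obs["start_day"] > obs["end_day"]).any():
        raise SchemaError("observation_period: start_date after end_date")
    n_before = len(obs)
    obs["_span"] = obs["end_day"] - obs["start_day"]
    obs = (
        obs.sort_values(["person_id", "_span", "start_day"], ascending=[True, False, True])
        .drop_duplicates("person_id", keep="first")
        .drop(columns="_span")
        .reset_index(drop=True)
    )
    report.extra_observation_periods = n_before - len(obs)
    if report.extra_observation_periods:
        logger.warning(
            "dropped %d extra observation periods (kept longest per person)",
            report.extra_observation_periods,
        )

    def _filter(df: pd.DataFrame, label: str) -> tuple[pd.DataFrame, int, int]:
        merged = df.merge(obs, on="person_id", how="left")
        known = merged["start_day"].notna()
        n_unknown = int((~known).sum())
        merged = merged[known]
        inside = (merged["day"] >= merged["start_day"]) & (
            merged["day"] <= merged["end_day"]
        )
        n_outside = int((~inside).sum())
        out = merged.loc[inside, list(df.columns)].reset_index(drop=True)
        if n_unknown:
            logger.warning("%s: dropped %d records for unobserved persons", label, n_unknown)
        if n_outside:
            logger.warning("%s: dropped %d records outside observation", label, n_outside)
        return out, n_unknown, n_outside

    exp, report.exposures_no_observation, report.exposures_outside_period = _filter(
        exposures, "drug_exposure"
    )
    cond, report.conditions_no_observation, report.conditions_outside_period = _filter(
        conditions, "condition_occurrence"
    )
    return Cohort(exposures=exp, conditions=cond, observation=obs, drop_report=report)


def _read_table(path: str, fmt: str, required: list[str], table: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "parquet":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing columns {missing} in {path}")
    return df


def read_cohort(
    exposure_path: str,
    condition_path: str,
    observation_path: str,
    format: str = "csv",
) -> Cohort:
    """Read and validate the three cohort tables.

    Records outside the owning person's observation period are dropped; the
    counts are logged and available on the returned cohort's ``drop_report``.
    """
    exp = _read_table(exposure_path, format, EXPOSURE_COLUMNS, "drug_exposure")
    cond = _read_table(condition_path, format, CONDITION_COLUMNS, "condition_occurrence")
    obs = _read_table(observation_path, format, OBSERVATION_COLUMNS, "observation_period")

    exposures = pd.DataFrame(
        {
            "person_id": exp["person_id"],
            "drug_id": exp["drug_concept_id"],
            "day": dates_to_days(
                exp["drug_exposure_start_date"].astype("string"),
                "drug_exposure",
                "drug_exposure_start_date",
            ),
        }
    )
    conditions = pd.DataFrame(
        {
            "person_id": cond["person_id"],
            "condition_id": cond["condition_concept_id"],
            "day": dates_to_days(
                cond["condition_start_date"].astype("string"),
                "condition_occurrence",
                "condition_start_date",
            ),
        }
    )
    observation = pd.DataFrame(
        {
            "person_id": obs["person_id"],
            "start_day": dates_to_days(
                obs["observation_period_start_date"].astype("string"),
                "observation_period",
                "observation_period_start_date",
            ),
            "end_day": dates_to_days(
                obs["observation_period_end_date"].astype("string"),
                "observation_period",
                "observation_period_end_date",
            ),
        }
    )
    return validate_cohort(exposures, conditions, observation)


def write_cohort(cohort: Cohort, directory: str, format: str = "csv") -> dict[str, str]:
    """Write the three cohort tables; inverse of :func:`read_cohort`.

    Returns a mapping of table name to file path.
    """
    os.makedirs(directory, exist_ok=True)
    ext = {"csv": "csv", "parquet": "parquet"}[format]
    paths: dict[str, str] = {}

    frames = {
        "exposures": pd.DataFrame(
            {
                "person_id": cohort.exposures["person_id"],
                "drug_concept_id": cohort.exposures["drug_id"],
                "drug_exposure_start_date": days_to_dates(cohort.exposures["day"]).to_numpy(),
            }
        ),
        "conditions": pd.DataFrame(
            {
                "person_id": cohort.conditions["person_id"],
                "condition_concept_id": cohort.conditions["condition_id"],
                "condition_start_date": days_to_dates(cohort.conditions["day"]).to_numpy(),
            }
        ),
        "observation": pd.DataFrame(
            {
                "person_id": cohort.observation["person_id"],
                "observation_period_start_date": days_to_dates(
                    cohort.observation["start_day"]
                ).to_numpy(),
                "observation_period_end_date": days_to_dates(
                    cohort.observation["end_day"]
                ).to_numpy(),
            }
        ),
    }
    for key, frame in frames.items():
        path = os.path.join(directory, f"{FILE_NAMES[key]}.{ext}")
        try:
            if format == "csv":
                frame.to_csv(path, index=False)
            else:
                frame.to_parquet(path, index=False)
        except OSError as exc:  # unwritable directory, disk full, ...
            raise InputError(f"cannot write {path}: {exc}") from exc
        paths[key] = path
    return paths
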