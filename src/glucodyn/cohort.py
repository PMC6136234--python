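"""Per-subject covariate records and the joined cohort table."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import pandas as pd

from glucodyn.errors import ParameterError

#: Antidiabetic therapy coding used throughout the cohort statistics:
#: 1 = none, 2 = diet with/without oral agents,
#: 3 = oral agents with/without insulin, 4 = insulin alone.
THERAPY_CODES = (1, 2, 3, 4)


@dataclass
class SubjectRecord:
    """Covariates for one subject, as used by the regression core model."""

    subject_id: str
    group: str
    age: float
    sex: str  # "M" or "F"
    diabetes_duration: float  # years; 0 for non-diabetic subjects
    bmi: float  # kg/m^2
    carb_intake: float  # g/day
    therapy_code: int
    hba1c: float  # %

    def __post_init__(self) -> None:
        if self.therapy_code not in THERAPY_CODES:
            raise ParameterError(f"therapy_code must be one of {THERAPY_CODES}")
        if self.age < 0 or self.diabetes_duration < 0:
            raise ParameterError("age and diabetes duration must be >= 0")
        if self.sex not in ("M", "F"):
            raise ParameterError("sex must be 'M' or 'F'")


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """One row per subject; raises on duplicate subject ids."""
    df = pd.DataFrame([asdict(r) for r in records])
    if df.empty:
        raise ParameterError("no subject records supplied")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ParameterError(f"duplicate subject ids: {dupes}")
    return df


def join_cohort_table(covariates: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Join covariates to per-subject metrics on ``subject_id``.

    Missingness must be explicit: every subject present in one frame must be
    present in the other.
    """
    missing = set(covariates["subject_id"]) ^ set(metrics["subject_id"])
    if missing:
        raise ParameterError(f"subject ids not present in both tables: {sorted(missing)}")
    merged = covariates.merge(
        metrics.drop(columns=[c for c in ("group",) if c in metrics.columns]),
        on="subject_id",
        validate="one_to_one",
    )
    return merged
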