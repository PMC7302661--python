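"""Hospitalization-level cohort container and column dictionary.

A cohort is one row per hospitalization.  The column roster mirrors the
admission data a hospital benchmarking system typically holds: demographics,
29 Elixhauser comorbidity indicators, a broad principal-diagnosis category
(7 levels), a fine principal-diagnosis category (long-tailed refinement),
admission-source indicators, 11 admission laboratory values, and the 30-day
mortality outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 29 Elixhauser comorbidity indicators (column prefix ``cm_``).
COMORBIDITIES = [
    "chf", "arrhythmia", "valvular", "pulm_circ", "pvd", "htn",
    "paralysis", "neuro_other", "chronic_pulm", "dm_uncomplicated",
    "dm_complicated", "hypothyroid", "renal_failure", "liver",
    "peptic_ulcer", "aids", "lymphoma", "mets_cancer", "solid_tumor",
    "rheumatoid", "coagulopathy", "obesity", "weight_loss",
    "fluid_electrolyte", "blood_loss_anemia", "deficiency_anemia",
    "alcohol_abuse", "drug_abuse", "depression",
]
COMORBIDITY_COLS = [f"cm_{c}" for c in COMORBIDITIES]

#: 11 admission laboratory values (first 24 h), column prefix ``lab_``.
LABS = [
    "sodium", "bun", "gfr", "glucose", "albumin", "bilirubin",
    "wbc", "hematocrit", "ph", "paco2", "pao2",
]
LAB_COLS = [f"lab_{x}" for x in LABS]

#: Broad principal-diagnosis categories.
DX_CATEGORIES = [
    "cardiovascular", "psychiatric_substance", "infection",
    "gastrointestinal", "respiratory", "genitourinary_renal", "other",
]

RACE_ETHNICITY = ["white", "black", "hispanic", "other"]

BINARY_COLS = COMORBIDITY_COLS + [
    "surgical", "ed_admission", "nursing_facility",
    "transfer_from_va", "organ_transplant", "died_30d",
]

MANDATORY_COLS = (
    ["hospital_id", "tier", "age", "sex", "race_ethnicity"]
    + COMORBIDITY_COLS
    + ["dx_category", "fine_dx_category"]
    + ["surgical", "ed_admission", "nursing_facility",
       "transfer_from_va", "organ_transplant"]
    + LAB_COLS
    + ["died_30d"]
)

#: Variables treated as continuous by the balance diagnostics.
CONTINUOUS_VARS = ["age", "predicted_mortality"] + LAB_COLS
#: Variables treated as categorical (binary indicators included).
CATEGORICAL_VARS = (
    ["sex", "race_ethnicity", "dx_category", "surgical", "ed_admission",
     "nursing_facility"] + COMORBIDITY_COLS + ["died_30d"]
)


class CohortError(ValueError):
    """Invalid cohort input (missing column, bad value, empty table)."""


@dataclass
class CohortTable:
    """One row per hospitalization plus variable-role metadata.

    ``df`` holds the data; ``continuous`` / ``categorical`` record which
    roster columns the diagnostics should treat as numeric distributions
    versus count tables.  Unknown columns are preserved untouched.
    """

    df: pd.DataFrame
    continuous: list[str] = field(default_factory=lambda: list(CONTINUOUS_VARS))
    categorical: list[str] = field(default_factory=lambda: list(CATEGORICAL_VARS))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def hospitals(self) -> list:
        return sorted(self.df["hospital_id"].unique())

    def validate(self) -> None:
        if len(self.df) == 0:
            raise CohortError("cohort has 0 rows")
        missing = [c for c in MANDATORY_COLS if c not in self.df.columns]
        if missing:
            raise CohortError(f"missing mandatory column(s): {missing}")
        for col in BINARY_COLS:
            vals = self.df[col]
            bad = ~vals.isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortError(
                    f"non-binary value in indicator column '{col}' at row {row}"
                )
        for col in LAB_COLS + ["age"]:
            if not np.isfinite(self.df[col].to_numpy(dtype=float)).all():
                raise CohortError(f"non-finite values in column '{col}'")

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), list(self.continuous), list(self.categorical))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path)
        table = cls(df)
        table.validate()
        return table


def design_matrix(
    df: pd.DataFrame,
    roster: list[str],
    drop_first: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix for ``roster``: categoricals one-hot encoded.

    Category levels are sorted so the encoding is deterministic regardless of
    row order; with ``drop_first`` the lexicographically first level is the
    reference.  Returns the matrix and the expanded column names.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for var in roster:
        s = df[var]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.dropna()))
            keep = levels[1:] if drop_first and len(levels) > 1 else levels
            for lev in keep:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{var}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(var)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names
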