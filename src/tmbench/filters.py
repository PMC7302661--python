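"""Cohort eligibility cascade with a CONSORT-style audit trail.

Rules, in order: (1) drop admissions transferred from another system
hospital (the original admitting hospital is the hospital of record);
(2) drop organ-transplant admissions; (3) drop rows with a missing principal
diagnosis; (4) drop rows whose fine principal-diagnosis category is rare
(frequency below 1-in-300 of the remaining eligible rows); (5) drop
hospitals with fewer remaining rows than the template size times the
matching ratio; (6) drop hospitals whose psychiatric/substance-abuse share
exceeds the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .cohort import CohortError, CohortTable

RARE_DENOMINATOR_FRACTION = 300  # "rarer than 1 in 300 hospitalizations"


@dataclass
class ExclusionStep:
    rule: str
    rows_excluded: int
    hospitals_excluded: int
    rows_remaining: int
    hospitals_remaining: int


@dataclass
class ExclusionLog:
    rows_in: int
    hospitals_in: int
    steps: list[ExclusionStep] = field(default_factory=list)

    @property
    def rows_out(self) -> int:
        return self.steps[-1].rows_remaining if self.steps else self.rows_in

    def check_conservation(self) -> bool:
        return self.rows_in - sum(s.rows_excluded for s in self.steps) == self.rows_out

    def to_dict(self) -> dict:
        return {
            "rows_in": self.rows_in,
            "hospitals_in": self.hospitals_in,
            "steps": [vars(s) for s in self.steps],
            "rows_out": self.rows_out,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def render(self) -> str:
        """Human-readable consort-style cascade."""
        lines = [f"Assessed: {self.rows_in} hospitalizations "
                 f"at {self.hospitals_in} hospitals"]
        for s in self.steps:
            lines.append(
                f"  - {s.rule}: excluded {s.rows_excluded} rows"
                f" ({s.hospitals_excluded} hospitals);"
                f" {s.rows_remaining} rows at {s.hospitals_remaining}"
                f" hospitals remain")
        return "\n".join(lines)


def min_volume(template_size: int, ratio: int) -> int:
    """Smallest eligible-hospitalization count guaranteeing a ratio:1 pool."""
    if template_size <= 0 or ratio <= 0:
        raise ValueError("template_size and ratio must be positive")
    return template_size * ratio


def rare_categories(cohort: CohortTable) -> set:
    """Fine-diagnosis categories rarer than 1-in-300 of the cohort.

    A category is rare when its count is strictly below n/300 for the n rows
    of the cohort passed in (callers supply the post-transfer,
    post-transplant, post-missing cohort).
    """
    n = len(cohort)
    if n == 0:
        raise CohortError("empty cohort")
    counts = cohort.df["fine_dx_category"].value_counts()
    threshold = n / RARE_DENOMINATOR_FRACTION
    return set(counts.index[counts < threshold])


def apply_exclusions(
    cohort: CohortTable,
    template_size: int = 300,
    ratio: int = 3,
    psych_threshold: float = 0.90,
    rare_on_initial: bool = False,
) -> tuple[CohortTable, ExclusionLog]:
    """Run the full cascade; returns the eligible cohort and its audit log.

    ``rare_on_initial`` switches the 1-in-300 denominator from the
    post-step-3 cohort (default) to the unfiltered input.
    """
    df = cohort.df
    log = ExclusionLog(rows_in=len(df), hospitals_in=df["hospital_id"].nunique())

    def record(rule: str, kept):
        nonlocal df
        excluded_rows = len(df) - int(kept.sum())
        before_h = set(df.loc[kept, "hospital_id"])
        excluded_h = df["hospital_id"].nunique() - len(before_h)
        df = df[kept]
        log.steps.append(ExclusionStep(
            rule=rule, rows_excluded=excluded_rows,
            hospitals_excluded=excluded_h,
            rows_remaining=len(df),
            hospitals_remaining=df["hospital_id"].nunique()))

    record("transfer from another system hospital", df["transfer_from_va"] == 0)
    record("organ transplantation", df["organ_transplant"] == 0)
    record("missing principal diagnosis", df["dx_category"].notna())

    denominator = cohort if rare_on_initial else CohortTable(df)
    if len(df) > 0:
        rare = rare_categories(denominator)
        record("rare principal diagnosis", ~df["fine_dx_category"].isin(rare))
    else:
        record("rare principal diagnosis", df["fine_dx_category"].notna())

    cutoff = min_volume(template_size, ratio)
    sizes = df.groupby("hospital_id")["hospital_id"].transform("size")
    record(f"hospital volume < {cutoff}", sizes >= cutoff)

    psych = (df["dx_category"] == "psychiatric_substance")
    share = psych.groupby(df["hospital_id"]).transform("mean")
    record(f"psychiatric/substance share > {psych_threshold:.0%}",
           share <= psych_threshold)

    out = CohortTable(df.reset_index(drop=True),
                      list(cohort.continuous), list(cohort.categorical))
    if len(out) == 0 or out.df["hospital_id"].nunique() == 0:
        raise AllHospitalsExcluded(log)
    return out, log


class AllHospitalsExcluded(CohortError):
    """Every hospital fell out of the cascade; the log is attached."""

    def __init__(self, log: ExclusionLog):
        super().__init__("all hospitals excluded by the eligibility cascade")
        self.log = log
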