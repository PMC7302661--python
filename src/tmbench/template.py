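"""Representative-template selection.

Candidate templates are simple random samples (without replacement) of m
hospitalizations from the eligible cohort; the selected template minimizes
the Mahalanobis distance between the candidate mean and the population mean
on a roster of selection variables, using the population covariance of
those variables.  A tiered variant selects one template per critical-care
tier from that tier's pooled rows, optionally fixing the template's
surgical/non-surgical split to the tier's median hospital.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import pinvh

from .cohort import CohortTable, design_matrix

#: default selection roster: predicted and observed mortality, demographics,
#: surgical indicator, the 7 broad diagnosis categories, and 7 major
#: comorbidities (heart failure, chronic pulmonary disease, paralysis,
#: renal failure, liver disease, metastatic cancer, depression)
DEFAULT_SELECTION_ROSTER = [
    "predicted_mortality", "died_30d", "sex", "race_ethnicity", "surgical",
    "dx_category", "cm_chf", "cm_chronic_pulm", "cm_paralysis",
    "cm_renal_failure", "cm_liver", "cm_mets_cancer", "cm_depression",
]

DEFAULT_TEMPLATE_SIZE = 300
DEFAULT_N_CANDIDATES = 1000


@dataclass
class Template:
    """Selected template: row labels, selection roster, and its distance."""

    row_ids: np.ndarray
    roster: list[str]
    distance: float
    tier: int | None = None
    surgical_count: int | None = None
    candidate_index: int = 0

    def __post_init__(self):
        if len(set(self.row_ids.tolist())) != len(self.row_ids):
            raise ValueError("template rows must be distinct")
        if self.distance < 0:
            raise ValueError("selection distance must be >= 0")

    @property
    def size(self) -> int:
        return len(self.row_ids)

    def rows(self, cohort: CohortTable) -> pd.DataFrame:
        return cohort.df.loc[self.row_ids]


def draw_candidates(cohort: CohortTable, m: int, k: int, seed: int) -> list[np.ndarray]:
    """k independent simple random samples of m row labels, no replacement."""
    n = len(cohort)
    if m > n:
        raise ValueError(f"template size {m} exceeds cohort size {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    index = cohort.df.index.to_numpy()
    return [index[rng.choice(n, size=m, replace=False)] for _ in range(k)]


def mahalanobis(u, v, cov) -> float:
    """sqrt((u-v)' cov^- (u-v)); pseudo-inverse handles singular cov."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if u.shape != v.shape or cov.shape != (u.size, u.size):
        raise ValueError("dimension mismatch")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    d = u - v
    q = float(d @ pinvh(cov) @ d)
    return float(np.sqrt(max(q, 0.0)))


def _selection_matrix(cohort: CohortTable, roster):
    X, names = design_matrix(cohort.df, list(roster))
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"zero-variance selection column(s) dropped: {dropped}")
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return X, names


def select_template(
    cohort: CohortTable,
    candidates: list[np.ndarray],
    roster: list[str] | None = None,
    tier: int | None = None,
) -> Template:
    """Candidate minimizing Mahalanobis(candidate mean, population mean).

    Ties break toward the lowest candidate index, so selection is
    deterministic given the candidate list.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    roster = list(roster or DEFAULT_SELECTION_ROSTER)
    X, _ = _selection_matrix(cohort, roster)
    pop_mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    cov_inv = pinvh(cov)

    pos = {label: i for i, label in enumerate(cohort.df.index)}
    best_i, best_d = 0, np.inf
    distances = []
    for i, ids in enumerate(candidates):
        rows = [pos[label] for label in ids]
        d = X[rows].mean(axis=0) - pop_mean
        dist = float(np.sqrt(max(d @ cov_inv @ d, 0.0)))
        distances.append(dist)
        if dist < best_d:
            best_i, best_d = i, dist
    ids = np.asarray(candidates[best_i])
    surgical = int(cohort.df.loc[ids, "surgical"].sum()) if "surgical" in cohort.df else None
    return Template(row_ids=ids, roster=roster, distance=best_d, tier=tier,
                    surgical_count=surgical, candidate_index=best_i)


@dataclass
class SurgicalMix:
    """Fixed surgical/non-surgical template split for one tier."""

    n_surgical: int
    n_nonsurgical: int
    median_proportion: float
    eligible: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.n_surgical, self.n_nonsurgical))


def fix_surgical_mix(tier_cohort: CohortTable, m: int, ratio: int = 3) -> SurgicalMix:
    """Template split fixed at the tier's median within-hospital surgical share.

    n_surgical = round(m * p*), where p* is the median over the tier's
    hospitals of their surgical proportion.  Hospitals lacking a ratio:1
    pool in either stratum are flagged ineligible.
    """
    df = tier_cohort.df
    by_hosp = df.groupby("hospital_id")["surgical"]
    props = by_hosp.mean()
    if len(props) == 0:
        raise ValueError("tier has no hospitals")
    p_star = float(props.median())
    n_surg = int(round(m * p_star))
    n_non = m - n_surg
    if p_star > 0 and (n_surg == 0 or n_surg == m):
        warnings.warn("surgical split rounded to a degenerate 0/m stratum")
    surg_counts = by_hosp.sum()
    sizes = by_hosp.size()
    eligible = {
        h: bool(surg_counts[h] >= ratio * n_surg
                and (sizes[h] - surg_counts[h]) >= ratio * n_non)
        for h in props.index
    }
    return SurgicalMix(n_surgical=n_surg, n_nonsurgical=n_non,
                       median_proportion=p_star, eligible=eligible)


def draw_candidates_stratified(
    cohort: CohortTable, n_surgical: int, n_nonsurgical: int, k: int, seed: int
) -> list[np.ndarray]:
    """Candidates with a fixed surgical/non-surgical composition."""
    df = cohort.df
    surg_idx = df.index[df["surgical"] == 1].to_numpy()
    non_idx = df.index[df["surgical"] == 0].to_numpy()
    if n_surgical > len(surg_idx) or n_nonsurgical > len(non_idx):
        raise ValueError("stratum pool smaller than requested stratum size")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(k):
        s = surg_idx[rng.choice(len(surg_idx), n_surgical, replace=False)]
        ns = non_idx[rng.choice(len(non_idx), n_nonsurgical, replace=False)]
        out.append(np.concatenate([s, ns]))
    return out


def select_tier_templates(
    cohort: CohortTable,
    m: int = DEFAULT_TEMPLATE_SIZE,
    k: int = DEFAULT_N_CANDIDATES,
    roster: list[str] | None = None,
    seed: int = 0,
    fix_surgical: bool = False,
    ratio: int = 3,
) -> dict[int, Template]:
    """One template per critical-care tier, drawn from the tier's pooled rows."""
    templates: dict[int, Template] = {}
    for j, tier in enumerate(sorted(cohort.df["tier"].unique())):
        sub = CohortTable(cohort.df[cohort.df["tier"] == tier],
                          cohort.continuous, cohort.categorical)
        tier_seed = seed + 1000 * (j + 1)
        if fix_surgical:
            mix = fix_surgical_mix(sub, m, ratio)
            cands = draw_candidates_stratified(
                sub, mix.n_surgical, mix.n_nonsurgical, k, tier_seed)
        else:
            cands = draw_candidates(sub, m, k, tier_seed)
        templates[int(tier)] = select_template(sub, cands, roster, tier=int(tier))
    return templates
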