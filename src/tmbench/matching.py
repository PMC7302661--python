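"""Optimal 1:1 matching of hospital samples to the template.

For each hospital, the engine selects the subset of its hospitalizations
that minimizes the total Mahalanobis pair distance to the template cases,
subject to:

* near-exact constraints — a large additive penalty per mismatched pair on
  the listed variables, making exact agreement lexicographically dominant
  whenever it is attainable;
* fine balance — the matched sample's category distribution must equal the
  template's exactly on the listed variables.  Multiple variables are
  balanced on their cross-classification (the nested-refinement behaviour
  of layered fine-balance matching), which implies exact marginal balance
  of each listed variable.

The constrained assignment is a min-cost-flow problem; it is solved here in
its equivalent assignment-matrix form, where per-category dummy rows absorb
exactly the pool surplus of each category (realizing the category capacity
nodes of the flow network) and forbidden row/column combinations carry
infinite cost.  The Jonker–Volgenant solver is exact, so reported optima
are true optima.  Infeasible constraint sets are reported with the binding
variable named; an instance exceeding the size budget is reported as
non-converged — never a silent partial match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from scipy.optimize import linear_sum_assignment

from .cohort import CohortTable


class MatchingError(ValueError):
    pass


@dataclass
class MatchSpec:
    """Variable rosters and constraints for one matching run."""

    distance_vars: list[str]
    near_exact: list[str] = field(default_factory=list)
    fine_balance: list[str] = field(default_factory=list)
    penalty: float | None = None  # default: (m+1) * max base distance
    ratio: int = 3
    max_cells: int = 25_000_000  # solver size budget -> non-convergence

    def validate(self) -> None:
        if not self.distance_vars:
            raise MatchingError("distance roster must be non-empty")
        if self.penalty is not None and self.penalty <= 0:
            raise MatchingError("penalty must be positive")
        if self.ratio < 1:
            raise MatchingError("ratio must be >= 1")


@dataclass
class MatchResult:
    """Outcome of matching one hospital's pool to the template."""

    hospital_id: str
    feasible: bool
    pairs: list[tuple] = field(default_factory=list)
    total_distance: float = 0.0
    reason: str | None = None
    binding_variable: str | None = None
    fine_balance_satisfied: dict[str, bool] = field(default_factory=dict)
    near_exact_mismatches: dict[str, int] = field(default_factory=dict)
    template_rows: pd.DataFrame | None = None
    matched_rows: pd.DataFrame | None = None

    @property
    def non_converged(self) -> bool:
        return self.reason == "non_converged"

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["template_row", "hospital_row"])

    def to_json_dict(self) -> dict:
        return {
            "hospital_id": self.hospital_id,
            "feasible": self.feasible,
            "reason": self.reason,
            "binding_variable": self.binding_variable,
            "total_distance": self.total_distance,
            "n_pairs": len(self.pairs),
            "fine_balance_satisfied": self.fine_balance_satisfied,
            "near_exact_mismatches": self.near_exact_mismatches,
        }


# ---------------------------------------------------------------------------
# encoding and distances


def _encode(df: pd.DataFrame, roster: list[str]):
    from .cohort import design_matrix

    return design_matrix(df, roster, drop_first=True)


def _encode_to(df: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Encode rows onto a fixed expanded-column list (indicator-aware)."""
    cols = []
    for name in names:
        if name.endswith("]") and "[" in name:
            var, lev = name[:-1].split("[", 1)
            cols.append((df[var].astype(str) == lev).to_numpy(float))
        else:
            cols.append(df[name].to_numpy(float))
    return np.column_stack(cols)


def matching_covariance(reference: pd.DataFrame | CohortTable, spec: MatchSpec):
    """Pooled covariance of the distance roster on the reference cohort.

    Returns ``(cov, names)``; the names fix the categorical encoding so
    template and pool rows are embedded identically.
    """
    df = reference.df if isinstance(reference, CohortTable) else reference
    X, names = _encode(df, list(spec.distance_vars))
    cov = np.atleast_2d(np.cov(X, rowvar=False))
    return cov, names


def distance_matrix(
    template_df: pd.DataFrame,
    pool_df: pd.DataFrame,
    spec: MatchSpec,
    cov: np.ndarray | None = None,
    names: list[str] | None = None,
) -> np.ndarray:
    """Base Mahalanobis pair distances, template rows x pool rows."""
    if cov is None or names is None:
        combined = pd.concat([template_df, pool_df])
        cov, names = matching_covariance(combined, spec)
    T = _encode_to(template_df, names)
    P = _encode_to(pool_df, names)
    if not (np.isfinite(T).all() and np.isfinite(P).all()):
        raise MatchingError("non-finite covariate value in distance roster")
    VI = pinvh(np.atleast_2d(cov))
    # (x-y)' VI (x-y) on explicit differences: exact zeros for equal rows
    diff = T[:, None, :] - P[None, :, :]
    sq = np.einsum("mnp,pq,mnq->mn", diff, VI, diff, optimize=True)
    return np.sqrt(np.maximum(sq, 0.0))


def pair_distance(
    t_row: pd.Series,
    h_row: pd.Series,
    spec: MatchSpec,
    cov: np.ndarray,
    names: list[str],
    penalty: float = 0.0,
) -> float:
    """Distance between one template row and one pool row.

    Base Mahalanobis distance plus ``penalty`` per mismatched near-exact
    variable.
    """
    base = distance_matrix(t_row.to_frame().T, h_row.to_frame().T, spec, cov, names)[0, 0]
    mismatches = sum(t_row[v] != h_row[v] for v in spec.near_exact)
    return float(base + penalty * mismatches)


# ---------------------------------------------------------------------------
# fine balance


def _joint_categories(df: pd.DataFrame, variables: list[str]) -> pd.Series:
    if len(variables) == 1:
        return df[variables[0]].astype(str)
    return df[variables].astype(str).agg("|".join, axis=1)


def _fine_balance_feasible(template_df, pool_df, variables) -> bool:
    t = _joint_categories(template_df, variables).value_counts()
    p = _joint_categories(pool_df, variables).value_counts()
    return all(p.get(cat, 0) >= cnt for cat, cnt in t.items())


def _binding_variable(template_df, pool_df, variables) -> str:
    """First variable (priority order) whose layer breaks feasibility."""
    for i in range(1, len(variables) + 1):
        if not _fine_balance_feasible(template_df, pool_df, variables[:i]):
            return variables[i - 1]
    raise AssertionError("called on a feasible constraint set")


def check_fine_balance(result: MatchResult, variable: str):
    """Exact-count audit of one fine-balance variable.

    Returns ``(flag, deficits)``: flag is True iff every category count in
    the matched sample equals the template's; deficits maps category ->
    (matched - template) count for categories where they differ.
    """
    if result.template_rows is None or result.matched_rows is None:
        raise MatchingError("result carries no row data")
    if variable not in result.template_rows.columns:
        raise MatchingError(f"unknown variable '{variable}'")
    t = result.template_rows[variable].astype(str).value_counts()
    m = result.matched_rows[variable].astype(str).value_counts()
    cats = sorted(set(t.index) | set(m.index))
    deficits = {c: int(m.get(c, 0)) - int(t.get(c, 0)) for c in cats}
    deficits = {c: d for c, d in deficits.items() if d != 0}
    return (len(deficits) == 0), deficits


# ---------------------------------------------------------------------------
# the solver


def optimal_match(
    template_df: pd.DataFrame,
    hospital_df: pd.DataFrame,
    spec: MatchSpec,
    cov: np.ndarray | None = None,
    names: list[str] | None = None,
    hospital_id: str = "",
) -> MatchResult:
    """Minimum-total-distance 1:1 match of a hospital pool to the template."""
    spec.validate()
    m = len(template_df)
    hospital_df = hospital_df.sort_index()  # deterministic tie-breaking
    n = len(hospital_df)
    if not hospital_id and "hospital_id" in hospital_df.columns and n:
        hospital_id = str(hospital_df["hospital_id"].iloc[0])

    if n < spec.ratio * m:
        return MatchResult(hospital_id=hospital_id, feasible=False,
                           reason="ineligible_pool")

    cells = (n * n) if spec.fine_balance else (m * n)
    if cells > spec.max_cells:
        return MatchResult(hospital_id=hospital_id, feasible=False,
                           reason="non_converged")

    if spec.fine_balance and not _fine_balance_feasible(
            template_df, hospital_df, spec.fine_balance):
        return MatchResult(
            hospital_id=hospital_id, feasible=False,
            reason="fine_balance_infeasible",
            binding_variable=_binding_variable(template_df, hospital_df,
                                               spec.fine_balance))

    base = distance_matrix(template_df, hospital_df, spec, cov, names)
    penalty = spec.penalty
    if penalty is None:
        penalty = (m + 1) * (float(base.max()) if base.size else 1.0)
        penalty = max(penalty, 1.0)
    D = base.copy()
    for v in spec.near_exact:
        tv = template_df[v].to_numpy()
        hv = hospital_df[v].to_numpy()
        D = D + penalty * (tv[:, None] != hv[None, :]).astype(float)

    if spec.fine_balance:
        t_cat = _joint_categories(template_df, spec.fine_balance)
        p_cat = _joint_categories(hospital_df, spec.fine_balance).to_numpy()
        t_counts = t_cat.value_counts()
        p_counts = pd.Series(p_cat).value_counts()
        cost = np.full((n, n), np.inf)
        cost[:m, :] = D
        r = m
        for cat in sorted(p_counts.index):
            extra = int(p_counts[cat]) - int(t_counts.get(cat, 0))
            if extra <= 0:
                continue
            cols = np.flatnonzero(p_cat == cat)
            cost[r:r + extra, cols] = 0.0
            r += extra
        assert r == n, "dummy-row accounting failed"
        rows, cols = linear_sum_assignment(cost)
        order = rows < m
        t_idx, h_idx = rows[order], cols[order]
    else:
        t_idx, h_idx = linear_sum_assignment(D)

    total = float(D[t_idx, h_idx].sum())
    t_labels = template_df.index.to_numpy()
    h_labels = hospital_df.index.to_numpy()
    pairs = list(zip(t_labels[t_idx], h_labels[h_idx]))  # template order
    matched = hospital_df.loc[[h for _, h in pairs]]
    result = MatchResult(
        hospital_id=hospital_id, feasible=True, pairs=list(pairs),
        total_distance=total,
        template_rows=template_df, matched_rows=matched,
    )
    for v in spec.fine_balance:
        flag, _ = check_fine_balance(result, v)
        result.fine_balance_satisfied[v] = flag
    for v in spec.near_exact:
        tv = template_df.loc[[t for t, _ in pairs], v].to_numpy()
        hv = matched[v].to_numpy()
        result.near_exact_mismatches[v] = int((tv != hv).sum())
    return result


def match_all_hospitals(
    cohort: CohortTable,
    template: "pd.DataFrame",
    spec: MatchSpec,
) -> dict[str, MatchResult]:
    """Match every hospital's pool to the template.

    The covariance is pooled over the full eligible cohort so every hospital
    is measured with the same metric.  Template rows belonging to a hospital
    are still available to that hospital's pool (the template is a sample of
    the system at large).
    """
    cov, names = matching_covariance(cohort, spec)
    out: dict[str, MatchResult] = {}
    for hid, sub in cohort.df.groupby("hospital_id", sort=True):
        out[str(hid)] = optimal_match(template, sub, spec, cov, names,
                                      hospital_id=str(hid))
    return out
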