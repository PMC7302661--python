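"""Hospital ranking on 30-day mortality.

Two comparators:

* template-matching ranks (:func:`rank_matched`): logistic regression of
  the stacked matched samples' outcomes on hospital effects (sum-to-zero
  coding, so an effect is the deviation from the average hospital) plus
  logit of predicted mortality, with cluster-robust standard errors
  clustered on the template case each row was matched to.  Each template
  case defines one cluster holding its matched row from every hospital.

* regression benchmarking (:func:`rank_regression`): the conventional
  indirect-standardization comparator — a hierarchical (random-intercept
  per hospital) logistic model on the full cohort adjusted for predicted
  mortality, estimated as two-stage empirical Bayes: per-hospital log-odds
  offsets against the pooled risk-adjusted model, between-hospital variance
  by DerSimonian–Laird, posterior-mode shrinkage.

Hospitals are ranked ascending in estimated effect (rank 1 = lowest
mortality) and cut into performance categories: top quintile, middle three
quintiles, bottom quintile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .diagnostics import chi_square_independence
from .matching import MatchResult

CATEGORIES = ["top", "median", "bottom"]


class BenchmarkError(ValueError):
    pass


@dataclass
class BenchmarkReport:
    """Per-hospital effect estimates, ranks, and quintile categories."""

    frame: pd.DataFrame  # index hospital_id; estimate, se, rank, category
    method: str
    metadata: dict = field(default_factory=dict)

    @property
    def hospitals(self) -> list[str]:
        return list(self.frame.index)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


# ---------------------------------------------------------------------------
# logistic fitting helpers


def _logit(p):
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _irls(X, y, ridge=0.0, offset=None, maxiter=100, tol=1e-10):
    """Newton/IRLS logistic fit with optional scalar L2 on all columns."""
    n, p = X.shape
    beta = np.zeros(p)
    off = np.zeros(n) if offset is None else offset
    for _ in range(maxiter):
        eta = off + X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X.T * w) @ X + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _cluster_robust_cov(X, y, beta, clusters, ridge=0.0, offset=None):
    n, p = X.shape
    off = np.zeros(n) if offset is None else offset
    mu = 1.0 / (1.0 + np.exp(-(off + X @ beta)))
    w = mu * (1.0 - mu)
    bread = np.linalg.inv((X.T * w) @ X + ridge * np.eye(p))
    resid = (y - mu)[:, None] * X
    meat = np.zeros((p, p))
    for _, idx in pd.Series(range(n)).groupby(pd.Series(clusters)).groups.items():
        g = resid[list(idx)].sum(axis=0)
        meat += np.outer(g, g)
    return bread @ meat @ bread


# ---------------------------------------------------------------------------
# template-matching ranks


def rank_matched(
    match_results: dict[str, MatchResult],
    cohort: CohortTable | None = None,
) -> BenchmarkReport:
    """Rank hospitals on the 30-day mortality of their matched samples."""
    usable = {h: r for h, r in match_results.items() if r.feasible}
    if len(usable) < 2:
        raise BenchmarkError("need feasible matches from >= 2 hospitals")
    hospitals = sorted(usable)
    frames = []
    for h in hospitals:
        r = usable[h]
        sub = r.matched_rows[["died_30d", "predicted_mortality"]].copy()
        sub["hospital_id"] = h
        sub["template_slot"] = [t for t, _ in r.pairs]
        frames.append(sub)
    data = pd.concat(frames, ignore_index=True)
    if data["predicted_mortality"].isna().any():
        raise BenchmarkError("predicted_mortality missing; fit the risk model first")

    H = len(hospitals)
    n = len(data)
    hosp_pos = {h: i for i, h in enumerate(hospitals)}
    # sum-to-zero hospital coding: H-1 effect columns, last hospital = -1 row
    Z = np.zeros((n, H - 1))
    hi = data["hospital_id"].map(hosp_pos).to_numpy()
    for j in range(H - 1):
        Z[hi == j, j] = 1.0
    Z[hi == H - 1, :] = -1.0
    X = np.column_stack([np.ones(n), Z, _logit(data["predicted_mortality"])])
    y = data["died_30d"].to_numpy(float)

    deaths = data.groupby("hospital_id")["died_30d"].agg(["sum", "count"])
    degenerate = (deaths["sum"] == 0) | (deaths["sum"] == deaths["count"])
    ridge = 1.0 if degenerate.any() else 0.0
    beta = _irls(X, y, ridge=ridge)
    V = _cluster_robust_cov(X, y, beta, data["template_slot"].to_numpy(),
                            ridge=ridge)

    eff = np.empty(H)
    se = np.empty(H)
    eff[: H - 1] = beta[1:H]
    eff[H - 1] = -beta[1:H].sum()
    for j in range(H - 1):
        se[j] = math.sqrt(max(V[1 + j, 1 + j], 0.0))
    c = np.zeros(len(beta))
    c[1:H] = -1.0
    se[H - 1] = math.sqrt(max(c @ V @ c, 0.0))

    frame = pd.DataFrame({"estimate": eff, "se": se}, index=pd.Index(hospitals, name="hospital_id"))
    frame["rank"] = _rank_ascending(frame)
    frame["category"] = None
    return BenchmarkReport(
        frame=frame, method="template_matching",
        metadata={"ridge_fallback": bool(degenerate.any()),
                  "risk_slope": float(beta[-1]), "n_rows": n,
                  "excluded_infeasible": sorted(set(match_results) - set(usable))},
    )


def _rank_ascending(frame: pd.DataFrame) -> np.ndarray:
    """Ranks 1..H by estimate; ties broken by hospital id (index order)."""
    order = frame.reset_index().sort_values(
        ["estimate", "hospital_id"], kind="mergesort").index.to_numpy()
    ranks = np.empty(len(frame), dtype=int)
    ranks[order] = np.arange(1, len(frame) + 1)
    return ranks


# ---------------------------------------------------------------------------
# regression comparator


def rank_regression(cohort: CohortTable) -> BenchmarkReport:
    """Empirical-Bayes random-intercept ranking on the full cohort."""
    df = cohort.df
    hospitals = sorted(df["hospital_id"].unique())
    if len(hospitals) < 2:
        raise BenchmarkError("need >= 2 hospitals for a between-hospital model")
    if df["predicted_mortality"].isna().any():
        raise BenchmarkError("predicted_mortality missing; fit the risk model first")
    y = df["died_30d"].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), _logit(df["predicted_mortality"])])
    beta = _irls(X, y)
    offset = X @ beta

    delta = np.empty(len(hospitals))
    dse = np.empty(len(hospitals))
    flagged = []
    lam = 0.01  # weak prior, regularizes all-survivor hospitals
    for i, h in enumerate(hospitals):
        mask = (df["hospital_id"] == h).to_numpy()
        o = offset[mask]
        yy = y[mask]
        if yy.sum() in (0, len(yy)):
            flagged.append(h)
        d = 0.0
        for _ in range(50):
            mu = 1.0 / (1.0 + np.exp(-(o + d)))
            g = (yy - mu).sum() - lam * d
            hss = (mu * (1 - mu)).sum() + lam
            step = g / hss
            d += step
            if abs(step) < 1e-10:
                break
        delta[i] = d
        dse[i] = 1.0 / math.sqrt(hss)

    w = 1.0 / dse**2
    mu_hat = float((w * delta).sum() / w.sum())
    q = float((w * (delta - mu_hat) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (len(hospitals) - 1)) / denom)
    shrink = tau2 / (tau2 + dse**2) if tau2 > 0 else np.zeros_like(dse)
    b = shrink * (delta - mu_hat)
    post_sd = np.sqrt(1.0 / (1.0 / max(tau2, 1e-300) + 1.0 / dse**2)) if tau2 > 0 \
        else np.zeros_like(dse)

    frame = pd.DataFrame(
        {"estimate": b, "se": post_sd},
        index=pd.Index(hospitals, name="hospital_id"))
    frame["rank"] = _rank_ascending(frame)
    frame["category"] = None
    return BenchmarkReport(
        frame=frame, method="regression",
        metadata={"tau2": tau2, "mu": mu_hat,
                  "degenerate_hospitals": flagged},
    )


# ---------------------------------------------------------------------------
# quintile categories and agreement


def categorize(report: BenchmarkReport) -> BenchmarkReport:
    """Assign top / median / bottom quintile categories (ceiling rule)."""
    H = len(report.frame)
    if H < 5:
        raise BenchmarkError("need >= 5 hospitals for quintile categories")
    k = math.ceil(H / 5)
    ranks = report.frame["rank"]
    cat = np.where(ranks <= k, "top", np.where(ranks > H - k, "bottom", "median"))
    report.frame["category"] = cat
    return report


def compare_rankings(a: BenchmarkReport, b: BenchmarkReport):
    """3x3 category agreement table and its Pearson chi-square test."""
    if set(a.hospitals) != set(b.hospitals):
        raise BenchmarkError("reports cover different hospital sets")
    if a.frame["category"].isna().any() or b.frame["category"].isna().any():
        raise BenchmarkError("categorize both reports first")
    ca = a.frame["category"]
    cb = b.frame.loc[a.frame.index, "category"]
    table = pd.crosstab(ca, cb).reindex(
        index=CATEGORIES, columns=CATEGORIES, fill_value=0)
    res = chi_square_independence(table.to_numpy())
    return table, res.statistic, res.pvalue


def category_agreement(a: BenchmarkReport, b: BenchmarkReport) -> float:
    """Fraction of hospitals assigned the same performance category."""
    cb = b.frame.loc[a.frame.index, "category"]
    return float((a.frame["category"] == cb).mean())
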