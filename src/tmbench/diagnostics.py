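"""Match-quality diagnostics.

Two complementary audits of a matched benchmarking design:

* the cross-match test — pool the template cases with one hospital's matched
  sample, pair all 2n subjects by exact minimum-weight non-bipartite
  matching on Mahalanobis distance, and count pairs containing one subject
  from each group.  Too few cross-group pairs means the two samples occupy
  different regions of covariate space; the exact permutation null of the
  cross-pair count gives the p-value.

* omnibus balance tests — for every matching variable, a Kruskal–Wallis test
  (continuous) or Pearson chi-square test (categorical) of equality of
  distribution across the hospitals' matched samples.

The cross-match null is discrete: for groups of size n the cross-pair count
A1 has the same parity as n, and the attainable test levels are the jumps
of the null CDF, so the test is conservative at any nominal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from scipy.special import gammaln
from scipy.stats import chi2, kruskal

from .cohort import CONTINUOUS_VARS


class DiagnosticsError(ValueError):
    pass


class TestResult(NamedTuple):
    statistic: float | None
    pvalue: float | None
    status: str = "ok"  # "ok" | "degenerate"


# ---------------------------------------------------------------------------
# cross-match test


@dataclass
class CrossmatchResult:
    a1: int                 # cross-group pairs in the optimal pairing
    n_pairs: int
    p_value: float
    poorly_matched: bool
    threshold: float = 0.05
    null_mean: float = 0.0


def _log_perfect_matchings(m: int) -> float:
    """log of the number of perfect pairings of m subjects (m even)."""
    return gammaln(m + 1) - (m / 2) * np.log(2.0) - gammaln(m / 2 + 1)


def crossmatch_null_pmf(n1: int, n2: int) -> dict[int, float]:
    """Exact null pmf of the cross-pair count A1 for group sizes n1, n2.

    Under the permutation null all pairings of the 2n labels are equally
    likely; the number of pairings with exactly ``a`` cross pairs is
    C(n1,a) C(n2,a) a! M(n1-a) M(n2-a), with M(m) the number of perfect
    pairings of m subjects.  Computed in log space, exact and stable at any
    group size.
    """
    if (n1 + n2) % 2:
        raise DiagnosticsError("combined group size must be even")
    log_total = _log_perfect_matchings(n1 + n2)
    pmf = {}
    for a in range(min(n1, n2) + 1):
        if (n1 - a) % 2 or (n2 - a) % 2:
            continue
        lc = (gammaln(n1 + 1) - gammaln(a + 1) - gammaln(n1 - a + 1)
              + gammaln(n2 + 1) - gammaln(a + 1) - gammaln(n2 - a + 1)
              + gammaln(a + 1)
              + _log_perfect_matchings(n1 - a)
              + _log_perfect_matchings(n2 - a))
        pmf[a] = float(np.exp(lc - log_total))
    return pmf


def crossmatch_pvalue(a1: int, n1: int, n2: int) -> float:
    """P(A1 <= a1) under the exact permutation null."""
    pmf = crossmatch_null_pmf(n1, n2)
    return float(min(1.0, sum(p for a, p in pmf.items() if a <= a1)))


def _pairwise_mahalanobis(X: np.ndarray, cov: np.ndarray | None) -> np.ndarray:
    if cov is None:
        cov = np.atleast_2d(np.cov(X, rowvar=False))
    VI = pinvh(np.atleast_2d(cov))
    XV = X @ VI
    sq = (np.einsum("ij,ij->i", XV, X)[:, None]
          + np.einsum("ij,ij->i", XV, X)[None, :] - 2.0 * XV @ X.T)
    return np.sqrt(np.maximum(sq, 0.0))


def crossmatch_test(
    template_rows: pd.DataFrame,
    matched_rows: pd.DataFrame,
    roster: list[str],
    cov: np.ndarray | None = None,
    threshold: float = 0.05,
    max_group: int | None = None,
    seed: int = 0,
) -> CrossmatchResult:
    """Cross-match test of one hospital's matched sample against the template.

    Pairs the pooled subjects by exact minimum-weight perfect matching
    (blossom algorithm) on the Mahalanobis distance over ``roster``.
    ``max_group`` caps each group at a seeded random subsample — the blossom
    solver is cubic in the pooled size, so production-scale groups (300 per
    side) are tested on a subsample; the test on the subsample is still
    exact and its null still holds, at reduced power.
    """
    if max_group is not None and (len(template_rows) > max_group
                                  or len(matched_rows) > max_group):
        rng = np.random.default_rng(seed)
        k = min(max_group, len(template_rows), len(matched_rows))
        template_rows = template_rows.iloc[
            np.sort(rng.choice(len(template_rows), k, replace=False))]
        matched_rows = matched_rows.iloc[
            np.sort(rng.choice(len(matched_rows), k, replace=False))]
    n1, n2 = len(template_rows), len(matched_rows)
    if n1 == 0 or n2 == 0:
        raise DiagnosticsError("both groups must be nonempty")
    if (n1 + n2) % 2:
        raise DiagnosticsError("combined group size must be even")
    from .cohort import design_matrix

    combined = pd.concat([template_rows, matched_rows])
    X, _ = design_matrix(combined, list(roster))
    D = _pairwise_mahalanobis(X, cov)
    N = n1 + n2
    G = nx.Graph()
    for i in range(N):
        for j in range(i + 1, N):
            G.add_edge(i, j, weight=float(D[i, j]))
    pairing = nx.min_weight_matching(G)
    labels = np.array([0] * n1 + [1] * n2)
    a1 = sum(1 for i, j in pairing if labels[i] != labels[j])
    p = crossmatch_pvalue(a1, n1, n2)
    pmf = crossmatch_null_pmf(n1, n2)
    return CrossmatchResult(
        a1=int(a1), n_pairs=N // 2, p_value=p,
        poorly_matched=bool(p < threshold), threshold=threshold,
        null_mean=float(sum(a * q for a, q in pmf.items())),
    )


# ---------------------------------------------------------------------------
# univariate balance tests


def kruskal_wallis(groups: list) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square reference."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise DiagnosticsError("need >= 2 nonempty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(None, None, "degenerate")
    h, p = kruskal(*arrays)
    return TestResult(float(h), float(p), "ok")


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square on an r x c count table, df=(r-1)(c-1)."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise DiagnosticsError("table must hold nonnegative integer counts")
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not (row_ok.all() and col_ok.all()):
        warnings.warn("dropping zero-marginal rows/columns from the table")
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return TestResult(None, None, "degenerate")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult(stat, float(chi2.sf(stat, df)), "ok")


# ---------------------------------------------------------------------------
# balance report across matched samples


@dataclass
class BalanceReport:
    """Per-variable omnibus balance across hospitals' matched samples."""

    table: pd.DataFrame   # variable, test, statistic, pvalue, balanced, status
    threshold: float
    n_balanced: int = 0
    n_unbalanced: int = 0

    def __post_init__(self):
        ok = self.table["status"] != "degenerate"
        self.n_balanced = int((self.table["balanced"]).sum())
        self.n_unbalanced = int((ok & ~self.table["balanced"]).sum())

    @property
    def percent_balanced(self) -> float:
        return 100.0 * self.n_balanced / len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def balance_table(
    matched_samples: dict[str, pd.DataFrame],
    roster: list[str],
    threshold: float = 0.05,
    continuous: list[str] | None = None,
) -> BalanceReport:
    """One omnibus test per roster variable across all matched samples.

    Continuous variables get Kruskal–Wallis across hospitals; categorical
    variables a Pearson chi-square on the hospital-by-category count table.
    A variable constant everywhere is marked degenerate-balanced.
    """
    if len(matched_samples) < 2:
        raise DiagnosticsError("need matched samples from >= 2 hospitals")
    continuous = set(continuous if continuous is not None else CONTINUOUS_VARS)
    rows = []
    frames = list(matched_samples.values())
    for var in roster:
        if var in continuous:
            groups = [f[var].to_numpy(float) for f in frames]
            res = kruskal_wallis(groups)
            test = "kruskal_wallis"
        else:
            counts = pd.DataFrame(
                {hid: f[var].astype(str).value_counts()
                 for hid, f in matched_samples.items()}
            ).fillna(0).T
            if counts.shape[1] < 2:
                res = TestResult(None, None, "degenerate")
            else:
                res = chi_square_independence(counts.to_numpy())
            test = "chi_square"
        if res.status == "degenerate":
            warnings.warn(f"variable '{var}' is degenerate; marked balanced")
            balanced = True
        else:
            balanced = res.pvalue >= threshold
        rows.append({"variable": var, "test": test,
                     "statistic": res.statistic, "pvalue": res.pvalue,
                     "balanced": balanced, "status": res.status})
    return BalanceReport(table=pd.DataFrame(rows), threshold=threshold)


def plot_balance_summary(reports: dict[str, BalanceReport], path=None):
    """Stacked bars of balanced vs unbalanced variable counts per run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    runs = list(reports)
    bal = [reports[r].n_balanced for r in runs]
    unbal = [reports[r].n_unbalanced for r in runs]
    fig, ax = plt.subplots(figsize=(1.2 * len(runs) + 2, 4))
    ax.bar(runs, bal, label="balanced", color="#40c0c0")
    ax.bar(runs, unbal, bottom=bal, label="unbalanced", color="#e08840")
    ax.set_ylabel("matching variables")
    ax.legend()
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
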