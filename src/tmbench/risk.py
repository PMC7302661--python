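"""Predicted 30-day mortality model (illness-severity covariate).

A main-effects logistic regression of the 30-day outcome on admission
covariates: age, sex, race/ethnicity, surgical indicator, admission-source
indicators, principal-diagnosis terms (the 7 broad categories plus
indicators for the 20 most common fine categories), the 29 comorbidity
indicators, and the 11 admission labs.  The fitted probability is attached
to every row and used downstream both as a matching variable and as the
risk adjuster in the benchmarking models.  Discrimination is summarized by
the c-statistic (area under the ROC curve).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .cohort import COMORBIDITY_COLS, LAB_COLS, CohortTable, design_matrix

DEFAULT_ROSTER = (
    ["age", "sex", "race_ethnicity", "surgical", "ed_admission",
     "nursing_facility", "dx_category"]
    + COMORBIDITY_COLS
    + LAB_COLS
)

#: number of most-common fine-diagnosis indicator terms added to the roster
N_FINE_DX_TERMS = 20


class RiskModelError(ValueError):
    pass


@dataclass
class RiskModel:
    """Fitted logistic mortality model."""

    coefficients: dict[str, float]
    intercept: float
    c_statistic: float
    roster: list[str]
    ridge_fallback: bool = False
    fine_dx_terms: list[str] = field(default_factory=list)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X, names = _build_design(df, self.roster, self.fine_dx_terms)
        beta = np.array([self.coefficients.get(n, 0.0) for n in names])
        return self.intercept + X @ beta

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(df)))

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "c_statistic": self.c_statistic,
            "roster": self.roster,
            "fine_dx_terms": self.fine_dx_terms,
            "ridge_fallback": self.ridge_fallback,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _build_design(df: pd.DataFrame, roster, fine_dx_terms):
    X, names = design_matrix(df, list(roster))
    if fine_dx_terms:
        extra = np.column_stack(
            [(df["fine_dx_category"] == t).to_numpy(float) for t in fine_dx_terms]
        )
        X = np.hstack([X, extra])
        names = names + [f"fine_dx[{t}]" for t in fine_dx_terms]
    return X, names


def c_statistic(predictions, outcomes) -> float:
    """Concordance of predictions with the binary outcome.

    Probability that a randomly chosen death outranks a randomly chosen
    survivor, ties counted 1/2 — the normalized Mann–Whitney statistic.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes)
    if p.shape != y.shape:
        raise RiskModelError("predictions and outcomes differ in length")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise RiskModelError("c-statistic undefined: only one outcome class present")
    ranks = rankdata(p)  # mid-ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def fit_risk_model(
    cohort: CohortTable,
    roster: list[str] | None = None,
    include_fine_dx: bool = True,
) -> RiskModel:
    """Maximum-likelihood logistic fit; fills ``predicted_mortality``.

    Estimation is IRLS (tolerance 1e-8, 100 iterations).  Quasi-separation
    or a singular/non-converged fit falls back to an L2-penalized fit and
    sets ``ridge_fallback`` on the returned model.  Rows with a missing
    principal diagnosis are scored at the reference diagnosis category.
    """
    roster = list(roster or DEFAULT_ROSTER)
    df = cohort.df
    if "died_30d" not in df.columns:
        raise RiskModelError("outcome column 'died_30d' is missing")
    missing = [c for c in roster if c not in df.columns and c != "fine_dx_category"]
    if missing:
        raise RiskModelError(f"roster column(s) missing from cohort: {missing}")
    y = df["died_30d"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise RiskModelError("outcome has a single class; cannot fit")

    fit_df = df.copy()
    if "dx_category" in roster:
        fit_df["dx_category"] = fit_df["dx_category"].fillna("cardiovascular")
    fine_terms: list[str] = []
    if include_fine_dx and "fine_dx_category" in df.columns:
        counts = df["fine_dx_category"].value_counts()
        fine_terms = sorted(counts.index[:N_FINE_DX_TERMS].tolist())
    X, names = _build_design(fit_df, roster, fine_terms)

    ridge = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(y, sm.add_constant(X, has_constant="add"),
                           family=sm.families.Binomial())
            res = model.fit(maxiter=100, tol=1e-8)
            params = res.params
            # the intercept may legitimately be large (it absorbs raw-scale
            # lab means); runaway slopes indicate (quasi-)separation
            if (not np.all(np.isfinite(params))
                    or np.abs(params[1:]).max() > 30
                    or not getattr(res, "converged", True)):
                raise RuntimeError("suspect separation / divergence")
        except Exception:
            ridge = True
    if ridge:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, max_iter=2000)
        lr.fit(X, y)
        intercept = float(lr.intercept_[0])
        beta = lr.coef_[0]
    else:
        intercept = float(params[0])
        beta = np.asarray(params[1:])

    lp = intercept + X @ beta
    pred = 1.0 / (1.0 + np.exp(-lp))
    cohort.df["predicted_mortality"] = np.clip(pred, 1e-12, 1 - 1e-12)
    model = RiskModel(
        coefficients=dict(zip(names, map(float, beta))),
        intercept=intercept,
        c_statistic=c_statistic(pred, y),
        roster=roster,
        ridge_fallback=ridge,
        fine_dx_terms=fine_terms,
    )
    return model
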