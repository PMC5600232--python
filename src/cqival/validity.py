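"""Construct-validity screen: global ratings regressed on subscale scores.

Each 0-10 global rating (department, hospital) is modelled by ordinary
least squares on the nine subscale scores with dummy-coded demographic
covariates (age band, sex, education, self-rated physical and psychological
health, country of origin, number of admissions).  With multiply imputed
data the model is fitted per completed dataset and coefficients are pooled
by Rubin's rules; significance flags come from the pooled intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .imputation import PooledEstimate, rubin_pool
from .scales import score_subscales
from .survey_model import SurveyDataset


@dataclass
class RegressionReport:
    outcome: str
    coefficients: pd.DataFrame  # term, estimate, ci_low, ci_high, significant
    m: int
    n: int

    def subscale_row(self, name: str) -> pd.Series:
        return self.coefficients.loc[name]


def _design_matrix(ds: SurveyDataset, outcome: str):
    names = [s.name for s in ds.item_map.subscales]
    scores = score_subscales(ds)
    df = pd.concat([scores[names], ds.data[list(ds.item_map.covariate_fields)],
                    ds.data[outcome].rename("outcome")], axis=1)
    df = df.dropna()
    X = df[names].astype(float)
    # categorical covariates dummy-coded against their first observed level
    for cov in ds.item_map.covariate_fields:
        dummies = pd.get_dummies(df[cov].astype("category"), prefix=cov, drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    return X, df["outcome"].astype(float)


def fit_global_rating_model(
    datasets: list[SurveyDataset], outcome_field: str = "department_rating"
) -> RegressionReport:
    """OLS per completed dataset, pooled by Rubin's rules.

    Raises on a rank-deficient design, naming the aliased columns.
    """
    if not datasets:
        raise ValueError("no datasets")
    per_term: dict[str, list[tuple[float, float]]] = {}
    n = None
    for ds in datasets:
        X, y = _design_matrix(ds, outcome_field)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # identify aliased columns by pivoted QR of the design
            _, r = np.linalg.qr(X.to_numpy())
            bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
            raise ValueError(f"rank-deficient design; aliased columns: {bad}")
        fit = sm.OLS(y, X).fit()
        n = len(y)
        for term in X.columns:
            per_term.setdefault(term, []).append((fit.params[term], fit.bse[term] ** 2))
    m = len(datasets)
    rows = []
    for term, est in per_term.items():
        if m == 1:
            q, u = est[0]
            half = 1.96 * np.sqrt(u)
            pooled = PooledEstimate(q, u, 0.0, u, np.inf, q - half, q + half, 1)
        else:
            pooled = rubin_pool(est, m)
        rows.append(
            {
                "term": term,
                "estimate": pooled.estimate,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "significant": not (pooled.ci_low <= 0.0 <= pooled.ci_high),
            }
        )
    coef = pd.DataFrame(rows).set_index("term")
    return RegressionReport(outcome_field, coef, m, n)


class GlobalRatingValidity:
    """Estimator wrapper for the pooled construct-validity regression.

    Attributes (after :meth:`fit`): ``report_`` and ``coefficients_``.
    """

    def __init__(self, outcome_field: str = "department_rating"):
        self.outcome_field = outcome_field

    def get_params(self, deep=True) -> dict:
        return {"outcome_field": self.outcome_field}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, datasets: list[SurveyDataset]) -> "GlobalRatingValidity":
        self.report_ = fit_global_rating_model(datasets, self.outcome_field)
        self.coefficients_ = self.report_.coefficients
        return self
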