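"""Subscale scoring, department aggregation, and reliability screens.

A subscale score is the mean of its item codes (1-4 items average into
[1, 4]; yes/no items into [0, 1]).  Department-level values are unweighted
means over a department's respondents, computed per item so that
department-level reliability can be assessed on aggregated items.
Internal consistency uses Cronbach's alpha with a 0.70 acceptance cutoff;
distinctness of subscales uses Pearson inter-scale correlations with
r >= 0.70 flagged as overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey_model import SurveyDataset

ALPHA_CUTOFF = 0.70
OVERLAP_CUTOFF = 0.70


def score_subscales(ds: SurveyDataset, min_prop_observed: float = 0.5) -> pd.DataFrame:
    """Per-respondent subscale scores (mean of available items).

    A score is missing when fewer than ``min_prop_observed`` of the
    subscale's items were answered; a completed (post-imputation) dataset
    never triggers this.  Returns a frame indexed like ``ds.data`` with the
    grouping labels plus one column per subscale.
    """
    df = ds.data
    out = df[["hospital_id", "department_id"]].copy()
    for sub in ds.item_map.subscales:
        block = df[list(sub.items)]
        n_obs = block.notna().sum(axis=1)
        score = block.mean(axis=1)
        score[n_obs < min_prop_observed * len(sub.items)] = np.nan
        out[sub.name] = score
    return out


def aggregate_to_department(values: pd.DataFrame) -> pd.DataFrame:
    """Unweighted department means of every numeric column.

    ``values`` must carry ``hospital_id`` and ``department_id`` columns;
    one output row per (hospital, department).
    """
    for col in ("hospital_id", "department_id"):
        if col not in values.columns:
            raise ValueError(f"{col} column required for aggregation")
    grouped = values.groupby(["hospital_id", "department_id"], sort=True)
    out = grouped.mean(numeric_only=True)
    out["n_respondents"] = grouped.size()
    return out.reset_index()


def aggregate_items_to_department(ds: SurveyDataset) -> pd.DataFrame:
    """Department-level item means (one row per department, one column per item)."""
    cols = ["hospital_id", "department_id", *ds.item_map.item_ids]
    return aggregate_to_department(ds.data[cols])


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance)."""
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 items and 2 observations")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 complete observations")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


def interscale_correlations(scores: pd.DataFrame, subscale_names) -> tuple[pd.DataFrame, list]:
    """Pearson correlation matrix of subscale scores plus overlap flags.

    Off-diagonal pairs with r >= 0.70 are flagged as overlapping
    (insufficiently distinct constructs).
    """
    sub = scores[list(subscale_names)].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 rows for correlations")
    corr = sub.corr(method="pearson")
    flags = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(subscale_names)
        for b in list(subscale_names)[i + 1 :]
        if corr.loc[a, b] >= OVERLAP_CUTOFF
    ]
    return corr, flags


@dataclass
class ReliabilityReport:
    """Alpha at both levels plus inter-scale correlation screens."""

    alpha_individual: dict
    alpha_department: dict
    corr_individual: pd.DataFrame
    corr_department: pd.DataFrame
    overlap_individual: list
    overlap_department: list

    def alpha_acceptable(self, level: str = "individual") -> dict:
        table = self.alpha_individual if level == "individual" else self.alpha_department
        return {k: v >= ALPHA_CUTOFF for k, v in table.items()}


def reliability_report(completed: list[SurveyDataset]) -> ReliabilityReport:
    """Alpha and inter-scale screens pooled over completed datasets.

    Alpha is averaged across imputed datasets (simple mean, matching how
    the original analysis pooled reliability); correlation matrices are
    element-wise averages.
    """
    if not completed:
        raise ValueError("no datasets")
    item_map = completed[0].item_map
    names = [s.name for s in item_map.subscales]
    a_ind = {n: [] for n in names}
    a_dep = {n: [] for n in names}
    corr_i, corr_d = [], []
    for ds in completed:
        dept_items = aggregate_items_to_department(ds)
        for sub in item_map.subscales:
            a_ind[sub.name].append(cronbach_alpha(ds.data[list(sub.items)]))
            a_dep[sub.name].append(cronbach_alpha(dept_items[list(sub.items)]))
        scores = score_subscales(ds)
        corr_i.append(interscale_correlations(scores, names)[0])
        dept_scores = aggregate_to_department(scores)
        corr_d.append(interscale_correlations(dept_scores, names)[0])
    ci = sum(corr_i) / len(corr_i)
    cd = sum(corr_d) / len(corr_d)

    def _flags(corr):
        return [
            (a, b, float(corr.loc[a, b]))
            for i, a in enumerate(names)
            for b in names[i + 1 :]
            if corr.loc[a, b] >= OVERLAP_CUTOFF
        ]

    return ReliabilityReport(
        alpha_individual={n: float(np.mean(v)) for n, v in a_ind.items()},
        alpha_department={n: float(np.mean(v)) for n, v in a_dep.items()},
        corr_individual=ci,
        corr_department=cd,
        overlap_individual=_flags(ci),
        overlap_department=_flags(cd),
    )
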