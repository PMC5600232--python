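"""Generalizability analysis for unbalanced nested survey designs.

Estimates variance components by Henderson's Method 1 (analogous ANOVA) for
respondents nested in departments (p:d) and respondents nested in
departments nested in hospitals (p:d:h), then projects measurement precision
(standard error of measurement, SEM) and reliability (G coefficient) for
hypothetical numbers of respondents and departments — a D-study — including
minimum-sample solvers against admissible-noise thresholds.

For a department mean of n_p respondents,

    SEM_d = sqrt(sigma2_res / n_p),        G_d = sigma2_d / (sigma2_d + SEM_d^2)

and for a hospital mean of n_d departments with n_p respondents each,

    SEM_h = sqrt(sigma2_d / n_d + sigma2_res / (n_d * n_p)),
    G_h   = sigma2_h / (sigma2_h + SEM_h^2).

Admissible noise is phrased as a 95%-interpretation bound: a SEM threshold
``t`` corresponds to a full confidence-interval width of about
``1.96 * t * 2`` score units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Estimated variance components for one subscale score."""

    sigma2_res: float
    sigma2_d: float
    sigma2_h: float = 0.0
    design: str = "p:d"  # or "p:d:h"
    truncated: tuple[str, ...] = ()

    @property
    def total(self) -> float:
        return self.sigma2_res + self.sigma2_d + self.sigma2_h

    def shares(self) -> dict:
        """Whole-percent shares of total variance plus the hospital ratio.

        The hospital ratio sigma2_h / (sigma2_h + sigma2_d) is reported to
        two decimals; it is 0.0 when both group components vanish.
        """
        tot = self.total
        if tot <= 0:
            return {"department_pct": 0, "hospital_pct": 0, "hospital_ratio": 0.0}
        grp = self.sigma2_h + self.sigma2_d
        ratio = self.sigma2_h / grp if grp > 0 else 0.0
        return {
            "department_pct": int(round(100.0 * self.sigma2_d / tot)),
            "hospital_pct": int(round(100.0 * self.sigma2_h / tot)),
            "hospital_ratio": round(ratio, 2),
        }


def vc_nested_2level(y, departments) -> VarianceComponents:
    """Henderson Method 1 components for the unbalanced p:d design.

    ``y`` is the subscale score per respondent, ``departments`` the
    department label per respondent.  Negative between-department estimates
    are truncated to zero (logged).
    """
    y = np.asarray(y, dtype=float)
    d = pd.Series(np.asarray(departments))
    if y.shape[0] != d.shape[0]:
        raise ValueError("y and departments must align")
    mask = ~np.isnan(y)
    y, d = y[mask], d[mask].reset_index(drop=True)
    N = len(y)
    groups = pd.Series(y).groupby(d.values)
    n_d = groups.size().to_numpy(dtype=float)
    k = len(n_d)
    if k < 2:
        raise ValueError("need at least 2 departments")
    if N - k <= 0:
        raise ValueError("all departments are singletons; residual inestimable")
    means = groups.mean().to_numpy()
    grand = y.mean()
    ss_w = float(((y - groups.transform("mean").to_numpy()) ** 2).sum())
    ms_w = ss_w / (N - k)
    ms_b = float((n_d * (means - grand) ** 2).sum()) / (k - 1)
    c = (N - float((n_d**2).sum()) / N) / (k - 1)
    sigma2_d = (ms_b - ms_w) / c
    truncated = ()
    if sigma2_d < 0:
        log.info("between-department component %.4g truncated to 0", sigma2_d)
        truncated = ("sigma2_d",)
        sigma2_d = 0.0
    return VarianceComponents(ms_w, sigma2_d, 0.0, "p:d", truncated)


def vc_nested_3level(y, departments, hospitals) -> VarianceComponents:
    """Henderson Method 1 components for the unbalanced p:d:h design.

    Solves the stratum expected-mean-square equations bottom-up:

        E[MS_res]  = sigma2_res
        E[MS_d(h)] = sigma2_res + k1 * sigma2_d
        E[MS_h]    = sigma2_res + k2 * sigma2_d + k3 * sigma2_h

    with coefficients determined by the (unequal) group sizes.  Negative
    solutions are truncated to zero after solving, hospital last.
    """
    y = np.asarray(y, dtype=float)
    h = np.asarray(hospitals)
    d = np.asarray(departments)
    if not (len(y) == len(h) == len(d)):
        raise ValueError("y, departments, hospitals must align")
    mask = ~np.isnan(y)
    y, h, d = y[mask], h[mask], d[mask]
    df = pd.DataFrame({"y": y, "h": h, "d": d})
    N = len(df)
    cell = df.groupby(["h", "d"], sort=False)["y"]
    n_ij = cell.size()
    cell_mean = cell.mean()
    hosp = df.groupby("h", sort=False)["y"]
    n_i = hosp.size()
    hosp_mean = hosp.mean()
    a = len(n_i)
    b_total = len(n_ij)
    if a < 2:
        raise ValueError("need at least 2 hospitals")
    if b_total - a <= 0:
        raise ValueError("no department replication within hospitals")
    if N - b_total <= 0:
        raise ValueError("all departments are singletons; residual inestimable")
    grand = df["y"].mean()

    ss_res = float(((df["y"] - cell.transform("mean")) ** 2).sum())
    # department-within-hospital and hospital strata sums of squares
    hosp_of_cell = n_ij.index.get_level_values("h")
    ss_d = float(
        (n_ij.to_numpy() * (cell_mean.to_numpy() - hosp_mean.loc[hosp_of_cell].to_numpy()) ** 2).sum()
    )
    ss_h = float((n_i.to_numpy() * (hosp_mean.to_numpy() - grand) ** 2).sum())

    ms_res = ss_res / (N - b_total)
    ms_d = ss_d / (b_total - a)
    ms_h = ss_h / (a - 1)

    nij2 = n_ij.to_numpy(dtype=float) ** 2
    nij2_over_ni = float((nij2 / n_i.loc[hosp_of_cell].to_numpy(dtype=float)).sum())
    nij2_over_N = float(nij2.sum()) / N
    ni2_over_N = float((n_i.to_numpy(dtype=float) ** 2).sum()) / N

    k1 = (N - nij2_over_ni) / (b_total - a)
    k2 = (nij2_over_ni - nij2_over_N) / (a - 1)
    k3 = (N - ni2_over_N) / (a - 1)

    sigma2_res = ms_res
    sigma2_d = (ms_d - ms_res) / k1
    sigma2_h = (ms_h - ms_res - k2 * sigma2_d) / k3
    truncated = []
    if sigma2_d < 0:
        log.info("between-department component %.4g truncated to 0", sigma2_d)
        truncated.append("sigma2_d")
        sigma2_d = 0.0
    if sigma2_h < 0:
        log.info("between-hospital component %.4g truncated to 0", sigma2_h)
        truncated.append("sigma2_h")
        sigma2_h = 0.0
    return VarianceComponents(sigma2_res, sigma2_d, sigma2_h, "p:d:h", tuple(truncated))


class NestedVarianceComponents:
    """Estimator wrapper around the Henderson Method 1 solvers.

    Parameters
    ----------
    design : {"p:d", "p:d:h"}
        Two-level (respondents in departments) or three-level (respondents
        in departments in hospitals) nesting.

    Attributes (after :meth:`fit`)
    ------------------------------
    components_ : VarianceComponents
    """

    def __init__(self, design: str = "p:d"):
        self.design = design

    def get_params(self, deep: bool = True) -> dict:
        return {"design": self.design}

    def set_params(self, **params) -> "NestedVarianceComponents":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, y, departments, hospitals=None) -> "NestedVarianceComponents":
        if self.design == "p:d":
            self.components_ = vc_nested_2level(y, departments)
        elif self.design == "p:d:h":
            if hospitals is None:
                raise ValueError("hospitals required for the p:d:h design")
            self.components_ = vc_nested_3level(y, departments, hospitals)
        else:
            raise ValueError(f"unknown design {self.design!r}")
        return self


def pool_components(per_imputation: list[VarianceComponents]) -> VarianceComponents:
    """Average components element-wise across imputed datasets."""
    if not per_imputation:
        raise ValueError("nothing to pool")
    designs = {c.design for c in per_imputation}
    if len(designs) > 1:
        raise ValueError("mixed designs cannot be pooled")
    return VarianceComponents(
        float(np.mean([c.sigma2_res for c in per_imputation])),
        float(np.mean([c.sigma2_d for c in per_imputation])),
        float(np.mean([c.sigma2_h for c in per_imputation])),
        per_imputation[0].design,
        tuple(sorted({t for c in per_imputation for t in c.truncated})),
    )


def sem_department(components: VarianceComponents, n_p: int) -> float:
    """SEM of a department mean score over n_p respondents."""
    if n_p <= 0:
        raise ValueError("n_p must be positive")
    return math.sqrt(components.sigma2_res / n_p)


def sem_hospital(components: VarianceComponents, n_d: int, n_p: int) -> float:
    """SEM of a hospital mean over n_d departments of n_p respondents each."""
    if n_d <= 0 or n_p <= 0:
        raise ValueError("n_d and n_p must be positive")
    return math.sqrt(components.sigma2_d / n_d + components.sigma2_res / (n_d * n_p))


def g_coefficient(components: VarianceComponents, n_p: int, n_d: int | None = None) -> float:
    """Reliability-like ratio of object variance to object-plus-error variance.

    Department level when ``n_d`` is None, hospital level otherwise.
    """
    if n_d is None:
        err = sem_department(components, n_p) ** 2
        obj = components.sigma2_d
    else:
        err = sem_hospital(components, n_d, n_p) ** 2
        obj = components.sigma2_h
    denom = obj + err
    return obj / denom if denom > 0 else 0.0


def noise_bound(sem_threshold: float) -> float:
    """Width of the 95% interpretation interval implied by a SEM threshold."""
    return 1.96 * sem_threshold * 2


def min_respondents(
    components: VarianceComponents, threshold: float, grid_step: int = 50, n_max: int = 100_000
) -> int | None:
    """Smallest multiple of ``grid_step`` with department-level SEM below threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if components.sigma2_res <= 0:
        return grid_step
    n = grid_step
    while n <= n_max:
        if sem_department(components, n) < threshold:
            return n
        n += grid_step
    return None


def min_departments(
    components: VarianceComponents, n_p: int, threshold: float, n_max: int = 100_000
) -> int | None:
    """Smallest integer number of departments (each with ``n_p`` respondents)
    with hospital-level SEM below threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if math.isinf(threshold):
        return 1
    for n_d in range(1, n_max + 1):
        if sem_hospital(components, n_d, n_p) < threshold:
            return n_d
    return None


@dataclass
class DStudyResult:
    """SEM/G surfaces over candidate sample sizes plus minimum solutions."""

    subscale: str
    threshold: float
    department_grid: pd.DataFrame  # columns n_p, sem, g
    hospital_grid: pd.DataFrame  # columns n_d, n_p, sem, g
    min_respondents_department: int | None
    min_departments_hospital: int | None
    components: VarianceComponents = field(repr=False, default=None)


def dstudy_grid(
    components: VarianceComponents,
    n_p_grid=(25, 50, 75, 100, 150, 200, 300, 400),
    n_d_grid=(1, 2, 4, 6, 8, 10, 15, 20),
    threshold: float = 0.10,
    subscale: str = "",
    min_n_p_for_departments: int | None = None,
) -> DStudyResult:
    """Full D-study: SEM and G at every grid point plus minimum-sample answers.

    ``min_n_p_for_departments`` is the per-department sample size assumed
    when solving for the minimum number of departments; it defaults to the
    solved minimum respondents per department.
    """
    dep = pd.DataFrame(
        {
            "n_p": list(n_p_grid),
            "sem": [sem_department(components, n) for n in n_p_grid],
            "g": [g_coefficient(components, n) for n in n_p_grid],
        }
    )
    rows = []
    for n_d in n_d_grid:
        for n_p in n_p_grid:
            rows.append(
                {
                    "n_d": n_d,
                    "n_p": n_p,
                    "sem": sem_hospital(components, n_d, n_p),
                    "g": g_coefficient(components, n_p, n_d),
                }
            )
    hosp = pd.DataFrame(rows)
    n_p_min = min_respondents(components, threshold)
    n_p_for_depts = min_n_p_for_departments or n_p_min
    n_d_min = (
        min_departments(components, n_p_for_depts, threshold)
        if n_p_for_depts is not None
        else None
    )
    return DStudyResult(subscale, threshold, dep, hosp, n_p_min, n_d_min, components)
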