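"""Ordinal confirmatory factor analysis of the 9-subscale structure.

The individual-level model treats each ordinal item as a discretized
indicator of a standard-normal latent: inter-item association is measured
by polychoric correlation (tetrachoric for yes/no items), and the
congeneric 9-factor model Sigma = Lambda Phi Lambda' (factor variances
fixed at 1, every item loading on exactly one factor) is fitted by
diagonally weighted least squares on the off-diagonal correlations:

    F(theta) = sum_{i<j} w_ij (r_ij - sigma_ij(theta))^2

with w_ij = 1 / avar(sqrt(N) r_ij) ~ 1 / (1 - r_ij^2)^2 and a naive test
statistic chi2 = (N - 1) * F_min.  The mean-and-variance adjustment of the
full WLSMV statistic is deliberately not reproduced (it requires the joint
asymptotic covariance of all polychorics); the decision layer — CFI, TLI,
RMSEA with cutoffs 0.95 / 0.95 / 0.06 and the two-of-three acceptance
rule — is implemented exactly.

Department-level runs aggregate item means per department, correlate them
with Pearson's r and fit with unit weights (the aggregates are effectively
continuous).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .scales import aggregate_items_to_department
from .survey_model import ItemMap, SurveyDataset

log = logging.getLogger(__name__)

CFI_CUTOFF = 0.95
TLI_CUTOFF = 0.95
RMSEA_CUTOFF = 0.06

_CLIP = 8.2  # effective +-infinity on the standard-normal scale


def bvn_cdf(a, b, rho: float):
    """Standard bivariate normal P(X <= a, Y <= b), vectorized via Owen's T."""
    a = np.clip(np.asarray(a, dtype=float), -_CLIP, _CLIP)
    b = np.clip(np.asarray(b, dtype=float), -_CLIP, _CLIP)
    if abs(rho) < 1e-12:
        return stats.norm.cdf(a) * stats.norm.cdf(b)
    rho = np.clip(rho, -0.9999, 0.9999)
    denom = np.sqrt(1.0 - rho * rho)
    az = np.where(a == 0, 1e-12, a)
    bz = np.where(b == 0, 1e-12, b)
    wa = (bz - rho * az) / (az * denom)
    wb = (az - rho * bz) / (bz * denom)
    p = (
        0.5 * (stats.norm.cdf(a) + stats.norm.cdf(b))
        - special.owens_t(az, wa)
        - special.owens_t(bz, wb)
    )
    opposite = (az * bz < 0) | ((az * bz == 0) & (az + bz < 0))
    p = p - 0.5 * opposite
    return np.clip(p, 0.0, 1.0)


def _cell_probabilities(tau_x, tau_y, rho: float) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal over the threshold grid."""
    ax = np.concatenate([[-np.inf], tau_x, [np.inf]])
    ay = np.concatenate([[-np.inf], tau_y, [np.inf]])
    A, B = np.meshgrid(ax, ay, indexing="ij")
    cdf = bvn_cdf(A, B, rho)
    return cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]


def _thresholds(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Category codes and standard-normal thresholds from marginal proportions."""
    cats, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return cats, stats.norm.ppf(cum)


@dataclass(frozen=True)
class PolychoricResult:
    rho: float
    tau_x: np.ndarray
    tau_y: np.ndarray
    var: float  # approximate sampling variance of rho
    n: int


def polychoric_loglik(table: np.ndarray, tau_x, tau_y, rho: float) -> float:
    """Contingency-table log-likelihood under the bivariate-normal model."""
    probs = np.maximum(_cell_probabilities(tau_x, tau_y, rho), 1e-300)
    return float((table * np.log(probs)).sum())


def estimate_polychoric(x, y) -> PolychoricResult:
    """Two-step maximum-likelihood polychoric (or tetrachoric) correlation.

    Thresholds come from the marginal cumulative proportions; the
    correlation maximizes the contingency-table likelihood by bounded
    one-dimensional search on (-0.999, 0.999).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 paired observations")
    cats_x, tau_x = _thresholds(x)
    cats_y, tau_y = _thresholds(y)
    if len(cats_x) < 2 or len(cats_y) < 2:
        raise ValueError("a variable with a single observed category has no polychoric correlation")
    ix = np.searchsorted(cats_x, x)
    iy = np.searchsorted(cats_y, y)
    table = np.zeros((len(cats_x), len(cats_y)))
    np.add.at(table, (ix, iy), 1.0)

    res = optimize.minimize_scalar(
        lambda r: -polychoric_loglik(table, tau_x, tau_y, r),
        bounds=(-0.999, 0.999),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    return PolychoricResult(rho, tau_x, tau_y, (1 - rho**2) ** 2 / n, n)


def polychoric_matrix(df: pd.DataFrame, items) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise polychoric correlation matrix and DWLS weight matrix.

    Weights are 1 / avar(sqrt(N) rho_hat) ~ 1 / (1 - rho^2)^2 (unit-N
    convention; the fitted parameters are invariant to weight scale and the
    test statistic applies the sample size separately).  A non-PSD matrix
    is repaired to the nearest PSD correlation matrix (logged).
    """
    items = list(items)
    p = len(items)
    R = np.eye(p)
    W = np.ones((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            est = estimate_polychoric(df[items[i]], df[items[j]])
            R[i, j] = R[j, i] = est.rho
            W[i, j] = W[j, i] = 1.0 / (1 - est.rho**2) ** 2
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        log.info("polychoric matrix not PSD (min eig %.3g); repairing", eig.min())
        R = nearest_psd_correlation(R)
    return R, W


def nearest_psd_correlation(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped projection onto PSD matrices with unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, eps, None)
    A = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    return A / np.outer(d, d)


@dataclass(frozen=True)
class CfaModelSpec:
    """Item-to-factor assignment for the congeneric factor model."""

    item_names: tuple[str, ...]
    factor_names: tuple[str, ...]
    factor_index: tuple[int, ...]  # owning factor per item

    @classmethod
    def from_item_map(cls, item_map: ItemMap) -> "CfaModelSpec":
        return cls(
            item_names=item_map.item_ids,
            factor_names=tuple(s.name for s in item_map.subscales),
            factor_index=tuple(item_map.item_factor_index()),
        )

    @property
    def p(self) -> int:
        return len(self.item_names)

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def n_free(self) -> int:
        return self.p + self.k * (self.k - 1) // 2

    @property
    def df(self) -> int:
        df = self.p * (self.p - 1) // 2 - self.n_free
        if df <= 0:
            raise ValueError("model is not identified (non-positive degrees of freedom)")
        return df


def _unpack(theta, spec: CfaModelSpec):
    p, k = spec.p, spec.k
    lam_vals = theta[:p]
    Lam = np.zeros((p, k))
    Lam[np.arange(p), list(spec.factor_index)] = lam_vals
    Phi = np.eye(k)
    iu = np.triu_indices(k, 1)
    Phi[iu] = theta[p:]
    Phi[(iu[1], iu[0])] = theta[p:]
    return Lam, Phi


def _dwls_objective(theta, R, W, spec, mask):
    Lam, Phi = _unpack(theta, spec)
    Sigma = Lam @ Phi @ Lam.T
    E = (R - Sigma) * mask
    M = W * E
    f = 0.5 * float((M * E).sum())  # counts each i<j pair once
    grad_L_full = -2.0 * (M @ Lam @ Phi)
    grad_lam = grad_L_full[np.arange(spec.p), list(spec.factor_index)]
    G = Lam.T @ M @ Lam
    iu = np.triu_indices(spec.k, 1)
    grad_phi = -2.0 * G[iu]
    return f, np.concatenate([grad_lam, grad_phi])


def fit_cfa(
    R: np.ndarray,
    W: np.ndarray,
    spec: CfaModelSpec,
    N: int,
    start_loading: float = 0.7,
    start_phi: float = 0.3,
    gtol: float = 1e-6,
    max_iter: int = 500,
):
    """Minimize the weighted least-squares discrepancy on the off-diagonals.

    Returns ``(loadings, factor_corr, F_min, chi2, df)`` with
    chi2 = (N - 1) * F_min.  Factor correlations outside the PSD cone are
    projected back (Heywood-style repair, warned).
    """
    p, k = spec.p, spec.k
    if R.shape != (p, p):
        raise ValueError("correlation matrix does not match the model spec")
    mask = 1.0 - np.eye(p)
    theta0 = np.concatenate(
        [np.full(p, start_loading), np.full(k * (k - 1) // 2, start_phi)]
    )
    bounds = [(-0.999, 0.999)] * len(theta0)
    res = optimize.minimize(
        _dwls_objective,
        theta0,
        args=(R, W, spec, mask),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14},
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        raise RuntimeError(
            f"CFA did not converge in {max_iter} iterations "
            f"(max gradient {np.max(np.abs(res.jac)):.3g})"
        )
    Lam, Phi = _unpack(res.x, spec)
    eig = np.linalg.eigvalsh(Phi)
    if eig.min() < -1e-10:
        warnings.warn("factor correlation matrix not PSD; projecting", stacklevel=2)
        Phi = nearest_psd_correlation(Phi)
    f_min = float(res.fun)
    chi2 = (N - 1) * f_min
    loadings = Lam[np.arange(p), list(spec.factor_index)]
    return loadings, Phi, f_min, chi2, spec.df


def baseline_chi2(R: np.ndarray, W: np.ndarray, N: int) -> tuple[float, int]:
    """Independence-model statistic: no structure, sigma_ij = 0 off-diagonal."""
    p = R.shape[0]
    iu = np.triu_indices(p, 1)
    f = float((W[iu] * R[iu] ** 2).sum())
    return (N - 1) * f, p * (p - 1) // 2


@dataclass(frozen=True)
class FitIndices:
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    n: float
    cfi: float
    tli: float | None
    rmsea: float
    verdict: str

    def summary(self) -> dict:
        return {
            "CFI": round(self.cfi, 2),
            "TLI": round(self.tli, 2) if self.tli is not None else None,
            "RMSEA": round(self.rmsea, 2),
            "verdict": self.verdict,
            "chi2": self.chi2_model,
            "df": self.df_model,
            "n": self.n,
        }


def fit_indices(chi2_m, df_m, chi2_b, df_b, n) -> FitIndices:
    """CFI, TLI and RMSEA from model and baseline statistics.

    CFI   = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0)
    TLI   = ((chi2_b/df_b) - (chi2_m/df_m)) / ((chi2_b/df_b) - 1)
    RMSEA = sqrt(max(chi2_m - df_m, 0) / (df_m (n - 1)))
    """
    if df_m <= 0 or df_b <= 0:
        raise ValueError("degrees of freedom must be positive")
    if n <= 1:
        raise ValueError("need n > 1")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    ratio_b = chi2_b / df_b
    if ratio_b <= 1:
        warnings.warn("baseline chi2/df <= 1; TLI undefined", stacklevel=2)
        tli = None
    else:
        tli = (ratio_b - chi2_m / df_m) / (ratio_b - 1)
    rmsea = float(np.sqrt(num / (df_m * (n - 1))))
    verdict = evaluate_fit(cfi, tli, rmsea)
    return FitIndices(chi2_m, df_m, chi2_b, df_b, n, cfi, tli, rmsea, verdict)


def evaluate_fit(cfi, tli, rmsea) -> str:
    """Two-of-three acceptance rule over the published cutoffs.

    good = all three criteria met; acceptable = exactly two; poor otherwise.
    An undefined TLI counts as an unmet criterion.
    """
    met = sum(
        [
            cfi is not None and cfi >= CFI_CUTOFF,
            tli is not None and tli >= TLI_CUTOFF,
            rmsea is not None and rmsea <= RMSEA_CUTOFF,
        ]
    )
    return "good" if met == 3 else ("acceptable" if met == 2 else "poor")


class OrdinalCFA:
    """Confirmatory factor analysis estimator for ordinal survey items.

    Parameters
    ----------
    spec : CfaModelSpec or None
        Item-to-factor map; derived from the dataset's item map if None.
    level : {"individual", "department"}
        Individual level uses polychoric correlations and DWLS weights;
        department level aggregates item means per department and fits the
        Pearson correlations with unit weights.

    Attributes (after :meth:`fit`)
    ------------------------------
    loadings_, factor_corr_, discrepancy_, chi2_, df_, fit_indices_
    """

    def __init__(self, spec: CfaModelSpec | None = None, level: str = "individual"):
        self.spec = spec
        self.level = level

    def get_params(self, deep=True) -> dict:
        return {"spec": self.spec, "level": self.level}

    def set_params(self, **params):
        for key, v in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, v)
        return self

    def fit(self, ds: SurveyDataset) -> "OrdinalCFA":
        spec = self.spec or CfaModelSpec.from_item_map(ds.item_map)
        items = list(spec.item_names)
        if self.level == "individual":
            R, W = polychoric_matrix(ds.data, items)
            n = len(ds.data)
        elif self.level == "department":
            agg = aggregate_items_to_department(ds)
            if len(agg) < 2:
                raise ValueError("department-level CFA needs at least 2 departments")
            R = agg[items].corr().to_numpy()
            W = np.ones_like(R)
            n = len(agg)
        else:
            raise ValueError(f"unknown level {self.level!r}")
        loadings, phi, f_min, chi2, df = fit_cfa(R, W, spec, n)
        chi2_b, df_b = baseline_chi2(R, W, n)
        self.spec_ = spec
        self.corr_ = R
        self.weights_ = W
        self.n_ = n
        self.loadings_ = pd.Series(loadings, index=items)
        self.factor_corr_ = pd.DataFrame(phi, index=spec.factor_names, columns=spec.factor_names)
        self.discrepancy_ = f_min
        self.chi2_, self.df_ = chi2, df
        self.chi2_baseline_, self.df_baseline_ = chi2_b, df_b
        self.fit_indices_ = fit_indices(chi2, df, chi2_b, df_b, n)
        return self


def pooled_fit_indices(runs: list[OrdinalCFA]) -> FitIndices:
    """Average chi2 statistics and n across imputed-data runs, then index."""
    if not runs:
        raise ValueError("no CFA runs to pool")
    chi2_m = float(np.mean([r.chi2_ for r in runs]))
    chi2_b = float(np.mean([r.chi2_baseline_ for r in runs]))
    n = float(np.mean([r.n_ for r in runs]))
    return fit_indices(chi2_m, runs[0].df_, chi2_b, runs[0].df_baseline_, n)


def cfa_by_group(
    datasets: list[SurveyDataset],
    group_field: str = "specialty",
    min_group_n: int = 200,
    spec: CfaModelSpec | None = None,
) -> dict:
    """Independent CFA per group, pooled across imputed datasets.

    Groups with fewer than ``min_group_n`` respondents are skipped with a
    warning.  Returns ``{group: FitIndices}``.
    """
    if not datasets:
        raise ValueError("no datasets")
    groups = sorted(datasets[0].data[group_field].dropna().unique())
    out = {}
    for g in groups:
        n_g = int((datasets[0].data[group_field] == g).sum())
        if n_g < min_group_n:
            warnings.warn(f"group {g!r} has n={n_g} < {min_group_n}; skipped", stacklevel=2)
            continue
        runs = []
        for ds in datasets:
            sub = SurveyDataset(
                ds.data[ds.data[group_field] == g].reset_index(drop=True),
                ds.item_map,
                provenance=dict(ds.provenance),
            )
            runs.append(OrdinalCFA(spec=spec, level="individual").fit(sub))
        out[g] = pooled_fit_indices(runs)
    return out


def department_level_cfa(
    datasets: list[SurveyDataset], spec: CfaModelSpec | None = None
) -> FitIndices:
    """Continuous-ML-style CFA on department item means, pooled over imputations."""
    runs = [OrdinalCFA(spec=spec, level="department").fit(ds) for ds in datasets]
    return pooled_fit_indices(runs)
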