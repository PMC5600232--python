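"""Chained-equations multiple imputation with predictive mean matching.

Each of ``m`` completed datasets comes from an independent chain.  Within a
chain, items are visited in a fixed order (ascending missingness fraction);
the working model for an item is a linear regression on its subscale
co-items and the demographic covariates, with posterior-style draws of the
coefficients, and missing cells are filled with the observed value of one of
the ``n_donors`` nearest predicted neighbours — so imputed codes always lie
in the item's observed support.

Convergence is monitored on per-variable chain means via the potential
scale reduction factor, and pooled inference across completed datasets uses
Rubin's rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .survey_model import SurveyDataset

log = logging.getLogger(__name__)


@dataclass
class ImputationSet:
    """The m completed datasets plus the chain diagnostics that produced them."""

    datasets: list[SurveyDataset]
    chain_means: dict  # variable -> (m, n_iter) array of per-iteration chain means
    settings: dict

    @property
    def m(self) -> int:
        return len(self.datasets)

    def rhat_per_variable(self) -> dict:
        return {v: rhat(c) for v, c in self.chain_means.items()}


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and their variances."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    m: int


def rubin_pool(estimates, m: int | None = None, alpha: float = 0.05) -> PooledEstimate:
    """Pool ``(Q_i, U_i)`` pairs: Q̄, W̄, B, T = W̄ + (1 + 1/m)B, Rubin df.

    ``estimates`` is a sequence of (point estimate, squared standard error).
    """
    est = list(estimates)
    m = m if m is not None else len(est)
    if m < 2 or len(est) != m:
        raise ValueError("need m >= 2 estimates")
    q = np.array([e[0] for e in est], dtype=float)
    u = np.array([e[1] for e in est], dtype=float)
    if (u < 0).any():
        raise ValueError("within-imputation variances must be non-negative")
    qbar = q.mean()
    wbar = u.mean()
    b = q.var(ddof=1)
    t = wbar + (1 + 1 / m) * b
    if b > 0:
        df = (m - 1) * (1 + wbar / ((1 + 1 / m) * b)) ** 2
    else:
        df = np.inf
    half = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(t) if t > 0 else 0.0
    return PooledEstimate(qbar, wbar, b, t, df, qbar - half, qbar + half, m)


def rhat(chains) -> float:
    """Potential scale reduction factor over per-chain iteration series.

    ``chains`` is an (m, L) array.  Returns 1.0 when all chains are the
    same constant (the 0/0 convention for already-converged series).
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    m, L = c.shape
    if L < 2:
        raise ValueError("need at least two iterations per chain")
    w = c.var(axis=1, ddof=1).mean()
    bhat = L * c.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((w * (L - 1) / L + bhat / L) / w))


def _pmm_draw(y_obs, X_obs, X_mis, rng, n_donors=5, ridge=1e-6):
    """One predictive-mean-matching draw for the missing rows.

    Coefficients are drawn from their approximate posterior
    (sigma^2 from a scaled inverse chi-square, beta from a normal) so that
    chains mix; matching uses observed-row predictions under the posterior
    mean and missing-row predictions under the draw.
    """
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs + ridge * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2_star = sigma2_hat * dof / stats.chi2.rvs(dof, random_state=rng)
    cov = sigma2_star * XtX_inv
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    k = min(n_donors, n)
    out = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        idx = np.argpartition(np.abs(pred_obs - pm), k - 1)[:k]
        out[i] = y_obs[idx[rng.integers(k)]]
    return out


class ChainedImputer:
    """Multiple imputation by chained equations with PMM donors.

    Parameters
    ----------
    m : number of completed datasets (independent chains), default 10.
    n_iterations : chained-equation cycles per chain, default 20.
    max_iterations : ceiling when extending for convergence, default 200.
    n_donors : PMM donor-pool size, default 5.
    random_state : root seed; chain seeds are derived from it.

    Attributes (after :meth:`fit`)
    ------------------------------
    result_ : ImputationSet
    rhat_ : dict of per-variable potential scale reduction factors
    """

    def __init__(self, m=10, n_iterations=20, max_iterations=200, n_donors=5, random_state=0):
        self.m = m
        self.n_iterations = n_iterations
        self.max_iterations = max_iterations
        self.n_donors = n_donors
        self.random_state = random_state

    def get_params(self, deep=True) -> dict:
        return {
            "m": self.m,
            "n_iterations": self.n_iterations,
            "max_iterations": self.max_iterations,
            "n_donors": self.n_donors,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _predictors(self, item_map, item):
        sub = next(s for s in item_map.subscales if item in s.items)
        co_items = [i for i in sub.items if i != item]
        return co_items, list(item_map.covariate_fields)

    def fit(self, ds: SurveyDataset) -> "ChainedImputer":
        if self.m < 2:
            raise ValueError("m must be >= 2")
        item_map = ds.item_map
        items = list(item_map.item_ids)
        df = ds.data
        miss_frac = df[items].isna().mean()
        fully_missing = miss_frac[miss_frac >= 1.0].index.tolist()
        if fully_missing:
            raise ValueError(f"variables 100% missing cannot be imputed: {fully_missing}")
        to_impute = [i for i in items if miss_frac[i] > 0]
        visit_order = sorted(to_impute, key=lambda i: (miss_frac[i], i))

        root = np.random.default_rng(self.random_state)
        chain_seeds = root.integers(2**31 - 1, size=self.m)

        completed, chain_means = [], {v: [] for v in visit_order}
        for chain in range(self.m):
            rng = np.random.default_rng(chain_seeds[chain])
            filled, means = self._run_chain(ds, visit_order, rng)
            for v in visit_order:
                chain_means[v].append(means[v])
            completed.append(
                SurveyDataset(
                    filled,
                    item_map,
                    provenance={**ds.provenance, "imputation_chain": chain},
                )
            )
        self.result_ = ImputationSet(
            datasets=completed,
            chain_means={v: np.asarray(c) for v, c in chain_means.items()},
            settings=self.get_params(),
        )
        self.rhat_ = self.result_.rhat_per_variable() if len(visit_order) and self.n_iterations >= 2 else {}
        bad = {v: r for v, r in self.rhat_.items() if r > 1.1}
        if bad:
            warnings.warn(
                f"imputation chains may not have converged (Rhat > 1.1): {sorted(bad)}",
                stacklevel=2,
            )
        return self

    def _run_chain(self, ds, visit_order, rng):
        item_map = ds.item_map
        df = ds.data.copy()
        covs = [c for c in item_map.covariate_fields if c in df.columns]
        # covariates used as predictors only: mean-fill any residual holes
        cov_block = df[covs].astype(float)
        cov_block = cov_block.fillna(cov_block.mean())
        miss_idx = {v: df.index[df[v].isna()] for v in visit_order}
        # start values: random draws from the observed distribution
        for v in visit_order:
            obs = df[v].dropna().to_numpy()
            df.loc[miss_idx[v], v] = rng.choice(obs, size=len(miss_idx[v]))
        means = {v: [] for v in visit_order}
        for _ in range(self.n_iterations):
            for v in visit_order:
                co_items, _ = self._predictors(item_map, v)
                pred_cols = [c for c in co_items if c in df.columns]
                X = np.column_stack(
                    [np.ones(len(df)), df[pred_cols].to_numpy(float), cov_block.to_numpy(float)]
                )
                mis_mask = df.index.isin(miss_idx[v])
                y_obs = df.loc[~mis_mask, v].to_numpy(float)
                if mis_mask.any():
                    draws = _pmm_draw(
                        y_obs, X[~mis_mask], X[mis_mask], rng, self.n_donors
                    )
                    df.loc[miss_idx[v], v] = draws
                means[v].append(float(df.loc[miss_idx[v], v].mean()) if len(miss_idx[v]) else np.nan)
        return df, {v: np.asarray(m) for v, m in means.items()}


def impute(ds: SurveyDataset, m=10, n_iterations=20, max_iterations=200, seed=0) -> ImputationSet:
    """Functional wrapper over :class:`ChainedImputer`."""
    imp = ChainedImputer(
        m=m, n_iterations=n_iterations, max_iterations=max_iterations, random_state=seed
    ).fit(ds)
    return imp.result_
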