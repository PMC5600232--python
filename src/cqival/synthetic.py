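"""Hierarchical ordinal survey simulator with known ground truth.

Respondents are nested in departments nested in hospitals.  For each
subscale j the latent respondent score is

    z_pdj = mu_j + a_hj + b_dj + e_pj

with a ~ N(0, sigma2_h_j) per hospital, b ~ N(0, sigma2_d_j) per department,
and respondent residuals e drawn jointly across subscales with correlation
matrix R and per-subscale variance sigma2_p_j.  Each item of subscale j is a
discretized congeneric indicator of the standardized latent:

    x* = lambda * zstd + sqrt(1 - lambda^2) * eps,   eps ~ N(0, 1)

cut at thresholds tau (three cuts -> categories 1..4) or a single cut
(binary 0/1).  Global 0-10 ratings are a clamped, rounded linear
combination of the latent subscale scores plus noise.  The exact components,
thresholds, loadings and per-respondent latents are returned as ground
truth so downstream estimators can be tested for parameter recovery.

Defaults emulate the published national study: its variance components,
individual-level inter-scale correlations, and skewed subscale means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .survey_model import BINARY, ItemMap, SurveyDataset, default_item_map

_COVARIATE_LEVELS = {
    "age_band": ([1, 2, 3, 4, 5, 6, 7, 8], [0.02, 0.07, 0.08, 0.13, 0.23, 0.24, 0.11, 0.12]),
    "sex": ([1, 2], [0.48, 0.52]),
    "education": ([1, 2, 3], [0.29, 0.46, 0.25]),
    "physical_health": ([1, 2, 3, 4, 5], [0.06, 0.22, 0.47, 0.20, 0.05]),
    "psych_health": ([1, 2, 3, 4, 5], [0.18, 0.24, 0.48, 0.09, 0.01]),
    "origin": ([1, 2, 3, 4, 5, 6], [0.925, 0.007, 0.013, 0.012, 0.008, 0.035]),
    "n_admissions": ([1, 2, 3, 4], [0.58, 0.26, 0.09, 0.07]),
}

_SPECIALTIES = ("surgery", "obstetrics_gynaecology", "internal_medicine", "cardiology")


def _default_thresholds() -> dict:
    """Cuts on the standard-normal item latent reproducing skewed means.

    Four-point category probabilities are the normal-CDF rectangles between
    consecutive cuts; binary items use a single cut at the (1-mean) quantile.
    """
    # category probabilities chosen to land near the published subscale means
    probs = {
        3.4: (0.03, 0.10, 0.31, 0.56),
        3.5: (0.02, 0.08, 0.28, 0.62),
        3.0: (0.08, 0.17, 0.42, 0.33),
    }
    taus = {}
    for mean, p in probs.items():
        cum = np.cumsum(p)[:3]
        taus[mean] = tuple(stats.norm.ppf(cum))
    out = {}
    for name in reference.SUBSCALE_NAMES:
        mean, _ = reference.SUBSCALE_MEANS[name]
        if name in ("admission", "information_discharge"):
            out[name] = (stats.norm.ppf(1.0 - mean),)
        else:
            out[name] = taus[mean]
    return out


@dataclass
class GeneratorConfig:
    """Full specification of one simulated survey.

    Variance components are on the latent subscale-score scale; the default
    values, correlations and rating weights reproduce the published study's
    structure.  ``respondents_per_department`` may be an int (balanced) or a
    ``(low, high)`` tuple for a discrete-uniform unbalanced design.
    """

    n_hospitals: int = 23
    departments_per_hospital: int | list[int] = 4
    respondents_per_department: int | tuple[int, int] = 45
    subscale_names: tuple[str, ...] = reference.SUBSCALE_NAMES
    mu: dict = field(default_factory=lambda: {k: v[0] for k, v in reference.SUBSCALE_MEANS.items()})
    sigma2_h: dict = field(default_factory=lambda: {k: v[2] for k, v in reference.VARIANCE_COMPONENTS.items()})
    sigma2_d: dict = field(default_factory=lambda: {k: v[1] for k, v in reference.VARIANCE_COMPONENTS.items()})
    sigma2_p: dict = field(default_factory=lambda: {k: v[0] for k, v in reference.VARIANCE_COMPONENTS.items()})
    correlation: np.ndarray = field(default_factory=reference.interscale_correlation_matrix)
    loading: float = 0.8
    thresholds: dict = field(default_factory=_default_thresholds)
    rating_beta: dict = field(default_factory=lambda: dict(reference.DEPARTMENT_RATING_BETA))
    rating_intercept: float = 4.5
    rating_noise_sd: float = 1.0
    missing_mechanism: str = "MCAR"
    missing_rate: float = 0.0
    mar_covariate: str = "age_band"
    mar_factors: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for d in (self.sigma2_h, self.sigma2_d, self.sigma2_p):
            if any(v < 0 for v in d.values()):
                raise ValueError("variance components must be non-negative")
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (len(self.subscale_names),) * 2 or not np.allclose(R, R.T):
            raise ValueError("correlation matrix must be square symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("inter-subscale correlation matrix is not positive semi-definite")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if abs(self.loading) > 1:
            raise ValueError("|loading| must be <= 1")
        for name, tau in self.thresholds.items():
            if list(tau) != sorted(tau) or len(set(tau)) != len(tau):
                raise ValueError(f"thresholds for {name} must be strictly increasing")


@dataclass
class GroundTruth:
    """Everything the generator used, for parameter-recovery testing."""

    config: GeneratorConfig
    latent_scores: pd.DataFrame  # respondent x subscale latent z, plus labels
    hospital_effects: pd.DataFrame
    department_effects: pd.DataFrame

    def components(self, subscale: str) -> tuple[float, float, float]:
        c = self.config
        return (c.sigma2_p[subscale], c.sigma2_d[subscale], c.sigma2_h[subscale])


def _department_sizes(cfg: GeneratorConfig, rng: np.random.Generator, n_departments: int):
    rp = cfg.respondents_per_department
    if isinstance(rp, int):
        return np.full(n_departments, rp, dtype=int)
    low, high = rp
    return rng.integers(low, high + 1, size=n_departments)


def generate(config: GeneratorConfig, item_map: ItemMap | None = None):
    """Simulate one survey; returns ``(SurveyDataset, GroundTruth)``.

    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    item_map = item_map or default_item_map()
    rng = np.random.default_rng(config.seed)
    names = list(config.subscale_names)
    J = len(names)

    dph = config.departments_per_hospital
    if isinstance(dph, int):
        dph = [dph] * config.n_hospitals
    hosp_labels = [f"H{i + 1:03d}" for i in range(config.n_hospitals)]
    dept_labels = []
    for hi, nd in enumerate(dph):
        for di in range(nd):
            dept_labels.append(f"{hosp_labels[hi]}D{di + 1:02d}")
    n_dept = len(dept_labels)
    sizes = _department_sizes(config, rng, n_dept)
    N = int(sizes.sum())

    sd_h = np.array([np.sqrt(config.sigma2_h[n]) for n in names])
    sd_d = np.array([np.sqrt(config.sigma2_d[n]) for n in names])
    sd_p = np.array([np.sqrt(config.sigma2_p[n]) for n in names])
    mu = np.array([config.mu[n] for n in names])

    hosp_eff = rng.normal(size=(config.n_hospitals, J)) * sd_h
    dept_eff = rng.normal(size=(n_dept, J)) * sd_d

    # respondent residuals: correlated across subscales, scaled per subscale
    L = np.linalg.cholesky(np.asarray(config.correlation, float) + 1e-10 * np.eye(J))
    resid = rng.normal(size=(N, J)) @ L.T * sd_p

    hosp_index_of_dept = np.repeat(np.arange(config.n_hospitals), dph)
    dept_of_resp = np.repeat(np.arange(n_dept), sizes)
    hosp_of_resp = hosp_index_of_dept[dept_of_resp]

    z = mu + hosp_eff[hosp_of_resp] + dept_eff[dept_of_resp] + resid

    total_sd = np.sqrt(sd_h**2 + sd_d**2 + sd_p**2)
    zstd = (z - mu) / total_sd

    lam = config.loading
    cols = {}
    for j, name in enumerate(names):
        sub = item_map.subscale(name)
        tau = np.asarray(config.thresholds[name])
        for item in sub.items:
            xstar = lam * zstd[:, j] + np.sqrt(1 - lam**2) * rng.normal(size=N)
            if sub.scale_kind == BINARY:
                cols[item] = (xstar > tau[0]).astype(float)
            else:
                cols[item] = (np.searchsorted(tau, xstar) + 1).astype(float)

    beta = np.array([config.rating_beta.get(n, 0.0) for n in names])
    for rating in item_map.global_rating_fields:
        raw = (
            config.rating_intercept
            + z @ beta
            + rng.normal(scale=config.rating_noise_sd, size=N)
        )
        cols[rating] = np.clip(np.round(raw), 0, 10)

    df = pd.DataFrame(
        {
            "respondent_id": np.arange(N),
            "hospital_id": [hosp_labels[h] for h in hosp_of_resp],
            "department_id": [dept_labels[d] for d in dept_of_resp],
            "specialty": rng.choice(_SPECIALTIES, size=N),
            item_map.admission_gate_field: np.ones(N),
        }
    )
    for k, v in cols.items():
        df[k] = v
    for cov, (levels, probs) in _COVARIATE_LEVELS.items():
        df[cov] = rng.choice(levels, size=N, p=probs).astype(float)

    ds = SurveyDataset(
        df,
        item_map,
        provenance={"generator": "cqival.synthetic", "seed": config.seed},
    )
    truth = GroundTruth(
        config=config,
        latent_scores=pd.DataFrame(z, columns=names).assign(
            hospital_id=df["hospital_id"].to_numpy(),
            department_id=df["department_id"].to_numpy(),
        ),
        hospital_effects=pd.DataFrame(hosp_eff, columns=names, index=hosp_labels),
        department_effects=pd.DataFrame(dept_eff, columns=names, index=dept_labels),
    )
    if config.missing_rate > 0:
        ds = inject_missingness(
            ds,
            config.missing_mechanism,
            config.missing_rate,
            seed=int(rng.integers(2**31 - 1)),
            covariate=config.mar_covariate,
            factors=config.mar_factors,
        )
    return ds, truth


def inject_missingness(
    ds: SurveyDataset,
    mechanism: str,
    rate: float,
    seed: int,
    covariate: str = "age_band",
    factors: dict | None = None,
) -> SurveyDataset:
    """Blank item cells at the given rate.

    MCAR: every item cell independently missing with probability ``rate``.
    MAR-on-covariate: the rate is multiplied per respondent by
    ``factors[category]`` of the stated covariate (default factor 1.0).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = ds.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    items = list(ds.item_map.item_ids)
    n = len(out.data)
    if mechanism == "MCAR":
        p = np.full(n, rate)
    elif mechanism == "MAR-on-covariate":
        factors = factors or {}
        cats = out.data[covariate]
        p = np.clip(cats.map(lambda c: rate * factors.get(c, 1.0)).to_numpy(float), 0, 0.99)
    else:
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    mask = rng.random(size=(n, len(items))) < p[:, None]
    arr = out.data[items].to_numpy(float)
    arr[mask] = np.nan
    out.data[items] = arr
    out.provenance = {**out.provenance, "missingness": {"mechanism": mechanism, "rate": rate}}
    return out


def table_seeded_config(**overrides) -> GeneratorConfig:
    """A generator config carrying the published study's structure."""
    return replace(GeneratorConfig(), **overrides)
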