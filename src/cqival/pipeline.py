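"""End-to-end orchestration: simulate/load -> exclude -> impute -> score ->
CFA -> generalizability -> validity, with a machine-readable report.

The report bundles a fit-index grid (overall, per specialty, department
level), the reliability block (alpha per subscale at both levels, flagged
overlapping pairs), variance components with whole-percent shares, the
D-study minimum-sample answers per subscale, and the construct-validity
regressions.  Every truncation, PSD repair, skipped group and convergence
warning is collected into a provenance section so the analysis decisions
are auditable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cfa as cfa_mod
from . import gtheory, reference
from .imputation import ChainedImputer
from .scales import reliability_report, score_subscales
from .survey_model import (
    BINARY,
    SurveyDataset,
    apply_exclusions,
    default_item_map,
    load_survey,
)
from .synthetic import GeneratorConfig, generate
from .validity import fit_global_rating_model

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage toggles, inputs and thresholds for one pipeline run."""

    input_csv: str | None = None  # if None, simulate from generator_config
    generator_config: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    m: int = 5
    n_iterations: int = 5
    run_exclusions: bool = True
    run_imputation: bool = True
    run_reliability: bool = True
    run_cfa: bool = False  # polychoric CFA over 34 items is the slow stage
    run_cfa_by_group: bool = False
    run_department_cfa: bool = True
    run_gtheory: bool = True
    run_validity: bool = True
    sem_threshold_four_point: float = reference.SEM_THRESHOLD_FOUR_POINT
    sem_threshold_binary: float = reference.SEM_THRESHOLD_BINARY
    alpha_cutoff: float = 0.70
    overlap_cutoff: float = 0.70
    output_dir: str | None = None

    def validate(self) -> None:
        for t in (self.sem_threshold_four_point, self.sem_threshold_binary,
                  self.alpha_cutoff, self.overlap_cutoff):
            if t <= 0:
                raise ValueError("thresholds must be positive")


def _fit_block(fi: cfa_mod.FitIndices) -> dict:
    return {
        "CFI": fi.cfi,
        "TLI": fi.tli,
        "RMSEA": fi.rmsea,
        "chi2": fi.chi2_model,
        "df": fi.df_model,
        "n": fi.n,
        "verdict": fi.verdict,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the report dict (also written to disk
    when ``config.output_dir`` is set)."""
    config.validate()
    report: dict = {"config": {"seed": config.seed, "m": config.m}, "provenance": []}
    item_map = default_item_map()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            _run_stages(config, item_map, report)
        except Exception as exc:  # annotate which stage failed, then re-raise
            stage = report.get("_stage", "setup")
            raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
        finally:
            report["provenance"].extend(str(w.message) for w in caught)
            report.pop("_stage", None)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
        (out / "report.txt").write_text(_render_text(report))
    return report


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _run_stages(config: PipelineConfig, item_map, report: dict) -> dict:
    report["_stage"] = "input"
    if config.input_csv:
        ds = load_survey(config.input_csv, item_map)
    else:
        gen_cfg = replace(config.generator_config, seed=config.seed)
        ds, _truth = generate(gen_cfg, item_map)
    report["n_received"] = ds.n

    if config.run_exclusions:
        report["_stage"] = "exclusions"
        ds, excl = apply_exclusions(ds)
        report["exclusions"] = excl.to_dict()

    report["_stage"] = "imputation"
    if config.run_imputation and ds.items().isna().any().any():
        imp = ChainedImputer(
            m=config.m, n_iterations=config.n_iterations, random_state=config.seed
        ).fit(ds)
        completed = imp.result_.datasets
        report["imputation"] = {
            "m": config.m,
            "rhat_max": max(imp.rhat_.values()) if imp.rhat_ else None,
        }
    else:
        completed = [ds]

    if config.run_reliability:
        report["_stage"] = "reliability"
        rel = reliability_report(completed)
        report["reliability"] = {
            "alpha_individual": rel.alpha_individual,
            "alpha_department": rel.alpha_department,
            "alpha_acceptable": rel.alpha_acceptable(),
            "overlap_individual": rel.overlap_individual,
            "overlap_department": rel.overlap_department,
        }

    fit_grid: dict = {}
    if config.run_cfa:
        report["_stage"] = "cfa_individual"
        runs = [cfa_mod.OrdinalCFA(level="individual").fit(d) for d in completed]
        fit_grid["all_individual"] = _fit_block(cfa_mod.pooled_fit_indices(runs))
    if config.run_cfa_by_group:
        report["_stage"] = "cfa_by_group"
        by_group = cfa_mod.cfa_by_group(completed)
        fit_grid.update({f"specialty_{g}": _fit_block(fi) for g, fi in by_group.items()})
    if config.run_department_cfa:
        report["_stage"] = "cfa_department"
        fit_grid["all_department"] = _fit_block(cfa_mod.department_level_cfa(completed))
    if fit_grid:
        report["fit_indices"] = fit_grid

    if config.run_gtheory:
        report["_stage"] = "gtheory"
        report["gtheory"] = _gtheory_block(completed, config)

    if config.run_validity:
        report["_stage"] = "validity"
        block = {}
        for outcome in item_map.global_rating_fields:
            rep = fit_global_rating_model(completed, outcome)
            block[outcome] = {
                term: {
                    "estimate": row["estimate"],
                    "ci": [row["ci_low"], row["ci_high"]],
                    "significant": bool(row["significant"]),
                }
                for term, row in rep.coefficients.iterrows()
            }
        report["validity"] = block

    return report


def _gtheory_block(completed: list[SurveyDataset], config: PipelineConfig) -> dict:
    item_map = completed[0].item_map
    out = {}
    for sub in item_map.subscales:
        per_imp_2, per_imp_3 = [], []
        for ds in completed:
            scores = score_subscales(ds)
            y = scores[sub.name].to_numpy()
            d = scores["department_id"].to_numpy()
            h = scores["hospital_id"].to_numpy()
            per_imp_2.append(gtheory.vc_nested_2level(y, d))
            per_imp_3.append(gtheory.vc_nested_3level(y, d, h))
        vc2 = gtheory.pool_components(per_imp_2)
        vc3 = gtheory.pool_components(per_imp_3)
        threshold = (
            config.sem_threshold_binary
            if sub.scale_kind == BINARY
            else config.sem_threshold_four_point
        )
        dstudy = gtheory.dstudy_grid(vc3, threshold=threshold, subscale=sub.name)
        out[sub.name] = {
            "components_pd": {
                "sigma2_res": vc2.sigma2_res,
                "sigma2_d": vc2.sigma2_d,
            },
            "components_pdh": {
                "sigma2_res": vc3.sigma2_res,
                "sigma2_d": vc3.sigma2_d,
                "sigma2_h": vc3.sigma2_h,
            },
            "shares": vc3.shares(),
            "threshold": threshold,
            "min_respondents": dstudy.min_respondents_department,
            "min_departments": dstudy.min_departments_hospital,
        }
    return out


def _render_text(report: dict) -> str:
    lines = ["Survey validation report", "=" * 30]
    if "exclusions" in report:
        e = report["exclusions"]
        lines.append(
            f"Received {e['n_received']}, excluded {e['n_excluded_no_admission']} (gate) "
            f"+ {e['n_excluded_incomplete']} (incomplete), retained {e['n_retained']}."
        )
    for name, block in report.get("fit_indices", {}).items():
        tli = "NA" if block["TLI"] is None else f"{block['TLI']:.2f}"
        lines.append(
            f"CFA {name}: CFI={block['CFI']:.2f} TLI={tli} "
            f"RMSEA={block['RMSEA']:.2f} -> {block['verdict']}"
        )
    if "reliability" in report:
        rel = report["reliability"]
        for sub, a in rel["alpha_individual"].items():
            lines.append(
                f"alpha[{sub}] individual={a:.2f} department={rel['alpha_department'][sub]:.2f}"
            )
        for a, b, r in rel["overlap_department"]:
            lines.append(f"OVERLAP (department level): {a} ~ {b}, r={r:.2f}")
    for sub, g in report.get("gtheory", {}).items():
        s = g["shares"]
        lines.append(
            f"{sub}: res={g['components_pdh']['sigma2_res']:.3f} "
            f"dept={g['components_pdh']['sigma2_d']:.3f} ({s['department_pct']}%) "
            f"hosp={g['components_pdh']['sigma2_h']:.3f} ({s['hospital_pct']}%) "
            f"min_n_p={g['min_respondents']} min_n_d={g['min_departments']}"
        )
    return "\n".join(lines) + "\n"
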