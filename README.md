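# cqival

Two-level psychometric validation of hierarchical patient-experience
surveys: synthetic nested survey generation, exclusion filtering, multiple
imputation, subscale scoring and reliability screens, ordinal confirmatory
factor analysis, and unbalanced nested generalizability (G/D-study)
analysis with minimum-sample solvers.

## Scientific problem

Patient-experience questionnaires such as the CQI Inpatient Hospital Care
instrument score respondents on nine subscales (communication with nurses,
communication with doctors, information at admission and discharge, pain
management, and so on) built from 34 four-point or yes/no items. Hospitals
are compared on subscale means, so two questions matter beyond ordinary
item-level psychometrics:

1. **Does the 9-factor structure hold** for ordinal item data, at the
   individual level and for department-level aggregates? This needs
   polychoric correlations and diagonally weighted least-squares (DWLS)
   factor analysis, judged by CFI/TLI/RMSEA under a 2-of-3 rule.
2. **How many respondents and departments are needed** before a department
   or hospital mean is precise enough to discriminate? Respondents are
   nested in departments nested in hospitals with very unequal group
   sizes, so variance components are estimated with Henderson's analogous
   ANOVA for unbalanced nested designs, and D-study projections convert
   them into a standard error of measurement (SEM) for mean scores:

   - department level: `SEM = sqrt(sigma2_res / n_p)`
   - hospital level: `SEM = sqrt(sigma2_d / n_d + sigma2_res / (n_d * n_p))`

   Minimum sample sizes are the smallest `n_p` (on a step-50 grid) or
   integer `n_d` pushing SEM below 0.10 (four-point subscales) or 0.025
   (binary subscales).

Because respondent-level data of this kind are never public, the package
ships a hierarchical synthetic generator (correlated latent subscale
scores with department and hospital random effects, discretized to ordinal
items, with configurable MCAR/MAR missingness) that serves as ground truth
for every estimator.

## Worked example

```python
from cqival import (
    GeneratorConfig, generate, inject_missingness, ChainedImputer,
    score_subscales, reliability_report, vc_nested_3level,
    VarianceComponents, min_respondents, min_departments, reference,
)
from cqival.gtheory import pool_components

# simulate 8 hospitals x 4 departments x 60 respondents, add 5% MCAR
# missingness, and multiply impute
cfg = GeneratorConfig(n_hospitals=8, departments_per_hospital=4,
                      respondents_per_department=60, seed=11)
ds, truth = generate(cfg)
miss = inject_missingness(ds, "MCAR", 0.05, seed=12)
imp = ChainedImputer(m=5, n_iterations=20, random_state=11).fit(miss)
print(f"{ds.n} respondents, max R-hat {max(imp.rhat_.values()):.3f}")

rel = reliability_report(imp.result_.datasets)
print(f"alpha[communication_nurses] = {rel.alpha_individual['communication_nurses']:.2f}")

# pooled G-study for one subscale across the imputed datasets
per_imp = []
for d in imp.result_.datasets:
    s = score_subscales(d)
    per_imp.append(vc_nested_3level(s["own_contribution"].to_numpy(),
                                    s["department_id"].to_numpy(),
                                    s["hospital_id"].to_numpy()))
vc = pool_components(per_imp)
print(f"own_contribution components: res={vc.sigma2_res:.3f} "
      f"dept={vc.sigma2_d:.3f} hosp={vc.sigma2_h:.3f}")
print(f"shares: {vc.shares()}")

# D-study planning answers from the published variance components
published = VarianceComponents(*reference.VARIANCE_COMPONENTS["admission"])
print("min respondents/department (admission, binary threshold):",
      min_respondents(published, reference.SEM_THRESHOLD_BINARY, grid_step=50))
discharge = VarianceComponents(*reference.VARIANCE_COMPONENTS["information_discharge"])
print("min departments/hospital (discharge, 100 respondents each):",
      min_departments(discharge, 100, reference.SEM_THRESHOLD_BINARY))
```

Output:

```
1920 respondents, max R-hat 1.035
alpha[communication_nurses] = 0.78
own_contribution components: res=0.489 dept=0.008 hosp=0.022
shares: {'department_pct': 2, 'hospital_pct': 4, 'hospital_ratio': 0.73}
min respondents/department (admission, binary threshold): 100
min departments/hospital (discharge, 100 respondents each): 10
```

The full pipeline (exclusions, imputation, reliability, CFA grid,
G-theory, validity regressions, JSON + text report) is available as a
library call and a CLI:

```python
from cqival import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=7, output_dir="out"))
```

```sh
cqi simulate --seed 9 --out survey.csv
cqi run --seed 9 --out-dir report/
```

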