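"""Published reference quantities for the inpatient-experience instrument.

These constants are the printed inputs of the original national validation
study (23 hospitals, 515 department evaluations): per-subscale variance
components from the unbalanced nested designs, individual-level inter-scale
correlations, subscale means/SDs, and the global-rating regression weights.
They seed the synthetic-data generator and the sample-size reproductions;
nothing here is an output of this package.
"""

from __future__ import annotations

import numpy as np

SUBSCALE_NAMES = (
    "admission",
    "communication_nurses",
    "communication_doctors",
    "own_contribution",
    "explanation_treatment",
    "pain_management",
    "communication_medication",
    "feeling_safety",
    "information_discharge",
)

#: Per-subscale variance components on the subscale-score scale:
#: (residual i.e. respondent-within-department, between-department,
#: between-hospital).
VARIANCE_COMPONENTS = {
    "admission": (0.059, 0.003, 0.000),
    "communication_nurses": (0.360, 0.005, 0.004),
    "communication_doctors": (0.490, 0.006, 0.004),
    "own_contribution": (0.404, 0.014, 0.020),
    "explanation_treatment": (0.435, 0.012, 0.003),
    "pain_management": (0.376, 0.008, 0.002),
    "communication_medication": (0.805, 0.012, 0.008),
    "feeling_safety": (0.446, 0.010, 0.002),
    "information_discharge": (0.089, 0.005, 0.000),
}

#: Published whole-percent variance shares (department %, hospital %) and
#: the hospital/(hospital+department) ratio, as printed.
PUBLISHED_SHARES = {
    "admission": (5, 0, 0.0),
    "communication_nurses": (1, 1, 0.44),
    "communication_doctors": (1, 1, 0.40),
    "own_contribution": (3, 5, 0.59),
    "explanation_treatment": (3, 1, 0.20),
    "pain_management": (2, 1, 0.20),
    "communication_medication": (1, 1, 0.40),
    "feeling_safety": (2, 0, 0.17),
    "information_discharge": (5, 0, 0.0),
}

#: Individual-level subscale means and SDs (binary subscales on 0-1,
#: four-point on 1-4).
SUBSCALE_MEANS = {
    "admission": (0.6, 0.25),
    "communication_nurses": (3.4, 0.61),
    "communication_doctors": (3.4, 0.71),
    "own_contribution": (3.0, 0.66),
    "explanation_treatment": (3.5, 0.67),
    "pain_management": (3.5, 0.62),
    "communication_medication": (3.0, 0.91),
    "feeling_safety": (3.4, 0.68),
    "information_discharge": (0.7, 0.31),
}

#: Individual-level inter-scale Pearson correlations (upper triangle of the
#: published table), subscale order as in SUBSCALE_NAMES.
_R_UPPER = [
    [1.00, 0.30, 0.29, 0.31, 0.39, 0.25, 0.38, 0.35, 0.42],
    [0.00, 1.00, 0.56, 0.49, 0.51, 0.55, 0.47, 0.46, 0.35],
    [0.00, 0.00, 1.00, 0.42, 0.56, 0.41, 0.43, 0.37, 0.33],
    [0.00, 0.00, 0.00, 1.00, 0.44, 0.38, 0.46, 0.39, 0.31],
    [0.00, 0.00, 0.00, 0.00, 1.00, 0.45, 0.57, 0.43, 0.43],
    [0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.42, 0.41, 0.32],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.47, 0.45],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00, 0.38],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.00],
]


def interscale_correlation_matrix() -> np.ndarray:
    """Individual-level 9x9 inter-scale correlation matrix."""
    u = np.asarray(_R_UPPER)
    r = np.triu(u, 1)
    return r + r.T + np.eye(9)


#: Global department-rating regression weights per subscale (point
#: estimates of the published construct-validity regression).
DEPARTMENT_RATING_BETA = {
    "admission": 0.14,
    "communication_nurses": 1.00,
    "communication_doctors": 0.08,
    "own_contribution": 0.31,
    "explanation_treatment": -0.03,
    "pain_management": 0.34,
    "communication_medication": -0.01,
    "feeling_safety": 0.21,
    "information_discharge": 0.54,
}

#: Published response accounting: distributed, returned, excluded.
RESPONSE_COUNTS = (74090, 23476, 552)

#: Precision thresholds for the D-study: admissible SEM for a department or
#: hospital mean, by item scale (four-point 1-4 vs binary 0-1).
SEM_THRESHOLD_FOUR_POINT = 0.10
SEM_THRESHOLD_BINARY = 0.025
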