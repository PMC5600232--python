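"""Survey data model: item map, dataset container, CSV I/O and exclusion filters.

The instrument measured here is a standardized inpatient-experience
questionnaire: 34 experience items grouped into 9 subscales, two 0-10 global
ratings (department and hospital), and a set of demographic covariates.
Respondents are nested in departments, which are nested in hospitals.

Two subscales (admission, information at discharge) use yes/no items coded
0/1; the other seven use a 4-point frequency scale coded 1-4.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

FOUR_POINT = "four_point"
BINARY = "binary"

#: Structural columns every survey table carries besides items.
ID_FIELDS = ("respondent_id", "hospital_id", "department_id", "specialty")


@dataclass(frozen=True)
class Subscale:
    name: str
    items: tuple[str, ...]
    scale_kind: str  # FOUR_POINT or BINARY

    @property
    def score_range(self) -> tuple[float, float]:
        return (0.0, 1.0) if self.scale_kind == BINARY else (1.0, 4.0)


@dataclass(frozen=True)
class ItemMap:
    """Mapping of questionnaire items to subscales plus auxiliary fields.

    ``core_items`` drive the completion filter: a respondent must have
    answered at least half of them to be retained.
    """

    subscales: tuple[Subscale, ...]
    global_rating_fields: tuple[str, str] = ("department_rating", "hospital_rating")
    covariate_fields: tuple[str, ...] = (
        "age_band",
        "sex",
        "education",
        "physical_health",
        "psych_health",
        "origin",
        "n_admissions",
    )
    admission_gate_field: str = "admitted_last_12m"
    core_items: tuple[str, ...] = ()

    def __post_init__(self):
        names = [s.name for s in self.subscales]
        if len(set(names)) != len(names):
            raise ValueError("duplicate subscale names")
        all_items = [i for s in self.subscales for i in s.items]
        if len(set(all_items)) != len(all_items):
            raise ValueError("an item is assigned to two subscales")
        if not self.core_items:
            object.__setattr__(self, "core_items", tuple(all_items))

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i for s in self.subscales for i in s.items)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def subscale(self, name: str) -> Subscale:
        for s in self.subscales:
            if s.name == name:
                return s
        raise KeyError(name)

    def scale_kind(self, item: str) -> str:
        for s in self.subscales:
            if item in s.items:
                return s.scale_kind
        raise KeyError(item)

    def item_factor_index(self) -> np.ndarray:
        """Index of the owning subscale for each item, in item_ids order."""
        idx = []
        for j, s in enumerate(self.subscales):
            idx.extend([j] * len(s.items))
        return np.asarray(idx, dtype=int)


def default_item_map() -> ItemMap:
    """The published 9-subscale structure with its questionnaire Q-codes."""
    subs = (
        Subscale("admission", tuple(f"Q4{c}" for c in "abcdefghij"), BINARY),
        Subscale("communication_nurses", ("Q6", "Q7", "Q8"), FOUR_POINT),
        Subscale("communication_doctors", ("Q9", "Q10"), FOUR_POINT),
        Subscale("own_contribution", ("Q13", "Q14", "Q15", "Q17", "Q25"), FOUR_POINT),
        Subscale("explanation_treatment", ("Q18", "Q19", "Q20"), FOUR_POINT),
        Subscale("pain_management", ("Q21", "Q22"), FOUR_POINT),
        Subscale("communication_medication", ("Q23", "Q24"), FOUR_POINT),
        Subscale("feeling_safety", ("Q27", "Q28", "Q29"), FOUR_POINT),
        Subscale("information_discharge", ("Q31", "Q32", "Q33", "Q34"), BINARY),
    )
    return ItemMap(subscales=subs)


@dataclass
class SurveyDataset:
    """A respondent-by-variable table plus the item map that types it.

    ``data`` holds one row per respondent with the columns in ``ID_FIELDS``,
    one column per item, the two global ratings, the admission-gate field and
    the covariates.  Missing values are NaN.
    """

    data: pd.DataFrame
    item_map: ItemMap
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    def items(self) -> pd.DataFrame:
        return self.data[list(self.item_map.item_ids)]

    def copy(self) -> "SurveyDataset":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class ExclusionReport:
    n_received: int
    n_excluded_no_admission: int
    n_excluded_incomplete: int
    n_retained: int

    def to_dict(self) -> dict:
        return {
            "n_received": self.n_received,
            "n_excluded_no_admission": self.n_excluded_no_admission,
            "n_excluded_incomplete": self.n_excluded_incomplete,
            "n_retained": self.n_retained,
        }


class SurveyFormatError(ValueError):
    """Structural problem with an input survey table."""


def _range_mask(col: pd.Series, kind: str) -> pd.Series:
    """True where the value is out of range for its scale kind (NaN passes)."""
    if kind == BINARY:
        ok = col.isin([0, 1])
    else:
        ok = col.isin([1, 2, 3, 4])
    return ~ok & col.notna()


def validate_dataset(ds: SurveyDataset) -> int:
    """Coerce out-of-range codes to missing in place; return count coerced."""
    n_bad = 0
    df = ds.data
    for item in ds.item_map.item_ids:
        bad = _range_mask(df[item], ds.item_map.scale_kind(item))
        n_bad += int(bad.sum())
        df.loc[bad, item] = np.nan
    for rating in ds.item_map.global_rating_fields:
        if rating in df.columns:
            bad = ~df[rating].isin(range(11)) & df[rating].notna()
            n_bad += int(bad.sum())
            df.loc[bad, rating] = np.nan
    return n_bad


def load_survey(path, item_map: ItemMap | None = None) -> SurveyDataset:
    """Read a survey CSV into a typed :class:`SurveyDataset`.

    Out-of-range item codes are coerced to missing with a single summary
    warning.  Missing cells are empty or the literal ``NA``.
    """
    item_map = item_map or default_item_map()
    df = pd.read_csv(path, na_values=["NA", ""], dtype={"specialty": "string"})
    if len(df) == 0:
        raise SurveyFormatError(f"no data rows in {path}")
    for col in ("hospital_id", "department_id"):
        if col not in df.columns:
            raise SurveyFormatError(f"mandatory column {col!r} missing from {path}")
    missing_items = [c for c in item_map.item_ids if c not in df.columns]
    if missing_items:
        raise SurveyFormatError(f"item columns missing: {missing_items}")
    if "respondent_id" not in df.columns:
        df.insert(0, "respondent_id", np.arange(len(df)))
    numeric = [c for c in df.columns if c not in ("specialty",) and df[c].dtype == object]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ds = SurveyDataset(df, item_map, provenance={"source": str(path)})
    n_bad = validate_dataset(ds)
    ds.provenance["n_out_of_range"] = n_bad
    if n_bad:
        warnings.warn(f"{n_bad} out-of-range codes set to missing", stacklevel=2)
    return ds


def write_survey(ds: SurveyDataset, path) -> None:
    ds.data.to_csv(path, index=False, na_rep="")


def apply_exclusions(ds: SurveyDataset) -> tuple[SurveyDataset, ExclusionReport]:
    """Drop respondents failing the admission gate or the completion filter.

    Rules, checked in order (each respondent counted once):

    1. a negative or missing answer to the "hospitalized in the last 12
       months" gate question excludes the respondent;
    2. fewer than half of the core items answered excludes the respondent
       (exactly half is retained).
    """
    df = ds.data
    gate = ds.item_map.admission_gate_field
    if gate in df.columns:
        gate_fail = ~(df[gate] == 1)
    else:
        gate_fail = pd.Series(False, index=df.index)
    core = list(ds.item_map.core_items)
    n_core = len(core)
    answered = df[core].notna().sum(axis=1)
    incomplete = (answered < n_core / 2.0) & ~gate_fail
    keep = ~gate_fail & ~incomplete
    report = ExclusionReport(
        n_received=len(df),
        n_excluded_no_admission=int(gate_fail.sum()),
        n_excluded_incomplete=int(incomplete.sum()),
        n_retained=int(keep.sum()),
    )
    out = SurveyDataset(
        df.loc[keep].reset_index(drop=True),
        ds.item_map,
        provenance={**ds.provenance, "exclusions": report.to_dict()},
    )
    return out, report


def response_rate_summary(
    n_distributed: int, n_returned: int, n_excluded: int
) -> dict:
    """Gross/net response rates (percent, one decimal) and net sample size."""
    if n_distributed <= 0:
        raise ValueError("n_distributed must be positive")
    if not (0 <= n_excluded <= n_returned <= n_distributed):
        raise ValueError("require 0 <= n_excluded <= n_returned <= n_distributed")
    n_net = n_returned - n_excluded
    return {
        "gross_rate": round(100.0 * n_returned / n_distributed, 1),
        "net_rate": round(100.0 * n_net / n_distributed, 1),
        "n_net": n_net,
    }


def exclusion_report_to_json(report: ExclusionReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
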