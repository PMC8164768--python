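"""Population attributable risk via the case-distribution (Bruzzi) estimator.

``PAR = 1 - sum_j p_j / RR_j`` where ``p_j`` is the proportion of observed
cases falling in joint exposure category ``j`` and ``RR_j`` that category's
relative risk versus the all-reference category.  A PAR of 0 means none of
the incidence is attributable to the modeled factors; deflating composite
incidence by ``1 - PAR`` yields the baseline (all-reference) hazard.

Because risk-factor distributions differ by residence and the BMI effect
switches at age 50, the PAR is estimated separately in the four groups
(age segment below/at-or-above 50) x (urban/rural), with a case's segment
decided by attained age at diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .risk_model import RelativeRiskModel, ValidationError


@dataclass
class CaseDistribution:
    """Proportion of cases and relative risk per joint exposure category."""

    proportions: np.ndarray
    relative_risks: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.relative_risks = np.asarray(self.relative_risks, dtype=float)
        if self.proportions.shape != self.relative_risks.shape:
            raise ValidationError("proportions and relative_risks differ in length")
        if np.any(self.proportions < 0):
            raise ValidationError("case proportions must be non-negative")
        if abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"case proportions sum to {self.proportions.sum()!r}, not 1"
            )
        if np.any(self.relative_risks <= 0):
            raise ValidationError("relative risks must be positive")


@dataclass(frozen=True)
class PARSet:
    """Attributable-risk fractions indexed by age segment x residence."""

    urban_lt50: float
    urban_ge50: float
    rural_lt50: float
    rural_ge50: float

    def __post_init__(self) -> None:
        for name, v in self.to_dict().items():
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"PAR {name}={v} outside [0, 1)")

    def get(self, residence: str, age: float, age_split: float = 50.0) -> float:
        seg = "lt50" if age < age_split else "ge50"
        return getattr(self, f"{residence}_{seg}")

    def to_dict(self) -> dict[str, float]:
        return {
            "urban_lt50": self.urban_lt50,
            "urban_ge50": self.urban_ge50,
            "rural_lt50": self.rural_lt50,
            "rural_ge50": self.rural_ge50,
        }

    @classmethod
    def from_dict(cls, d) -> "PARSet":
        missing = {"urban_lt50", "urban_ge50", "rural_lt50", "rural_ge50"} - set(d)
        if missing:
            raise ValidationError(f"PAR set missing keys: {sorted(missing)}")
        return cls(**{k: float(d[k]) for k in
                      ("urban_lt50", "urban_ge50", "rural_lt50", "rural_ge50")})


def bruzzi_par(dist: CaseDistribution) -> float:
    """``1 - sum_j p_j / RR_j`` for a validated case distribution."""
    return float(1.0 - np.sum(dist.proportions / dist.relative_risks))


_SEGMENT_COLS = ["education", "bmi_cat", "height_cat", "famhist_cat",
                 "parity_cat", "menarche_cat"]


def _case_distribution(cases: pd.DataFrame, model: RelativeRiskModel,
                       segment: str) -> CaseDistribution:
    """Joint case distribution built sparsely from observed cases.

    The joint category of a case is its full cross-classification over the
    six predictors; the segment-appropriate BMI map supplies its RR.
    """
    bmi_eff = model.bmi_lt50 if segment == "lt50" else model.bmi_ge50
    grouped = cases.groupby(_SEGMENT_COLS, observed=True).size()
    counts = grouped.to_numpy(dtype=float)
    keys = np.array(list(grouped.index), dtype=int)
    log_rr = (
        model.effects["education"].log_rr[keys[:, 0]]
        + bmi_eff.log_rr[keys[:, 1]]
        + model.effects["height"].log_rr[keys[:, 2]]
        + model.effects["family_history"].log_rr[keys[:, 3]]
        + model.effects["parity"].log_rr[keys[:, 4]]
        + model.effects["menarche"].log_rr[keys[:, 5]]
    )
    p = counts / counts.sum()
    p = p / p.sum()  # guard rounding so the invariant holds exactly
    return CaseDistribution(proportions=p, relative_risks=np.exp(log_rr))


def par_set_from_cohort(records: pd.DataFrame, model: RelativeRiskModel) -> PARSet:
    """Estimate the four PARs from a cohort's observed breast-cancer cases.

    ``records`` uses the categorized cohort frame (see
    :mod:`bcrisk.interface_io`): columns ``event``, ``exit_age``,
    ``residence`` and the six ``*_cat``/``education`` category codes.  A
    case's age segment is its attained age at diagnosis.
    """
    cases = records[records["event"] == "bc"]
    values = {}
    for residence in ("urban", "rural"):
        for segment in ("lt50", "ge50"):
            if segment == "lt50":
                sel = (cases["residence"] == residence) & (
                    cases["exit_age"] < model.age_split
                )
            else:
                sel = (cases["residence"] == residence) & (
                    cases["exit_age"] >= model.age_split
                )
            sub = cases[sel]
            if len(sub) == 0:
                raise ValidationError(
                    f"no breast-cancer cases in group {residence}/{segment}"
                )
            values[f"{residence}_{segment}"] = bruzzi_par(
                _case_distribution(sub, model, segment)
            )
    return PARSet(**values)
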