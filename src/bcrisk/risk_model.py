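"""Relative-risk model for breast cancer: categorical risk-factor profiles and RR(x).

The model is multiplicative on the hazard scale: ``RR(x) = exp(sum of
per-predictor log relative risks)``.  Every predictor is age-constant except
body-mass index, which carries two separate category->log-RR maps, one for
attained ages below 50 and one for 50 and above (the proportional-hazards
check in model development shows the BMI association reverses around
menopause).  The reference category of every predictor has log-RR exactly 0,
and the lowest-risk category is the reference so that population attributable
risk is well defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

AGE_SPLIT = 50.0

# Ordered category labels.  Boundaries are left-closed/right-open on the
# printed lower bounds so the partition of the real line is exhaustive.
EDUCATION_LEVELS = (
    "no_formal_school",
    "primary_school",
    "middle_school",
    "high_school",
    "college_university",
)
BMI_LEVELS = ("<18.5", "18.5-23.9", "24.0-27.9", ">=28")
BMI_CUTS = (18.5, 24.0, 28.0)
HEIGHT_LEVELS = ("<150.2", "150.2-154.1", "154.2-158.1", ">=158.2")
HEIGHT_CUTS = (150.2, 154.2, 158.2)
FAMILY_HISTORY_LEVELS = ("0", "1", ">=2")
PARITY_LEVELS = ("nulliparous", "1", "2", ">=3")
MENARCHE_LEVELS = ("<=12", "13-14", "15-16", ">=17")
MENARCHE_CUTS = (13.0, 15.0, 17.0)

RESIDENCES = ("urban", "rural")

#: physiologic plausibility windows used by :func:`categorize`
PLAUSIBLE_RANGES = {
    "bmi": (10.0, 60.0),
    "height_cm": (100.0, 200.0),
    "menarche_age": (8.0, 25.0),
    "parity": (0, 15),
}

PREDICTORS = (
    "education",
    "bmi",
    "height",
    "family_history",
    "parity",
    "menarche",
)

_LEVELS = {
    "education": EDUCATION_LEVELS,
    "bmi": BMI_LEVELS,
    "height": HEIGHT_LEVELS,
    "family_history": FAMILY_HISTORY_LEVELS,
    "parity": PARITY_LEVELS,
    "menarche": MENARCHE_LEVELS,
}


def levels_of(predictor: str) -> tuple[str, ...]:
    """Ordered category labels for a predictor name."""
    return _LEVELS[predictor]


class ValidationError(ValueError):
    """Raised when raw covariates or serialized models fail validation."""


@dataclass(frozen=True)
class RiskFactorProfile:
    """One woman's categorized predictor values plus residence.

    Every field holds the integer index of the category within the ordered
    level list for that predictor (0 = first printed category).
    """

    education: int
    bmi_category: int
    height_category: int
    family_history: int
    parity: int
    menarche_category: int
    residence: str

    def __post_init__(self) -> None:
        for name, idx in (
            ("education", self.education),
            ("bmi", self.bmi_category),
            ("height", self.height_category),
            ("family_history", self.family_history),
            ("parity", self.parity),
            ("menarche", self.menarche_category),
        ):
            nlev = len(_LEVELS[name])
            if not (isinstance(idx, (int, np.integer)) and 0 <= idx < nlev):
                raise ValidationError(
                    f"{name}: category index {idx!r} outside 0..{nlev - 1}"
                )
        if self.residence not in RESIDENCES:
            raise ValidationError(f"residence must be one of {RESIDENCES}")

    def category_indices(self) -> dict[str, int]:
        return {
            "education": self.education,
            "bmi": self.bmi_category,
            "height": self.height_category,
            "family_history": self.family_history,
            "parity": self.parity,
            "menarche": self.menarche_category,
        }


def _bin(value: float, cuts: Sequence[float]) -> int:
    """Index of the left-closed bin containing ``value``."""
    idx = 0
    for c in cuts:
        if value >= c:
            idx += 1
    return idx


def categorize(
    raw: Mapping[str, object],
    residence: str | None = None,
) -> RiskFactorProfile:
    """Map a raw covariate record to a :class:`RiskFactorProfile`.

    ``raw`` needs keys ``education`` (level label or index), ``bmi``,
    ``height_cm``, ``family_history`` (count), ``parity`` (count) and
    ``menarche_age`` (years); ``residence`` may be a key of ``raw`` or passed
    separately.  Values outside the physiologic plausibility windows raise
    :class:`ValidationError` naming the offending field.  Already-categorized
    input (integer category indices where counts coincide with indices, e.g.
    family history) maps to itself, so the operation is idempotent.
    """
    res = residence if residence is not None else raw.get("residence")
    if res not in RESIDENCES:
        raise ValidationError(f"residence must be one of {RESIDENCES}, got {res!r}")

    edu = raw["education"]
    if isinstance(edu, str):
        if edu not in EDUCATION_LEVELS:
            raise ValidationError(f"education: unknown level {edu!r}")
        edu_idx = EDUCATION_LEVELS.index(edu)
    else:
        edu_idx = int(edu)
        if not 0 <= edu_idx < len(EDUCATION_LEVELS):
            raise ValidationError(f"education: index {edu_idx} outside 0..4")

    def _check(name: str, value: float) -> float:
        lo, hi = PLAUSIBLE_RANGES[name]
        v = float(value)
        if not (lo <= v <= hi) or math.isnan(v):
            raise ValidationError(
                f"{name}: value {value!r} outside plausible range [{lo}, {hi}]"
            )
        return v

    bmi = _check("bmi", raw["bmi"])
    height = _check("height_cm", raw["height_cm"])
    menarche = _check("menarche_age", raw["menarche_age"])
    parity = int(_check("parity", raw["parity"]))
    fh = int(raw["family_history"])
    if fh < 0:
        raise ValidationError(f"family_history: count {fh} negative")

    return RiskFactorProfile(
        education=edu_idx,
        bmi_category=_bin(bmi, BMI_CUTS),
        height_category=_bin(height, HEIGHT_CUTS),
        family_history=min(fh, 2),
        parity=min(parity, 3),
        menarche_category=_bin(menarche, MENARCHE_CUTS),
        residence=res,
    )


@dataclass
class PredictorEffect:
    """Per-category log relative risks for one predictor."""

    name: str
    levels: tuple[str, ...]
    log_rr: np.ndarray  # aligned with levels
    reference: int
    encoding: str = "categorical"  # or "ordinal"
    ci: list | None = None  # metadata only, never used in projection

    def __post_init__(self) -> None:
        self.log_rr = np.asarray(self.log_rr, dtype=float)
        if self.log_rr.shape != (len(self.levels),):
            raise ValidationError(
                f"{self.name}: log_rr length {self.log_rr.size} != "
                f"{len(self.levels)} levels"
            )
        if not np.all(np.isfinite(self.log_rr)):
            raise ValidationError(f"{self.name}: non-finite log relative risk")
        if not 0 <= self.reference < len(self.levels):
            raise ValidationError(f"{self.name}: reference index out of range")
        if self.log_rr[self.reference] != 0.0:
            raise ValidationError(
                f"{self.name}: reference level log-RR must be exactly 0"
            )
        if self.encoding not in ("categorical", "ordinal"):
            raise ValidationError(f"{self.name}: unknown encoding {self.encoding!r}")


@dataclass
class RelativeRiskModel:
    """Multiplicative relative-risk model with an age-segmented BMI effect.

    ``effects`` maps the five age-constant predictors to their
    :class:`PredictorEffect`; BMI has one effect per age segment
    (``bmi_lt50``, ``bmi_ge50``) with the switch at :attr:`age_split`.
    ``par`` optionally carries the four attributable-risk fractions
    (age segment x residence) used to deflate composite incidence rates.
    """

    effects: dict[str, PredictorEffect]
    bmi_lt50: PredictorEffect = None  # type: ignore[assignment]
    bmi_ge50: PredictorEffect = None  # type: ignore[assignment]
    age_split: float = AGE_SPLIT
    par: "object | None" = None  # PARSet; typed loosely to avoid an import cycle

    def __post_init__(self) -> None:
        expected = {"education", "height", "family_history", "parity", "menarche"}
        if set(self.effects) != expected:
            raise ValidationError(
                f"effects must cover exactly {sorted(expected)}, "
                f"got {sorted(self.effects)}"
            )
        if self.bmi_lt50 is None or self.bmi_ge50 is None:
            raise ValidationError("both BMI age segments must be present")

    # -- evaluation -----------------------------------------------------

    def bmi_effect(self, attained_age: float) -> PredictorEffect:
        return self.bmi_lt50 if attained_age < self.age_split else self.bmi_ge50

    def log_relative_risk(self, profile: RiskFactorProfile, attained_age: float) -> float:
        idx = profile.category_indices()
        total = 0.0
        for name in ("education", "height", "family_history", "parity", "menarche"):
            eff = self.effects[name]
            i = idx[name]
            if i >= len(eff.levels):
                raise ValidationError(f"{name}: level index {i} absent from model")
            total += float(eff.log_rr[i])
        total += float(self.bmi_effect(attained_age).log_rr[idx["bmi"]])
        return total

    def log_rr_pair(self, profile: RiskFactorProfile) -> tuple[float, float]:
        """(log RR below age split, log RR at/above age split)."""
        base = 0.0
        idx = profile.category_indices()
        for name in ("education", "height", "family_history", "parity", "menarche"):
            base += float(self.effects[name].log_rr[idx[name]])
        return (
            base + float(self.bmi_lt50.log_rr[idx["bmi"]]),
            base + float(self.bmi_ge50.log_rr[idx["bmi"]]),
        )

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        def eff_dict(e: PredictorEffect) -> dict:
            d = {
                "name": e.name,
                "encoding": e.encoding,
                "levels": list(e.levels),
                "log_rr": [float(v) for v in e.log_rr],
                "reference": e.reference,
            }
            if e.ci is not None:
                d["ci"] = e.ci
            return d

        out = {
            "predictors": [eff_dict(self.effects[n]) for n in
                           ("education", "height", "family_history", "parity",
                            "menarche")],
            "bmi_lt50": eff_dict(self.bmi_lt50),
            "bmi_ge50": eff_dict(self.bmi_ge50),
            "bmi_age_split": self.age_split,
        }
        if self.par is not None:
            out["par"] = self.par.to_dict()
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RelativeRiskModel":
        required = {"predictors", "bmi_lt50", "bmi_ge50", "bmi_age_split"}
        missing = required - set(data)
        if missing:
            raise ValidationError(f"model JSON missing keys: {sorted(missing)}")

        def eff(d: Mapping) -> PredictorEffect:
            for key in ("name", "encoding", "levels", "log_rr", "reference"):
                if key not in d:
                    raise ValidationError(f"predictor entry missing key {key!r}")
            return PredictorEffect(
                name=d["name"],
                levels=tuple(d["levels"]),
                log_rr=np.asarray(d["log_rr"], dtype=float),
                reference=int(d["reference"]),
                encoding=d["encoding"],
                ci=d.get("ci"),
            )

        effects = {e["name"]: eff(e) for e in data["predictors"]}
        par = None
        if data.get("par") is not None:
            from .attributable_risk import PARSet

            par = PARSet.from_dict(data["par"])
        return cls(
            effects=effects,
            bmi_lt50=eff(data["bmi_lt50"]),
            bmi_ge50=eff(data["bmi_ge50"]),
            age_split=float(data["bmi_age_split"]),
            par=par,
        )

    @classmethod
    def load(cls, path) -> "RelativeRiskModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def relative_risk(
    profile: RiskFactorProfile, attained_age: float, model: RelativeRiskModel
) -> float:
    """Evaluate ``RR(x)`` at an attained age.

    Multiplicative over predictors; piecewise constant in age with the single
    discontinuity at ``model.age_split`` coming from the BMI segment switch.
    An all-reference profile returns exactly 1.
    """
    if not 30.0 <= attained_age < 85.0:
        raise ValidationError(f"attained_age {attained_age} outside [30, 85)")
    return math.exp(model.log_relative_risk(profile, attained_age))


def _rr(levels, rrs, name, reference=0, ci=None, encoding="categorical"):
    return PredictorEffect(
        name=name,
        levels=tuple(levels),
        log_rr=np.log(np.asarray(rrs, dtype=float)),
        reference=reference,
        encoding=encoding,
        ci=ci,
    )


def default_model(with_par: bool = True) -> RelativeRiskModel:
    """The shipped relative-risk model (hazard-ratio point estimates).

    Estimated by age- and study-site-stratified Cox regression on a
    nationwide Chinese prospective cohort of ~300,000 women; confidence
    intervals are carried as metadata only.  The four attributable-risk
    fractions (age segment x residence) ship alongside when ``with_par``.
    """
    effects = {
        "education": _rr(
            EDUCATION_LEVELS,
            [1.00, 1.17, 1.37, 1.60, 1.87],
            "education",
            ci=[None, [1.11, 1.23], [1.24, 1.51], [1.39, 1.85], [1.54, 2.27]],
        ),
        "height": _rr(
            HEIGHT_LEVELS,
            [1.00, 1.13, 1.28, 1.45],
            "height",
            ci=[None, [1.09, 1.18], [1.18, 1.39], [1.28, 1.65]],
        ),
        "family_history": _rr(
            FAMILY_HISTORY_LEVELS,
            [1.00, 1.10, 1.57],
            "family_history",
            ci=[None, [0.99, 1.23], [1.27, 1.95]],
        ),
        "parity": _rr(
            PARITY_LEVELS,
            [1.78, 1.66, 1.41, 1.00],
            "parity",
            reference=3,
            ci=[[1.29, 2.45], [1.40, 1.96], [1.22, 1.62], None],
        ),
        "menarche": _rr(
            MENARCHE_LEVELS,
            [1.52, 1.32, 1.15, 1.00],
            "menarche",
            reference=3,
            ci=[[1.31, 1.76], [1.20, 1.46], [1.09, 1.21], None],
        ),
    }
    bmi_lt50 = _rr(
        BMI_LEVELS,
        [1.00, 0.95, 0.90, 0.85],
        "bmi_lt50",
        ci=[None, [0.84, 1.07], [0.71, 1.14], [0.60, 1.21]],
    )
    bmi_ge50 = _rr(
        BMI_LEVELS,
        [1.00, 1.25, 1.57, 1.96],
        "bmi_ge50",
        ci=[None, [1.17, 1.33], [1.38, 1.78], [1.62, 2.38]],
    )
    par = None
    if with_par:
        from .attributable_risk import PARSet

        par = PARSet(
            urban_lt50=0.74, urban_ge50=0.76, rural_lt50=0.63, rural_ge50=0.65
        )
    return RelativeRiskModel(
        effects=effects, bmi_lt50=bmi_lt50, bmi_ge50=bmi_ge50, par=par
    )
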