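"""Competing-risk absolute risk by exact piecewise integration.

The absolute risk that a woman aged ``a`` with risk factors ``x`` develops
breast cancer by age ``a + tau`` is

    P(a, tau, x) = int_a^{a+tau} h1(t,x) exp[-int_a^t (h1(u,x) + h2(u)) du] dt

with ``h1(t,x) = h10(t) RR(x; t)`` and ``h2`` the competing mortality
hazard.  Both hazards are piecewise constant (rate bands plus the age-50
BMI/PAR switch), so on each piece of length ``d`` with constants ``h1, h2``
the integral has the closed form

    S * h1/(h1+h2) * (1 - exp(-(h1+h2) d)),

``S`` being the all-cause survival carried in from earlier pieces.  Pieces
are always split at the age-50 switch, so no piece straddles it; the segment
of a piece is decided by its start age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attributable_risk import PARSet
from .hazard_engine import RateTable
from .risk_model import RelativeRiskModel, RiskFactorProfile, ValidationError


@dataclass(frozen=True)
class ProjectionQuery:
    """Starting age, horizon in years, and the woman's risk-factor profile."""

    a: float
    tau: float
    profile: RiskFactorProfile

    def __post_init__(self) -> None:
        if self.a < 30.0:
            raise ValidationError(f"starting age {self.a} below 30")
        if self.tau <= 0:
            raise ValidationError(f"horizon tau={self.tau} must be positive")


@dataclass(frozen=True)
class ProjectionResult:
    probability: float
    breakpoints: tuple[float, ...]


def _piece_grid(table: RateTable, residence: str, a: float, end: float,
                age_split: float) -> np.ndarray:
    pts = table.breakpoints(residence, age_split)
    inner = pts[(pts > a) & (pts < end)]
    return np.concatenate([[a], inner, [end]])


def project(
    query: ProjectionQuery,
    model: RelativeRiskModel,
    table: RateTable,
    pars: PARSet | None = None,
) -> ProjectionResult:
    """Evaluate ``P(a, tau, x)`` exactly.

    ``pars`` defaults to the PAR set shipped inside the model.  The horizon
    may be fractional; pieces are clipped to ``[a, a + tau)`` exactly.
    """
    pars = pars if pars is not None else model.par
    if pars is None:
        raise ValidationError("no PAR set supplied and model carries none")
    a, end = query.a, query.a + query.tau
    if a < table.age_min or end > table.age_max:
        raise ValidationError(
            f"projection window [{a}, {end}) outside rate coverage "
            f"[{table.age_min}, {table.age_max})"
        )
    residence = query.profile.residence
    rr_lt, rr_ge = np.exp(model.log_rr_pair(query.profile))
    grid = _piece_grid(table, residence, a, end, model.age_split)

    survival = 1.0
    prob = 0.0
    for t0, t1 in zip(grid[:-1], grid[1:]):
        rr = rr_lt if t0 < model.age_split else rr_ge
        h1 = table.baseline_hazard(pars, residence, t0, model.age_split) * rr
        h2 = table.competing_hazard(residence, t0)
        lam = h1 + h2
        d = t1 - t0
        if lam > 0.0:
            decay = np.exp(-lam * d)
            prob += survival * (h1 / lam) * (1.0 - decay)
            survival *= decay
        # lam == 0: the piece contributes nothing and survival is unchanged
    return ProjectionResult(probability=float(prob), breakpoints=tuple(grid))


def project_batch(
    a: np.ndarray,
    tau: np.ndarray,
    rr_lt50: np.ndarray,
    rr_ge50: np.ndarray,
    residence: np.ndarray,
    model: RelativeRiskModel,
    table: RateTable,
    pars: PARSet | None = None,
) -> np.ndarray:
    """Vectorized projection for many women sharing the rate-band structure.

    ``rr_lt50``/``rr_ge50`` are each woman's relative risks in the two age
    segments; ``residence`` is an array of 'urban'/'rural' labels.  Used by
    expected-case calibration, where one projection per cohort member is
    required.  Agrees with :func:`project` to floating-point rounding.
    """
    pars = pars if pars is not None else model.par
    if pars is None:
        raise ValidationError("no PAR set supplied and model carries none")
    a = np.asarray(a, dtype=float)
    tau = np.asarray(tau, dtype=float)
    end = a + tau
    if np.any(tau <= 0):
        raise ValidationError("all horizons must be positive")
    if np.any(a < table.age_min) or np.any(end > table.age_max):
        raise ValidationError("some projection window outside rate coverage")

    out = np.empty(a.shape, dtype=float)
    residence = np.asarray(residence)
    for res in ("urban", "rural"):
        sel = residence == res
        if not np.any(sel):
            continue
        pts = table.breakpoints(res, model.age_split)
        starts, stops = pts[:-1], pts[1:]  # global pieces
        h10 = table.baseline_hazard(pars, res, starts, model.age_split)
        h2 = table.competing_hazard(res, starts)
        seg_ge = starts >= model.age_split

        ai, ei = a[sel][:, None], end[sel][:, None]
        dur = np.clip(np.minimum(ei, stops[None, :]) -
                      np.maximum(ai, starts[None, :]), 0.0, None)
        rr = np.where(seg_ge[None, :], rr_ge50[sel][:, None],
                      rr_lt50[sel][:, None])
        h1 = h10[None, :] * rr
        lam = h1 + h2[None, :]
        cum = np.cumsum(lam * dur, axis=1)
        surv_in = np.exp(-(cum - lam * dur))  # survival entering each piece
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lam > 0, h1 / np.where(lam > 0, lam, 1.0), 0.0)
        contrib = surv_in * frac * (1.0 - np.exp(-lam * dur))
        out[sel] = contrib.sum(axis=1)
    return out


def ten_year_risk(
    profile: RiskFactorProfile,
    a: float,
    model: RelativeRiskModel,
    table: RateTable,
    pars: PARSet | None = None,
) -> float:
    """``P(a, 10, x)`` — the 10-year absolute risk used for screening indices."""
    return project(ProjectionQuery(a=a, tau=10.0, profile=profile),
                   model, table, pars).probability
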