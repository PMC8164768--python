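"""Calibration and discrimination machinery for the absolute-risk model.

Calibration compares expected case counts ``E`` (sums of projected
probabilities over each woman's observed follow-up) with observed counts
``O``; the E/O ratio takes an exact Poisson confidence interval (chi-square
quantiles for the observed count — this reproduces published subgroup
intervals where a normal approximation differs in the second decimal).
Discrimination is the 10-year c-statistic (Mann-Whitney probability with
ties counted 1/2), optionally pooled within age x residence strata to
remove the separation contributed by age and residence themselves, plus
risk-quintile hazard ratios and risk-stratified screening indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .absolute_risk import project_batch
from .attributable_risk import PARSet
from .cox_fitting import PredictorSpec, fit_stratified_cox
from .hazard_engine import RateTable
from .risk_model import RelativeRiskModel, ValidationError


@dataclass(frozen=True)
class CalibrationCell:
    """Expected vs observed cases in one subgroup, with exact Poisson CI."""

    label: str
    expected: float
    observed: int
    ratio: float
    ci_low: float
    ci_high: float

    def rounded(self) -> tuple[float, float, float]:
        """(ratio, ci_low, ci_high) at the 2-decimal report convention."""
        return (round(self.ratio, 2), round(self.ci_low, 2),
                round(self.ci_high, 2))


@dataclass(frozen=True)
class ScreeningIndexRow:
    cutoff: float
    pct_high_risk: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    nns: float


# ---------------------------------------------------------------------------
# expected cases
# ---------------------------------------------------------------------------


def predicted_cumulative_risk(
    records: pd.DataFrame,
    model: RelativeRiskModel,
    table: RateTable,
    pars: PARSet | None = None,
    horizon: float | None = None,
    horizon_rule: str = "observed",
) -> np.ndarray:
    """Projected breast-cancer probability per woman.

    With ``horizon=None`` the per-woman window is set by ``horizon_rule``:
    ``"observed"`` projects from enrollment to exit age, while
    ``"potential"`` projects to the administrative censoring age
    (``censor_age`` column) regardless of the event — the unbiased
    convention for expected-case calibration, since the competing-risk
    integral already accounts probabilistically for death and diagnosis
    (truncating at an observed event makes the projection itself depend on
    the outcome).  A fixed ``horizon`` (e.g. 10 years, clipped to rate
    coverage) gives the fixed-horizon risk used for discrimination.
    """
    entry = records["entry_age"].to_numpy(dtype=float)
    if horizon is None:
        if horizon_rule == "observed":
            tau = records["exit_age"].to_numpy(dtype=float) - entry
        elif horizon_rule == "potential":
            if "censor_age" not in records.columns:
                raise ValidationError(
                    "horizon_rule 'potential' needs a censor_age column"
                )
            tau = records["censor_age"].to_numpy(dtype=float) - entry
        else:
            raise ValidationError(
                f"unknown horizon_rule {horizon_rule!r}"
            )
    else:
        tau = np.minimum(entry + horizon, table.age_max) - entry
    log_lt = np.zeros(len(records))
    for name, col in (("education", "education"), ("height", "height_cat"),
                      ("family_history", "famhist_cat"),
                      ("parity", "parity_cat"), ("menarche", "menarche_cat")):
        log_lt += model.effects[name].log_rr[records[col].to_numpy()]
    bmi = records["bmi_cat"].to_numpy()
    log_ge = log_lt + model.bmi_ge50.log_rr[bmi]
    log_lt = log_lt + model.bmi_lt50.log_rr[bmi]
    return project_batch(
        entry, tau, np.exp(log_lt), np.exp(log_ge),
        records["residence"].to_numpy(), model, table, pars,
    )


def expected_cases(
    records: pd.DataFrame,
    model: RelativeRiskModel,
    table: RateTable,
    pars: PARSet | None = None,
    by: str | None = None,
    horizon_rule: str = "observed",
):
    """Total expected cases ``E = sum_i P(a_i, tau_i, x_i)``.

    ``horizon_rule`` sets each woman's projection window (see
    :func:`predicted_cumulative_risk`).  With ``by`` (a column of
    ``records``), also returns per-subgroup ``(E, O)`` pairs; subgroup
    expectations sum to the total exactly.
    """
    if len(records) == 0:
        return (0.0, {}) if by else 0.0
    p = predicted_cumulative_risk(records, model, table, pars,
                                  horizon_rule=horizon_rule)
    total = float(p.sum())
    if by is None:
        return total
    observed = (records["event"] == "bc").to_numpy()
    sub = {}
    for label, idx in records.groupby(by, sort=True).indices.items():
        sub[label] = (float(p[idx].sum()), int(observed[idx].sum()))
    return total, sub


def eo_ratio_ci(E: float, O: int, level: float = 0.95,
                label: str = "overall") -> CalibrationCell:
    """E/O with the exact (chi-square quantile) Poisson interval for ``O``."""
    if O < 1:
        raise ValidationError("E/O ratio undefined for zero observed cases")
    if E <= 0:
        raise ValidationError("expected count must be positive")
    alpha = 1.0 - level
    o_low = chi2.ppf(alpha / 2.0, 2 * O) / 2.0
    o_high = chi2.ppf(1.0 - alpha / 2.0, 2 * (O + 1)) / 2.0
    return CalibrationCell(
        label=label, expected=float(E), observed=int(O),
        ratio=float(E) / O, ci_low=float(E) / o_high, ci_high=float(E) / o_low,
    )


def calibration_deciles(predicted, outcomes, n_bins: int = 10):
    """Expected/observed agreement across sample deciles of predicted risk.

    Bins are by rank of the prediction (stable order breaks ties), sizes
    differing by at most one.
    """
    predicted = np.asarray(predicted, dtype=float)
    outcomes = np.asarray(outcomes)
    if predicted.size < n_bins:
        raise ValidationError(f"need at least {n_bins} observations")
    if np.any((predicted < 0) | (predicted > 1)):
        raise ValidationError("predictions must lie in [0, 1]")
    if np.all(predicted == predicted[0]):
        raise ValidationError(
            "constant predictions cannot be binned; use fewer bins"
        )
    order = np.argsort(predicted, kind="stable")
    cells = []
    for i, idx in enumerate(np.array_split(order, n_bins)):
        E = float(predicted[idx].sum())
        O = int(np.sum(outcomes[idx]))
        if O >= 1 and E > 0:
            cells.append(eo_ratio_ci(E, O, label=f"decile {i + 1}"))
        else:
            cells.append(CalibrationCell(
                label=f"decile {i + 1}", expected=E, observed=O,
                ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
            ))
    return cells


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------


def ten_year_case_status(records: pd.DataFrame, horizon: float = 10.0,
                         deaths_as_controls: bool = False):
    """(eligible mask, case indicator) for fixed-horizon discrimination.

    Cases developed breast cancer within ``horizon`` years of enrollment;
    controls remained event-free with at least ``horizon`` years of
    follow-up.  Women censored — or, unless ``deaths_as_controls``, dead of
    other causes — before the horizon are excluded.
    """
    fu = records["exit_age"].to_numpy() - records["entry_age"].to_numpy()
    event = records["event"].to_numpy()
    case = (event == "bc") & (fu <= horizon)
    control = fu >= horizon
    if deaths_as_controls:
        control |= (event == "death")
    control &= ~case
    return case | control, case


def auc_10yr(predicted, status, level: float = 0.95):
    """c-statistic: P(random case outranks random control), ties count 1/2.

    The confidence interval uses the Hanley-McNeil asymptotic variance.
    """
    predicted = np.asarray(predicted, dtype=float)
    status = np.asarray(status, dtype=bool)
    n1 = int(status.sum())
    n0 = int((~status).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("need at least one case and one control")
    ranks = rankdata(predicted)
    auc = (ranks[status].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc)
           + (n0 - 1) * (q2 - auc * auc)) / (n1 * n0)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(auc - half), float(auc + half))


def adjusted_auc(predicted, status, strata):
    """AUC pooled within strata, weighted by each stratum's case-control
    pair count — the between-stratum (age, residence) separation contributes
    nothing.  Strata without both a case and a control are uninformative.
    """
    predicted = np.asarray(predicted, dtype=float)
    status = np.asarray(status, dtype=bool)
    strata = np.asarray(strata)
    num = 0.0
    wsum = 0.0
    for s in np.unique(strata):
        sel = strata == s
        n1 = int(status[sel].sum())
        n0 = int((~status[sel]).sum())
        if n1 == 0 or n0 == 0:
            continue
        a, _ = auc_10yr(predicted[sel], status[sel])
        w = n1 * n0
        num += w * a
        wsum += w
    if wsum == 0:
        raise ValidationError("no stratum contains both a case and a control")
    return num / wsum


def quintile_rr(
    records: pd.DataFrame,
    predicted,
    n_quantiles: int = 5,
    ties: str = "efron",
    band_width: float = 5.0,
) -> pd.DataFrame:
    """Hazard ratios by quantile of predicted risk, lowest as reference.

    ``predicted`` should be a fixed-horizon (e.g. 10-year) risk: a risk
    projected over *observed* follow-up is artificially small for cases,
    whose follow-up stops at diagnosis, and would invert the gradient.
    Quantile boundaries come from the validation sample's own predicted-risk
    distribution (boundary ties go to the lower quantile); the indicators
    enter a Cox model stratified by residence and 5-year enrollment-age
    band, so the quantile effect is age- and residence-adjusted.
    """
    predicted = np.asarray(predicted, dtype=float)
    edges = np.quantile(predicted, np.linspace(0, 1, n_quantiles + 1)[1:-1])
    code = np.searchsorted(edges, predicted, side="left")
    work = records.copy()
    work["risk_q"] = code
    band = (np.floor(work["entry_age"] / band_width) * band_width).astype(int)
    work["stratum"] = work["residence"].astype(str) + "|" + band.astype(str)
    events = (work["event"] == "bc").to_numpy()
    cases_by_q = np.bincount(code[events], minlength=n_quantiles)
    if cases_by_q[0] == 0:
        raise ValidationError("no events in the reference (lowest) quantile")
    fit = fit_stratified_cox(
        work,
        [PredictorSpec(name="risk_q", column="risk_q", kind="categorical",
                       n_levels=n_quantiles, reference=0)],
        ties=ties,
    )
    rows = [{"quantile": 1, "cases": int(cases_by_q[0]), "rr": 1.0,
             "ci_low": np.nan, "ci_high": np.nan}]
    for q in range(1, n_quantiles):
        j = fit.groups["risk_q"][q - 1]
        b, s = fit.beta[j], fit.se[j]
        rows.append({
            "quantile": q + 1,
            "cases": int(cases_by_q[q]),
            "rr": float(np.exp(b)),
            "ci_low": float(np.exp(b - 1.959963984540054 * s)),
            "ci_high": float(np.exp(b + 1.959963984540054 * s)),
        })
    return pd.DataFrame(rows)


def screening_indices(predicted, status, cutoffs) -> pd.DataFrame:
    """Risk-stratified screening performance at each 10-year-risk cutoff.

    High risk means predicted risk at or above the cutoff; NNS (screens per
    detected case) is the reciprocal of the PPV.  A cutoff classifying
    nobody as high risk yields an undefined PPV/NNS (NaN) but still emits
    its row.
    """
    predicted = np.asarray(predicted, dtype=float)
    status = np.asarray(status, dtype=bool)
    rows = []
    for cutoff in cutoffs:
        if not 0.0 < cutoff < 1.0:
            raise ValidationError(f"cutoff {cutoff} outside (0, 1)")
        high = predicted >= cutoff
        tp = int(np.sum(high & status))
        fp = int(np.sum(high & ~status))
        fn = int(np.sum(~high & status))
        tn = int(np.sum(~high & ~status))
        ppv = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        rows.append(ScreeningIndexRow(
            cutoff=float(cutoff),
            pct_high_risk=float(np.mean(high)),
            sensitivity=tp / (tp + fn) if (tp + fn) else np.nan,
            specificity=tn / (tn + fp) if (tn + fp) else np.nan,
            ppv=ppv,
            npv=tn / (tn + fn) if (tn + fn) else np.nan,
            nns=1.0 / ppv if ppv and ppv > 0 else np.nan,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
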