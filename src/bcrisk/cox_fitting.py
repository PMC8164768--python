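"""Stratified Cox regression on the age timescale, and model-building steps.

The relative-risk model is fitted by maximizing the stratified partial
likelihood with *age* as the timescale: a subject enrolled at ``entry_age``
enters the risk set only from that age on (left truncation / delayed entry),
and risk sets are formed within strata defined jointly by study site and
5-year enrollment-age band.  Ties are handled by Efron's correction by
default (age data are heavily tied when recorded coarsely); Breslow is
available via ``ties="breslow"``.

The model-building operations mirror standard epidemiological practice:
episode splitting at age 50 so BMI can carry a different hazard ratio in
each age segment, BIC-guided cutoff selection for continuous covariates,
backward elimination on group Wald tests, likelihood-ratio tests for
interactions, and a Schoenfeld-residual check of proportional hazards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .risk_model import ValidationError

logger = logging.getLogger(__name__)

EVENT_CODES = ("bc", "death", "censored")


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge (or the likelihood is degenerate)."""


@dataclass(frozen=True)
class CohortRecord:
    """One follow-up episode: ages, outcome, covariate codes, stratum labels."""

    entry_age: float
    exit_age: float
    event: str
    study_site: str
    residence: str
    covariates: dict

    def __post_init__(self) -> None:
        if not self.entry_age < self.exit_age:
            raise ValidationError(
                f"entry_age {self.entry_age} must be < exit_age {self.exit_age}"
            )
        if self.event not in EVENT_CODES:
            raise ValidationError(f"event must be one of {EVENT_CODES}")


def add_stratum(df: pd.DataFrame, band_width: float = 5.0) -> pd.DataFrame:
    """Attach the joint (study site, 5-year enrollment-age band) stratum label.

    Must be called on enrollment records *before* episode splitting so the
    band reflects age at enrollment, not episode start.
    """
    out = df.copy()
    band = (np.floor(out["entry_age"] / band_width) * band_width).astype(int)
    out["stratum"] = out["study_site"].astype(str) + "|" + band.astype(str)
    return out


def split_followup_at_age(df: pd.DataFrame, split_age: float = 50.0) -> pd.DataFrame:
    """Split episodes spanning ``split_age`` into two contiguous episodes.

    The below-split episode is censored at the split and carries no event;
    the at-or-above episode carries the original event.  Total person-time
    is conserved exactly.  A ``segment`` column (0 below, 1 at/above the
    split, by episode start) is attached.
    """
    spans = (df["entry_age"] < split_age) & (df["exit_age"] > split_age)
    below = df[spans].copy()
    below["exit_age"] = split_age
    below["event"] = "censored"
    above = df[spans].copy()
    above["entry_age"] = split_age
    out = pd.concat([df[~spans], below, above], ignore_index=True)
    out["segment"] = (out["entry_age"] >= split_age).astype(int)
    return out


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictorSpec:
    """How one predictor enters the design matrix.

    kind 'categorical' emits one indicator per non-reference level, 'ordinal'
    a single per-step column (level index minus reference), 'binary' the raw
    0/1 column.  ``age_segmented`` (the BMI case) doubles the categorical
    block, one set per age segment, and requires a ``segment`` column from
    :func:`split_followup_at_age`.
    """

    name: str
    column: str
    kind: str = "categorical"
    n_levels: int = 2
    reference: int = 0
    age_segmented: bool = False


def build_design(
    df: pd.DataFrame, specs: list[PredictorSpec]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Design matrix, column names, and predictor -> column-index groups."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    for spec in specs:
        start = len(names)
        if spec.kind == "binary":
            cols.append(df[spec.column].to_numpy(dtype=float))
            names.append(spec.name)
        elif spec.kind == "ordinal":
            code = df[spec.column].to_numpy(dtype=float)
            if spec.age_segmented:
                seg = df["segment"].to_numpy()
                for s in (0, 1):
                    cols.append((code - spec.reference) * (seg == s))
                    names.append(f"{spec.name}[step]@seg{s}")
            else:
                cols.append(code - spec.reference)
                names.append(f"{spec.name}[step]")
        elif spec.kind == "categorical":
            code = df[spec.column].to_numpy()
            segments = (None,) if not spec.age_segmented else (0, 1)
            for seg in segments:
                mask = (
                    np.ones(len(df), dtype=bool)
                    if seg is None
                    else (df["segment"].to_numpy() == seg)
                )
                for level in range(spec.n_levels):
                    if level == spec.reference:
                        continue
                    cols.append(((code == level) & mask).astype(float))
                    tag = f"{spec.name}[{level}]" if seg is None else \
                        f"{spec.name}[{level}]@seg{seg}"
                    names.append(tag)
        else:
            raise ValidationError(f"unknown predictor kind {spec.kind!r}")
        groups[spec.name] = list(range(start, len(names)))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, groups


# ---------------------------------------------------------------------------
# stratified partial likelihood
# ---------------------------------------------------------------------------


@dataclass
class _StratumData:
    """Static per-stratum structure reused across Newton iterations."""

    X: np.ndarray              # (n_s, p)
    utimes: np.ndarray         # ascending unique event times, (k,)
    dcount: np.ndarray         # ties per unique time, (k,)
    tied_rows: list            # row indices of events at each unique time
    sum_x_events: np.ndarray   # sum of X over all event rows, (p,)
    order_exit: np.ndarray     # rows sorted by exit ascending
    order_entry: np.ndarray    # rows sorted by entry ascending
    bound_exit: np.ndarray     # (k+1,) boundaries into order_exit
    bound_entry: np.ndarray    # (k+1,) boundaries into order_entry


def _prepare_stratum(entry, exit_, dflag, X) -> _StratumData | None:
    ev = np.flatnonzero(dflag)
    if ev.size == 0:
        return None
    times = exit_[ev]
    utimes, inverse, dcount = np.unique(times, return_inverse=True,
                                        return_counts=True)
    tied_rows = [ev[inverse == g] for g in range(utimes.size)]
    order_exit = np.argsort(exit_, kind="stable")
    order_entry = np.argsort(entry, kind="stable")
    n = exit_.size
    be = np.concatenate([np.searchsorted(exit_[order_exit], utimes, "left"), [n]])
    ba = np.concatenate([np.searchsorted(entry[order_entry], utimes, "left"), [n]])
    return _StratumData(
        X=X, utimes=utimes, dcount=dcount, tied_rows=tied_rows,
        sum_x_events=X[ev].sum(axis=0),
        order_exit=order_exit, order_entry=order_entry,
        bound_exit=be, bound_entry=ba,
    )


def _segment_sums(values_sorted: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Suffix sums of ``values_sorted`` evaluated at each boundary.

    Returns an array ``suf`` with ``suf[g] = values_sorted[bounds[g]:].sum(0)``.
    """
    csum = np.concatenate(
        [np.zeros((1,) + values_sorted.shape[1:]), np.cumsum(values_sorted, 0)]
    )
    total = csum[-1]
    return total - csum[bounds[:-1]]


def _suffix_outer(X: np.ndarray, w: np.ndarray, order: np.ndarray,
                  bounds: np.ndarray) -> np.ndarray:
    """Suffix sums of ``w_j x_j x_j^T`` at each boundary via segment GEMMs."""
    k = bounds.size - 1
    p = X.shape[1]
    seg = np.zeros((k, p, p))
    for g in range(k):
        lo, hi = bounds[g], bounds[g + 1]
        if hi > lo:
            rows = order[lo:hi]
            Xi = X[rows]
            seg[g] = (Xi * w[rows][:, None]).T @ Xi
    return np.cumsum(seg[::-1], axis=0)[::-1]


def _stratum_contrib(sd: _StratumData, beta: np.ndarray, ties: str,
                     want_derivs: bool):
    """(loglik, grad, info) contribution of one stratum at ``beta``."""
    X = sd.X
    eta = X @ beta
    r = np.exp(eta)
    k = sd.utimes.size

    w_exit = r[sd.order_exit]
    w_entry = r[sd.order_entry]
    S0 = _segment_sums(w_exit[:, None], sd.bound_exit)[:, 0] - \
        _segment_sums(w_entry[:, None], sd.bound_entry)[:, 0]
    if want_derivs:
        rx = r[:, None] * X
        S1 = _segment_sums(rx[sd.order_exit], sd.bound_exit) - \
            _segment_sums(rx[sd.order_entry], sd.bound_entry)
        S2 = _suffix_outer(X, r, sd.order_exit, sd.bound_exit) - \
            _suffix_outer(X, r, sd.order_entry, sd.bound_entry)

    ll = float(eta[np.concatenate(sd.tied_rows)].sum())
    grad = sd.sum_x_events.copy() if want_derivs else None
    info = np.zeros((X.shape[1],) * 2) if want_derivs else None

    for g in range(k):
        d = int(sd.dcount[g])
        # d == 1 makes Efron and Breslow coincide
        if ties == "efron" and d > 1:
            rows = sd.tied_rows[g]
            s0t = float(r[rows].sum())
            ell = np.arange(d) / d
            s0l = S0[g] - ell * s0t
        else:
            s0l = np.full(d, S0[g])
        if np.any(s0l <= 0):
            raise ConvergenceError("non-positive risk-set weight (degenerate)")
        ll -= float(np.log(s0l).sum())
        if not want_derivs:
            continue
        if ties == "efron" and d > 1:
            rows = sd.tied_rows[g]
            s1t = (r[rows][:, None] * X[rows]).sum(axis=0)
            Xt = X[rows]
            s2t = (Xt * r[rows][:, None]).T @ Xt
            S1l = S1[g][None, :] - ell[:, None] * s1t[None, :]
            mean_l = S1l / s0l[:, None]
            grad -= mean_l.sum(axis=0)
            S2l = S2[g][None, :, :] - ell[:, None, None] * s2t[None, :, :]
            info += (S2l / s0l[:, None, None]).sum(axis=0)
            info -= np.einsum("li,lj->ij", mean_l, mean_l)
        else:
            mean = S1[g] / S0[g]
            grad -= d * mean
            info += d * (S2[g] / S0[g] - np.outer(mean, mean))
    return ll, grad, info


@dataclass
class FitResult:
    """Maximum partial-likelihood estimates with Wald inference."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n_events: int
    n_records: int
    n_strata: int
    iterations: int
    ties: str
    groups: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def wald_z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.wald_z))

    def group_wald(self, name: str) -> tuple[float, int, float]:
        """Joint Wald chi-square for all columns of one predictor."""
        idx = self.groups[name]
        b = self.beta[idx]
        V = self.cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        return stat, df, float(chi2.sf(stat, df))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "hr": np.exp(self.beta),
                "se": self.se,
                "z": self.wald_z,
                "p": self.wald_p,
            },
            index=self.names,
        )


def _prepare_strata(df: pd.DataFrame, X: np.ndarray, stratum_col: str):
    entry = df["entry_age"].to_numpy(dtype=float)
    exit_ = df["exit_age"].to_numpy(dtype=float)
    dflag = (df["event"].to_numpy() == "bc")
    if np.any(entry >= exit_):
        raise ValidationError("entry_age must be strictly below exit_age")
    strata = []
    for _, idx in df.groupby(stratum_col, sort=False).indices.items():
        sd = _prepare_stratum(entry[idx], exit_[idx], dflag[idx], X[idx])
        if sd is not None:
            strata.append(sd)
    return strata, int(dflag.sum())


def fit_stratified_cox(
    df: pd.DataFrame,
    specs: list[PredictorSpec],
    ties: str = "efron",
    stratum_col: str = "stratum",
    tol: float = 1e-8,
    max_iter: int = 100,
    init: np.ndarray | None = None,
) -> FitResult:
    """Fit the stratified Cox model on the age timescale.

    Risk sets are left-truncated at ``entry_age``; strata without events are
    uninformative and dropped.  Convergence is Newton-Raphson with step
    halving, declared at gradient max-norm below ``tol``.  Deterministic
    given the input (and invariant to record order and stratum relabeling).
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    X, names, groups = build_design(df, specs)
    p = X.shape[1]
    if p == 0:
        raise ValidationError("empty design")
    if np.any(X.std(axis=0) == 0):
        flat = [names[j] for j in np.flatnonzero(X.std(axis=0) == 0)]
        raise ValidationError(f"design columns constant overall: {flat}")
    strata, n_events = _prepare_strata(df, X, stratum_col)
    if n_events == 0:
        raise ValidationError("no breast-cancer events in any stratum")

    def evaluate(beta, want_derivs=True):
        ll = 0.0
        grad = np.zeros(p) if want_derivs else None
        info = np.zeros((p, p)) if want_derivs else None
        for sd in strata:
            out = _stratum_contrib(sd, beta, ties, want_derivs)
            ll += out[0]
            if want_derivs:
                grad += out[1]
                info += out[2]
        return ll, grad, info

    loglik_null = evaluate(np.zeros(p), want_derivs=False)[0]
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    ll, grad, info = evaluate(beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(
                f"singular information matrix (separation?): {err}"
            ) from err
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            try:
                ll_new, grad_new, info_new = evaluate(cand)
            except (FloatingPointError, OverflowError):
                ll_new = -np.inf
            # relative slack: near the optimum the true change is below the
            # roundoff of a partial likelihood summed over thousands of events
            if np.isfinite(ll_new) and ll_new >= ll - 1e-9 * (abs(ll) + 1.0):
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"step halving failed at iteration {n_iter}; "
                f"gradient max-norm {np.max(np.abs(grad)):.3e}"
            )
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "coefficients diverging (complete separation?)"
            )
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; "
            f"gradient max-norm {np.max(np.abs(grad)):.3e}"
        )
    if np.max(np.abs(beta)) > 15:
        # monotone likelihood: the gradient vanishes while the estimate
        # runs to infinity (complete separation of an event pattern)
        raise ConvergenceError(
            "estimate diverged (|log HR| > 15): monotone partial "
            "likelihood, typically complete separation"
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    logger.info(
        "Cox fit: %d params, %d events, %d strata, %d iterations, loglik %.4f",
        p, n_events, len(strata), n_iter, ll,
    )
    return FitResult(
        names=names, beta=beta, se=se, cov=cov, loglik=ll,
        loglik_null=loglik_null, n_events=n_events, n_records=len(df),
        n_strata=len(strata), iterations=n_iter, ties=ties, groups=groups,
    )


def likelihood_ratio_test(fit_full: FitResult, fit_reduced: FitResult):
    """2*(ll_full - ll_reduced) against chi-square with the df difference."""
    df = fit_full.n_params - fit_reduced.n_params
    if df <= 0:
        raise ValidationError(
            f"models not nested: df difference {df} must be positive"
        )
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    return stat, df, float(chi2.sf(stat, df))


def select_cutoffs_bic(
    df: pd.DataFrame,
    variable: str,
    candidate_cutsets: list[tuple[float, ...]],
    base_specs: list[PredictorSpec] | None = None,
    ties: str = "efron",
):
    """Choose category cutoffs for a raw continuous variable by smallest BIC.

    ``BIC = -2 loglik + k ln(d)`` with ``k`` the number of parameters the
    categorized variable adds and ``d`` the number of events (the effective
    sample size of a partial likelihood).  Ties break toward fewer
    parameters, then lexicographically smaller cutsets.
    """
    if len(candidate_cutsets) == 0:
        raise ValidationError("no candidate cutsets supplied")
    base_specs = list(base_specs or [])
    raw = df[variable].to_numpy(dtype=float)
    results: dict[tuple[float, ...], float] = {}
    for cutset in candidate_cutsets:
        cuts = tuple(sorted(cutset))
        code = np.zeros(len(df), dtype=int)
        for c in cuts:
            code += (raw >= c).astype(int)
        counts = np.bincount(code, minlength=len(cuts) + 1)
        if np.any(counts == 0) or len(cuts) < 1:
            logger.warning("cutset %s yields an empty category; skipped", cuts)
            continue
        work = df.copy()
        work[f"_{variable}_cat"] = code
        spec = PredictorSpec(
            name=variable, column=f"_{variable}_cat",
            kind="categorical", n_levels=len(cuts) + 1,
        )
        fit = fit_stratified_cox(work, base_specs + [spec], ties=ties)
        k = len(fit.groups[variable])
        results[cuts] = -2.0 * fit.loglik + k * np.log(fit.n_events)
    if not results:
        raise ValidationError("every candidate cutset produced an empty category")
    best = min(results, key=lambda c: (results[c], len(c), c))
    return best, results


def backward_eliminate(
    df: pd.DataFrame,
    specs: list[PredictorSpec],
    alpha: float = 0.05,
    ties: str = "efron",
    method: str = "wald",
):
    """Stepwise backward elimination on predictor-level tests.

    Repeatedly drops the predictor with the largest p-value above ``alpha``
    (group Wald chi-square by default; ``method="lrt"`` refits without each
    candidate) until every remaining predictor is significant.  Returns the
    retained specs, the elimination trace ``[(name, p), ...]``, and the
    final fit.
    """
    if method not in ("wald", "lrt"):
        raise ValidationError("method must be 'wald' or 'lrt'")
    current = list(specs)
    trace: list[tuple[str, float]] = []
    if not current:
        return current, trace, None
    fit = fit_stratified_cox(df, current, ties=ties)
    while len(current) > 1:
        if method == "wald":
            pvals = {s.name: fit.group_wald(s.name)[2] for s in current}
        else:
            pvals = {}
            for s in current:
                reduced = [t for t in current if t.name != s.name]
                fit_red = fit_stratified_cox(df, reduced, ties=ties)
                pvals[s.name] = likelihood_ratio_test(fit, fit_red)[2]
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            break
        trace.append((worst, pvals[worst]))
        logger.info("backward elimination: dropping %s (p=%.4f)",
                    worst, pvals[worst])
        current = [s for s in current if s.name != worst]
        keep = np.concatenate(
            [fit.groups[s.name] for s in current]
        ).astype(int)
        warm = fit.beta[keep]
        fit = fit_stratified_cox(df, current, ties=ties, init=warm)
    return current, trace, fit


def encoding_lrt(
    df: pd.DataFrame,
    specs: list[PredictorSpec],
    predictor: str,
    ties: str = "efron",
):
    """Likelihood-ratio test of ordinal vs categorical encoding.

    Answers the nonlinearity question — are a predictor's per-level log
    hazard ratios proportional to its level index? — by nesting the
    single-slope (ordinal) design inside the fully categorical one.  A
    small p-value says the per-level effects are not linear in level and
    the categorical encoding should be kept.  Returns (statistic, df, p).
    """
    import dataclasses as _dc

    full_specs = [
        _dc.replace(s, kind="categorical") if s.name == predictor else s
        for s in specs
    ]
    reduced_specs = [
        _dc.replace(s, kind="ordinal") if s.name == predictor else s
        for s in specs
    ]
    fit_full = fit_stratified_cox(df, full_specs, ties=ties)
    fit_reduced = fit_stratified_cox(df, reduced_specs, ties=ties)
    return likelihood_ratio_test(fit_full, fit_reduced)


def schoenfeld_ph_test(
    fit: FitResult,
    df: pd.DataFrame,
    specs: list[PredictorSpec],
    stratum_col: str = "stratum",
) -> pd.DataFrame:
    """Proportional-hazards check on scaled Schoenfeld residuals.

    For each covariate, tests the correlation of the scaled residuals with
    event age (identity time transform) using the standard one-degree
    chi-square score statistic; a small p-value flags a time-varying effect.
    Requires at least 3 events.
    """
    X, names, _ = build_design(df, specs)
    strata, n_events = _prepare_strata(df, X, stratum_col)
    if n_events < 3:
        raise ValidationError(f"need at least 3 events, have {n_events}")
    p = X.shape[1]
    resid = []
    times = []
    V = np.zeros((p, p))
    for sd in strata:
        r = np.exp(sd.X @ fit.beta)
        S0 = _segment_sums(r[sd.order_exit, None], sd.bound_exit)[:, 0] - \
            _segment_sums(r[sd.order_entry, None], sd.bound_entry)[:, 0]
        rx = r[:, None] * sd.X
        S1 = _segment_sums(rx[sd.order_exit], sd.bound_exit) - \
            _segment_sums(rx[sd.order_entry], sd.bound_entry)
        S2 = _suffix_outer(sd.X, r, sd.order_exit, sd.bound_exit) - \
            _suffix_outer(sd.X, r, sd.order_entry, sd.bound_entry)
        for g in range(sd.utimes.size):
            mean = S1[g] / S0[g]
            Vg = S2[g] / S0[g] - np.outer(mean, mean)
            for row in sd.tied_rows[g]:
                resid.append(sd.X[row] - mean)
                times.append(sd.utimes[g])
                V += Vg
    resid = np.asarray(resid)
    times = np.asarray(times)
    d = len(times)
    Vinv = np.linalg.inv(V)
    scaled = d * resid @ Vinv + fit.beta[None, :]
    g = times - times.mean()
    gss = float(g @ g)
    out = []
    for j in range(p):
        num = float(g @ scaled[:, j])
        stat = num ** 2 / (d * Vinv[j, j] * gss)
        corr = float(np.corrcoef(times, scaled[:, j])[0, 1])
        out.append({"covariate": names[j], "corr": corr,
                    "chisq": stat, "p": float(chi2.sf(stat, 1))})
    return pd.DataFrame(out).set_index("covariate")
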