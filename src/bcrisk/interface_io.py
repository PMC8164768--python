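"""File formats, configuration and the end-to-end pipeline orchestrator.

The cohort file is a flat CSV of one row per woman with raw covariate
values; reading validates the schema, categorizes the raw covariates and
excludes rows with implausible values (the counts and row numbers are
logged, echoing the exclusion flow of cohort studies).  All randomness
flows from named seeds in the configuration; every artifact carries enough
provenance (seed, config hash, package version) to be regenerated
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attributable_risk import par_set_from_cohort
from .cox_fitting import (
    PredictorSpec,
    add_stratum,
    fit_stratified_cox,
    schoenfeld_ph_test,
    split_followup_at_age,
)
from .hazard_engine import RateTable, default_rate_table
from .risk_model import (
    RelativeRiskModel,
    ValidationError,
    categorize,
    default_model,
)
from .validation import (
    adjusted_auc,
    auc_10yr,
    calibration_deciles,
    eo_ratio_ci,
    expected_cases,
    predicted_cumulative_risk,
    quintile_rr,
    screening_indices,
    ten_year_case_status,
)

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "id", "entry_age", "exit_age", "event", "education", "bmi", "height_cm",
    "family_history", "parity", "menarche_age", "study_site", "residence",
]
EVENT_CODES = ("bc", "death", "censored")


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write the cohort CSV (required schema columns first, extras after)."""
    extras = [c for c in df.columns
              if c not in COHORT_COLUMNS
              and not c.endswith("_cat") and c != "stratum"
              and c != "segment"]
    df[COHORT_COLUMNS + extras].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; returns the categorized frame.

    Adds integer category-code columns (``bmi_cat``, ``height_cat``,
    ``famhist_cat``, ``parity_cat``, ``menarche_cat``; ``education`` is
    normalized to its 0-4 code).  Rows with implausible covariates or
    non-increasing follow-up are excluded and logged by reason;
    structurally malformed input (missing columns, unknown event codes,
    unparseable numbers) raises with the offending row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    bad_event = ~df["event"].isin(EVENT_CODES)
    if bad_event.any():
        row = int(np.flatnonzero(bad_event)[0]) + 2  # 1-based + header
        raise ValidationError(
            f"unknown event code {df['event'][bad_event].iloc[0]!r} "
            f"at line {row}"
        )
    for col in ("entry_age", "exit_age", "bmi", "height_cm",
                "family_history", "parity", "menarche_age"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"column {col!r}: unparseable value at line "
                f"{int(np.flatnonzero(bad)[0]) + 2}"
            )
        df[col] = coerced

    exclusions: dict[str, list[int]] = {}

    def _exclude(mask, reason):
        rows = np.flatnonzero(mask.to_numpy())
        if rows.size:
            exclusions[reason] = [int(r) + 2 for r in rows]
        return mask

    drop = _exclude(df["entry_age"] >= df["exit_age"], "entry>=exit")
    drop = drop | _exclude(df[["entry_age", "exit_age", "bmi", "height_cm",
                               "family_history", "parity",
                               "menarche_age"]].isna().any(axis=1),
                           "missing value")

    keep = df[~drop].copy()
    codes = {"education": [], "bmi_cat": [], "height_cat": [],
             "famhist_cat": [], "parity_cat": [], "menarche_cat": []}
    implausible_rows = []
    for i, row in keep.iterrows():
        try:
            prof = categorize(
                {
                    "education": row["education"],
                    "bmi": row["bmi"],
                    "height_cm": row["height_cm"],
                    "family_history": row["family_history"],
                    "parity": row["parity"],
                    "menarche_age": row["menarche_age"],
                },
                residence=row["residence"],
            )
        except ValidationError:
            implausible_rows.append(i)
            continue
        codes["education"].append(prof.education)
        codes["bmi_cat"].append(prof.bmi_category)
        codes["height_cat"].append(prof.height_category)
        codes["famhist_cat"].append(prof.family_history)
        codes["parity_cat"].append(prof.parity)
        codes["menarche_cat"].append(prof.menarche_category)
    if implausible_rows:
        exclusions["implausible covariate"] = [
            int(r) + 2 for r in implausible_rows
        ]
        keep = keep.drop(index=implausible_rows)
    for col, vals in codes.items():
        keep[col] = vals
    keep = keep.reset_index(drop=True)
    for reason, rows in exclusions.items():
        logger.info("read_cohort: excluded %d rows (%s), e.g. lines %s",
                    len(rows), reason, rows[:5])
    logger.info("read_cohort: %d records read, %d excluded",
                len(keep), sum(len(v) for v in exclusions.values()))
    keep.attrs["exclusions"] = exclusions
    return keep


def categorize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Attach category-code columns to a frame of raw covariates (vectorized).

    The in-memory fast path equivalent to the row-wise categorization of
    :func:`read_cohort`; assumes values already validated/plausible.
    """
    from .risk_model import BMI_CUTS, HEIGHT_CUTS, MENARCHE_CUTS

    out = df.copy()

    def cut(col, cuts):
        v = out[col].to_numpy(dtype=float)
        return np.searchsorted(np.asarray(cuts), v, side="right")

    out["bmi_cat"] = cut("bmi", BMI_CUTS)
    out["height_cat"] = cut("height_cm", HEIGHT_CUTS)
    out["menarche_cat"] = cut("menarche_age", MENARCHE_CUTS)
    out["famhist_cat"] = np.minimum(out["family_history"].astype(int), 2)
    out["parity_cat"] = np.minimum(out["parity"].astype(int), 3)
    return out


def split_derivation_test(records: pd.DataFrame, fraction: float = 2 / 3,
                          seed: int = 0):
    """Random disjoint exhaustive split; derivation gets ``floor(n*fraction)``."""
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"split fraction {fraction} outside (0, 1)")
    n = len(records)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_der = int(np.floor(n * fraction))
    der = records.iloc[np.sort(perm[:n_der])].reset_index(drop=True)
    test = records.iloc[np.sort(perm[n_der:])].reset_index(drop=True)
    return der, test


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


DEFAULT_SPECS = [
    PredictorSpec(name="education", column="education", kind="categorical",
                  n_levels=5, reference=0),
    PredictorSpec(name="bmi", column="bmi_cat", kind="categorical",
                  n_levels=4, reference=0, age_segmented=True),
    PredictorSpec(name="height", column="height_cat", kind="categorical",
                  n_levels=4, reference=0),
    PredictorSpec(name="family_history", column="famhist_cat",
                  kind="categorical", n_levels=3, reference=0),
    PredictorSpec(name="parity", column="parity_cat", kind="categorical",
                  n_levels=4, reference=3),
    PredictorSpec(name="menarche", column="menarche_cat", kind="categorical",
                  n_levels=4, reference=3),
]


#: parsimonious per-step encoding; the choice for small cohorts where the
#: fully categorical design would leave event-free categories
ORDINAL_SPECS = [
    PredictorSpec(name="education", column="education", kind="ordinal",
                  n_levels=5, reference=0),
    PredictorSpec(name="bmi", column="bmi_cat", kind="ordinal",
                  n_levels=4, reference=0, age_segmented=True),
    PredictorSpec(name="height", column="height_cat", kind="ordinal",
                  n_levels=4, reference=0),
    PredictorSpec(name="family_history", column="famhist_cat",
                  kind="ordinal", n_levels=3, reference=0),
    PredictorSpec(name="parity", column="parity_cat", kind="ordinal",
                  n_levels=4, reference=3),
    PredictorSpec(name="menarche", column="menarche_cat", kind="ordinal",
                  n_levels=4, reference=3),
]


@dataclass
class PipelineConfig:
    """Paths, stage toggles and seeds driving :func:`run_pipeline`."""

    cohort_path: str | None = None
    rates_path: str | None = None
    model_path: str | None = None
    output_dir: str = "bcrisk_output"
    run_fit: bool = True
    run_par: bool = True
    run_project: bool = True
    run_validate: bool = True
    split_fraction: float = 2 / 3
    split_seed: int = 1
    simulate_n: int | None = None
    simulate_seed: int = 0
    screening_cutoffs: tuple = tuple(np.round(np.arange(0.004, 0.0205, 0.002), 4))
    report_decimals: int = 2
    fit_encoding: str = "categorical"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValidationError("split fraction must be in (0, 1)")
        if self.fit_encoding not in ("categorical", "ordinal"):
            raise ValidationError("fit_encoding must be categorical|ordinal")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "screening_cutoffs" in data:
            data["screening_cutoffs"] = tuple(data["screening_cutoffs"])
        return cls(**data)


def _round_floats(obj, nd):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute read-or-simulate -> split -> fit -> PAR -> project -> validate.

    Writes ``report.json`` (full precision plus a display-rounded copy),
    the predicted-risk cohort CSV and calibration-plot data into the output
    directory, and returns the report dictionary.  Deterministic given the
    configuration.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        model = (RelativeRiskModel.load(config.model_path)
                 if config.model_path else default_model())
        table = (RateTable.from_csv(config.rates_path)
                 if config.rates_path else default_rate_table())
        if config.cohort_path:
            stage = "read"
            cohort = read_cohort(config.cohort_path)
        elif config.simulate_n:
            stage = "simulate"
            from .synthetic_cohort import SimulationConfig, simulate_cohort

            cohort = simulate_cohort(SimulationConfig(
                n=config.simulate_n, seed=config.simulate_seed,
                model=model, rate_table=table,
            ))
        else:
            raise ValidationError("neither cohort_path nor simulate_n given")

        report: dict = {
            "provenance": {
                "package_version": __version__,
                "rates": table.provenance,
                "n_records": len(cohort),
                "split_seed": config.split_seed,
                "simulate_seed": (config.simulate_seed
                                  if config.cohort_path is None else None),
            }
        }

        stage = "split"
        derivation, test = split_derivation_test(
            cohort, config.split_fraction, config.split_seed
        )
        report["split"] = {"derivation_n": len(derivation),
                           "test_n": len(test)}

        if config.run_fit:
            stage = "fit"
            work = add_stratum(derivation)
            work = split_followup_at_age(work, model.age_split)
            specs = (DEFAULT_SPECS if config.fit_encoding == "categorical"
                     else ORDINAL_SPECS)
            fit = fit_stratified_cox(work, specs)
            ph = schoenfeld_ph_test(fit, work, specs)
            report["fit"] = {
                "n_events": fit.n_events,
                "n_strata": fit.n_strata,
                "loglik": fit.loglik,
                "iterations": fit.iterations,
                "hazard_ratios": {
                    name: float(np.exp(b))
                    for name, b in zip(fit.names, fit.beta)
                },
                "se": dict(zip(fit.names, map(float, fit.se))),
                "ph_min_p": float(ph["p"].min()),
            }

        if config.run_par:
            stage = "par"
            pars = par_set_from_cohort(cohort, model)
            report["par"] = pars.to_dict()
        else:
            pars = model.par

        # project over the potential (administrative) window when the cohort
        # records it: expected counts are then unbiased for observed counts
        horizon_rule = ("potential" if "censor_age" in cohort.columns
                        else "observed")

        if config.run_project:
            stage = "project"
            pred = predicted_cumulative_risk(test, model, table, model.par,
                                             horizon_rule=horizon_rule)
            test = test.copy()
            test["predicted_risk"] = pred
            test.to_csv(out_dir / "test_cohort_predicted.csv", index=False)
            report["project"] = {
                "mean_predicted_risk": float(np.mean(pred)),
                "max_predicted_risk": float(np.max(pred)),
            }

        if config.run_validate:
            stage = "validate"
            E, by_res = expected_cases(test, model, table, model.par,
                                       by="residence",
                                       horizon_rule=horizon_rule)
            O = int((test["event"] == "bc").sum())
            overall = eo_ratio_ci(E, O)
            pred = predicted_cumulative_risk(test, model, table, model.par,
                                             horizon_rule=horizon_rule)
            outcomes = (test["event"] == "bc").to_numpy()
            cells = calibration_deciles(pred, outcomes)
            pd.DataFrame([c.__dict__ for c in cells]).to_csv(
                out_dir / "calibration_deciles.csv", index=False
            )
            pred10 = predicted_cumulative_risk(test, model, table, model.par,
                                               horizon=10.0)
            eligible, case = ten_year_case_status(test)
            auc, auc_ci = auc_10yr(pred10[eligible], case[eligible])
            band = (np.floor(test["entry_age"] / 5.0) * 5.0).astype(int)
            strata = (test["residence"].astype(str) + "|" +
                      band.astype(str)).to_numpy()
            adj = adjusted_auc(pred10[eligible], case[eligible],
                               strata[eligible])
            qrr = quintile_rr(test, pred10)
            scr = screening_indices(pred10[eligible], case[eligible],
                                    config.screening_cutoffs)
            scr.to_csv(out_dir / "screening_indices.csv", index=False)
            report["validate"] = {
                "overall": {"E": overall.expected, "O": overall.observed,
                            "ratio": overall.ratio,
                            "ci": [overall.ci_low, overall.ci_high]},
                "by_residence": {
                    str(k): {"E": v[0], "O": v[1]} for k, v in by_res.items()
                },
                "decile_ratios": [c.ratio for c in cells],
                "auc_10yr": auc,
                "auc_10yr_ci": list(auc_ci),
                "auc_adjusted": adj,
                "quintile_rr": qrr.to_dict(orient="records"),
            }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out_dir / "report_rounded.json", "w") as fh:
        json.dump(_round_floats(report, config.report_decimals), fh,
                  indent=2, sort_keys=True)
    return report
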