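"""Shared fixtures: the shipped model/rates and reusable simulated cohorts.

The two large cohorts are expensive (piecewise-exponential simulation of
100k/200k women under the shipped model and rates), so they are built once
per session and shared by the module and acceptance tests that need the
same study conditions.
"""

import numpy as np
import pandas as pd
import pytest

import bcrisk as b

#: single fixed seed family for every stochastic test in the suite
SUITE_SEED = 2024


@pytest.fixture(scope="session")
def model():
    return b.default_model()


@pytest.fixture(scope="session")
def rates():
    return b.default_rate_table()


@pytest.fixture(scope="session")
def cohort_100k(model, rates):
    cfg = b.SimulationConfig(n=100_000, seed=SUITE_SEED, model=model,
                             rate_table=rates)
    return b.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_200k(model, rates):
    cfg = b.SimulationConfig(n=200_000, seed=SUITE_SEED, model=model,
                             rate_table=rates)
    return b.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def calibration_200k(cohort_200k, model, rates):
    """(expected total, observed total, decile cells, predictions, outcomes)."""
    pred = b.predicted_cumulative_risk(cohort_200k, model, rates)
    outcomes = (cohort_200k["event"] == "bc").to_numpy()
    cells = b.calibration_deciles(pred, outcomes)
    return float(pred.sum()), int(outcomes.sum()), cells, pred, outcomes


def random_profile(rng) -> b.RiskFactorProfile:
    return b.RiskFactorProfile(
        education=int(rng.integers(5)),
        bmi_category=int(rng.integers(4)),
        height_category=int(rng.integers(4)),
        family_history=int(rng.integers(3)),
        parity=int(rng.integers(4)),
        menarche_category=int(rng.integers(4)),
        residence=("urban", "rural")[int(rng.integers(2))],
    )


def oracle_project(profile, a, tau, model, table, pars=None, step=1.0 / 365):
    """Independent fine-grid trapezoid oracle for the projection integral.

    Survival is evaluated exactly at grid nodes (the cumulative hazard of a
    piecewise-constant hazard is piecewise linear); only the outer integral
    is approximated, on a daily grid aligned to every hazard breakpoint.
    """
    pars = pars if pars is not None else model.par
    res = profile.residence
    pts = table.breakpoints(res, model.age_split)
    end = a + tau
    edges = np.concatenate([[a], pts[(pts > a) & (pts < end)], [end]])
    rr_lt, rr_ge = np.exp(model.log_rr_pair(profile))
    total = 0.0
    H = 0.0  # cumulative all-cause hazard from a to the piece start
    for t0, t1 in zip(edges[:-1], edges[1:]):
        rr = rr_lt if t0 < model.age_split else rr_ge
        h1 = table.baseline_hazard(pars, res, t0) * rr
        h2 = table.competing_hazard(res, t0)
        lam = h1 + h2
        npts = max(int(np.ceil((t1 - t0) / step)) + 1, 2)
        grid = np.linspace(t0, t1, npts)
        surv = np.exp(-(H + lam * (grid - t0)))
        total += float(np.trapezoid(h1 * surv, grid))
        H += lam * (t1 - t0)
    return total


def simulate_simple_cohort(rng, n, beta, prevalence=0.3, base_hazard=0.01,
                           entry_lo=40.0, entry_span=20.0, horizon=12.0,
                           sites=("A",)):
    """Tiny purpose-built generator: one binary covariate, constant hazard.

    Independent of the package's piecewise-exponential machinery, so Cox
    parameter-recovery tests have a data source that does not share code
    with the fitter under test.
    """
    entry = entry_lo + rng.random(n) * entry_span
    z = (rng.random(n) < prevalence).astype(float)
    t = entry + rng.exponential(1.0 / (base_hazard * np.exp(beta * z)))
    exit_ = np.minimum(t, entry + horizon)
    event = np.where(t <= exit_, "bc", "censored")
    df = pd.DataFrame({
        "entry_age": entry, "exit_age": exit_, "event": event,
        "study_site": rng.choice(sites, n), "z": z,
    })
    return b.add_stratum(df)
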