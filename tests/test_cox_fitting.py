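"""Stratified Cox fitter and model-building steps.

Parameter estimates are checked against three independent routes: a
brute-force grid maximization of the hand-written partial likelihood on a
toy dataset, the closed-form null log-likelihood, and lifelines (whose Cox
implementation is unrelated to this one) on left-truncated, tied and
stratified data.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import bcrisk as b
from bcrisk.cox_fitting import FitResult

from conftest import SUITE_SEED, simulate_simple_cohort


def toy_frame(rows):
    df = pd.DataFrame(rows, columns=["entry_age", "exit_age", "event", "z"])
    df["study_site"] = "A"
    return b.add_stratum(df)


Z_SPEC = [b.PredictorSpec(name="z", column="z", kind="binary")]


class TestCohortRecord:
    def test_valid_record_constructs(self):
        rec = b.CohortRecord(45.0, 55.0, "bc", "U1", "urban",
                             {"education": 2})
        assert rec.event == "bc"

    def test_invariants_enforced(self):
        with pytest.raises(b.ValidationError, match="entry_age"):
            b.CohortRecord(55.0, 55.0, "bc", "U1", "urban", {})
        with pytest.raises(b.ValidationError, match="event"):
            b.CohortRecord(45.0, 55.0, "dead", "U1", "urban", {})


class TestSplitFollowup:
    def test_spanning_record_splits_into_censored_then_event(self):
        df = toy_frame([(45.0, 55.0, "bc", 1.0)])
        out = b.split_followup_at_age(df, 50.0).sort_values("entry_age")
        assert len(out) == 2
        first, second = out.iloc[0], out.iloc[1]
        assert (first.entry_age, first.exit_age, first.event) == (45.0, 50.0,
                                                                  "censored")
        assert (second.entry_age, second.exit_age, second.event) == (50.0,
                                                                     55.0,
                                                                     "bc")
        assert (out.segment.tolist()) == [0, 1]

    def test_non_spanning_records_pass_through(self):
        df = toy_frame([(52.0, 60.0, "censored", 0.0),
                        (40.0, 49.0, "bc", 1.0)])
        out = b.split_followup_at_age(df, 50.0)
        assert len(out) == 2
        assert set(out.event) == {"censored", "bc"}

    def test_person_time_conserved_exactly(self):
        rng = np.random.default_rng(SUITE_SEED)
        entry = 30 + rng.random(500) * 40
        exit_ = entry + 0.5 + rng.random(500) * 20
        df = toy_frame([(e, x, ev, 0.0) for e, x, ev in
                        zip(entry, exit_,
                            rng.choice(["bc", "death", "censored"], 500))])
        out = b.split_followup_at_age(df, 50.0)
        before = (df.exit_age - df.entry_age).sum()
        after = (out.exit_age - out.entry_age).sum()
        assert after == pytest.approx(before, abs=1e-9)
        # events preserved one-to-one
        assert (out.event == "bc").sum() == (df.event == "bc").sum()

    def test_split_outside_observed_range_is_noop(self):
        df = toy_frame([(40.0, 45.0, "bc", 1.0)])
        out = b.split_followup_at_age(df, 90.0)
        assert len(out) == 1 and out.iloc[0].exit_age == 45.0


class TestPartialLikelihood:
    def test_toy_mle_matches_grid_maximization(self):
        """One stratum, entries at 40: events at 50 (z=1) and 55 (z=0), a
        z=1 subject censored at 60.  The written-out partial likelihood is
        L(b) = e^b/(2 e^b + 1) * 1/(1 + e^b); brute-force grid maximization
        (and calculus: e^b = 1/sqrt(2)) gives b = -ln(2)/2."""
        df = toy_frame([(40, 50.0, "bc", 1.0), (40, 55.0, "bc", 0.0),
                        (40, 60.0, "censored", 1.0)])

        def loglik(bgrid):
            eb = np.exp(bgrid)
            return bgrid - np.log(2 * eb + 1) - np.log(1 + eb)

        grid = np.linspace(-3, 3, 200001)
        expected = grid[np.argmax(loglik(grid))]
        assert expected == pytest.approx(-np.log(2) / 2, abs=1e-4)
        fit = b.fit_stratified_cox(df, Z_SPEC)
        assert fit.beta[0] == pytest.approx(-np.log(2) / 2, abs=1e-8)
        assert fit.loglik == pytest.approx(float(loglik(fit.beta[0])),
                                           abs=1e-10)

    def test_null_loglik_closed_form_breslow_and_efron(self):
        """At beta=0 the Breslow partial log-likelihood is -sum over events
        of ln(risk-set size); Efron replaces tied denominators by
        prod_l (n_g - l) for l = 0..d-1."""
        df = toy_frame([(40, 50.0, "bc", 1.0), (41, 50.0, "bc", 0.0),
                        (40, 55.0, "bc", 0.0), (42, 60.0, "censored", 1.0),
                        (44, 58.0, "censored", 0.0)])
        # risk set at 50: all 5 subjects (tied pair of events, d=2);
        # at 55: exits 55, 60, 58 -> size 3
        breslow_null = -(2 * np.log(5) + np.log(3))
        efron_null = -(np.log(5) + np.log(4) + np.log(3))
        fitB = b.fit_stratified_cox(df, Z_SPEC, ties="breslow")
        fitE = b.fit_stratified_cox(df, Z_SPEC, ties="efron")
        assert fitB.loglik_null == pytest.approx(breslow_null, abs=1e-12)
        assert fitE.loglik_null == pytest.approx(efron_null, abs=1e-12)

    def test_agrees_with_lifelines_left_truncated_stratified_tied(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(SUITE_SEED)
        df = simulate_simple_cohort(rng, 3000, beta=0.6, sites=("A", "B"))
        df["exit_age"] = np.maximum(np.ceil(df["exit_age"]),
                                    np.floor(df["entry_age"]) + 1.0)  # ties
        df = df[df.exit_age > df.entry_age]
        fit = b.fit_stratified_cox(df, Z_SPEC)
        ldf = df[["entry_age", "exit_age", "z", "stratum"]].copy()
        ldf["E"] = (df.event == "bc").astype(int)
        cph = lifelines.CoxPHFitter().fit(
            ldf, duration_col="exit_age", event_col="E",
            entry_col="entry_age", strata=["stratum"],
        )
        assert fit.beta[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert fit.se[0] == pytest.approx(cph.standard_errors_.iloc[0],
                                          abs=1e-6)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_null_covariate_estimate_near_zero(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = simulate_simple_cohort(rng, 10_000, beta=0.0)
        fit = b.fit_stratified_cox(df, Z_SPEC)
        assert abs(fit.beta[0]) < 3 * fit.se[0]

    def test_recovers_true_log_hazard_ratio(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = simulate_simple_cohort(rng, 50_000, beta=np.log(1.5))
        fit = b.fit_stratified_cox(df, Z_SPEC)
        assert abs(fit.beta[0] - np.log(1.5)) < 3 * fit.se[0]

    def test_invariant_to_record_order_and_stratum_relabeling(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = simulate_simple_cohort(rng, 2000, beta=0.4, sites=("A", "B"))
        fit1 = b.fit_stratified_cox(df, Z_SPEC)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["stratum"] = "relabel:" + shuffled["stratum"]
        fit2 = b.fit_stratified_cox(shuffled, Z_SPEC)
        assert fit1.beta[0] == pytest.approx(fit2.beta[0], abs=1e-10)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_age_segmented_effect_jointly_recovered(self):
        """An effect of +0.5 below age 50 and -0.5 above, simulated
        piecewise, is recovered by episode splitting plus the segmented
        design within 3 SE for both segments."""
        rng = np.random.default_rng(SUITE_SEED)
        n = 50_000
        entry = 40 + rng.random(n) * 10
        z = (rng.random(n) < 0.4).astype(int)
        lam_lo = 0.004 * np.exp(0.5 * z)
        lam_hi = 0.004 * np.exp(-0.5 * z)
        u = rng.exponential(size=n)
        d1 = np.clip(50 - entry, 0, None)
        t = np.where(u < lam_lo * d1, entry + u / lam_lo,
                     50 + (u - lam_lo * d1) / lam_hi)
        exit_ = np.minimum(t, entry + 12)
        df = b.add_stratum(pd.DataFrame({
            "entry_age": entry, "exit_age": exit_,
            "event": np.where(t <= exit_, "bc", "censored"),
            "study_site": "A", "z": z,
        }))
        df = b.split_followup_at_age(df, 50.0)
        spec = [b.PredictorSpec(name="z", column="z", kind="categorical",
                                n_levels=2, reference=0, age_segmented=True)]
        fit = b.fit_stratified_cox(df, spec)
        est = dict(zip(fit.names, zip(fit.beta, fit.se)))
        b0, s0 = est["z[1]@seg0"]
        b1, s1 = est["z[1]@seg1"]
        assert abs(b0 - 0.5) < 3 * s0
        assert abs(b1 - (-0.5)) < 3 * s1

    def test_complete_separation_raises(self):
        df = toy_frame([(40, 50.0, "bc", 1.0), (40, 55.0, "bc", 0.0),
                        (40, 60.0, "censored", 0.0)])
        with pytest.raises(b.ConvergenceError):
            b.fit_stratified_cox(df, Z_SPEC)

    def test_constant_design_column_rejected(self):
        df = toy_frame([(40, 50.0, "bc", 1.0), (40, 55.0, "bc", 1.0)])
        with pytest.raises(b.ValidationError, match="constant"):
            b.fit_stratified_cox(df, Z_SPEC)


def _dummy_fit(loglik, n_params):
    return FitResult(
        names=[f"p{i}" for i in range(n_params)],
        beta=np.zeros(n_params), se=np.ones(n_params),
        cov=np.eye(n_params), loglik=loglik, loglik_null=loglik,
        n_events=10, n_records=10, n_strata=1, iterations=1, ties="efron",
    )


class TestLikelihoodRatio:
    def test_identical_logliks_give_zero_statistic_p_one(self):
        stat, df, p = b.likelihood_ratio_test(_dummy_fit(-50.0, 3),
                                              _dummy_fit(-50.0, 1))
        assert stat == 0.0 and p == 1.0

    def test_chi_square_tail_worked_example(self):
        stat, df, p = b.likelihood_ratio_test(_dummy_fit(-100.0, 5),
                                              _dummy_fit(-103.0, 3))
        assert stat == pytest.approx(6.0)
        assert df == 2
        assert p == pytest.approx(chi2.sf(6.0, 2))
        assert p == pytest.approx(0.0498, abs=5e-4)

    def test_non_nested_inputs_rejected(self):
        with pytest.raises(b.ValidationError, match="nested"):
            b.likelihood_ratio_test(_dummy_fit(-100.0, 2), _dummy_fit(-99.0, 2))


class TestCutoffSelectionBIC:
    @staticmethod
    def _frame(rng, n=4000, beta=0.8, threshold=25.0):
        raw = 18 + rng.random(n) * 17  # uniform 18-35
        z = (raw >= threshold).astype(float)
        entry = 40 + rng.random(n) * 15
        t = entry + rng.exponential(1.0 / (0.02 * np.exp(beta * z)))
        exit_ = np.minimum(t, entry + 10)
        return b.add_stratum(pd.DataFrame({
            "entry_age": entry, "exit_age": exit_,
            "event": np.where(t <= exit_, "bc", "censored"),
            "study_site": "A", "raw": raw,
        }))

    def test_equal_k_candidates_larger_loglik_wins(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = self._frame(rng)
        best, bics = b.select_cutoffs_bic(df, "raw",
                                          [(25.0,), (31.0,)])
        assert best == (25.0,)  # the true threshold fits better
        assert bics[(25.0,)] < bics[(31.0,)]

    def test_null_data_penalty_favors_fewer_parameters(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = self._frame(rng, beta=0.0)
        best, bics = b.select_cutoffs_bic(
            df, "raw", [(26.0,), (22.0, 26.0, 30.0)]
        )
        assert best == (26.0,)

    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = self._frame(rng, n=1500)
        best, _ = b.select_cutoffs_bic(df, "raw", [(24.0,)])
        assert best == (24.0,)

    def test_empty_category_candidate_skipped_then_error(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = self._frame(rng, n=1500)
        with pytest.raises(b.ValidationError, match="empty"):
            b.select_cutoffs_bic(df, "raw", [(50.0,)])  # nobody above 50


class TestBackwardElimination:
    def test_null_predictor_dropped_strong_retained(self):
        """A true hazard ratio of 2 is always retained; an independent null
        predictor is dropped at its nominal alpha=0.05 false-retention
        rate, so it survives at most one of three replicates."""
        rng = np.random.default_rng(SUITE_SEED)
        n = 50_000
        null_dropped = 0
        for _ in range(3):
            entry = 40 + rng.random(n) * 20
            strong = (rng.random(n) < 0.3).astype(float)
            null = (rng.random(n) < 0.5).astype(float)
            t = entry + rng.exponential(
                1.0 / (0.01 * np.exp(np.log(2.0) * strong))
            )
            exit_ = np.minimum(t, entry + 12)
            df = b.add_stratum(pd.DataFrame({
                "entry_age": entry, "exit_age": exit_,
                "event": np.where(t <= exit_, "bc", "censored"),
                "study_site": "A", "strong": strong, "null": null,
            }))
            specs = [
                b.PredictorSpec(name="strong", column="strong", kind="binary"),
                b.PredictorSpec(name="null", column="null", kind="binary"),
            ]
            kept, trace, fit = b.backward_eliminate(df, specs, alpha=0.05)
            assert "strong" in [s.name for s in kept]
            if [s.name for s in kept] == ["strong"]:
                assert trace[0][0] == "null" and trace[0][1] > 0.05
                null_dropped += 1
        assert null_dropped >= 2

    def test_all_significant_no_elimination(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = simulate_simple_cohort(rng, 20_000, beta=0.8)
        kept, trace, _ = b.backward_eliminate(df, Z_SPEC, alpha=0.05)
        assert [s.name for s in kept] == ["z"] and trace == []

    def test_empty_predictor_set_returned_empty(self):
        kept, trace, fit = b.backward_eliminate(pd.DataFrame(), [], alpha=0.05)
        assert kept == [] and trace == [] and fit is None


class TestEncodingLRT:
    @staticmethod
    def _leveled_cohort(rng, effects, n=30_000):
        entry = 40 + rng.random(n) * 15
        level = rng.integers(0, 4, n)
        t = entry + rng.exponential(
            1.0 / (0.01 * np.exp(np.asarray(effects)[level]))
        )
        exit_ = np.minimum(t, entry + 10)
        return b.add_stratum(pd.DataFrame({
            "entry_age": entry, "exit_age": exit_,
            "event": np.where(t <= exit_, "bc", "censored"),
            "study_site": "A", "lvl": level,
        }))

    SPEC = [b.PredictorSpec(name="lvl", column="lvl", kind="categorical",
                            n_levels=4, reference=0)]

    def test_linear_effects_accept_ordinal_encoding(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = self._leveled_cohort(rng, [0.0, 0.3, 0.6, 0.9])
        stat, dof, p = b.encoding_lrt(df, self.SPEC, "lvl")
        assert dof == 2 and p > 0.01

    def test_threshold_effects_reject_ordinal_encoding(self):
        rng = np.random.default_rng(SUITE_SEED)
        df = self._leveled_cohort(rng, [0.0, 1.0, 1.0, 1.0])
        stat, dof, p = b.encoding_lrt(df, self.SPEC, "lvl")
        assert p < 1e-6


class TestSchoenfeld:
    def test_null_rejection_rate_matches_nominal_level(self):
        """Under proportional hazards the test p-values are ~uniform: the
        fraction below 0.05 over 200 replicates stays near 5%."""
        rng = np.random.default_rng(SUITE_SEED)
        hits = 0
        for _ in range(200):
            df = simulate_simple_cohort(rng, 1500, beta=0.3, prevalence=0.5,
                                        base_hazard=0.03, entry_span=15.0,
                                        horizon=10.0)
            fit = b.fit_stratified_cox(df, Z_SPEC)
            p = b.schoenfeld_ph_test(fit, df, Z_SPEC)["p"].iloc[0]
            hits += p < 0.05
        assert 0.02 <= hits / 200 <= 0.09

    def test_detects_effect_reversal_at_age_50(self):
        rng = np.random.default_rng(SUITE_SEED)
        n = 50_000
        entry = 40 + rng.random(n) * 10
        z = (rng.random(n) < 0.4).astype(float)
        lam_lo = 0.004 * np.exp(0.5 * z)
        lam_hi = 0.004 * np.exp(-0.5 * z)
        u = rng.exponential(size=n)
        d1 = np.clip(50 - entry, 0, None)
        t = np.where(u < lam_lo * d1, entry + u / lam_lo,
                     50 + (u - lam_lo * d1) / lam_hi)
        exit_ = np.minimum(t, entry + 12)
        df = b.add_stratum(pd.DataFrame({
            "entry_age": entry, "exit_age": exit_,
            "event": np.where(t <= exit_, "bc", "censored"),
            "study_site": "A", "z": z,
        }))
        fit = b.fit_stratified_cox(df, Z_SPEC)
        p = b.schoenfeld_ph_test(fit, df, Z_SPEC)["p"].iloc[0]
        assert p < 0.05

    def test_two_events_insufficient(self):
        df = toy_frame([(40, 50.0, "bc", 1.0), (40, 55.0, "bc", 0.0),
                        (40, 60.0, "censored", 1.0)])
        fit_dummy = _dummy_fit(-1.0, 1)
        with pytest.raises(b.ValidationError, match="3 events"):
            b.schoenfeld_ph_test(fit_dummy, df, Z_SPEC)
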