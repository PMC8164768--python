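# Methods

This note records the scientific and numerical choices behind `bcrisk`, in
the spirit of a model-description appendix: what is assumed, what is
tunable, what the synthetic cohorts do and do not emulate, and where the
design was genuinely open.

## Relative-risk model

The hazard of invasive breast cancer for a woman with categorized profile
$x$ at age $t$ is $h_1(t,x)=h_{10}(t)\,\mathrm{RR}(x;t)$ with
$\log \mathrm{RR}$ additive over six predictors. Categories follow the
conventions of Chinese cohort studies: BMI cut at 18.5/24.0/28.0 kg/m²
(the Chinese overweight/obesity criteria), height at its quartiles
(150.2/154.2/158.2 cm), menarche at 13/15/17 years, parity at 1/2/3+
births, family history of any cancer at 0/1/2+ affected first-degree
relatives (a surrogate for breast-cancer family history, which these
cohorts did not record), and five education levels. Category boundaries
are left-closed/right-open on the printed lower bounds, which makes the
partition of each covariate axis exhaustive; printed integer gaps (e.g.
"≤12" followed by "13–14" for menarche) are closed by letting the lower
category absorb the gap.

Every predictor's effect is constant in age except BMI. Schoenfeld
residual checks in this model class show the BMI association reversing
around menopause, so the model carries two BMI category→log-RR maps with a
hard switch at age 50; `relative_risk` is therefore piecewise constant in
age with (at most) one discontinuity. The reference level of each
predictor has log-RR exactly 0 by construction, and the shipped model's
references are the lowest-risk categories so that the attributable risk is
interpretable as removable incidence. Serialization stores log-RRs, not
RRs, so the reference's zero survives round trips exactly; the published
confidence intervals travel as metadata and are never used in projection.

The shipped default (`default_model()`) is fully categorical. Education
and height print per-level hazard ratios that are nearly proportional to
level, so an ordinal (single per-step log-RR) encoding is also supported
(`ORDINAL_SPECS`) and is the recommended design for small cohorts, where a
fully categorical design leaves event-free categories and a monotone
partial likelihood; the default stays categorical because it reproduces
the published per-level estimates verbatim.

## Cox fitting

`fit_stratified_cox` maximizes the stratified partial likelihood with age
as the timescale: a woman enters the risk set at her enrollment age (left
truncation is always applied) and leaves at exit; risk sets form within
strata defined by study site × 5-year enrollment-age band (up to 100
strata). Ties use Efron's correction by default — ages recorded coarsely
produce heavy ties, and Efron is the accurate standard — with Breslow
available via `ties="breslow"`. The implementation is Newton–Raphson with
step halving, gradient max-norm tolerance 1e-8, at most 100 iterations;
suffix sums over exit- and entry-sorted orders give each stratum's
risk-set aggregates in $O(n\log n)$ per iteration, with the Hessian
assembled from per-segment GEMMs. Step acceptance uses a relative
tolerance of 1e-9·(|loglik|+1): near the optimum the true change in a
partial likelihood summed over thousands of events is below float
roundoff, and an absolute threshold would spuriously reject converged
steps. Estimates diverging beyond |log HR| > 15 raise a convergence error
(monotone likelihood / complete separation). The fitter agrees with
lifelines to ~1e-6 on left-truncated, tied, stratified data in the test
suite; lifelines is used only as a cross-check, never as the engine.

Model-building steps mirror standard practice:

* **Episode splitting at 50** (`split_followup_at_age`) conserves
  person-time exactly and lets BMI enter as segment-specific columns;
  strata are assigned from *enrollment* age before splitting.
* **Cutoff selection** minimizes BIC $=-2\ell + k\ln d$ with $d$ = number
  of events — the effective information of a partial likelihood scales
  with events, not subjects. Ties break toward fewer parameters, then
  lexicographically.
* **Backward elimination** drops the predictor with the largest
  group-Wald p-value above α = 0.05 until all remain significant
  (per-group joint tests, since predictors are multi-level); a
  likelihood-ratio variant is available via `method="lrt"`. Wald is the
  default reading of "assessed all variables with P < 0.05".
* **Proportional hazards** are checked by the standard one-degree
  chi-square on scaled Schoenfeld residuals against event age (identity
  time transform), pooled across strata.
* Nonlinearity screening is implemented as an ordinal-vs-categorical
  likelihood-ratio test per predictor (both encodings exist in the design
  builder), a deliberately smaller surface than fractional polynomials
  that answers the same question — are the per-level effects proportional
  to level?

## Attributable risk and baseline hazard

`bruzzi_par` implements $\mathrm{PAR}=1-\sum_j p_j/\mathrm{RR}_j$ over the
*joint* cross-classification of the six predictors, built sparsely from
observed cases — marginal products would assume an independence the data
do not claim. Because risk-factor distributions differ by residence and
the BMI effect switches at 50, PARs are estimated in the four (age
segment × residence) groups, a case's segment decided by attained age at
diagnosis, with the segment-appropriate BMI relative risk in its joint RR.
The identity $(1-\mathrm{PAR})\,E_q[\mathrm{RR}]=1$ (exact when the case
distribution is induced by covariate distribution $q$) is enforced to
1e-10 in tests and ties the PAR to hazard conservation: the
covariate-average of $h_{10}\mathrm{RR}$ reproduces composite incidence.

`RateTable` holds piecewise-constant rates on age bands covering [30, 85),
validated eagerly at load (contiguity, non-negativity, breast-cancer
mortality ≤ all-cause). Internal units are events per person-year; the
per-100,000 convention exists only at the CSV boundary. The shipped
default is synthetic (see README): its incidence shape is monotone
non-decreasing and its scale is set so the *all-ages* crude rate — using
an approximate Chinese female age structure in which ~41% of women are
under 30, where incidence is negligible — matches the published crude
54.3/34.5 per 100,000. Calibrating to the adult-only crude instead would
halve adult rates and is epidemiologically wrong, since published crude
rates are whole-population figures. The final open-ended band is carried
as 80–85 (explicit widths are required).

## Absolute-risk projection

Both hazards are constant within pieces delimited by rate-band edges and
the age-50 switch, so each piece of length $d$ contributes
$S\cdot\frac{h_1}{h_1+h_2}\big(1-e^{-(h_1+h_2)d}\big)$ with $S$ the
carried-in survival — the integral is exact, and a zero-hazard piece
contributes nothing while leaving $S$ unchanged. Pieces never straddle 50;
a piece's segment is decided by its start age. Horizons may be fractional;
windows are clipped to [a, a+τ) exactly. A vectorized batch path
(`project_batch`) evaluates one projection per cohort member for
calibration; it matches the scalar path to ~1e-16 and the independent
daily-grid trapezoid oracle to <1e-6 (the oracle evaluates survival
exactly at nodes, so only the outer integral is approximated).

Two conventions exist for the per-woman projection window in
expected-case calibration (`horizon_rule`):

* `"observed"` — enrollment to exit. Simple, but the window then depends
  on the outcome: cases' windows end at diagnosis, which both shrinks
  total $E$ (by roughly half the average cumulative all-cause hazard) and
  *inverts* calibration-decile gradients, because being a case
  mechanically lowers the prediction used for ranking.
* `"potential"` — enrollment to the administrative censoring age
  (`censor_age` column). Unbiased by construction: the competing-risk
  integral already accounts probabilistically for death and diagnosis, so
  $E[\text{observed cases}] = \sum_i P_i$ exactly. This matches how
  registry-linked cohorts are actually validated (follow-up does not end
  at diagnosis) and is what the pipeline uses whenever the cohort records
  the censoring age.

Risk-quintile hazard ratios and screening indices always rank on the
fixed 10-year risk for the same reason.

## Validation suite

E/O ratios take exact Poisson intervals via chi-square quantiles,
$O_{\mathrm{low}}=\tfrac12\chi^2_{\alpha/2}(2O)$,
$O_{\mathrm{high}}=\tfrac12\chi^2_{1-\alpha/2}(2O+2)$ — this reproduces
published subgroup intervals where the normal approximation differs in the
second decimal. Calibration deciles are sample-rank bins (stable ties,
sizes within one). The c-statistic is the Mann–Whitney probability with
ties counted ½, CI by the Hanley–McNeil variance; the age- and
residence-adjusted AUC pools within-stratum Mann–Whitney statistics
weighted by case×control pair counts, so purely between-stratum separation
contributes nothing. (A regression-based covariate adjustment would be an
alternative reading; it is noted, not implemented.) Ten-year case status
uses the cumulative/dynamic rule: cases are diagnoses within 10 years,
controls are event-free with ≥10 years of follow-up, others are excluded
(an option treats earlier other-cause deaths as controls). Screening
indices are standard 2×2 quantities with NNS = 1/PPV; report rounding to
two decimals happens only at the interface.

## Synthetic cohorts

`simulate_cohort` emulates a single-wave nationwide cohort: ~44.5% urban,
ten study sites, per-residence category marginals and the enrollment-age
mixture taken from the published baseline table, and per-subject
administrative censoring uniform within ±2 years of the 10.2-year median
follow-up (a stand-in for staggered recruitment against a fixed end date).
Event times are sampled *exactly* by inversion of the piecewise-constant
cumulative hazards, using the same PAR/hazard pathway the projector uses —
generator and evaluator share one hazard definition, so self-calibration
closure is a genuine end-to-end test of the projection code, not of a
duplicated formula. Seven risk factors that model development considered
and rejected (smoking, alcohol, menopausal status, pill use,
breastfeeding, physical activity, soybean intake) are generated as
null-effect columns so variable selection has true negatives.

What the generator does not emulate: covariate dependence (defaults are
independent marginals per residence — a Gaussian-copula coupling with a
configurable rank correlation exists for sensitivity runs), calendar
trends, measurement error, informative loss to follow-up, and ER-subtype
heterogeneity. Consequences worth stating: with independent marginals the
cohort-estimated PARs equal $1-1/E_q[\mathrm{RR}]$ per group, which for
the under-50 segments is lower than published PARs estimated on real
(positively dependent) covariates; passing self-calibration here shows the
pipeline's internal consistency, not field calibration against real
registries.

## Problem sizes and statistical power of the test suite

The simulation-based tests run at n = 100,000 (parameter recovery,
variable selection; ~900 events) and n = 200,000 (calibration closure,
discrimination; ~1,800 events), with a fixed suite seed. Two checks sit at
the edge of attainability at these sizes, and the suite reports them
honestly rather than loosening them: retaining the weak family-history
effect (driven by a 2% prevalence category with HR ≈ 1.6) in backward
elimination needs roughly the full ~2,300-event scale of the source study,
and a ±10% band on all ten calibration deciles is about one Poisson
standard deviation for the low-risk deciles at ~80–100 expected events
each.

## Known limitations

The model applies to women 30–84 (rate-table coverage governs projection
bounds) and carries no confidence intervals on projected risks. PAR
variance is not estimated. Family history of any cancer overstates
inherited breast-cancer risk in the 2+ relatives category. The shipped
rate table is synthetic; substantive use requires registry rates. The
fitter supports no time-dependent covariates beyond the BMI segment
switch, no frailty terms, and no robust variance.
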