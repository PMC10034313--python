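# Methods

## The problem

Population-based cancer registries that rely on passive follow-up (linkage
to death notifications) systematically miss some deaths: name misspellings
break the linkage, and patients who emigrate out of the registry's catchment
area die where the registry cannot see it.  Such patients stay coded
"alive" and accumulate follow-up time forever.  Because genuine patients die
off while these phantoms persist, the bias grows with follow-up time; in
relative-survival terms the patient cohort eventually appears to outlive the
general population, with cumulative relative survival climbing past 100 %.
This package detects and removes such records so that long-term survival
estimates stay below (or at) population survival.

## Relative survival by period analysis

For a stratum of patients, observed cumulative survival S_obs(j) over annual
follow-up intervals j = 1..J is estimated with the actuarial life-table
method restricted to a recent calendar window (period analysis, default the
last 5 years of follow-up).  Person-time is decomposed per interval: a
record contributes to interval j iff the calendar time it spends in
follow-up interval (j-1, j] intersects the window; earlier diagnoses enter
late (left truncation), and records leaving the window are withdrawn.  The
interval estimator is

    p̂(j) = 1 − d(j)/n'(j),    n'(j) = n(j) − (w(j) + l(j))/2,

with deaths d, withdrawals w and late entrants l both weighted 1/2 (the
classic actuarial convention, applied symmetrically to delayed entry).
Variances are Greenwood's.

Expected survival uses the Ederer II principle: for interval j the annual
survival probability from the population life table — matched on sex,
attained age and calendar year at the interval start, in completed years —
is averaged over exactly the patients at risk in that interval, and the
cumulative expected curve is the running product of these means.  Relative
survival is RS(j) = S_obs(j)/S_exp(j), with se(RS) = se(S_obs)/S_exp
(the expected curve treated as fixed).  1-year conditional relative
survival is cRS(j) = RS(j)/RS(j−1).  Age standardisation applies the
International Cancer Survival Standard weights 0.19/0.52/0.29 to the age
groups 15–54/55–74/75+ and combines standard errors as sqrt(Σ w² se²).

Life tables cover single years of age up to 99 and a span of calendar
years; attained ages above 99 reuse the age-99 value, and calendar years
outside the table's coverage are clamped to the nearest covered year (some
registries begin decades before typical life-table series; clamping avoids
extrapolation).

## Cohort preparation and stratification

Death-certificate-only and autopsy cases are excluded; for multiple
primaries only the latest diagnosis is kept; ages below 15 are dropped.
Follow-up is administratively truncated at the estimation horizon — 35
years for patients diagnosed before age 55, 30 years otherwise — and a
record truncated before its death becomes a censored record (the truncation
is administrative censoring, so vital status at the truncation point is
"alive").

The detector runs within strata of diagnosis group × sex × age group at
diagnosis; a cell is further split by stage only when every observed
non-missing stage level holds at least 500 patients, in which case
missing-stage cases form an additional stratum.  This keeps the comparison
populations homogeneous in prognosis without creating unstable small strata.

## The detector

Within a stratum with at least one death:

1. **Trigger.** Relative survival is estimated.  Correction is attempted
   only if (a) RS significantly exceeds 100 % in some follow-up year
   (one-sided z-test at level α = 0.05), or (b) RS rises significantly after
   its minimum (one-sided z-test on RS(J) − RS(j*), j* = argmin RS, with
   combined standard error).  Both tests use the curve's standard errors;
   a regular cancer cohort fails both and is left untouched.

2. **Classifier choice.** If fewer than 10 % of the stratum's patients
   died, the deceased give too little information about the joint tail of
   (follow-up time, age at exit), so the scoring fallback is used directly;
   otherwise the logistic classifier runs first.

3. **Logistic path.** Deceased patients with both follow-up time and age at
   exit at or above the current percentile (start 99.9, marginal empirical
   quantiles with linear interpolation, ties included) are outlier events
   for the regression logit P(outlier) = β₀ + β₁·fu_age + β₂·fu_time,
   fitted by maximum likelihood on the deceased only.  If the fit has no
   events or does not converge (including separation, detected by exploding
   coefficients or standard errors), the percentile drops by 0.05 and the
   fit repeats.  If neither β₁ nor β₂ is Wald-significant at 0.05, the
   stratum switches to the scoring path.  Otherwise alive patients with
   predicted probability ≥ 0.90 are flagged, flagged records are excluded,
   and RS is re-estimated; the percentile then drops 0.5 points per
   iteration until the trigger tests pass.  Flag sets accumulate across
   iterations.  If the cumulative flags would exceed 5 % of the stratum's
   deaths (strict >), the logistic path is abandoned for the scoring path
   — an implausibly large flag set indicates that the regression is
   capturing genuine survivors (e.g. after large therapy advances).

4. **Scoring path.** Alive patients are ranked by the Euclidean norm
   √(fu_age² + fu_time²); those at or above the current percentile of this
   score (among the remaining alive) are flagged, with the same 99.9-start
   /0.5-step schedule, the same re-estimation loop, and the same 5 % cap —
   on reaching the cap the last flag set not exceeding it is returned.

5. **Termination.** The percentile schedule is strictly decreasing and the
   loop additionally stops at a percentile floor of 50 (the stopping tests
   or the cap almost always fire first; the floor guarantees finiteness).

Flagged records are always alive records; deceased records are never
reclassified.  Flagged persons are excluded from re-estimation entirely —
no death date is imputed.

## Synthetic cohorts

Because the real registry data are access-restricted, evaluation uses
synthetic cohorts built from a mixture cure model on top of life-table
background mortality.  Per patient: diagnosis date uniform over the
registry's operating years, age at diagnosis uniform over the stratum's age
range, an excess-event time that is infinite with probability equal to the
cure fraction and otherwise Weibull (default shape 1, i.e. exponential),
and a background death time sampled year-by-year from the life table.  The
observed death time is the minimum of the two, administratively censored at
follow-up end.  Missed deaths are injected by relabelling a uniform random
sample of the deceased (default 5 %, matching the heaviest published
injection level; 1 % and 2 % are also standard) as alive with exit at
follow-up end.

The default scenario is one stratum of 50 000 men aged 55–74 with a
colorectal-like prognosis — cure fraction 0.35, excess rate 0.15/year,
giving ≈ 66 % 5-year and ≈ 38 % 20-year relative survival — diagnosed
1976–2016 with follow-up ending 2016-12-31.  The default life table is a
stylised Gompertz table, q(x) = A·e^(0.095·x) capped at 0.7, with A chosen
so that male q(70) ≈ 2.3 %, constant over calendar years 1993–2016.
Experiments default to five replicates, with per-replicate seeds derived
from a single scenario seed.

What the generator does *not* emulate: calendar trends in incidence or
survival (screening introductions, therapy advances), registry-specific
coverage gaps, stage-dependent hazards within a stratum, or
correlated linkage failures.  Passing tests therefore show that the
algorithm recovers injected missed deaths under stationary conditions; on
real data with strong period effects the 5 % cap is the main guard, and the
cap value itself should be re-tuned to the registry's expected
missed-death burden.

## Evaluation metrics

For injected cohorts: sensitivity = |injected ∩ flagged|/|injected|·100 and
the false-positive share |flagged \ injected|/|flagged|·100, plus relative
survival before correction, after correction, and on the uninjected truth
cohort.  Typical behaviour at 5 % injection (50 000 patients): sensitivity
≈ 28 %, false positives ≈ 23 %, flags ≈ 2 % of deaths — the cap (5 % of
*observed* deaths, which is less than the injected count) makes full
recovery impossible by construction, and the stopping rule aims at curve
regularity, not at exhaustive identification.  Short-follow-up missed
deaths are structurally undetectable by this approach, so corrections
concentrate at long follow-up.  On clean cohorts the trigger essentially
never fires and flags stay at zero.

## Numerical choices and edge cases

- Follow-up time is day-level, (exit − diagnosis)/365.25.
- Percentiles: `numpy.percentile` with linear interpolation; comparisons at
  thresholds are inclusive (≥), so an all-ties stratum flags everything and
  the 100th percentile flags the unique maximum.
- Logistic fit: Newton, relative tolerance 1e-8, 100 iterations max.
- A curve interval with zero effective at-risk truncates the curve there.
- Empty strata, zero-death strata and empty window overlaps return empty
  results rather than erroring.
- The cap comparison is strict (flags may equal exactly 5 % of deaths).
- Totals tables round half-up to the displayed precision.

## Limitations

The method reclassifies but cannot date the missed deaths, so corrected
absolute numbers of deaths remain understated; short-term survival bias is
essentially uncorrectable; and for low-mortality cancers the classifier
cannot cleanly separate phantoms from genuine long-term survivors (high
false-positive share).  These are properties of the method itself, visible
in the simulation harness, not implementation artifacts.
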