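# Methods

This note documents the model, its assumptions, the numerical choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## State space and cycle structure

The disease process is a discrete-time Markov chain with a one-year cycle
over nine states: disease-free untreated, disease-free on statin, non-fatal
acute MI, non-fatal other IHD, non-fatal ischemic stroke (IS),
statin-induced diabetes, a transient recovered-myopathy episode, fatal
ASCVD and fatal non-ASCVD. The two fatal states are absorbing; the three
non-fatal ASCVD states are mutually reachable (comorbidity) and can
progress to either fatal state; nothing returns from an ASCVD state to
disease-free. Acute MI is a separate state from other IHD solely because
its admission cost is roughly double.

Expected-value cohort propagation (`x_{t+1} = x_t P_t`), not
microsimulation: all quantities are population expectations. No half-cycle
correction is applied by default — transitions are treated as occurring at
cycle boundaries, the convention of decision-tree cohort software; a
half-cycle option exists on `discounted_totals` for sensitivity checks.
The lifetime horizon runs to age 100; mass still alive then stops accruing
(with the default inputs, well under 10% of a mid-age cohort).

**Acute vs chronic staging.** Rather than tunnel states, the engine tracks
per-cycle *inflow* into each state alongside occupancy. Entrants to a
non-fatal state get the admission cost, the caregiver/patient wage loss,
and the acute utility weight over the hospitalization window
(days/365 at utility 0.5, remainder of the year at the chronic weight);
continuing occupants get chronic-stage values. This is exact for
expected values and keeps the visible state space small. The same inflow
bookkeeping yields the lifetime ASCVD event fraction (first-entry mass
summed over cycles, so moves between ASCVD states are not double-counted).

## Transition inputs

Transition probabilities live in a CSV keyed by
`(sex, age_group, risk_group, from_state, to_state)`, with nine 5-year age
bands 30–34 … 70–75 and risk groups `overall`, `eligible`, `non_eligible`.
Post-first-event rows are pooled over sex and age (wildcard `all`),
because subsequent events are too sparse to stratify; the whole-population
average is used wherever a cohort occupies a post-event state.

**Annualization.** Ten-year cumulative incidences are converted with
`r = 1 − exp(ln(1 − p)/10)`. The conversion is applied to each row's
*total* exit probability and the annual probability is allocated across
destinations in proportion to their cause-specific cumulative incidences.
Converting each cause separately looks natural but is wrong under
competing risks — marginal annualizations of competing incidences do not
add, and a ten-cycle run would systematically under-produce the input
incidence (we measured ≈4 percentage points in high-incidence strata).
With the total-then-allocate rule, ten cycles of the resulting matrix
reproduce both the total 10-year exit probability and the cause shares
exactly.

**Aging across bands.** Eligibility is decided once at model entry, so a
sub-cohort that enters at band *b₀* and ages into band *b* should not use
band *b*'s `eligible` rows — those describe people *screened at that age*.
Instead the stratum's hazard ratio vs the overall population, measured at
*b₀*, scales the overall age-specific hazards for the rest of the
lifetime. This keeps the eligible/non-eligible mixture consistent with
the overall population at every age (without it we measured ~13 pp of
threshold-dependent distortion in lifetime event fractions). Beyond age
75 the last band's probabilities are carried forward; an
`elderly_multiplier` option can scale them.

## Treatment model

While on statin, disease-free exit hazards are multiplied by relative
risks 0.67 (both non-fatal IHD states), 0.69 (non-fatal IS), 0.83 (fatal
ASCVD); non-ASCVD mortality is unchanged. Adverse events exit the statin
state at 0.30%/cycle (diabetes: lifelong chronic cost 835.87 USD/yr,
utility 0.84, ASCVD hazards of the untreated disease-free stratum — no
published diabetes-specific ASCVD modifier is assumed) and 0.24%/cycle
(myopathy: one hospitalization episode at utility 0.56 during the stay,
then disease-free off statin, no chronic cost). Discontinuation for other
reasons (11.86%, a trial-level overall rate) is applied once at treatment
start by moving that fraction of the eligible stratum into the untreated
state; an annual variant is available, in which discontinuation applies
to the event-free residual of each cycle (so a rate of 1 is
representable). Treatment is otherwise lifelong with constant efficacy.

## Costs, utilities, discounting

Societal perspective, 2019 USD (6.9 RMB/USD). Statin-treated disease-free
years accrue drug (61.43) + registration (52.17) + one risk-assessment
visit (4.35/yr; the visit is charged annually — the source prices it per
visit without a frequency). Indirect costs use the human-capital
approach: daily wage = annual salary / 365 calendar days (the denominator
is configurable), lost by the patient plus exactly one caregiver for the
admission duration, scaled by (1 − unemployment). Premature death before
retirement (default 60, configurable) charges the discounted remaining
wage stream once, at the death cycle; by default only fatal *ASCVD*
deaths are charged, since background mortality is common to all
strategies (`productivity_loss_non_ascvd=True` switches this).
Both costs and QALYs are discounted at 5%/yr (sensitivity range 0–8%),
cycle 0 undiscounted.

## Strategies and the frontier

Thresholds: 10–20% (soft model) and 5–15% plus 7.5% (hard model), 1%
steps, plus a no-treatment comparator. "Risk higher than the threshold"
is implemented as ≥ (ties treated). Screening happens once at entry; no
re-screening. Results are census-weighted mixtures over sex × age-band
sub-cohorts (weights default to a bundled synthetic approximation of the
2019 national population structure; any `sex, age_group, weight` CSV can
replace it). Following the comparability convention for pairing the
highest threshold with no treatment, the default grid evaluation runs the
no-treatment arm on the highest threshold's stratified table with
treatment off.

Frontier construction sorts by QALYs, removes strictly dominated
strategies (≥ cost, ≤ QALYs, strict on one axis; duplicates keep the
first listed, with a warning), then iteratively removes any strategy
whose adjacent ICER exceeds the next strategy's (extended dominance),
recomputing until the ladder strictly increases. The optimum at a
willingness-to-pay is the most effective frontier strategy with ICER at
or below it, falling back to the reference. Equal-QALY pairs are resolved
by cost before any ICER is formed.

## Sensitivity analysis

One-way analysis re-evaluates a user-supplied figure of merit (typically
a pairwise ICER) with one parameter at each bound, all else at base;
bounds are 95% CIs where published, otherwise ±15% or urban/rural values.
PSA samples every non-fixed parameter jointly: log-normal for relative
risks (`meanlog = ln(base)`, `sdlog = (ln hi − ln lo)/3.92`), beta for
proportions/utilities and gamma for costs/durations, both moment-matched
to mean = base, sd = (hi − lo)/3.92 — one 2×1.96 normal-range convention
throughout. Transition tables are not sampled (parameter uncertainty per
the input manifest only). Each iteration uses an independent substream
keyed by (seed, iteration), so results are order-independent and prefixes
reproduce. Infeasible draws (row sums > 1) are re-drawn and counted.
Per-iteration optimality for acceptability curves is maximum net monetary
benefit (QALYs × WTP − cost), which coincides with the ICER-ladder choice
on the frontier but is well-defined draw by draw; ties split evenly. The
default WTP grid is 0–40,000 USD/QALY in 500-unit steps.

## Synthetic cohort generator

The generator emulates the summary features of the (access-restricted)
study population, not its raw data: ages 30–75 drawn from the census
weights, ~42% men, ten regions (5 urban, 5 rural, fixed log-hazard
offsets ±0.1–0.25). Latent first-event hazards are log-linear —
0.08/year of age (hazard doubling ≈ every 9 years), +0.35 for men, with a
0.5-SD log-normal frailty. Calibration is deterministic given the
realized cohort and happens on two independent dials:

* **Predicted risk scores** are uniform rescalings of the latent hazard on
  the cumulative-hazard scale, pinned so the realized cohort medians equal
  9.8% (soft) and 5.2% (hard). Because both scores are monotone in the
  same latent hazard with hard < soft scale, `risk_soft ≥ risk_hard`
  holds individual by individual.
* **True event hazards** get one multiplier solved by Brent root-finding
  on the analytic expectation (competing with a Gompertz non-ASCVD death
  hazard, 0.004·e^(0.09(age−50))) so the expected 12-year soft-event
  fraction equals 16.9%; the hard-event share of first events is set by
  the 11.4%/16.9% ratio, split within hard events as MI 22% / IS 55% /
  fatal 23%.

Predictions and truth deliberately differ in level (real risk scores are
miscalibrated too); `recalibrate_risk` rescales predictions per region on
the log-cumulative-hazard scale to match observed regional means, the
standard regional recalibration operation, preserving within-region
ranking.

Follow-up simulation draws exponential first-event times, types them, and
gives non-fatal survivors subsequent events from fixed pooled hazards
until death or censoring (12 years default). The estimator recovers
10-year cumulative incidences as within-stratum proportions, treating
censoring as event-free (loss to follow-up in the emulated cohort is
negligible; a Kaplan–Meier-style correction was judged unnecessary at
<1% censoring before the window). Degenerate strata are reported missing
(warning), never zero; rows whose empirical exit probabilities reach 1
(tiny strata) are rescaled to just below 1 with a warning.

**What the synthetic tests show — and don't.** Passing parameter-recovery
tests shows the pipeline is internally consistent: generated hazards →
simulated events → estimated tables → cohort model reproduces the
generating quantities within Monte-Carlo error. It does not validate the
published cohort's transition inputs (not public), real-world statin
adherence, or risk-score discrimination; the synthetic world's absolute
costs, QALYs and optimal thresholds are its own. The published
strategy-level ladders bundled in `statin_cua.published` anchor the parts
that *are* checkable from printed numbers: ICER arithmetic, frontier
classification, and optimal-threshold selection.

## Problem sizes and determinism

The test suite and acceptance script use a 50,000-individual synthetic
study (risk-score medians are then exact to ≈±0.002 and event fractions
to ≈±0.004), a 4-threshold soft-model grid for pipeline-level properties,
and a 200-iteration PSA — sizes chosen so the full suite runs in about
two minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances. All randomness flows through seeded
`numpy.random.Generator` instances; identical seeds give byte-identical
cohorts, tables and PSA draws.

## Known limitations

* Transitions out of the diabetes state use untreated disease-free ASCVD
  hazards; a diabetes-specific ASCVD modifier is not modeled.
* A person who develops an ASCVD event after statin-induced diabetes
  retains the ASCVD state's costs/utilities only (the chronic diabetes
  cost stops), slightly undercounting comorbidity costs.
* The recovered-myopathy episode ignores within-cycle mortality (one
  cycle, then disease-free).
* Statin disutility (0.999) applies only in the disease-free state, not
  within chronic disease states; configurable via the utility set.
* Hazards beyond age 75 carry the last band forward unless an elderly
  multiplier is supplied; life expectancy at old ages is therefore
  optimistic in the synthetic world.
* The printed ladders are rounded to 2 decimals (cost) and 4 (QALYs);
  ladder ICERs recomputed from them can differ from unrounded-internal
  values by a few percent where QALY gaps are ~1e-3.
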