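# Methods

## Scope and data model

The pipeline analyzes a fattening cohort recorded as four tables:
an animal roster (`animal_id`, `start_date`, optional
`age_at_start_days`), genotype calls per animal × marker, dated body
weights (kg, roughly monthly), and daily dry-matter intake (kg).  All
tabular I/O is CSV (UTF-8, header row, `.` decimal).  Genotype strings are
normalized by sorting allele symbols lexically, so `CT` and `TC` are the
same heterozygote and "first homozygote" always means the lexically
smaller allele.

The roster's `age_at_start_days` column is an extension of the minimal
layout: the association model uses *age at the trait's reference point* as
a covariate, and without an entry age that covariate would coincide
exactly with the days-to-reach response for DTR traits.  Readers default
the column to 0 (age becomes days on feed) when it is absent.

## Trait derivation

Days to reach a target weight (DTR) is the first upward crossing of the
weight trajectory, linearly interpolated between the two bracketing weigh
records; an exact hit returns the record's day; on a locally decreasing
series the *first* crossing wins.  No extrapolation is performed in either
direction — an animal whose records never attain a target contributes NaN
to every trait anchored on it and is thereby dropped from those analyses.

Interval DMI integrates the daily step function between two fractional DTR
endpoints, pro-rating the boundary days by fractional coverage.  The gain
denominator of interval FCR and ADWG is the *target* difference (exactly
100 or 50 kg), so FCR·ADWG = DDMI holds to machine precision — an identity
the test suite asserts on every simulated animal.  Totals run from DTR_W1
to the last weighing: TADWG = (FW − W1)/days, TFCR = TDMI/(FW − W1).
Whether the total window should instead start at day 0 is ambiguous in the
trait definitions; anchoring at W1 keeps every analyzed state inside the
interpolable range.

Season is the meteorological quarter of the calendar date (Dec–Feb
winter, Mar–May spring, Jun–Aug summer, Sep–Nov autumn).  Covariate
anchoring per trait: DTR_Wk at Wk, interval traits at the interval's end
target, totals and FW at the final weighing.

## Population genetics

Allele frequencies are count-derived: p = (2·hom₁ + het)/2n.  The HWE test
is a Pearson chi-square of the observed genotype counts against
n·(p², 2pq, q²) with exact frequencies, df = 1, no continuity correction; a
class observed zero times still contributes (0−E)²/E, and a monomorphic
marker raises an error rather than returning a meaningless statistic.

The diversity indices (Ho, He, Ne, PIC) are generic Σ-formulas over the
frequency vector.  In the summary path they are evaluated, by default, on
frequencies rounded to 2 decimals (`freq_decimals=2`).  This is the
*reported-precision convention*: published index tables for panels of this
kind are computed from the allele frequencies as reported, and only this
convention reproduces the packaged reference values at 4 decimals (exact
frequencies shift e.g. a Ho of 0.6568 to 0.6554).  The chi-square, by
contrast, reproduces only from exact frequencies.  Both behaviours are
explicit parameters, not silent defaults buried in the pipeline.

## Association model

Per trait × marker the model is y = μ + βA + S_j + G_k + e — fixed effects
only; nothing random beyond the residual is specified, so the fit is OLS
(statsmodels) on a reference-coded design (sorted levels, first level
reference).  Rank deficiency raises an error naming the aliased columns
(via column-pivoted QR) instead of silently dropping terms.

Term significance uses partial (Type III) F-tests: the full model against
the model with the entire term removed.  With genotype classes as
unbalanced as 10 vs 208 animals, sequential sums of squares would depend
on term order; the partial test does not (and equals Type II here since no
factor interactions are fitted).

Least-square means fix the age covariate at its sample grand mean and
weight all season levels equally (1/k); SEs come from x'·Cov(β)·x.  Tukey
comparisons are Tukey–Kramer on LSM contrasts: q = √2·|Δ|/SE(Δ) referred
to the studentized-range distribution with the model's residual df, which
reduces exactly to the two-sided t-test at k = 2.  Compact letters are the
maximal cliques of the "not significantly different" graph, lettered in
descending order of the clique's largest LSM (ties by level name); two
levels share no letter if and only if their adjusted p < α.

Interaction fits concatenate per-marker calls into a combination factor
("CCxAA"); combinations with fewer than `min_count` animals (default 3 —
the conventional "very low frequency" cut, configurable) are excluded and
logged with a machine-parsable reason code before fitting.

Model choice among candidates uses adjusted R², ties resolved toward fewer
parameters, deterministically.  No multiple-testing correction is applied
across the marker × trait grid — each test is reported at its nominal p,
matching standard practice for candidate-gene screens; an FDR column can
be added downstream without affecting any output here.

## Gene action

a = (M22 − M11)/2 and d = M12 − (M11+M22)/2 on least-square means, so the
effects inherit the model's covariate adjustment; the sign convention
(first-listed homozygote as subtrahend) follows the reference tables.  The
degree of dominance d/a is flagged undefined, not computed, when |a| falls
below 1e-9 of the means' scale.  A marker missing a genotype class (e.g.
one whose minor-allele homozygote never occurs) is reported not-estimable
rather than dropped.

## Synthetic herds

The generator emulates the study conditions the analysis assumes: 296
bulls by default, the packaged 15-marker panel with count-derived allele
frequencies and per-marker HWE-departure coefficients solved from the
reference genotype counts (f = 1 − het/2pq, so expected genotype
proportions equal the observed ones), monthly weighing from ~85 kg entry
weight past 450 kg, daily DMI, and entry dates spread over a calendar
year so all four seasons occur.

Growth is a daily latent-gain process: gain = baseline (0.9 kg/day,
targeting the ~0.9 kg/day total ADWG scale of commercial Holstein
fattening) + genotype (−a/d/+a per marker) + season (±0.02–0.03 kg/day
shifts) + animal (SD 0.08) + a residual redrawn each weigh interval
(SD 0.10 kg/day).  Observed weights read the latent trajectory at weigh
days, which makes planted effects exact on the ADWG scale.  Intake is
metabolic-weight driven, DMI = 0.10·W^0.75 + genotype + noise (SD 0.3),
spanning roughly 4.5 kg/day at 150 kg to 9.5 kg/day at 450 kg.  Entry age
is ~100 ± 10 days, putting simulated slaughter ages near 500 days.

All randomness flows from one integer seed through `numpy` seed
sequences; each animal owns a substream keyed by its index, so cohorts are
bit-reproducible and per-animal trajectories are stable under partial
regeneration.  With every SD at zero the trajectories are exactly linear,
which the closed-form tests exploit.

What the generator does *not* emulate: growth-curve curvature (gain is
piecewise constant in expectation, so interval ADWGs do not decline with
age as real finishing data do), sire/pedigree structure, climate beyond a
seasonal shift, or intake–gain feedback.  Consequently, passing tests
demonstrate the correctness of the estimators under the stated generating
model — unbiased planted-effect recovery, calibrated error rates — not the
biological realism of any particular fitted value.

One interaction of generator and model deserves note: because
time-to-weight is gain-determined in the simulation, age at a trait's
endpoint is nearly collinear with rate traits, and including the age
covariate absorbs planted gain effects.  The recovery checks therefore fit
gain-planted traits without the age covariate (intake-planted traits keep
the full model, where age is benign).  In real cohorts entry age varies
independently of growth rate and the covariate is informative rather than
collinear.

## Numerical and testing choices

Problem sizes in the test suite: error-rate calibration uses 1000–1500
replicates of n = 296 (acceptance) and 300 (unit); planted-effect recovery
averages 100 seeded herds of 296 animals and checks the mean against the
planted value within 2 Monte-Carlo standard errors; the normal-equation
oracle cross-checks 20–25 random unbalanced designs of n ≤ 30 at 1e-8.
Published-value regressions allow for the print precision of their inputs:
indices at 4 decimals, chi-squares to ±0.002 (last-digit rounding of the
source), gene-action effects to the rounding the 2-decimal (or integer)
published means can propagate.  Hypothesis-based property tests run
derandomized.
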