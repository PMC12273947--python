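# Methods

This note documents the statistical model, the data-correction
procedure, the synthetic-data generator and the numerical choices behind
`mortrend`.

## Cause taxonomy

Underlying causes are ICD-10 codes. Suicide is X60–X84 or Y87.0
(sequelae of intentional self-harm), split into hanging (X70), firearm
(X72–X74), poisoning (X60–X69) and other mechanisms (X71, X75–X83).
Two codes carry no mechanism information and are placed in the "other"
group by construction: X84 (unspecified means) and Y87.0. Four-character
subcodes inherit their three-character classification (X70.9 is
hanging), since registry extracts routinely carry 4-character codes
while analysis groups are defined at the 3-character level.

Garbage codes — codes uninformative for cause-of-death analysis — are
declared in a YAML map as non-overlapping 3-character ranges assigned to
named groups (e.g. undetermined intent, Y10–Y34). Each group lists its
target cause groups and a redistribution mode. The engine is agnostic to
the map's content; the packaged default map and weight table are
synthetic stand-ins with plausible values, clearly marked, because the
empirical weights used in real analyses come from country-specific death
investigations and are not redistributable here.

## Correction of counts

The correction runs in two steps, in the order the registry's quality
problems are usually treated:

1. **Missing demographics.** A record with unknown sex and/or age group
   has its unit weight split across the fully specified (sex, age-group)
   cells observed among records of the same year and cause category,
   proportionally to their weight, conditioning on whatever the record
   does carry (a known age restricts the split to that age group).
   Sparse strata fall back to the year-level mix, then to a uniform
   split over male/female × the analysis age groups; every fallback is
   logged and counted.

2. **Garbage-code redistribution.** Directly coded records aggregate
   into (year, sex, age-group, cause-group) cells. Garbage-coded weight
   is then moved to the group's target causes, by empirical weights
   w(group, stratum, target) that sum to one within each stratum
   (*empirical* mode; a stratum absent from the table falls back to the
   group's all-strata average weights), or proportionally to the
   directly observed target mix in the same cell (*proportional* mode;
   an all-zero mix splits uniformly). Both fallbacks are logged.

Total weight is conserved to 1e-9 at every step, and corrected suicide
mass is cell-wise ≥ directly coded mass, by construction; both are
enforced as invariants in the tests. Weight strata are sex × age-group
(no year dimension) by default, matching the single national weight set
such analyses typically rely on; year-stratified tables are accepted if
supplied. Fractional corrected counts are carried unrounded into rate
estimation; rounding is display-only.

Redistributed suicide mass initially carries no mechanism. It is split
across the four method groups proportionally to the directly coded
method mix of its (year, sex, age-group) cell, falling back to the
year-level mix, then uniform. The assignment rule is this package's
choice — investigation-based sources typically say where garbage deaths
go, not by which mechanism — and redistributed mass remains identifiable
(a `source` column) so the rule can be changed without refitting
anything upstream.

## Rates and summaries

Rates are 100 000 × deaths / person-years; fractional deaths are
allowed. Age groups use completed years with inclusive bounds (10–14,
15–19; adolescents are their union). Percent change over a period is
100·(last − first)/first on the series endpoints. The male:female
summary reports yearly ratios rounded to 2 decimals and their arithmetic
mean rounded to 1 decimal; the mean is taken over unrounded ratios.
(The ratio-of-means alternative agrees to 1 decimal on the packaged
series.)

## Joinpoint trend model

For yearly rates r(t), the model is continuous piecewise linear in
ln r(t) with hinge terms at joinpoints placed at observed years. For
each candidate number of joinpoints k = 0..k_max, every admissible
placement is fitted by least squares and scored with

    BIC(k) = n · ln(SSE/n) + (2k + 2) · ln(n).

Each joinpoint is charged two parameters — its location and its slope
change — the convention of the standard joinpoint surveillance software.
Charging only the slope change (p = k + 2) makes the penalty far too
weak: on 23-point series it routinely selects three joinpoints through
noise. Exact BIC ties resolve to fewer joinpoints, then to the earliest
placement. The selection was verified against brute-force enumeration on
randomized short series.

**Minimum segment length.** Boundary indices (the data ends and every
joinpoint) must be at least `min_obs_per_segment` (default 4)
observations apart: each segment contributes four observations beyond
the boundary it shares with its predecessor. The alternative reading —
four observations counting both endpoints — admits 4-year tail segments
which, on 23-year series with a strong late rise, lets the selection
split the final decade in two on rounding-level BIC margins.

**Weighting.** Least squares can be precision-weighted. For rates
derived from Poisson death counts, var(ln r) ≈ 1/count, so
`weighting="count"` uses supplied counts and `weighting="rate"` uses the
rate itself as a proxy when denominators are unavailable but roughly
constant over the window. The default is unweighted (`"none"`), the
right choice under homoscedastic log-scale noise. On the packaged
corrected-rate series — printed to two decimals, which puts rounding
noise of similar magnitude on small and large rates alike —
rate-weighting is what reproduces the published segment structure
exactly; unweighted fitting shifts one breakpoint by a year on a
near-tie.

**APC, AAPC, labels.** Segment slopes b are cumulative sums of (β₁,
δ₁…); APC = 100·(e^b − 1). The AAPC over a period is
100·(exp(Σ wᵢ bᵢ) − 1) with wᵢ the fraction of the period's year
intervals spanned by segment i. Trends are labelled Increasing /
Decreasing / Stable according to whether the CI excludes zero from
below / above / not at all, and p-values are binned (<0.05, <0.01,
<0.001) for table display.

**Confidence intervals.** The parametric method uses t intervals with
df = n − (2k + 2) and the fit covariance, conditional on the selected
joinpoints. Such intervals are known to undercover when the breakpoint
is estimated: in the package's own recovery study (one true break,
σ = 0.05 log-noise, 23 points), their coverage of the true segment
slopes is 78–84 % at nominal 95 %. The `ci_method="bootstrap"` option
therefore resamples the fitted path parametrically (variance from the
weighted residuals), re-searches the placement at the selected k on
every resample, and takes percentile intervals of the resampled
APC/AAPC; this restores coverage to about 90–93 % in the same study and
is the recommended method for inference. Residual undercoverage of a
point or two remains when the number of joinpoints itself is selected on
noisy data — a known post-selection effect, not removed by any CI method
implemented here.

**Numerical edge cases.** Zero rates are undefined on the log scale;
the default policy raises, and `zero_rate="substitute"` replaces zeros
by half the smallest positive rate (logged). SSE values below n·1e-16
(residual RMS < 1e-8 on the log scale) are treated as exactly zero so
that noiseless series tie on BIC and resolve to the simplest model
instead of competing on floating-point rounding. The continuity of the
fitted path at each joinpoint holds to 1e-10 and is asserted in tests.

`max_joinpoints` defaults to 3 for series of ≥ 20 points, otherwise to
the most the minimum-segment rule admits.

## Synthetic registry generator

The generator emulates a national vital-registration extract. Per
(year, sex, age-group) cell: the true suicide rate follows a configured
piecewise log-linear path (geometric compounding within phases, exact
kinks at phase starts); suicide counts are Poisson with mean
rate × population / 1e5 (rare-event counts; the standard surveillance
assumption), split across mechanisms by a multinomial mixture and given
concrete ICD-10 codes; other cause groups draw Poisson counts around
constant rates. Degradation is applied per record so that the correction
steps face realistic joint missingness: with channel probabilities
p(cause → gc-group | cell) the code is replaced by a code from the
garbage group, and sex/age are masked independently. Degradation never
adds or removes records, and every corruption is logged in the returned
ground truth (realised true counts per mechanism, expected rates,
mislabelling and masking tallies).

`channels_from_weights` inverts a redistribution weight table into
channel probabilities: expected mislabelled mass from cause c equals
M · w(g, stratum, c) for a chosen per-cell garbage load M, so the
expected composition of garbage deaths equals the weight table and
redistribution with that same table is unbiased for the true counts.
This is the configuration under which end-to-end recovery is tested
(mean relative error of corrected suicide counts < 2 % across cells
over 50 replicates).

The packaged study-like configuration uses 23 years (2000–2022), four
sex × age-group strata with populations near 8.5 million (declining
0.4 %/year), baseline suicide rates near the observed 2000 values
(0.61–4.65 per 100 000), one trend break per stratum between 2009 and
2014 with late-phase APCs of 4.8–10.6 %, a mechanism mixture of
hanging 0.66 / poisoning 0.16 / firearm 0.11 / other 0.07, other-cause
rates of 6–18 per 100 000, mislabelling probability drifting from 0.34
down to 0.20 (2017) and back to 0.25 (U-shaped data-quality history),
and missingness of 0.5 % (sex) and 1 % (age).

What the generator does *not* emulate: spatial structure, registration
undercoverage (all deaths are registered), year-varying redistribution
weights, and non-Poisson overdispersion. Passing recovery tests
therefore show the pipeline's internal consistency — correction inverts
the mislabelling it models, trends are recovered under log-Gaussian
noise — not robustness to weight misspecification, which in real use is
the dominant caveat and should be addressed by sensitivity analysis over
the weight table.

## Problem sizes used in the test suite

Property suites run at: 100 random record sets (~100 records each) for
conservation/monotonicity; 50 randomized short series (9–15 points,
≤ 2 joinpoints) for oracle equivalence; 200 noisy replicates
(23 points, σ = 0.05, 1000 bootstrap resamples each) for the recovery
study; 50 full synthetic-registry replicates (~350 000 records each)
for end-to-end unbiasedness. The recovery study fits the one-break
model (`max_joinpoints=1`), isolating location and slope uncertainty;
free model-count selection is validated separately by the
oracle-equivalence and BIC-nesting tests.
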