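# Methods

## The design and why it licenses an exact test

`scedkit` analyses replicated randomized single-case experimental
designs (SCEDs) with daily ordinal outcomes. Each participant's course
has a fixed total length (default 96 days) partitioned into baseline
(A), treatment (B, fixed at 56 days) and follow-up (C). The baseline
length — and hence the treatment start point — is randomized over an
admissible range (default 7–26 days, stratified 7–11 / 12–19 / 20–26
with cyclic allocation of participants to strata in enrollment order).
Follow-up absorbs the remainder, so with the defaults it spans 14–33
days and there are exactly 20 admissible designs.

Because the start point was randomized over a known finite set, the
null distribution of any test statistic is obtained *exactly* by
recomputing it under every admissible design on the same observed
series. No noise model (and in particular no autocorrelation
adjustment) is needed for validity: the inference is design-based.

## Daily measures

Five items are answered daily on a raw 1–10 scale and recoded to 0–9.
Items 1–3 sum to the daily anxiety score (0–27); the sum requires all
three items, with no rescaling of partial sums. Item 4 (impact, 0–9)
and item 5 (value-based action, 0–9) are scored individually. Item 5
is oriented opposite to the others — higher is better. We keep the
recoded value unchanged and propagate an improvement direction
(`increase`) into the analytics; an optional `reverse_item5` switch
applies the arithmetic flip `9 − x` for users who prefer all outcomes
on a higher-is-worse scale. Only responses answered on the day they
were prompted are valid; late answers score as wholly missing. There
is no imputation anywhere: every statistic uses observed values only,
and missingness is reported per participant and overall as
`100 × n_missing / n_expected` to one decimal.

## Quantified visual analysis

Per outcome and phase the package computes level (mean), variability
(min, max, range), and trend; across phase boundaries it computes
level change (later mean minus earlier mean, so negative = the outcome
fell), immediacy (mean of the first *k* observed treatment values
minus the mean of the last *k* observed baseline values, default
*k* = 3), and the percent of overlapping data (POD).

POD counts later-phase points not improved beyond the most favorable
value of the earlier phase: for a decrease-is-better outcome, points
strictly above the earlier phase's minimum; mirrored (strictly below
the earlier maximum) for increase-is-better outcomes. 0% between A
and B indicates a perfect effect. Points exactly tied with the
earlier extreme count as *not* overlapping by default — the strict
reading of "above the lowest value" — with a `ties=overlap` switch for
the non-strict rule. The choice matters for flat series: a constant
series has POD 0% under the strict rule and 100% under the non-strict
rule; both are reported with the tie rule echoed in every output.

Trend lines are ordinary least squares of value on absolute day index
within the phase by default. OLS was chosen as the default because it
is reproducible and closed-form checkable; the traditional
split-middle median line of visual analysis (line through the median
day/value points of the two halves, middle point dropped for odd *n*)
is available as `trend_method=split_middle`.

## Randomization test and p-value combination

The test statistic is MeanA − MeanBC: the baseline mean minus the
pooled mean of treatment and follow-up (pooled because follow-up
introduces no new intervention). Positive values mean the outcome was
lower after treatment entry. The default test is one-sided in that
improvement direction, matching the directional hypothesis and the
fact that a uniquely most extreme observed statistic among 20
scenarios gives p = 1/20 = 0.05; `two_sided` and `less` are options,
and the sidedness is echoed in every report. Ties with the observed
statistic count as extreme (conservative), so p ≥ 1/n always, and
attainable p values are exactly {k/n}. Tie detection uses an absolute
tolerance of 1e−12 on the statistic. The null set defaults to all
admissible designs; a stratum-restricted variant exists for
sensitivity analysis. A candidate scenario whose baseline or pooled
side contains no observed value is excluded from the null set with a
logged warning and n reduced accordingly; if the *observed* design has
an empty side the test is undefined and raises.

Per-participant p values are combined with the Edgington additive
method: under the joint null the p values of independent cases are
(stochastically no smaller than) independent uniforms, so their sum S
is referred to the Irwin–Hall CDF,

    P(Σ U_i ≤ S) = (1/n!) Σ_{k=0}^{⌊S⌋} (−1)^k C(n,k) (S − k)^n.

The alternating closed form is evaluated exactly with integer
binomials; it can leave [0, 1] only through floating error near S = n
and is clipped. The tests cross-check it against
`scipy.stats.irwinhall` and a Monte-Carlo sum of uniforms.

Note that with discrete, conservative component p values the additive
combination is itself conservative; this is inherent to the small
number of admissible start points, not a numerical issue.

## Tau-U

Tau-U is a Kendall-type nonoverlap effect size comparing baseline with
the pooled B∪C phase: `s_cross` sums sign(value_j − value_i) over all
cross-phase pairs, so negative values indicate the outcome fell.
With baseline-trend correction (the default) the within-baseline
signed pairs `s_trend_a` are subtracted and the denominator is
`n_A·n_BC + n_A(n_A−1)/2`; the simple variant is `s_cross/(n_A·n_BC)`.
Published Tau-U variants differ in exactly this denominator, so the
variant used is recorded in every result. Pairs involving missing
days are simply absent (pairwise deletion). Trend correction needs at
least two observed baseline points; below that an explicit
insufficient-data result (NaN, with the counts) is returned rather
than an exception.

## Synthetic cohorts

The generator exists so the whole pipeline is testable end to end on
data with the structure the analysis assumes. Per participant, a
latent process `x_t = μ_t + e_t` has stationary AR(1) noise `e_t`
(lag-1 coefficient φ, innovation SD σ) around a piecewise-linear mean:
`baseline_level` through phase A and the first `onset_delay_days` of
B, then a linear decline by `effect_size` over `ramp_days`, then flat
(a step shape is available for contrast). Observed scores are the
latent values rounded and clipped to the outcome bounds; impact is the
same latent scaled to 0–9 and value-based action its mirror image, so
the three outcomes cohere within a participant. Each day's response
is missing completely at random, and a missing day drops all three
outcomes at once (the daily items arrive in a single message).

Defaults: baseline level 12 on the 0–27 scale with noise SD 3 and
φ = 0.5 — a moderately anxious, visibly variable, serially dependent
series; effect size 9 beginning 21 days after treatment entry and
accruing over 28 days, i.e. a delayed gradual response consistent with
exposure-based work starting mid-program; missing rate 0.237. The
true within-person variance and autocorrelation of such daily-report
data are not identifiable from published summaries, so these are
exposed configuration, not asserted facts.

What passing tests on synthetic data do and do not show: they verify
the arithmetic and the design-based validity of the test (rejection
rate ≤ nominal under the null with the start point drawn uniformly),
and the round/clip/MCAR machinery. They do not validate the latent
model against real daily self-reports — real missingness is unlikely
to be MCAR, floor effects may be stronger than round-and-clip implies,
and real effects need not be piecewise linear.

## Numerical and degenerate-input choices

- Day indexing is 1-based; phase boundaries are closed; the treatment
  start day is the first day of phase B.
- Empty phases yield explicit insufficient-data results (NaN fields
  plus observed counts) so reports always render; only undefined
  *observed* test scenarios raise.
- Display rounding: mean changes to one decimal, POD to whole percent,
  p and Tau-U to two decimals, with p ≥ .995 rendered "≥.99";
  underlying values are kept at full precision everywhere.
- Child random streams for cohort members are spawned from the master
  seed (`numpy` SeedSequence), so cohorts are reproducible and
  participants independent.

## Problem sizes used in the checks

The statistical property checks run at desk scale: 2,000 null series
for the rejection-rate bound at α ∈ {.05, .10, .25}; 500 random short
series against exhaustive pair/count oracles for Tau-U and POD;
10^5 Monte-Carlo draws for the Irwin–Hall cross-check; 20,000-day
series for autocorrelation and missing-rate recovery. These sizes give
3–4-standard-error margins on every bound.

## Known limitations

- The randomization test's granularity is coarse: with 20 admissible
  start points the smallest attainable p is 0.05, and combining four
  such tests cannot reach conventional thresholds unless most
  components are near their minimum.
- Multiple-baseline designs with simultaneity constraints across
  participants are not modelled.
- Consistency of data patterns across participants (the sixth visual
  feature) is supported only by side-by-side tabulation; the judgment
  is the analyst's.
- Questionnaire handling is total-score arithmetic only; no
  psychometrics.
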