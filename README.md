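# scedkit

Analysis tools for **replicated randomized single-case experimental
designs (SCEDs)** with daily ordinal outcomes — the kind of N-of-1
anxiety trial where a handful of participants answer a short text-message
questionnaire every day for ~3 months, the start of treatment is
randomized, and the question is whether anxiety fell after treatment
entry.

It is written for trialists and methodologists running or re-analysing
such designs. The package covers the full pipeline:

- **Phase designs** — enumerate and draw the admissible baseline (A) /
  treatment (B) / follow-up (C) partitions of a fixed-length course
  (default: 96 days, 56-day treatment, baselines 7–26 days in three
  strata → 20 admissible designs).
- **Daily measures** — validation, 1–10 → 0–9 recoding, the daily
  anxiety sum (items 1–3, range 0–27), impact and value-based action
  (0–9), same-day validity, missingness bookkeeping, CSV I/O.
- **Quantified visual analysis** — level, variability, trend (OLS or
  split-middle), immediacy at the phase boundary, and percent of
  overlapping data (POD) per phase pair.
- **Inference** — the exact randomization test over all admissible
  treatment start points with the mean-difference statistic
  `MeanA − MeanBC`, Edgington's additive p-value combination across
  participants, and Tau-U effect sizes with baseline-trend control.
- **Synthetic cohorts** — a generator producing bounded AR(1) daily
  series with a delayed, gradual treatment effect and MCAR missingness,
  so the whole pipeline is testable end to end.
- **Questionnaires** — total scores for the secondary outcome scales at
  the four assessment points.

## The statistics in brief

Because the treatment start point is randomized over a known set of
`n` admissible designs, the null distribution of the statistic

    T = mean(A) − mean(B ∪ C)

is obtained exactly by recomputing `T` under every admissible design on
the same series. The one-sided p value counts scenarios with `T` at
least as extreme as observed (ties included), so attainable p values
are exactly `{k/n}` and the smallest is `1/n` (0.05 with 20 designs).
Per-participant p values are combined with the Edgington additive
method: the sum `S = Σ pᵢ` is referred to the Irwin–Hall CDF

    P(Σ Uᵢ ≤ S) = (1/n!) Σ_{k=0}^{⌊S⌋} (−1)^k C(n,k) (S − k)^n.

Tau-U compares all baseline-vs-later pairs,
`τ = (S_cross − S_trendA) / (n_A·n_BC + n_A(n_A−1)/2)`, subtracting the
baseline's internal trend pairs. See `docs/methods.md` for assumptions,
tie rules and variants.

## Worked example

```python
import scedkit as sk

cohort = sk.simulate_cohort(4, master_seed=7)       # 4 synthetic cases
reports = [sk.analyze_participant(p.series, p.design)
           for p in cohort.participants]
print(sk.table2(reports))                           # mean change + POD
table, combined = sk.run_inference(cohort)          # randomization tests
print(table)
```

which prints (mean level changes and POD for daily anxiety):

```
participant_id  mean_change_A_to_B  mean_change_B_to_C  pod_A_to_B_percent  pod_B_to_C_percent
            P1                -4.1                -7.2                  57                  29
            P2                -0.3                -5.2                  78                  93
            P3                -1.4                -6.7                  83                  71
            P4                -3.8                -5.4                  40                  65

participant_id  observed_stat  p_value p_display  tau_u
            P1       6.681818     0.25       .25  -0.63
            P2       1.504545     0.85       .85  -0.13
            P3       3.398707     0.95       .95  -0.24
            P4       5.196154     0.90       .90  -0.59
  All combined            NaN     0.95       .95    NaN
```

Negative mean changes say anxiety fell from one phase to the next;
POD 0% would mean every later point improved beyond the best baseline
value. `observed_stat` is `MeanA − MeanBC`; each p value is exact over
the 20 admissible start points (so it cannot go below .05), and the
final row is the Edgington combination across the four cases. These
simulated cases carry a *delayed* effect, so the baseline-vs-everything
mean difference is diluted and individual p values stay large even
though Tau-U and the B→C changes show clear improvement — exactly the
granularity/delay interplay the design has to contend with.

The same pipeline runs from the shell:

```bash
scedkit report --n 4 --seed 7 --outdir out/   # simulate → score → analyze → randtest
scedkit simulate --config examples/config.yaml --n 4 --out daily.csv
scedkit score --raw daily.csv --designs daily.designs.json --out scored.csv
scedkit analyze --scored scored.csv --designs daily.designs.json --out table2.csv
scedkit randtest --scored scored.csv --designs daily.designs.json --out rt.json
```

Every analysis artifact carries a config echo (sidedness, tie rule,
Tau-U variant, seed) so a run is reproducible from its outputs alone.

## Layout

- `src/scedkit/design.py` — phase designs, enumeration, stratified draws
- `src/scedkit/daily.py` — daily items, scoring, missingness, CSV I/O
- `src/scedkit/questionnaires.py` — secondary-outcome total scores
- `src/scedkit/simulate.py` — synthetic cohort generator
- `src/scedkit/visual.py` — quantified visual analysis
- `src/scedkit/inference.py` — randomization test, Edgington, Tau-U
- `src/scedkit/cli.py` — `scedkit` command-line pipeline
- `docs/methods.md` — models, assumptions, design choices, limitations
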