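# errormatrix

Overview clinical intervention evidence at a glance.

When a clinician or guideline developer asks "should we use this
intervention?", the retrieved evidence is usually a mixed bag: a
meta-analysis here, a large trial there, a handful of small or biased
studies, and an expert guideline with no data at all. `errormatrix`
organises such a body of evidence along the three dimensions that
determine its reliability and assembles them into a four-step "error
matrix":

* **systematic error** ('bias') — an ordinal levels-of-evidence scale
  from 1a (meta-analysis of randomized trials with low risk of bias)
  down to 5 (expert opinion);
* **random error** ('play of chance') — the standard error of the log
  effect measure, classified into five named bands
  (ignorable < 0.10 ≤ small < 0.20 ≤ moderate < 0.30 ≤ substantial
  < 0.50 ≤ high);
* **design error** (external validity) — outcome importance on the GRADE
  1–9 scale (9 = most critical, e.g. mortality).

The four steps: **I** scatter studies by (level of evidence, SE) for one
outcome; **II** grid studies over (level × outcome importance); **III**
build a benefit/harm "Manhattan" bar landscape in which the tallest bars
on the "upper-west side" are the best evidence; **IV** report effect size
and direction (e.g. number needed to treat) — but only for outcomes whose
best evidence passes a validity screen.

## The statistics

For a 2×2 table with `a`/`b` events/non-events of `n1` intervention
patients and `c`/`d` of `n2` control patients (`N = n1 + n2`):

```
RR        = (a/n1) / (c/n2)          SE[ln RR] = √(1/a + 1/c − 1/n1 − 1/n2)
OR_Peto   = exp(Z/V)                 SE[ln OR_Peto] = 1/√V
  Z = a − n1(a+c)/N                  V = n1·n2·(a+c)·(b+d) / (N²(N−1))
```

Fixed-effect pooling over trials *i*:

```
RR_MH = R/S          SE[ln RR_MH]      = √(P/(R·S))
                       P = Σ [n1·n2·(a+c) − a·c·N]/N²,  R = Σ a·n2/N,  S = Σ c·n1/N
OR_Peto (pooled)     SE[ln OR_Peto]    = 1/√(Σ V_i),  point = exp(Σ Z_i / Σ V_i)
```

Meta-analyses reported only as an estimate with a 95% CI are placed on
the same scale by back-calculation, `SE = (ln U − ln L) / (2·1.959964)`.
Natural logs throughout; zero-event cells get no SE (code `Z`) rather
than a continuity correction.

## Worked example

Two packaged study tables reproduce published worked examples:
`example1` (peri-operative beta-blockade vs placebo for major non-cardiac
surgery, four graded outcomes) and `example2` (class 1a antiarrhythmics
for maintaining sinus rhythm after cardioversion of atrial fibrillation).

```python
>>> from errormatrix import (TwoByTwoTable, se_ln_rr, se_from_ci,
...                          load_fixture, best_available, build_step3)
>>> se_ln_rr(TwoByTwoTable(10, 90, 20, 80))   # a trial with its counts
0.36055512754639896
>>> se_from_ci(2.39, 1.03, 5.59)              # a review reporting OR + 95% CI
0.4314927463634976
>>> records, specs = load_fixture("example2")
>>> best_available(records, "all-cause mortality")[0].study_id
'PAFAC'
>>> panels = build_step3(records, specs)
>>> len(panels["BENEFIT"])
0
>>> [(b.study_id, b.band, round(b.height, 2)) for b in panels["HARM"]]
[('PAFAC', 'HIGH', 0.22), ('Lafuente-Lafuente', 'SUBSTANTIAL', 0.57), ('Sodermark', 'HIGH', 0.27)]
```

Reading: the antiarrhythmics evidence has an *empty* benefit panel — no
study suggests benefit — and the best available evidence (the level-1b
PAFAC trial, SE 0.78; the level-1c meta-analysis, SE 0.43) carries high
to substantial risk of random error, so the apparent mortality increase
is too unreliable to act on, and step IV declines to report an effect
size for it.

The same analyses run from the shell:

```sh
errormatrix step1 --fixture example1 --outcome "all-cause mortality" --max-se 0.40 --count
6
errormatrix step4 --fixture example2
errormatrix render --fixture example1 --out manhattan.svg
```

Study tables are plain CSV/JSON, one row per (study, level, outcome),
carrying either 2×2 counts, an estimate with its CI, a reported SE with
a direction flag, or a missingness code (`Z` zero events, `N` not
reported). See `errormatrix/io.py` for the schema and
`docs/methods.md` for the model and its assumptions.

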