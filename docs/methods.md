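# Methods

## The model

The package treats a body of clinical-intervention evidence as a set of
*study records*, each carrying an evidence level and one data cell per
outcome, and summarises reliability along three orthogonal dimensions.

**Systematic error** is an ordinal judgement, supplied by the user, on
the ten-step levels-of-evidence scale (1a, 1b, 1c, 1d, 2a, 2b, 3a, 3b,
4, 5; rank 1–10, lower = less bias). The package deliberately does not
compute levels from risk-of-bias components: that appraisal is expert
judgement, and the scale is an input.

**Random error** is the standard error of the natural log of a ratio
effect measure. For a single 2×2 table the SE of ln RR is
√(1/a + 1/c − 1/n1 − 1/n2); for the Peto odds ratio it is 1/√V with the
hypergeometric variance V = n1·n2·(a+c)·(b+d)/(N²(N−1)). Fixed-effect
pooling uses the Mantel–Haenszel P/R/S components for the log risk
ratio (SE = √(P/(R·S)), point R/S) and Σ Z / Σ V for the pooled Peto OR
(SE = 1/√ΣV). The SE is preferred over p-values because it is
comparable across studies of the same question regardless of how often
the data were looked at. SEs are then classified into five bands —
[0, 0.10) ignorable, [0.10, 0.20) small, [0.20, 0.30) moderate,
[0.30, 0.50) substantial, [0.50, ∞) high. The published band bounds
overlap at the edges ("0.10 to 0.20", "0.20 to 0.30"); the package
resolves them as left-closed/right-open, so a boundary SE belongs to
the *upper* band — consistent with an SE of exactly 0.10 being called a
small, not ignorable, risk.

**Design error** is captured through outcome importance on the GRADE
1–9 scale, with the standard category cut points (7–9 critical, 4–6
important but not critical, 1–3 not important). Outcomes are ordered by
score descending, ties broken by an explicit display order and then
name. Correlation between outcomes (e.g. cardiovascular deaths are also
all-cause deaths) is ignored; each outcome is treated marginally.

## The four matrix steps

* **Step I** scatters every study with a computable SE for one outcome
  at (level rank, SE). No filtering: seeing the imprecise studies is
  part of the point.
* **Step II** places every study that reports an outcome (including
  zero-event cells, excluding not-reported cells) into its (level,
  outcome) grid cell.
* **Step III** builds the Manhattan panels. Bars are omitted when the
  level is worse than a cutoff (default 2b) or the SE is at or beyond a
  cutoff (default 1.0). Bar height is linear, (cutoff − SE)/cutoff, a
  choice made here because the published figures define no numeric
  height: it is monotone, reproducible, and makes zero height coincide
  with the omission threshold. Each bar is assigned to the benefit or
  harm panel by the direction of its own estimate; estimates exactly at
  the null (|ln point| < 1e−12) go to neither panel and are logged.
* **Step IV** reports, per outcome, the best available estimate, its
  direction, and — when 2×2 counts exist — the absolute risk difference
  and NNT (exact value retained, display value rounded up to a whole
  patient). A validity screen (default: level no worse than 2b, band no
  worse than moderate) gates the step: outcomes whose best evidence
  fails it are reported as `INSUFFICIENT_EVIDENCE` with the failing
  dimension(s), never given an effect size.

"Best available" is resolved level-first: among records with a
computable SE, minimal level rank wins; ties broken by smaller SE, then
study id. A per-level query is the same call on a filtered record list.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `se_cutoff` | 1.0 | step III SE omission threshold (log-scale SE) |
| `level_cutoff` | `"2b"` | worst level drawn in step III |
| `ValidityScreen.max_level_rank` | 6 (= 2b) | step IV gate, systematic error |
| `ValidityScreen.max_band` | MODERATE | step IV gate, random error |
| `confidence` in `se_from_ci` | 0.95 | interval coverage; z = 1.959964, not 1.96, to avoid rounding bias |
| `adverse` per outcome | true | ratio < 1 means benefit; flip for desirable outcomes |

Band edges, cutoffs, colours and outcome specs are overridable through a
YAML config (`errormatrix.io.load_config`).

## Numerical choices and degenerate inputs

Natural logarithms throughout (base-10 would rank studies identically).
Zero-event cells raise a typed error carrying missingness code `Z`; no
continuity correction is applied by default, because an SE that cannot
be calculated should be reported as such, not manufactured. An explicit
`zero_correction=True` flag adds 0.5 to every cell for users who need an
estimate anyway. Tables with no non-events or fewer than two patients
make the Peto variance zero and raise a degenerate-table error. In
pooling, trials with zero events in both arms contribute nothing and are
skipped with a warning. The ln-RR radicand is clamped at zero against
floating-point residue (it is mathematically non-negative since a ≤ n1,
c ≤ n2). NNT is undefined at a zero risk difference and raises rather
than returning infinity.

## The packaged fixtures

The two worked-example tables store the *reported* per-study SEs
(provenance `AS_REPORTED`) because the underlying 2×2 counts were never
published; they are inputs, not recomputations, and every output
carries the provenance tag so they cannot be mistaken for computed
values. Direction flags per cell come from the published conclusions
(example 1: benefit for non-fatal myocardial infarction, harm for
all-cause mortality, cardiovascular mortality and non-fatal stroke;
example 2: harm throughout — its benefit panel is empty). Correctness of
the SE formulas themselves is established independently, by
hand-computed oracles and by property tests: the single-stratum
Mantel–Haenszel SE equals the per-study SE[ln RR] to 1e−12 over ≥1000
random tables, the two algebraic renderings of the Peto SE agree to
1e−12, arm-swapping inverts the Peto OR and preserves its SE, and
pooling strictly shrinks the Peto SE.

## The synthetic generator

`generate_synthetic_trials` emulates a set of parallel-group two-arm
trials: per-arm sizes uniform on a range (default 50–500, the scale of
the trials in the worked examples), event counts binomial at a control
probability (default 0.2) and an intervention probability `true_rr`
times that. All randomness flows through one seeded generator. It
reproduces sampling error only — no between-trial heterogeneity, no
bias, no missingness — so passing simulation checks demonstrate the
estimators' sampling behaviour under the fixed-effect model, not
robustness to the systematic or design errors the matrix itself is
about. The default simulation check (1000 replicates of 5 trials of
100–300 per arm at a true RR of 1) verifies that the pooled MH log-RR
stays within three pooled SEs of null in ≈99.7% of replicates.

## Known limitations

Heterogeneity assessment, random-effects models, Bayes-factor
alternatives, multiplicity adjustment for repeated looks, and automated
risk-of-bias scoring are out of scope by design. The step III figure
layout follows the published description (two 3D panels, outcome groups
× level ranks, five-band legend), not a pixel specification. The matrix
positions studies *relative to each other*; it is not an absolute
measure of error risk.
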