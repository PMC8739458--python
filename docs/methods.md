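# Methods

This note documents the models and numerical conventions behind
`lcmsqc`: what each module computes, the tunable parameters and their
defaults, what the synthetic-data generator does and does not emulate,
and the design choices made where more than one reasonable convention
exists.

## Data model

One analytical batch is one acquisition run on one instrument: a
calibrator series (Std-A .. Std-F, ascending nominal concentration),
QC samples and patient samples injected sequentially. Every
(sample, compound) pair yields one result row holding the analyte
measurements (peak area, confirming-ion area, RT, S/N, concentration)
and the paired internal-standard measurements (IS area, IS RT, IS S/N,
IS confirming-ion area). Batch metadata and per-compound calibration
curves are stored in their own tables; all three tables carry surrogate
integer keys.

Storage is SQLite via the standard library driver, with the DDL shipped
as portable SQL (`src/lcmsqc/schema.sql`). `STRICT` tables enforce that
numeric columns reject non-numeric text at insert time, and `CHECK`
constraints enforce sign conventions (areas ≥ 0, RTs > 0, r² ∈ [0, 1])
and the four-value sample-type vocabulary. Ingest is append-only and
idempotent per XML file name; a constraint violation rolls back the
whole batch. `instrument_id` is denormalized onto result rows so
per-instrument distribution queries are single-table — every
calibration analysis splits by instrument.

Timestamps are stored as ISO-8601 UTC text (lexicographic order =
chronological order). Date filters are half-open `(start, end]` on
injection time so month-partitioned views never double-count a boundary
injection; rows with a null injection time never match a date-restricted
filter.

## QC rules

Five rules, with fixed, tested boundary semantics (the choice at the
boundary is a convention, so it is documented rather than implied):

* **RRT**: RT / RT_IS, inside an inclusive window. Analyte and
  isotope-labelled IS co-elute, so the expected value is ~1.0 and
  windows are narrow (e.g. 0.984–1.024).
* **IS peak area**, **S/N**, **Std-A peak area**: minimum thresholds,
  *pass at equality*, fail strictly below.
* **Ion ratio**: confirming / quantifying area within a relative band:
  fail when |measured / expected − 1| > tolerance (default 0.20, the
  usual confirmation-assay practice). The expected ratio is configured
  per compound, or, when unset, derived as the mean ratio over the
  batch's calibrator rows with usable areas (per-batch drift in source
  conditions then cancels).

The Std-A rule runs once per (batch, compound) and attaches to the
first calibrator's row; "first" is resolved by the Std-letter labels
(A < B < …) and falls back to ascending nominal concentration when ids
do not follow the labeling convention.

Null handling is total: a rule with a null threshold is *disabled* and
passes through (explicitly marked `disabled`, which permits partial
rule sets during migration); a null measurement makes the flag
`not_evaluable`, never a failure. Patient and QC rows receive the four
per-result rules; calibrator rows are inputs to the Std-A and
ion-ratio context rather than individually flagged. The single-rule
check functions are sample-type agnostic, so calibrator distributions
can still be scored directly (as the historical-performance analyses
do).

**IS lot rescaling.** Internal-standard working solutions are prepared
in-lab and vary slightly between lots. A relative bias of up to 10%
(inclusive) between the current lot's mean IS area and the reference
lot's is accepted unchanged; beyond that the IS cutoff is rescaled
multiplicatively by the lot ratio, preserving the flag rate instead of
silently shifting the check's sensitivity. Rescaling the observed
areas by the inverse ratio would be mathematically equivalent for
flagging; the cutoff-side adjustment was chosen because it leaves
stored historical data untouched (the store is read-only by contract).

## Cutoff calibration

The empirical border for a parameter (IS area, analyte area, S/N, RRT)
is the quantile at level *p* (default 0.02) of the non-null historical
values of one compound × instrument group, using linear interpolation
between order statistics (the common "type 7" estimator) —
deterministic, widely implemented, and checkable against closed forms.
Groups with fewer than 50 usable values (configurable) are skipped with
a warning rather than yielding an unstable border. Whether calibrators
and QC only, or patients as well, contribute is a filter setting, not a
separate code path: patient data add the left tail produced by
matrix-effect ion suppression and give the more realistic view of how a
cutoff performs.

`fraction_below` counts *strictly below*, mirroring the engine's
pass-at-equality convention, so a predicted fail fraction equals the
realized flag rate exactly. Note a subtlety of the interpolated
estimator: the fraction strictly below the level-*p* border is not
bounded by *p* itself but by the order-statistic bracketing
`count(< border) ≤ floor((n−1)p)+1` and
`count(≤ border) ≥ floor((n−1)p)+1`; both bounds are property-tested.

Rule-set comparison double-runs the flag engine on the identical stored
selection. An observation is one (result, rule) pair evaluable under
both rule sets — pairs where either set disables the rule or cannot
evaluate it (null inputs) are excluded and reported separately. A *new*
flag fails under the new set and passed under the old; a *removed* flag
is the converse (a presumed false positive eliminated by the revision);
percentages are exact quotients over the observation count.

## Views

The five monitoring views (histogram, plotted average, plotted batch,
plotted Std-A signal, absolute RT vs monthly average) are computed as
plain data so any rendering layer stays a thin, stateless adapter. The
views layer adds no arithmetic beyond grouping: summaries are the
standard estimators (sample SD with ddof = 1; quantiles type 7), and
overlays/pass-fail markers are produced by the rule engine and
calibration module on the same rows, never re-derived.

Conventions chosen where none is canonical:

* histograms use equal-width bins spanning [min, max] (default 50),
  half-open [left, right) with the last bin closed so counts always sum
  to n;
* the rule-set cutoff overlay is attached only when the selection pins
  a single (compound, instrument) pair — anything else would be
  ambiguous;
* trend months are UTC calendar months; the monthly mean RT weighs
  every row equally (not mean-of-batch-means), and a batch belongs to
  the month of its first selected injection; deviations are exactly
  per-batch mean − monthly mean.

## Synthetic corpus generator

The generator emulates the production assay the toolkit targets; its
defaults are the study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| compound panel | 24 opioids/metabolites, nominal RTs 1.2–5.0 min | production panel size |
| calibrator levels | A–F at 1/5/10/25/50/100 ng/mL | six-point curve, Std-A lowest |
| samples per batch | 6 cal + 2 QC + 10 patients | typical confirmation batch |
| instruments | 2, IS-area scales configurable | assay split across two MS |
| IS peak area | lognormal(μ = 11, σ = 0.4) × instrument scale | positive, right-skewed signal; median ≈ 60k counts |
| bimodal fraction | 0 (opt-in second mode at μ − 1.5) | reproduces bimodal IS distributions when enabled |
| RRT noise | IS RT = nominal; analyte RT = nominal × N(1, 0.005) | RRT centers on 1.0 (co-elution) |
| patient suppression | prob 0.05, signal × 0.3 | dilute-and-shoot matrix effects hit ~5% of specimens |
| missing fields | rate 0.01 over optional numerics | sporadically incomplete exports |
| S/N | lognormal(4.0, 0.6) | median ≈ 55 |
| concentration noise | CV 8% around nominal | curve-level reproducibility |

Analyte peak area is IS area × (concentration / top-calibrator
concentration) × lognormal noise; the confirming-ion area is the
analyte area × the compound's expected ion ratio × N(1, 0.03). All
draws come from one seeded generator and the XML writer is
deterministic, so a fixed seed yields a byte-identical corpus.

**Planted violations.** `plant_failures` returns a config whose corpus
contains an exact number of rule violations: k IS areas below a cutoff,
m RRTs outside a window, j batches with a sub-cutoff Std-A, or exact
new-fail/removed-flag transitions between two rule sets. To make the
counts exact by construction, all *eligible non-planted* rows are
floored at the relevant cutoff or clipped into the window — a
deliberate trade of distributional realism on those rows for
construction-oracle exactness. Planted and forced rows are protected
from the missing-field mechanism, and every planted row is recorded in
a ground-truth CSV sidecar that only tests read.

What the generator does **not** emulate: chromatographic peak shapes,
within-batch drift and carryover, correlated multi-compound suppression
in a single specimen, calibration-curve nonlinearity, or realistic
opioid concentration pharmacology. Passing tests therefore demonstrate
the correctness of the parsing/storage/rule/calibration machinery and
the recoverability of planted statistical structure — not that any
particular clinical data set would show these distributions.

## Problem sizes and scenario design

The test and acceptance scenarios use desk-scale sizes chosen to keep
statistical claims well-powered: round trips on a 50-batch corpus
(21,600 rows); rule-engine oracle equivalence on 10⁴ randomized rows
salted with nulls and boundary-equal values; border recovery on 10⁵
lognormal draws (sampling SE of the 2% quantile ≈ 0.4%, against a 1%
tolerance), with convergence checked on the mean error of 10 replicates
per n ∈ {10³, 10⁴, 10⁵}; and instrument separation at 10⁴ rows per
instrument, where the border-ratio sampling SE is ≈ 1.6%, against a 5%
tolerance.

The instrument-separation scenario runs with patient suppression
disabled: a 5% suppression mixture places the 2% border inside the
suppressed subpopulation, roughly tripling the ratio's sampling error
and confounding the planted between-instrument factor the scenario
measures. Suppression is exercised by the default-condition tests
instead.

Planted-scenario sizes mirror the scale of a real rule-set review:
600 calibrator rows with exactly 21% planted below an IS cutoff, a
1,944-observation two-rule comparison with 31 planted new flags
(1.59%) and 138 planted removed flags (7.10%), and 2,500 patient/QC
RRT observations with 3 (0.12%) planted outside the 0.984–1.024
window.

## Known limitations

* The XML dialect is this package's own (documented in
  `docs/xml_dialect.md`); vendor exports need a translation shim that
  produces the same records.
* The `cc` (continuing-calibration) field is stored but carries no rule
  semantics.
* The S/N rule applies to the analyte only; IS S/N is stored, not
  flagged.
* LLOQ is carried in the rule configuration for reference, but no flag
  suppresses sub-LLOQ noise automatically.
* Calibration-curve acceptance (r² gating, back-calculated accuracy) is
  out of scope; curve parameters are stored for review only.
* Bimodal IS distributions are surfaced descriptively by the histogram
  view; no formal mixture/dip test is performed.
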