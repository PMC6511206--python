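# Methods

## The audit model

`dqaudit` operationalises a 12-item defect checklist for tabular research
dataset submissions. The checklist names the defect families; this package
supplies the deterministic, codebook-driven detector for each one. The
guiding rule is *reproducibility over cleverness*: every detector is a fixed
predicate of the raw cell text, the codebook, the analysis plan and the
reader's parse flags — no fuzzy matching, no repair, no imputation. The
same submission always yields the same profile.

Two design commitments follow from the 0–12 scoring rule (one point per
distinct item):

* **Binary presence per item.** A variable with 100 miscoded cells and a
  variable with one both contribute a single point for *miscoded values*.
  The evidence trail (`Finding` records with variable, row and observed
  text) preserves the full count for reporting.
* **At most one item per cell.** A cell like `"2600/2600"` is both embedded
  and (per fragment) implausible; the fixed precedence
  missing > embedded > uncoded > miscoded > implausible > unformatted
  assigns it to exactly one item so no cell is double-counted.

### Detector definitions and edge decisions

* *Missing codebook* — no codebook accompanied the dataset. When the
  codebook is absent, the six codebook-relative detectors (the cell-level
  items and codebook inconsistency) are undefined and are skipped; such a
  submission can therefore express at most 5 of the 12 items. This is a
  property of the measurement, not a bug: an auditor without a data
  dictionary cannot tell a miscode from a code.
* *Codebook inconsistency* — an undocumented dataset column, a required
  codebook variable with no column, or a coded variable whose observed
  non-missing values are **disjoint** from its code domain. Disjointness
  (rather than any out-of-domain value) separates a wrong coding scheme
  (inconsistency) from sporadic bad codes (miscoded values).
* *Inaccurate format* vs *unanalyzable structure* — both are driven by
  reader parse flags. Ragged rows, duplicate column names and blank header
  cells break the file's format; repeated header rows and interleaved blank
  blocks break its analyzability, as does a multi-point (longitudinal)
  study with no recognisable subject identifier (no declared identifier
  variable and a non-unique first column). The reader never repairs: every
  anomaly it tolerates is recorded as a flag, so the checks see exactly
  what a statistician opening the file would see.
* *Missing values* — any empty/sentinel cell in a *required* variable.
  Sentinels default to `"" , NA, N/A, .` and are configurable
  (`CheckConfig.missing_sentinels`); the per-variable threshold defaults to
  one cell (`missing_threshold=1`) because no defect-rate cutoff is part of
  the checklist definition.
* *Embedded values* — in numeric or coded variables only: two non-empty
  tokens joined by `/`, `;` or `,`; a value+unit pair (`45 kg`); or a
  dash range (`100-120`). Dates are exempt (their separators are layout,
  policed by *unformatted* instead). Delimiters and the unit regex are
  configurable because entry dialects vary by site.
* *Uncoded* vs *miscoded* — in a coded variable, non-numeric free text
  outside the code set is uncoded (`"male"` where `{1,2}` is expected); a
  parseable number outside the domain is miscoded (`"3"`). A cell numerically
  equal to a code (`"2.0"` vs code `"2"`) is accepted.
* *Implausible values* — a parseable numeric cell outside the variable's
  inclusive plausible range.
* *Unformatted values* — a date not matching the declared `strptime`
  layout, a non-numeric entry in a numeric variable, or a numeric entry
  with decoration (padding whitespace, separators) that survives the
  higher-precedence checks.

## Conformance classes

Unacceptable (documentation/structural items or a missing outcome variable)
outranks sub-optimal (entry errors, missing analytic variables): a dataset
with both kinds is rejected outright rather than cleaned, matching the
workflow in which unacceptable submissions are returned before analysis is
attempted. Conforming ⇔ zero defects ⇔ the zero band; the bands
(zero / one / two-plus) depend only on the score.

## Six Sigma metrics

`DPU = D/n`, `DPO = D/(n·o)`, `DPMO = 10⁶·DPO`, `Yield = (1−DPO)·100`,
`Sigma = Φ⁻¹(1−DPO) + 1.5` with `o = 12` opportunities per dataset (the
checklist length) by default. Internals are kept at full precision;
`MetricsSummary.display()` applies the conventional reporting format —
DPU/DPMO/Yield **truncated** (not rounded) to two decimals, Sigma rounded to
one. Truncation is deliberate: it is the convention that reproduces the
reference tables this implementation was validated against (e.g.
105/540 → DPMO 194,444.44 and Yield 80.55, where rounding would print
80.56). The 1.5σ shift is the standard long-term/short-term offset under
which six sigma corresponds to 3.4 DPMO; a zero-defect collection has
infinite sigma, reported as `inf` rather than clipped.

Pareto rows count *datasets affected* per item (binary presence, so counts
sum to the total defect score); ties are broken by checklist order, and the
cumulative column is the running share of all defect occurrences.

## Inferential layer

* Fisher's exact test (2×2 only) uses the two-sided point-probability
  convention: sum the hypergeometric probabilities of all margin-preserving
  tables no more likely than the observed one, ties at ~1e−7 relative
  tolerance. The implementation delegates to `scipy.stats.fisher_exact`;
  the test suite checks it against an independent exact-integer enumeration
  oracle over **every** 2×2 table with grand total ≤ 30 (46,375 tables,
  max observed discrepancy ≈ 4e−16).
* The chi-square test is Pearson's statistic without continuity correction,
  df = (r−1)(c−1). Expected counts below 5 trigger a warning, not an error:
  audit collections of a few dozen datasets routinely violate the rule of
  thumb, and the comparison is still reported (with the caveat attached).
* α = 0.05 is carried on every `TestResult`; no multiplicity adjustment is
  applied (none is part of the procedure being implemented).

## Synthetic data: what the generator states, and what it does not

`generate_clean` emits submissions that score 0 by construction: a small
clinical variable menu (identifiers, age, sex, blood pressure, weight,
height, a visit date, smoking status, a coded outcome), every cell inside
its range/domain/layout, plan variables present, codebook attached.
Multi-point (longitudinal) datasets add `subject_id` and `visit` columns
but keep an all-unique `record_id` as the *first* column — otherwise
detaching the codebook would make the subject-identifier heuristic fire and
contaminate missing-codebook injections with a spurious structural defect.

`inject_defects` mutations are unambiguous by design so that detection is
exact: a miscode is one above the largest permitted code, an implausible
value is 10× the range maximum, an embedded value is `120/80`, an
unformatted date flips the layout. Requesting cell-level items together
with a missing codebook is rejected (see above — the audit could not
observe them), as is any item the submission cannot host.

`build_fixture` reconstructs a whole audit collection from marginal
targets: band counts, total defects, missing-codebook count, and
(not defective, defective) margins for three stratifiers. Allocation is
deterministic: two defects per two-plus dataset, the surplus round-robin;
stratifier levels handed out in margin order within the non-defective and
defective groups; missing codebooks to the first defective datasets; item
identities drawn from fixed pools (rotated for variety). The two shipped
fixture specs reproduce a 45-dataset baseline (bands 6/8/31, 105 defects,
20 missing codebooks, capture cross-tab [[6,15],[0,24]], coordinator
[[5,23],[1,16]], returning-PI [[3,7],[3,32]]) and a 21-dataset follow-up
(bands 17/2/2, 12 defects, returning-PI [[14,0],[3,4]], capture
[[8,4],[9,0]], coordinator [[7,4],[10,0]], 11 electronically captured).
The fixture totals 105 and 12 are reconstructions from the printed
defects-per-unit values (2.33×45 and 0.57×21 — the unique integers whose
two-decimal quotients match), not printed counts.

What the generator does **not** emulate: statistically realistic
correlations between clinical variables, longitudinal trajectories,
multi-centre structure, the *joint* distribution of the three stratifiers
(only each margin is pinned; the joint assignment is a deterministic
convention), the per-item defect mix beyond the missing-codebook count, or
the per-dataset defect counts inside the two-plus band beyond their sum.
A green truth-recovery test therefore establishes that the detectors
recover *unambiguous, injected* defects exactly — not that they would
recover every messy real-world defect, where precedence boundaries
(e.g. `1,234` as thousands-separated vs embedded) are genuinely ambiguous.

## Numerical conventions

* Display truncation happens only at the reporting edge; all arithmetic and
  all tests of identities (Yield = 100 − DPMO/10⁴, DPO = DPU/o) run at full
  precision.
* Fisher p-values are clipped to [0,1]; degenerate 2×2 tables with a zero
  margin give p = 1 (a single admissible table).
* `compute_metrics` rejects an empty collection and any
  `opportunities_per_unit` smaller than the largest observed score.
* Seeds: all randomness flows through `numpy.random.default_rng`; child
  seeds are derived arithmetically modulo 2³¹−1, so fixture builds are
  bitwise reproducible per seed, including the bytes of written bundles.

## Known limitations

* The checklist's mapping onto the six data-quality domains (completeness,
  uniqueness, timeliness, accuracy, validity, consistency) is not modelled;
  no item covers duplicate records or timeliness.
* Cell-level checks key on the first occurrence of a duplicated column
  name; the duplicate itself is only reported as a format defect.
* The codebook schema (JSON, or a flat CSV dialect) is this package's own
  operationalisation — real submissions often carry codebooks as prose
  documents, which are out of scope.
* `check_values` requires Python `strptime` patterns for date layouts;
  free-form layout inference is deliberately not attempted.
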