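# Methods

## Setting and data model

One record per analyzed nodule-patient, with three classifications:
preoperative FNA cytology (Bethesda I–VI), intraoperative frozen section
(FS; malignancy / suspicious for malignancy / benign / indeterminate) and
final postoperative pathology (the binary gold standard, malignant vs
benign).  How nodule-level findings were reconciled to patient level for
bilateral/multifocal disease is not modeled: a record *is* the
nodule-patient unit, and covariates (age, sex, FNA-nodule diameter,
bilaterality, multifocality) are attributes of that unit.  Bilaterality
and multifocality are recorded for malignant pathology only, mirroring the
source cohort's reporting.

## Diagnostic metrics

A dichotomization scheme declares a non-empty proper subset of a stage's
categories positive.  Collapsing the category×outcome table gives TP/FP/
FN/TN and the five standard ratios.  Conventions:

- **Confidence intervals.** Wilson score by default, Clopper–Pearson by
  option.  The source study reports no metric CIs, so the choice is ours;
  Wilson is preferred because several observed proportions sit at or near
  1 (FS specificity and PPV are exactly 100%), where the Wald interval
  degenerates and Clopper–Pearson over-covers.
- **Undefined metrics.** A zero denominator (e.g. NPV with no
  test-negatives) yields an explicit `None`, never a silent 0; the other
  metrics are still returned.
- **Display.** Percents are rounded half-up to one decimal; exact integer
  fractions are retained everywhere internally.
- **Presets.** FNA-positive = {V, VI}; FS-positive = {MALIGNANCY};
  combined-positive = {MALIGNANCY}.  These are the clinically conventional
  cut-offs and reproduce every published panel.  Note the exploratory
  threshold search shows that raw accuracy on the FNA table is maximized
  by the *wider* cut-off {III, IV, V, VI}; the presets deliberately pin
  the conventional choice rather than an accuracy-maximizing one, and the
  search is exposed separately (`search_schemes`) with a deterministic
  tie-break (criterion, then sensitivity, then fewer positive categories,
  then lexical order).
- Bethesda I (nondiagnostic) and FS INDETERMINATE are ordinary negative
  categories unless a scheme includes them; they are never dropped, so
  every 2×2 total equals the cohort size.

## Net reclassification index

For old→new binary classifiers, the categorical NRI is the net proportion
of events moved to test-positive plus the net proportion of non-events
moved to test-negative; for binary schemes the point estimate telescopes
to ΔSensitivity + ΔSpecificity and is therefore computable from the two
marginal 2×2 tables alone (`nri_from_marginals`, exact rational
arithmetic).  The paired estimator (`nri_paired`) counts record-level
up/down moves per stratum and uses the standard asymptotic variance

    se² = [p↑,e + p↓,e − (p↑,e − p↓,e)²]/n_e
        + [p↑,ne + p↓,ne − (p↑,ne − p↓,ne)²]/n_ne

with a two-sided normal p (p = 1 by convention when no record moves).
When only margins are supplied no CI is emitted: the paired variance is
not identifiable from margins, and fabricating an approximate interval
would overstate what the data support.  NRIs display at three decimals.

## The staged rule and its accounting

A cascade rule maps every first-stage category to either a terminal label
or a deferral to the second stage.  Terminal labels live in the
second-stage vocabulary (Bethesda VI → MALIGNANCY), so combined tables
have the same four levels as the FS table.  The shipped rule is the
selective-FS policy: VI terminal-malignant, I–V deferred.  Usage
accounting reports the deferred count/fraction and total cost under
first-test-only, routine-both, and cascade scenarios (defaults: FNA
170 USD, FS 20 USD per specimen).  Flow tables keep exact
(from-category, to-category, outcome) counts; the Sankey JSON export
orders nodes by the fixed vocabularies.  Rendering is out of scope.

## Deterministic reconstruction of the study cohort

The published margins fully determine the cohort at the granularity the
headline numbers need; the reconstruction fills the rest deterministically:

1. **Forced blocks.** The combined (staged) MALIGNANCY row minus the
   Bethesda VI row gives the FS-MALIGNANCY calls among categories I–V;
   subtracting the I–V block from the FS table gives the FS×outcome
   distribution inside Bethesda VI.  Both must be componentwise
   nonnegative, and the printed VI→MALIGNANCY flow and benign∪indeterminate
   count among VI must equal their implied values — otherwise the
   constraint set is rejected with the violated identity named.
2. **Flow matrix.** Printed flows pin V→MALIGNANCY, III→MALIGNANCY and the
   per-category benign∪indeterminate totals.  The residual FS-MALIGNANCY
   flow is spread over the remaining Bethesda rows (IV, II, I)
   proportionally to each row's unallocated slack, capped by the row's
   malignant-outcome count — the FS-MALIGNANCY column has zero benign
   outcomes, so that cell can only hold malignant patients (Bethesda IV,
   with 2 malignant outcomes, caps at 2) — with largest-remainder
   rounding; FS-SUSPICIOUS takes the remaining slack.  The scarce
   INDETERMINATE calls are spread over the benign∪indeterminate blocks the
   same way.
3. **Outcome fill.** Within Bethesda I–V the malignant counts per
   (FNA, FS) cell form a capped transportation problem (row sums = the
   per-Bethesda malignant counts, column sums = the per-FS malignant
   counts among I–V, caps = the flow matrix); it is solved as an integer
   max-flow (networkx, Edmonds–Karp), which is deterministic for the
   fixed node order and raises if the margins are infeasible.
4. **Emission.** Records are emitted in fixed vocabulary order with
   sequential ids, so two builds are byte-identical (idempotence is
   tested).  Every quantity the acceptance script reports depends only on
   the forced margins, not on the discretionary fill.

A remarkable by-product: the reconstruction's up/down decomposition
reproduces the published paired-NRI 95% CIs (0.138–0.227 for FNA→FS,
0.103–0.167 for FNA→cascade) although only the point estimates are forced
by margins.  The tests assert the point estimates; the CIs are emergent.

Covariates are attached per outcome stratum by an even deterministic
(Bresenham-style) spread that hits the published outcome-conditional
counts exactly — age dichotomized at 55, sex, diameter in three strata
(<5, 5–10, ≥10 mm), bilaterality and multifocality among malignant
pathology.  Within a stratum, concrete ages/diameters cycle through a
fixed range; covariates are spread independently of FNA/FS category, so
the reconstruction carries no covariate–category dependence (none is
reported to emulate).

Known source inconsistencies, resolved as follows: the cohort size is
3807 (the figure 3837 appears twice in discussion text but contradicts
every table); the Bethesda VI malignancy rate is 99.2% = 2566/2587 (a
discussion figure of 99.7% contradicts the table); the deferral statement
"only 32% still need FS" (1220/3807) is taken as authoritative over an
abstract phrasing that suggests ~1/3 were *removed* from FS.

## Simulation model

`simulate_cohort` draws independent records: outcome ~
Bernoulli(prevalence); FNA category from an outcome-conditional
6-vector; FS category from an (outcome, FNA)-conditional 4-vector, with
an outcome-only fallback (and a collapse option).  Default parameters are
the empirical frequencies of the reconstruction, so the generator's
defaults *are* the study conditions: prevalence 3544/3807 ≈ 0.931 and the
table-derived conditionals.  Covariates are not simulated by default.
All randomness flows through one `numpy` generator seeded from the
config; identical seeds give byte-identical cohorts.

What the generator emulates: the categorical dependence structure
(outcome → FNA → FS) and the observed margins.  What it does not:
within-patient correlation beyond those conditionals, pathologist or
temporal drift, covariate–category dependence, and any selection process
upstream of FNA (ultrasound triage).  Passing tests therefore demonstrate
estimator correctness under the assumed categorical model, not robustness
to real-world selection effects.

## Numerical and testing choices

- Pearson χ² without continuity correction is the default (it reproduces
  the published sex×outcome p = 0.013); Yates correction by option.  The
  diameter comparison is treated as a plain 2×3 Pearson test (whether the
  source used a trend test is unstated).  Zero margins raise rather than
  propagate NaNs.
- Exact integer/rational arithmetic (`fractions.Fraction`) is used for
  rates and NRI components; floats only at the display/CI layer.
- Property tests run on hypothesis-generated random cohorts
  (derandomized) at sizes ≤ 40; Monte-Carlo checks use seeded cohorts of
  2 000–50 000 records, sizes chosen to keep sampling error well inside
  the asserted tolerances.
- The external-validation analysis of the source study is out of scope as
  a reproduction surface (its contingency table is not published); the
  pipeline accepts any conforming cohort file, so such a cohort can be
  analyzed when available.

## Limitations

The reconstruction is *a* patient-level cohort consistent with every
published margin, not the original data: cells the margins do not force
(which Bethesda II vs I patients account for particular FS-benign
malignancies, the covariate–category joint) are filled by the
deterministic conventions above.  All acceptance-grade quantities are
invariant to that fill.  No molecular testing, imaging workflow or
management recommendation logic is modeled.
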