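# Methods

## The problem

After Crotalinae (pit viper) envenoming, patients recover function at very
different rates, and no validated tool predicts who will do poorly. The
approach implemented here links routinely collected clinical variables and a
35-analyte serum cytokine/chemokine panel (Luminex 35-plex, sampled before
and after antivenom) to a patient-reported functional outcome, using a
discrete Bayesian belief network (BBN) learned from data. Arcs in these
networks are probabilistic associations — each arc carries a conditional
probability table, not a causal claim — and the documentation and exports
label them as such.

## Outcome: PSFS AUPC and the median split

The Patient-Specific Functional Scale (PSFS) is a 0–10 patient-reported
rating of self-nominated activities, assessed at days 0, 7, 14, 21 and 28.
Each trajectory is summarized by the area under the patient curve (AUPC):
the trapezoidal integral over the 28-day window divided by the maximum
possible area 10 × 28 = 280, giving a value in [0, 1]. Two conventions are
ours, because no interpolation or normalization rule is standard:

* **Endpoint extension.** If day 0 or day 28 is unobserved, the nearest
  observed score is carried outward as a constant. Interior missing visits
  are bridged by the trapezoid between the neighbouring observed days.
* **Normalization by 280.** Chosen so that the score is scale-free; a
  constant curve at score *s* has AUPC exactly *s*/10.

Patients with AUPC at or above the cohort median are labeled *good*
recovery, the rest *poor* (ties go to good; even cohorts use the midpoint
median). The split needs at least two patients.

## Preprocessing

1. **Log transform.** Analyte concentrations are natural-log transformed
   (`log(max(x, floor))`, floor default 0.5, standing in for values below
   the limit of quantitation). Natural log, not log10: typical serum panel
   concentrations in pg/mL have natural-log medians in the 1–8 range that
   match the magnitudes this pipeline reports (e.g. log HGF ≈ 6).
2. **Missingness filter.** A variable missing in strictly more than 20% of
   records is dropped; exactly 20% is kept.
3. **Discretization.** Continuous variables are cut at training-fold
   quantiles (tertiles by default; linear-interpolation quantiles). Three
   bins bound the conditional-probability-table size at cohort sizes of
   10–60. Binary flags (sex, comorbidity, antihistamine use) pass through.
   Cut points are fitted on training rows only — mutating a held-out value
   can never move a bin boundary — and out-of-range values clamp to the
   extreme bins. Missing values are never imputed.

## MDL scoring and structure search

Structures are scored by a two-part Minimum Description Length, in bits:
`data_bits` is the negative base-2 log-likelihood of the records under
maximum-likelihood CPTs, accumulated per family (node plus parents);
`model_bits` charges (log2 N_f)/2 per free parameter, where a node with
r bins and q parent configurations has (r − 1)·q free parameters. Lower is
better; the score decomposes over families, which makes greedy search cheap.

**Missing data.** Each family is scored on the records complete on that
family, and the data term is rescaled by n/n_f to the full record count.
Without the rescaling, a family whose members are missing-prone looks
cheaper merely because fewer of its records can be coded, and on null data
the search systematically attaches arcs to the most missing variables. The
rescaling is the identity on complete data. Expectation-maximization over
missing values is out of scope.

**Search.** Hill climbing from the empty graph with operators add / delete /
reverse arc, under acyclicity and a parent cap (default 3, to bound CPT
dimensionality at small n). Candidate moves are enumerated in (operator,
node-pair) lexicographic order and ties go to the earliest candidate, so the
result is fully deterministic; there are no random restarts. The outcome
node is treated like any other node during search.

**The sparsity gate (λ, default 0.01).** A move is accepted only when it
shortens the description length of the families it touches by more than a
fraction λ of their current code length; λ = 0 recovers plain MDL hill
climbing. The gate is deliberately *local* (relative to the touched
families, not the whole network's total): a gate proportional to the global
total grows linearly with the variable count, and at 40+ variables it
exceeds the largest likelihood gain any single outcome arc can achieve
(a median-split outcome conditioned on one tertile variable carries at most
about 0.67 bits per record), so no association could ever be accepted. A
`gate="global"` option retains that stricter variant for comparison.

Greedy search can in principle stop at a local optimum; in randomized
3-variable stress tests against exhaustive enumeration of all 25 DAGs this
occurs in well under 0.1% of datasets.

## Parameterization and inference

CPTs use Laplace smoothing: each cell is (count + α)/(total + α·r) with
α = 1 by default, counted over family-complete records; parent
configurations with no observations become uniform (also at α = 0).
Posteriors are computed by exact variable elimination with a greedy
min-size elimination order; evidence variables are reduced first and
unobserved variables are marginalized. With α > 0 the joint is strictly
positive; evidence of probability zero (possible at α = 0) raises a
dedicated error.

## The two-stage pipeline per timepoint

Pre- and post-antivenom panels are modeled independently.

1. **Selection.** One network is learned on the full table and one per
   leave-one-out fold. Every variable adjacent to the recovery node
   (first-degree associate) in at least one of those models is selected
   (the union rule); the adjacency frequency across models is always
   reported so users can see selection volatility at small n. A
   `min_frequency` threshold tightens the rule toward an intersection.
2. **Final model.** Structure and CPTs are refitted on the table restricted
   to the selected variables plus recovery.
3. **Evaluation.** Leave-one-out cross-validation: each patient is scored
   by P(recovery = good | evidence) from a model trained without them. In
   the default *nested* mode the whole pipeline — filter, discretization,
   selection, final model — is retrained inside each fold, so the held-out
   patient never influences any modeling choice; a non-nested mode
   (selection once, on all patients) is available for comparison and is
   flagged in all reports. Folds whose training labels collapse to one
   class, or that select no associate, score 0.5 and are flagged. The
   outcome labels themselves are fixed once from the whole cohort's median
   split — they are the outcome definition, not a tunable.

Scores feed a tie-corrected rank ROC: AUC = fraction of (good, poor) pairs
with the good patient scored higher, ties counting one half; the ROC sweeps
each distinct score once so tied scores collapse to single vertices, and the
trapezoidal area equals the rank statistic exactly. An AUC of 0.6 or above
is reported as a "good differentiator" (boundary inclusive).

Selection inside each fold defaults to the full + leave-one-out union
(`selection="loo_union"`), which at n patients costs O(n²) structure learns
per cross-validation; for the repeated calibration sweeps at n = 60 the
package uses the cheaper but equally leakage-free `selection="full_only"`
(associates of the single fold model), keeping many-seed calibration runs
tractable without touching the small-cohort default.

## Group contrasts

Per analyte, five-number summaries of the log values are computed per
recovery group on non-missing records. An analyte is flagged when the
absolute median difference exceeds 0.25 natural-log units — an explicit,
configurable numeric stand-in for the visual "difference based on box
plots" criterion, which is not reproducible as stated.

## The synthetic cohort generator

No patient-level data are distributed, so the generator produces cohorts
with the statistical structure the analysis assumes, plus the planted
ground truth (graph, per-patient latent severity, true labels) for testing.

* A scalar latent severity s ~ N(0, 1) per patient.
* Analytes: log value = baseline + sign · effect · s + N(0, 0.75), then
  exponentiated. Eight analytes are coupled (HGF, EOTAXIN, IL-10, IL-12,
  CCL2 rise with severity; CXCL10, CCL4, VEGF fall), mirroring the
  direction of good/poor contrasts seen in envenoming cohorts; the rest are pure noise.
  Baselines sit at plausible log pg/mL levels (HGF ≈ 6.2, CCL5 ≈ 7.3).
* Clinical: age ~ U(25, 80) and sex (80% female) are independent of
  severity; WBC and respiratory rate rise, CO2 falls, and antihistamine
  use becomes more likely with severity.
* PSFS: rises from a low day-0 score (mean 2.5) toward a plateau
  8.8 − 0.9 · effect · s with time constant 7 + 2 · effect · s days,
  observation noise SD 0.6, clamped to [0, 10]. At the default effect the
  AUPC distribution has median ≈ 0.72 and range ≈ 0.49–0.88, matching the
  scale of observed envenoming cohorts.
* Missingness is injected completely at random; the defaults blank a few
  low-abundance analytes in ~25% of records and CO2 in 15%.
* `severity_effect = 0` is the null regime: every feature is independent
  of recovery. `severity_effect = 3` is the strong-signal regime used in
  power checks.
* Paired mode (default) gives every patient both analyte timepoints;
  unpaired mode gives each patient exactly one.

What the generator does **not** emulate: assay chemistry (dilution, bead
fluorescence, quantitation limits as physical processes), batch effects
across plates, informative missingness, correlated analyte noise beyond the
shared severity factor, and dropout of PSFS visits. Tests passing on these
cohorts therefore demonstrate the pipeline's statistical machinery —
calibration under the null, power under strong coupling, leakage freedom —
not clinical validity on real envenoming data.

## Problem sizes used in the checks

Closed-form and oracle checks run at tiny sizes (3–6 nodes, up to 2000
records). Calibration uses 200 null cohorts of 60 patients; power uses
strong-signal cohorts of 60; structure recovery uses a 6-node chain at
n = 2000. The acceptance script runs the study-scale pipeline at n = 24
with the full nested leave-one-out-union selection, and the
calibration sweeps with fold-local single-model selection, as above.

## Known limitations

* Greedy search is a local optimizer; rare local optima exist (see above).
* With ~40 variables and 60 records, a handful of spurious arcs pass the
  MDL penalty by chance; this is inherent to score-based selection at this
  size and is why associate frequencies are always reported.
* Nested LOO-CV at small n is slightly pessimistic under the null (mean
  AUC ≈ 0.45 rather than 0.50 in the calibration sweep): selection fitting
  noise in each training fold produces weak anti-learning, a known
  small-sample effect of aggressive feature selection inside
  cross-validation.
* The AUPC normalization and interpolation are this package's inference
  from the plausible value range of the score, not a published rule.
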