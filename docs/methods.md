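# Methods

This note documents the models, statistical procedures, parameters and design
choices behind `idrbias`, and what the synthetic benchmarks do and do not
establish about real data.

## Data model

A dataset is a list of annotated proteins: an accession, an amino-acid
sequence, and two per-residue tracks — disorder (ORDER / DISORDER /
UNANNOTATED) and binding (NONBINDING / BINDING / UNANNOTATED).  Reference
files are FASTA-like, three physical lines per entry (header, sequence, label
string with `1`/`0`/`-`); the label alphabet is configurable because
benchmark distributions vary.  Binding is treated as a subset annotation of
disorder: proteins absent from the binding reference default to
all-NONBINDING (a strict mode leaves them unannotated instead).  Residue
coordinates are 1-based inclusive everywhere user-facing.  Non-standard
letters (X, U, B, Z, O, J) are kept in sequences but excluded from every
composition count, matching the 20-amino-acid scope of propensity scales.

## Regions, categories, classes

An IDR is a maximal run of at least `idr_min_len = 10` consecutive
disordered residues; unannotated residues break runs.  Binding regions are
maximal binding runs with `min_len = 1` (no minimum is imposed because none
is established for binding annotations).

IDR categories overlap and are functions of (region length, protein disorder
content, binding overlap), where disorder content counts *all* disordered
residues (also runs shorter than 10) over the sequence length:

| category | rule |
|---|---|
| fully disordered | protein content ≥ 0.8 |
| short | 10 ≤ length < 15 and content < 0.3 |
| long | length > 70 and 0.3 ≤ content ≤ 0.8 |
| binding | overlaps a binding region by ≥ 1 residue (additive) |
| other | no size rule matched |

Region statistics (counts, residue totals, median/mean lengths) count only
residues inside qualifying regions, while content counts every disordered
residue; the two definitions are deliberately kept distinct.

Protein-level classes are mutually exclusive and drive predictor routing.
Note the class rules use a *different* long threshold (> 15 residues,
`class_long_min = 16`) than the long region category (> 70); both are
separate configurable parameters:

1. fully disordered: content ≥ 0.8;
2. low content (≤ 0.3) with a short IDR (10–14);
3. low content with a binding IDR > 15 residues;
4. low content with a non-binding IDR > 15 residues;
5. high content (0.3 < c < 0.8) with a binding IDR;
6. high content with only non-binding IDRs.

A protein with low content that matches several rules is routed by the
precedence binding-long > non-binding-long > short (configurable); the
precedence is a package decision since multi-category proteins admit several
readings.  IDRs of exactly 15 residues trigger neither low-content rule —
the thresholds are implemented literally — so such proteins (and proteins
matching no rule at all) are UNASSIGNED.  High/low content boundaries are
inclusive at 0.3 for the low classes and strict (0.3, 0.8) for the high
classes, again following the rule text literally.

## Compositional enrichment

For a residue sample S and background B (by convention the non-disordered
residues of the same dataset, so scales for different samples share one
background and are directly comparable):

    enrichment(a) = (f_S(a) − f_B(a)) / f_B(a)   ∈ [−1, ∞)

Significance per amino acid is a two-sided permutation test on
|f_S(a) − f_B(a)|.  Under a random re-split of the pooled residues into
groups of the original sizes, the count of amino acid *a* in one group is
exactly hypergeometric (N = pooled total, K = pooled count of *a*,
n = group size), so the implementation samples that marginal directly
rather than materializing reshuffles — distributionally identical per amino
acid, vectorized, and deterministic given the seed.  The draw is taken for
the smaller of the two groups so that swapping sample and background with
the same seed reproduces identical p-values.  P-values use add-one
smoothing, p = (b + 1)/(n_resamples + 1); defaults are
`n_resamples = 10,000` and `alpha = 0.05`, with no multiple-testing
correction across the 20 amino acids (each call is reported at the per-AA
threshold, as is conventional for composition profiling).  Calls:
ENRICHED/DEPLETED when p < α by the sign of the frequency difference,
NEUTRAL otherwise.

Residues are the permutation unit; residue-level exchangeability ignores
within-protein autocorrelation of composition, which is absent in the
synthetic data (i.i.d. residues) but present in real sequences — p-values
on real data are therefore somewhat anti-conservative, and the calibration
results below certify the machinery, not real-sequence block structure.

## Scale comparison

Scales are compared by Kendall rank correlation; tau-b (tie-corrected) is
the default because computed enrichments can tie (e.g. at 0), and tau-a is
available for replication against sources whose variant is unknown (the two
coincide on untied data).  The matrix over a scale list is computed once per
pair and mirrored, so it is exactly symmetric with an exact unit diagonal.
The accuracy-vs-bias relation is the Pearson correlation between predictor
AUCs and the Kendall correlations of each predictor's putative-disorder
scale with the native disorder scale; it requires at least three predictors.
A published DisProt-derived disorder propensity ranking (P = 1.00 down to
W = C = 0.00) ships with the package as the external comparison scale.

## Predictor evaluation

All metrics pool residues across the proteins of a subset — they are not
per-protein averages — because per-residue benchmark AUCs are defined on
pooled residues.  Disorder is the positive class; unannotated residues are
excluded.  AUC is the Mann–Whitney rank statistic with ties averaged; AUPR
is the step integration of the precision–recall curve; MCC and F1 use the
predictor's native binary calls when present, else scores thresholded at
0.5 (the threshold is explicit and configurable).  Subsets with a single
class raise rather than reporting a degenerate value, and per-class tables
report such classes as missing, never as zeros.

### Bootstrap significance protocol

To compare two predictors, the protocol draws ⌊0.5·N⌋ proteins 100 times,
re-assesses both predictors on each identical draw, and tests the paired
per-draw metric values: Anderson–Darling normality of the differences at
0.05 (statistic computed directly; p-value by the D'Agostino–Stephens
approximation), then a paired Student t-test if normality is not rejected,
else a Wilcoxon signed-rank test.  Draws are *without* replacement by
default — a repeated half-split — because with-replacement draws would
double-count residues in pooled metrics; a classical bootstrap mode is
available.  Draws on which the metric is undefined are redrawn up to a cap.
If every paired difference is exactly zero (identical predictions) the
comparison reports p = 1.

A calibration caveat documented deliberately: the protocol measures whether
the *dataset-level* metric difference is robust across half-samples.  For
two predictors that genuinely produce the same scores it never rejects, but
for two *independent* uninformative predictors the realized dataset-level
difference is almost never exactly zero, and the half-sample spread has the
same order as that difference, so the protocol rejects far more often than
α under that null (≈0.85 observed in the acceptance suite at 200
repetitions).  It is a robustness assessment of an observed gap, not a
calibrated test of "both methods are equally accurate in expectation"; the
acceptance suite keeps a failing check in place to document this property
rather than masking it.

### Meta-predictor

Each predictor's scores are min–max normalized over all residues of the
dataset — per predictor, not per protein, since per-protein normalization
would destroy the cross-protein comparability that pooled metrics rely on.
The meta-track takes, for every protein, the normalized scores and the
native binary calls of the predictor routed for that protein's class
(routing by a class→predictor map with a default for UNASSIGNED; an
auto-routing mode picks the best per-class AUC).  Min–max is monotone, so
identity routing reproduces the routed predictor's AUC and AUPR exactly and
its calls verbatim.  The meta-predictor requires knowing each protein's
class a priori, so it is an upper bound/oracle construction, not a
deployable method.

## Synthetic benchmarks

The generator emulates the *structure* of a per-residue disorder benchmark:

* **Architecture.** For each requested class it places disordered (and
  optionally binding) segments that provably satisfy that class's rule —
  e.g. low-content proteins get segments totalling ≤ 0.28·L, fully
  disordered proteins one segment of 0.82–0.95·L — and re-derives every
  protein's class from the tracks before returning, raising on any mismatch.
  Infeasible requests (protein lengths too short for the class inequalities)
  fail validation before generation.
* **Composition.** Residues are i.i.d. from per-state frequency vectors: an
  ordered background close to the average protein composition, and a
  disordered composition obtained by reweighting it with canonical disorder
  biases.  Enrichment injections are multiplicative factors, renormalized,
  optionally per class.  I.i.d. sampling is sufficient for testing
  composition statistics and metrics; it reproduces no positional
  autocorrelation, termini preference or motif structure of real IDRs.
* **Scores.** Predictor tracks follow the binormal model: ordered residues
  score N(0,1), disordered N(δ,1) with δ = √2·Φ⁻¹(AUC_target), squashed to
  [0,1] by a logistic; binary calls threshold at the class midpoint δ/2.
  The closed form makes target AUCs verifiable analytically; a target of
  1.0 is generated as the separation limit.  Real predictor errors are not
  i.i.d. Gaussian — they correlate along the sequence and with composition
  — so passing tests certify the evaluation machinery, not realism of the
  error structure.

Presets fix the study conditions: `null` (no compositional difference,
100 × 100-residue proteins ≈ 5,000 + 5,000 residue pools) for type-I-error
calibration; `biased_scales` (three distinct injected bias profiles: fully
disordered, short, and a shared long+binding profile); `class_specialists`
(six classes × 15 proteins, six predictors at AUC 0.95 on their own class
and 0.55 elsewhere) for the meta-predictor benchmark; `caid_like` (165
proteins across all six classes, lengths 100–350) whose class mix was chosen
so the region-length statistics loosely track a real benchmark's (overall
median IDR length ≈ 34, short-IDR median 12).

## Numerical choices and problem sizes

All randomness flows through `numpy.random.Generator`; every entry point
takes a seed (or generator), records it in output metadata, and the pipeline
derives per-stage seeds from one run seed via a seed sequence, so reruns are
bit-identical.  Tie handling: ranks averaged in AUC; tau-b tie correction in
Kendall; permutation p-values count `≥ observed` so ties favour the null.
Degenerate inputs raise informative errors rather than returning NaN
(single-class subsets, constant scales, zero background frequencies,
constant-score normalization).

Test-suite problem sizes are desk-scale by design: calibration uses 200
replicates of 5,000 + 5,000 residues with 2,000 resamples; recovery uses
~20,000-residue pools and 10,000-residue score tracks; bootstrap power uses
300 × 80-residue proteins over 50 repetitions.  The acceptance script mirrors
these at the same or slightly reduced replicate counts and finishes in well
under a minute per stage.

## Known limitations

* The permutation unit is the residue; a protein-level block permutation
  (which would respect within-protein correlation on real data) is not
  implemented.
* The bootstrap protocol's null calibration caveat above.
* The meta-predictor needs ground-truth classes and is an oracle bound.
* Synthetic sequences have no positional structure; conclusions about real
  IDR biology require real annotated data, for which the readers accept the
  same file formats.
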