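# Methods

## Model

A tree-structured hybrid model (tree-SHM) over d binary inputs consists of
an ordered partition of the input positions into k contiguous blocks of
sizes n₁…n_k (the mechanistic prior), one black-box truth table
f_i : {0,1}^{n_i} → {0,1} per block, and an output table
g : {0,1}^k → {0,1}.  The label of input x is g(f₁(x|₁), …, f_k(x|_k)),
where x|_i denotes the block-i bits.  The input-output relation is stored as
a k-dimensional orthotope: one cell per input vector, 2^d cells in total.

Conventions fixed throughout the package: bit vectors are written
leftmost-first with the leftmost bit most significant, so lexicographic
order on bit strings equals numeric order on integer codes (all-zeros is
smallest, all-ones largest); module indices and positions are 1-based in
interfaces.  Block contiguity is assumed without loss of generality; a
`column_order` permutation in the structure file maps non-contiguous real
data onto it.

## Training

**Conflict graphs.**  For module i, defined orthotope cells are grouped by
their *context* (the bits outside block i).  Within a group, every pair of
cells with opposite labels contributes the edge between their block-i
projections.  Hash-grouping by context makes this O(k·N) in the number of
defined cells plus pairwise work inside groups; a naive scan over all cell
pairs is the reference implementation in the test suite and yields the same
edge sets.

**Parity state.**  Each graph carries a union-find structure augmented with
the parity (relative colour) of every vertex within its component.  Edge
insertion and the odd-cycle query ("would joining u and v merge two
same-coloured vertices?") are near-constant-time, so label determination can
update the graphs incrementally.  Breadth-first recolouring is the reference
implementation in the tests.  Colourings are anchored at the
lexicographically smallest vertex of each component (colour 0), making them
canonical up to the unresolvable global flip per component; a module's
function is unique (up to flip) exactly when its graph is connected.

**Label determination.**  Undefined cells are visited in lexicographic
order.  For each candidate label, the edges the assignment would induce are
tested against the parity state; if one label would close an odd cycle, the
opposite label is written immediately, its edges inserted, and the sweep
continues — later cells of the same pass see earlier deductions.  Sweeps
repeat until the table is total or a pass deduces nothing.  The alternative
schedule that restarts from the smallest undefined cell after every single
assignment reaches the same fixpoint; this is asserted in the tests, and the
full-sweep form is used because it is the cheaper of the two.  Edges are
maintained incrementally as cells are defined rather than rebuilt from
scratch between sweeps; since the edge set depends only on the set of
defined cells, both schedules yield identical graphs (also asserted in the
tests).

**Soundness.**  A ground-truth labelling induces a proper 2-colouring of
every conflict graph, so assigning a cell its true label can never close an
odd cycle; whenever a label is forced, it is therefore the true one.  The
converse does not hold: deduction is *not* complete relative to the set of
all tree-SHM completions consistent with the data.  The tests verify
soundness against an all-completions brute force on two-module instances
and measure (but never assert) completeness.

**Contradictory data.**  With noisy labels the graphs need not be
bipartite.  The default policy is *count-and-continue*: an edge whose
insertion contradicts the parity state is dropped (first-come-wins in the
deterministic scan order: modules in index order, cells in ascending code
order), a cell whose two candidate labels are both infeasible stays
undefined, and both events increment a reported conflict counter.  A strict
mode raises instead.  Graphs that have dropped edges are flagged and lose
the representative-vertex shortcut in the forcing query, falling back to
scanning all opposite-label vertices of the context group.

**Prediction.**  Determined cells (training or deduced) return their table
value.  Undetermined cells fall back to the majority training label (ties
break to 1) by default; `abstain` flags them so callers can restrict metrics
to the determined subset, and `random` draws a seeded fair coin.  Coverage
(the fraction of test cells determined without fallback) is always reported
alongside accuracy so results remain interpretable.

## Synthetic benchmark

The generator's defaults are the study conditions used everywhere in the
package: 30 random tree structures with k = 3 first-layer modules, block
sizes drawn uniformly from all ordered triples with entries in 2…6 and total
dimension d ∈ {8, …, 12}; per structure one random tree-SHM whose
truth-table entries are independent fair coins; training sets drawn
uniformly without replacement at fractions 0.20/0.30/0.40 of the 2^d cells
(size = round-half-up of fraction·2^d), five samples per structure and
fraction.  Label noise, when enabled, flips each training label
independently with probability p; feature-bit noise is not modelled.
Degenerate (constant) module or output functions are allowed by default —
they break no invariant, though they do produce instances whose labels
ignore a module and which are therefore harder to determine; an opt-in flag
resamples them.  Randomness flows through named child streams (structure /
functions / sampling / noise) spawned from one root seed, so enabling a
later stage never perturbs earlier draws and the whole benchmark is a pure
function of (config, seed).

Benchmark summary statistics (median/IQR and mean/SD of accuracy, recall,
precision and F1 per training fraction) are computed over the 150 runs per
fraction.  With the defaults the full 450-run design takes well under a
minute on one CPU; individual training runs on 4,096-cell orthotopes
complete in a few milliseconds.

Measured behaviour worth noting: with majority fallback the mean accuracy
at the 20 % fraction sits around 0.97 and at 40 % around 0.99.  The
fixpoint sweeps determine 89–94 % of held-out cells on average, and
deductions are always correct, so overall accuracy is dominated by
coverage.  How undetermined cells are scored is a reporting convention, not
part of the method; both the fallback and the coverage are therefore
surfaced explicitly.

## Clinical preprocessing

Five binary features are derived per patient, in fixed order (Age, BMI-1,
BMI-2, Acc-PaO₂/FiO₂, Acc-urine), grouped into a Biometric block (3 bits)
and a Physiology block (2 bits):

| feature | rule for '1' |
|---|---|
| Age | age ≥ 60 y |
| BMI-1 | BMI ≥ 26 |
| BMI-2 | 24.2 ≤ BMI < 26 or BMI ≥ 32 |
| Acc(Min(PaO₂/FiO₂)) | score < 298 mmHg |
| Acc(Min(urine output)) | score ≥ 9584 ml |

Min(·) takes the minimum measurement of each of the first seven ICU days;
the accumulation score Acc(x) = Σᵢ (8−i)·xᵢ weights day i by 8−i (weights
7…1), emphasising the days right after admission.  Threshold boundaries
follow the printed inequalities exactly.  Missing days are an error by
default; an off-by-default flag carries the previous day's minimum forward.
Distinct 5-bit patterns are labelled by their cohort mortality ratio:
label 1 (high mortality) when the ratio of non-survivors reaches 0.75.
Both the comparison direction (≥ by default) and the polarity (1 =
non-survivor) are configuration, since either convention is defensible.
The decision-tree feature-selection step that produced these thresholds is
not re-implemented; the rules are consumed as configuration.

**Synthetic cohort.**  No patient-level dataset is publicly deposited, so a
generator provides a synthetic stand-in for pipeline testing.  Ages are
normal (62 ± 9 y), BMI log-normal around 29, urine output log-normal around
780 ml/d with wide dispersion, and the PaO₂/FiO₂ weekly level comes from a
two-component severity mixture (30 % of patients around 7 mmHg, 70 % around
125 mmHg).  The low mode is deliberately far below anything physiological:
with weights summing to 28, the accumulated-minimum threshold of 298 mmHg
corresponds to a weekly average minimum near 10.6 mmHg, so a cohort
concentrated at the published median of 92 mmHg would binarize to a
constant bit and leave no recoverable structure.  The mixture keeps the
cohort median on the real scale (~92 mmHg) while letting every threshold
split the cohort.  Outcomes are produced by a *planted* two-module tree-SHM
(non-constant tables) evaluated on the patient's five bits, optionally
flipped with a noise probability.  Whether the observed pattern set
determines the full 32-cell orthotope depends on the draw — exactly as in
real cohorts, where only sufficiently covering training sets extrapolate
fully; zero-coverage draws were cross-checked against the all-completions
oracle and are genuinely underdetermined.  What the passing pipeline tests
show is that the operators compose correctly and that recoverable structure
is recovered; they do not show that real ICU data follows a tree-SHM, that
the planted functions resemble real physiology, or that the generator's
tails are clinically realistic.

## Comparison statistics

Classifiers are compared over multiple datasets by the Friedman test on
within-dataset ranks (rank 1 = best accuracy, ties averaged, so each row
sums to k(k+1)/2):

χ²_F = 12n/(k(k+1)) · (Σⱼ R̄ⱼ² − k(k+1)²/4),  df = k − 1.

The classic chi-square form is the default (the designs used here satisfy
the usual large-sample condition n > 15 or k > 4); scipy's implementation
with tie correction is the cross-check in the tests on tie-free data.
Post-hoc comparisons against a control use Holm's step-down method with
z = |R_c − R_j| / sqrt(k(k+1)/(6n)), two-sided normal raw p-values, and
rejection when the adjusted p falls below α or z exceeds the normal
critical value (3.090 at α = 0.001).

Metric conventions: the positive class is 1; precision, recall and F1
report 0 with a warning when their denominator is zero (relevant for
degenerate-prevalence instances).  Out-of-sample forecast performance is
accuracy restricted to the cells outside the training set — for binary
features every such cell lies outside the convex hull of the training data,
so this measures extrapolation.  Baseline classifier adapters (any
fit/predict estimator) run through the same harness as the hybrid learner;
their hyperparameter tuning is the caller's responsibility.

## Numerical and design choices

- Orthotope cells are write-once; redefinition with the same value is a
  no-op, with a different value an error.
- Enumeration of the full input space is capped at d ≤ 20 by default
  (the benchmarks use d ≤ 12).
- Majority-fallback ties break to 1; the majority is computed over training
  labels only.
- Deduction witnesses (module, vertex pair, context) are recorded for every
  forced label, enabling replay and explanation.
- Model JSON stores cells with provenance plus the deduction order, so a
  reloaded model reproduces the exact end-of-training graph state even for
  noisy (edge-dropping) runs.
- All file writes are atomic (write-temp-then-rename).

## Limitations

- Only two-layer tree structures are supported; inputs shared between
  modules (non-tree wiring) are out of scope.
- Deduction is sound but not complete: cells whose label is implied by the
  data in the all-completions sense may remain undetermined.
- Continuous or categorical features must be binarized upstream.
- The synthetic cohort is a test fixture, not a clinical simulator.
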