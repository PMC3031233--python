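# Methods

This note records the modelling and numerical choices behind `agerepair`,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Problem setting

Instances are human DNA repair genes, labelled positive when the gene is
ageing-related (in curated ageing-gene collections) and negative
otherwise. Cohorts of this kind have roughly 135–148 genes with 33
positives, so the positive class frequency sits near 0.22–0.24. The small
sample drives most design decisions below: interpretable low-variance
learners, stratified cross-validation, and exact (not asymptotic)
enrichment tests.

## Ontology closure

Gene annotation databases store only the most specific GO terms. Because
the ontology's `is_a` semantics implies every ancestor term also applies,
per-term statistics computed on raw annotations would be wrong; we
therefore extend each gene's specific biological-process terms with all
`is_a` ancestors before encoding. Choices:

- Only `is_a` edges are followed; `part_of` and other relations are
  ignored. The closure is the union of the specific terms and their proper
  ancestors, restricted to the `biological_process` namespace **after**
  closure (a BP term with a molecular-function parent keeps only its BP
  ancestors).
- Terms annotated to a gene but absent from the loaded ontology are
  skipped with a warning, not fatal: ontology releases drift, and the
  loader records release metadata in its logs rather than pinning one.
- `alt_id` aliases resolve to their canonical term; obsolete terms are
  excluded at load time; the `is_a` graph is verified acyclic.

The GO occurrence threshold *t* (minimum yes-count for a term column to
survive; default 3, sweep {3, 7, 11}) is applied after closure and before
duplicate removal, which makes column survival independent of which PPI
variant is being built. Raising *t* trades attribute availability for the
statistical reliability of each column's class-conditional estimates.

## Interaction features

An interaction is retained iff one endpoint is a cohort gene and its
evidence includes in vivo or in vitro experimentation; interactions
supported only by high-throughput screens are considered too weak.
Duplicate listings of a pair are merged first (evidence unioned), so a
pair is kept if any listing carries strong evidence. `#partners` counts
distinct partners (re-listed pairs count once; a self-interaction
contributes the protein itself once). The binary interaction columns
cover the *N* most connected proteins in the filtered network, ties broken
lexicographically for reproducibility.

## Classifiers

The two learners are trained deterministically given the dataset; there is
no stochastic choice anywhere in training.

**Decision tree.** Gain-ratio splitting restricted to candidates whose
information gain reaches the mean gain of all positive-gain per-attribute
candidates (the C4.5 eligibility guard, computed per attribute, with
numeric attributes contributing their gain-maximizing midpoint threshold).
A split must leave at least two branches with `min_leaf` (default 2)
instances. Nominal splits are multiway over observed values and consume
the attribute; numeric splits are binary at midpoints between consecutive
distinct observed values and may recur deeper. Instances missing the
tested value are routed whole to the heaviest branch, in training and in
prediction (fractional weighting is a non-goal). Pruning is pessimistic
subtree replacement: a node becomes a leaf when its upper-confidence error
estimate (exact binomial bound for zero observed errors, Wilson-style
upper bound otherwise, confidence 0.25) does not exceed the sum over its
leaves; by construction pruning never increases the tree's estimated
error. Gain-ratio ties break by attribute column order. Leaf
probabilities are Laplace-corrected class proportions, (k+1)/(n+2) — leaf
counts are tiny here and raw proportions would produce degenerate 0/1
scores that flatten the ROC ranking.

**Naive Bayes.** Priors are unsmoothed class frequencies. Nominal
conditionals are (count + 1) / (non-missing class count + |domain|);
numeric conditionals are per-class Gaussians whose variance is floored at
1e-6 of the attribute's global variance (absolute floor 1e-12) so constant
columns cannot produce singular densities. Posteriors are evaluated in log
space with log-sum-exp normalization; missing values are skipped, which is
exact under the model's conditional-independence assumption. An unseen
nominal value at prediction time is treated as missing and logged.

## Evaluation

Folds are stratified by class: within each class, instances are shuffled
with the seeded generator and dealt round-robin, carrying the position
across classes, so fold sizes and per-class counts both differ by at most
one. With only 33 positives, unstratified folds would occasionally starve
a test fold of positives and make the AUC undefined. AUC is computed once
on the predictions pooled over the ten test folds, by the rank-sum
formulation with midrank tie correction; pooling (rather than averaging
per-fold AUCs) is the convention of the Java data-mining toolkits this
design interoperates with for binary problems, and is stabler at this
sample size. The positive class for ROC purposes is *ageing*. Every
evaluation takes an explicit seed and reports it.

## Rule enrichment

Each root-to-leaf path is a conjunctive rule; repeated numeric tests on an
attribute collapse to the tightest interval. Coverage on a dataset counts
trials (instances satisfying every condition) and successes (trials in the
predicted class); instances missing any tested value are excluded from
both counts. Significance is the exact upper tail P(X ≥ k) of
Binomial(n, p₀), accumulated from log-factorial terms, with p₀ the
predicted class's relative frequency in the evaluated dataset (recomputed
per dataset: attribute cohorts and the expression cohort have slightly
different base rates). The test is one-sided because only
over-representation of the positive class is asked. No multiple-testing
correction is applied; reports carry the number of rules tested so users
can apply their own.

## Synthetic-data generator

The generator exists so every pipeline stage is testable end-to-end
without any external download. It is constructive — labels first, then
attributes drawn conditional on the label — so planted patterns have
exact, recorded coverage rather than expected coverage.

Defaults (chosen once to match the cohort regime described above):

- 140 genes, 33 positives (class frequency 0.236).
- Ontology: 150 BP terms, depth ≤ 6, level widths growing geometrically
  (factor 2), 25% of terms get a second parent.
- Annotations: ~5 specific terms per gene from the background; 3 planted
  terms annotated to positives with probability 0.8 and negatives 0.1.
- PPI: negatives draw 1 + Poisson(4) distinct background partners (mode
  ≈ 5); positives draw round(lognormal(log 18, 0.35)) — a heavy tail
  crossing the 15-partner mark that separates the classes. One positive
  gene is designated the hub and wired to exactly 10 positives and 1
  negative, mirroring the Ku80-like pattern; 15% of genes get one
  screen-only edge (exercises the evidence filter) and 5% a re-listed pair
  (exercises merging).
- Expression: 108 tissues, raw-scale lognormal values (median 1500); the
  planted tissue shifts positive means by e^shift (default shift 1.0); when
  the shift is positive, five positives are lifted above every other gene
  and the ground truth records the separating threshold, which lands in
  the thousands on the raw scale. Setting shift = 0 yields a null cohort
  with no expression signal at all.
- Ka/Ki: lognormal(log 0.3, 0.5) for both classes, 10% missing —
  deliberately non-predictive, reflecting that evolutionary rate carries
  little signal for this distinction.

What the generator does **not** emulate: the real GO topology or term
co-occurrence structure, the degree distribution of curated human
interactome databases, microarray normalization artefacts, or annotation
bias (well-studied ageing genes accumulate more annotations and
interactions in real databases — a confounder no synthetic null reproduces).
Passing the planted-signal tests therefore demonstrates that the pipeline
recovers structure that is present, not that real cohorts contain such
structure or that real-data accuracies would match.

## Problem sizes and determinism

Repeated-cohort experiments (planted-root recovery, null-cohort AUC) use
20 seeds each; the effect-size monotonicity check uses 5 shift values.
These sizes give binomial/rank statistics tight enough for the thresholds
tested (e.g. a 20-seed null AUC mean has a standard error of about 0.015)
while keeping a full test run under a minute. The same-seed runs are
byte-identical, including emitted files.

## Known limitations

- No fractional missing-value weighting, subtree raising or rule
  post-pruning in the tree; no kernel density option in Naive Bayes.
- The CSV reader relies on the JSON schema sidecar for exact typing;
  reading foreign CSVs requires supplying a schema.
- The binomial test conditions on observed coverage; rules selected by the
  tree on the same data are subject to selection optimism, which the
  per-dataset p₀ does not correct.
- Single-machine, single-threaded by design; grids over many cohorts are
  embarrassingly parallel but no executor is provided.
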