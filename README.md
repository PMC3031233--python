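# agerepair

Tools for asking a focused systems-biology question: **what distinguishes
ageing-related DNA repair genes from the rest of the DNA repair machinery?**
Some DNA repair genes cause progeroid (accelerated-ageing) syndromes when
defective — `WRN` in Werner's syndrome is the classic case — while most do
not. `agerepair` frames this as a supervised classification problem over
human DNA repair genes: each gene is an instance labelled *ageing* or
*non_ageing*, described by heterogeneous features, and the models are
deliberately interpretable so the learned structure itself (tree splits,
enriched rules) is the scientific output, not just an accuracy number.

## What the package does

**Feature construction.** For a cohort of genes it builds typed datasets
from five sources:

- *GO annotations*: each gene's specific biological-process terms are
  extended with every ancestor reachable over `is_a` edges (the ontology's
  semantics makes those implicit annotations real), then one-hot encoded;
  terms occurring in fewer than *t* genes are dropped (the occurrence
  threshold, conventionally *t* ∈ {3, 7, 11}).
- *Protein-protein interactions*: edges are kept only when one endpoint is
  in the cohort and the evidence includes in vivo or in vitro experiments
  (screen-only interactions are excluded). From the filtered network come
  the distinct-partner count `#partners` and binary `X_interaction`
  columns for the *N* most connected proteins.
- *DNA repair pathway* (12-category nominal), *Ka/Ki evolutionary rate*
  (numeric, missing allowed) and *tissue expression* (mean over probes per
  anatomy category; a separate expression-only dataset).

Five nested variants D1–D5 control the interaction block: D1 none, D2 adds
`#partners`, D3/D4/D5 add 10/20/30 interaction indicator columns.
Duplicate instances (identical on every attribute and the class) are
removed.

**Models.** Two classifiers are implemented in-package, both tolerant of
mixed types and missing values:

- a C4.5-style decision tree (gain-ratio splits with a mean-gain
  eligibility guard, midpoint numeric thresholds, pessimistic
  error-based pruning at confidence 0.25);
- Naive Bayes, scoring class *k* by
  P(C_k) · ∏ᵢ P(Aᵢ | C_k)
  with pseudo-count-smoothed nominal tables and per-class Gaussians.

**Evaluation.** Stratified 10-fold cross-validation; the Area Under the
ROC Curve is computed once on the pooled out-of-fold predictions via the
rank-sum (Mann–Whitney) formulation with midrank ties (0.5 = random,
1.0 = perfect).

**Rule analysis.** Every root-to-leaf path yields an IF–THEN rule; a rule
(or single attribute-value pattern) covering *n* genes of which *k* are in
its predicted class is scored with the exact one-sided binomial tail
P(X ≥ k), X ~ Binomial(n, p₀), where p₀ is the predicted class's relative
frequency in the dataset.

**Synthetic cohorts.** Because the kind of curated cohort this analysis
targets is assembled from many databases, the package ships a constructive
generator: 140 genes with 33 positives, a BP ontology DAG, a PPI network in
which positives have more partners (separating around 15) and one hub gene
whose 11 partners include 10 positives, and a 108-tissue expression matrix
with one tissue in which five positives are highly expressed. Every planted
pattern is recorded with exact realized coverage in a ground-truth file.

## Worked example

```python
from agerepair.simulate import GeneratorConfig, generate_cohort
from agerepair.features import build_dataset
from agerepair.classifiers import TreeLearner, NaiveBayesLearner
from agerepair.classifiers.tree import train_tree, root_attribute
from agerepair.evaluation import cross_validate, auc
from agerepair.rules import rules_report, attribute_value_pattern

cohort = generate_cohort(GeneratorConfig(seed=1))
data = build_dataset(cohort.records, cohort.interactions, cohort.ontology,
                     t=3, variant="D5")
print(f"{data.n_instances} instances, {len(data.attributes)} attributes, "
      f"positive frequency {data.class_frequency():.3f}")
for learner in (TreeLearner(), NaiveBayesLearner()):
    a = auc(cross_validate(data, learner, k=10, seed=1))
    print(f"{learner.name}: pooled 10-fold CV AUC = {a:.3f}")
tree = train_tree(data)
print("root attribute:", root_attribute(tree))
for rule in rules_report(tree, data):
    print(rule.render(), f" [n={rule.n_trials}, k={rule.n_successes}, "
                         f"p={rule.p_value:.3g}]")
hub = attribute_value_pattern(
    data, f"{cohort.ground_truth.hub_name}_interaction", "yes")
print(hub.render(), f" [n={hub.n_trials}, k={hub.n_successes}, "
                    f"p={hub.p_value:.3g}]")
```

prints

```
140 instances, 172 attributes, positive frequency 0.236
tree: pooled 10-fold CV AUC = 0.969
naive_bayes: pooled 10-fold CV AUC = 0.994
root attribute: #partners
IF (#partners <= 10.5) THEN class = non_ageing  [n=106, k=106, p=4.22e-13]
IF (#partners > 10.5) THEN class = ageing  [n=34, k=33, p=5.1e-20]
IF (DR091_interaction = yes) THEN class = ageing  [n=11, k=10, p=4.58e-06]
```

The tree roots on the partner count — genes whose proteins have many
interaction partners are predicted ageing-related — and the planted hub
gene's interaction column recovers its wired contingency exactly: of the 11
genes interacting with `DR091`, 10 are positives, an enrichment with exact
binomial tail 4.6 × 10⁻⁶ against the cohort's base rate of 0.236.

The same pipeline is scriptable from the shell:

```sh
agerepair simulate --seed 1 --out cohort/
agerepair build-dataset --ontology cohort/ontology.obo \
    --annotations cohort/annotations.tsv --ppi cohort/ppi.tsv \
    --genes cohort/genes.tsv --variant D5 --go-threshold 3 --out d5.csv
agerepair evaluate --dataset d5.csv --learner tree --folds 10 --seed 1
agerepair rules --dataset d5.csv
agerepair grid --ontology cohort/ontology.obo ... --out report/
```

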