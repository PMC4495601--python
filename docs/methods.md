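# Methods

## Problem and model

The package treats drug-target identification as rule-based
classification over a multi-relational feature store. The relations are
one-to-many (protein → degree bucket) and many-to-many (protein ↔ GO
term / pathway / domain); rather than flattening them into one sparse
table, each protein's related records are gathered into a nested item
set (a *case*), and an Apriori-style level-wise search mines the cases
directly. This preserves the semantics of the relational view while
using a conventional transactional miner as the engine.

### Network layer

Interaction records are binary, undirected and unweighted; detection-
method metadata in PSI-MI TAB input is ignored. The analysis network is
the one-step neighborhood of the seed proteins. Two constructions are
offered because public descriptions of such pipelines rarely say which
was used: `induced` (default) keeps all edges among included nodes,
`star` keeps only seed-incident edges. Induced is the default because
interactomes are locally clustered and neighbor–neighbor edges carry
real topological signal; `star` is retained for sensitivity checks.
The network summary averages shortest paths only within the largest
connected component — including unreachable pairs would make the mean
undefined — and reports the component count alongside so truncation is
visible.

### Feature encoding

* **Degree** is discretized with equal-frequency bucketing, default 5
  buckets, ties kept together. Equal-frequency is robust to the
  heavy-tailed degree distributions of real interactomes, where
  equal-width would put almost everything in the first bucket; it
  naturally produces narrow low-degree buckets and a wide top bucket.
  Labels are inclusive ranges over the *observed* values in the bucket
  (`10-77`), and `bucket_of` is total over the observed range, mapping
  unseen intermediate values to the bucket whose cut covers them.
* **Articulation** is a presence-only item (`articulation=Y`). Most
  proteins are not articulation points, and a two-state encoding would
  add a near-universal `articulation=N` item that floods the frequent-
  itemset lattice; `emit_negative_boolean_items=True` restores it.
* **GO aspect** is carried in the term label (`C:integral to plasma
  membrane`) rather than used as a filter; all three aspects
  participate in mining. True-path (ancestor) propagation is off by
  default — annotation rows are used as-is — with an optional closure
  over a flat term→parent table for sensitivity analyses. Evidence-code
  filtering is likewise off by default but configurable.

Negatives are drawn uniformly without replacement from network proteins
outside the positive set, which guarantees topology features exist for
every training case. Unlabeled proteins (e.g. connector genes — nodes
adjacent to both a disease gene and a known target) are excluded from
training and scored at prediction time with the training discretization
scheme.

## Mining

Frequent itemsets are found level-wise: candidates of size k+1 are
generated by prefix join over canonically sorted frequent k-itemsets,
pruned by downward closure, and counted by intersecting per-item
case-ID sets. Defaults: `min_support = 0.05` (fraction; an absolute
count is accepted), `min_probability = 0.4`, `max_itemset_size = 3` —
rules with at most two antecedent items, which keeps reports readable
and the search cheap; all are configurable. Rules have single-item
consequents only; multi-item consequents multiply cost without adding
interpretable rules. Rule order is total and deterministic:
probability desc, importance desc, antecedent size asc, lexicographic
rendering — reports are byte-identical across runs.

**Importance** is `log10[P(Y|X) / P(Y|¬X)]` estimated from the 2×2 case
contingency. Base 10 is the package convention (configurable). When
`P(Y|¬X) = 0` — or no case falls outside X — an additive constant
α = 0.5 is applied to all four cells before the ratio; the smoothing is
applied *only* in that degenerate branch so clean contingencies are
exact. At α = 0 the sign of the importance agrees exactly with the
direction of the conditional shift. A rule whose antecedent matches no
case returns NaN with a warning rather than a fabricated value.

## Classification

Best-rule aggregation: among rules whose antecedent is contained in the
case's items, the top-ranked rule per class state supplies p(Y) and
p(N); with both present `P(target) = p(Y) / (p(Y) + p(N))`; with only
Y-rules, p(Y); with only N-rules, `1 − p(N)` (the symmetric choice —
the contract for that branch was otherwise open); with none, the
training prior, flagged `fallback_used`. Best-rule keeps every
prediction explainable by one rule; a `weighted` alternative averages
the top-k matching rules per class. Items unseen at training time are
ignored with a per-case count. The decision threshold defaults to 0.5;
accuracy is threshold-dependent and reported as such.

## Evaluation

AUC is the tie-aware Mann–Whitney statistic computed from average
ranks, identical to the trapezoidal ROC area (cross-checked against
scikit-learn in the tests). Likelihood metrics use log base 10 and a
probability floor of 1e−6 (rule models can emit exact 0/1); the lift is
computed as the exact difference of the two mean log scores, so the
identity `lift = log_score − prior_log_score` holds to machine
precision by construction. The lift chart is cumulative-gains style
(positives captured vs fraction of ranked population), with the ideal
and diagonal curves attached.

Cross-validation is stratified k-fold (k = 10 default) via
scikit-learn's `StratifiedKFold`, seeded and fully reproducible. The
ablation study shares one fold assignment across feature masks so
differences are attributable to the features alone. Baselines run
behind the same learner interface: the Bernoulli naive Bayes is
implemented in-repo from the likelihood with add-one smoothing; the
decision tree and the one-hidden-layer neural network delegate to
scikit-learn over one-hot item indicators; a constant-prior dummy
learner anchors the no-signal floor.

## Enrichment

Term over-representation uses the upper-tail hypergeometric
`P(X ≥ k)` (scipy), equal to the one-tailed Fisher exact test on the
2×2 table — the tests assert this identity. The default population is
the tested universe (all network proteins), configurable because the
right background depends on the study design. Benjamini–Hochberg
q-values are reported, but the significance flag uses the raw p ≤ α
threshold (α = 0.05 default) to match common practice in this setting.

## Synthetic benchmark

The generator emulates the statistical shape of the real inputs at desk
scale: 600 proteins by default, preferential attachment with m = 2
(heavy-tailed degrees, which also keeps equal-frequency degree buckets
non-degenerate), Poisson per-protein annotation counts (means 3 GO,
1.5 pathway, 1 domain), Zipf-distributed term popularity (exponent 1.2
— real GAFs have very popular terms), and three planted rules with
confidence q = 0.95 covering 12 % of proteins each. Covered proteins
are positive with probability q; the rest with probability
`positive_rate × noise_rate` = 0.3 × 0.1 = 0.03, giving ≈ 36 %
prevalence — a deliberately balanced regime so 10-fold stratified CV is
well-posed at n = 600. Planted antecedent terms are *reserved*: never
drawn in background sampling, so the empirical confidence of a planted
rule concentrates at q. A topology-only variant plants a single rule on
the top-degree quintile, used to verify that removing topology features
destroys the lift when topology is the only signal.

What the generator does **not** emulate: biological semantics of terms,
correlated annotations (real GO terms co-occur along the DAG), homology
structure, false-positive interaction edges, and study-bias in
annotation density. Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted signal under realistic
sparsity — not expected performance on any real interactome snapshot.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at n = 600
proteins with 10-fold CV, the miner-vs-enumeration check on 100 random
case sets of ≤ 15 items / ≤ 40 cases, and the articulation check on 200
random graphs of ≤ 60 nodes — sizes at which the brute-force oracles
are exact and fast. Probability comparisons in rule filtering use a
1e−12 slack so exact-threshold rules (probability exactly equal to the
minimum) are kept regardless of floating-point division order. All
randomness funnels through explicit seeds; identical seeds give
byte-identical generated files and reports.

## Known limitations

* The exact discretization, importance smoothing and
  prediction-from-rules procedures of commercial association-mining
  suites are proprietary; the choices here (equal-frequency buckets,
  α-smoothing, best-rule aggregation) are documented stand-ins, each
  configurable.
* Best-rule probabilities are not calibrated; likelihood metrics on
  them are comparative, not absolute.
* The miner enumerates itemsets level-wise; at `max_itemset_size` well
  beyond 3 with thousands of frequent items, an FP-growth-style engine
  would be preferable.
* Enrichment is DAG-unaware; parent/child GO terms are tested
  independently.
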