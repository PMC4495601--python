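# mram — multi-relational association mining for drug-target prioritization

`mram` predicts which proteins in a protein–protein interaction network
(PIN) are likely drug targets by mining association rules over
heterogeneous per-protein features. It is aimed at computational
biologists who have a list of known drug targets, an interactome dump,
and functional annotations, and want an *explainable* ranked list of
candidate targets: every prediction traces back to a printable rule.

## The method

Each labeled protein becomes a *case* — a bag of `attribute=value`
items drawn from five feature dimensions:

* **degree centrality** `DC(p) = |{q : (p,q) ∈ E}|`, discretized into
  equal-frequency buckets rendered as inclusive ranges (`degree=10-77`);
* **articulation status** — whether removing the protein disconnects
  its network component;
* **GO terms** (all three aspects, the aspect kept as an `F:`/`P:`/`C:`
  label prefix), **pathways** and **protein domains**.

Known drug targets supply the positive class (`class=Y`); negatives are
sampled uniformly from the remaining network proteins. A level-wise
Apriori search with downward-closure pruning enumerates every itemset
with support ≥ `MINIMUM_SUPPORT`, then induces rules `X ⇒ y` with
single-item consequents kept when

```
probability = support(X ∪ {y}) / support(X)  ≥  MINIMUM_PROBABILITY
importance = log10[ P(y | X) / P(y | ¬X) ]
```

(the 2×2 contingency is additively smoothed only when `P(y|¬X) = 0`).
Classification is best-rule: the top-ranked matching rule per class
state supplies that state's probability and the two are renormalized
into `P(target)`; unmatched cases fall back to the class prior.
Performance is assessed by stratified 10-fold cross-validation with
accuracy, Mann–Whitney AUC, cumulative-gains lift charts and the
likelihood metrics

```
log_score = mean log10 p̂(true class)
lift      = log_score − prior log score
rmse      = sqrt(mean (1 − p̂(true class))²)
```

against decision-tree, naive-Bayes and neural-network baselines behind
one learner interface. Candidate *connector genes* (nodes adjacent to
both a disease gene and a known target) are scored at prediction time,
and predicted target sets can be tested for GO/pathway
over-representation with an upper-tail hypergeometric test plus
Benjamini–Hochberg q-values.

A synthetic benchmark generator ships with the package: a preferential-
attachment network with Zipf-distributed annotations and *planted*
high-confidence antecedent ⇒ target rules, so every stage is testable
without downloading any database.

## Worked example

```python
from mram import (SyntheticConfig, generate, build_pin, build_cases,
                  MiningParams, mine_rules, cross_validate)

dataset = generate(SyntheticConfig(seed=17))          # 600 proteins
net = build_pin(dataset.edges, dataset.positives | dataset.negatives)
cases = build_cases(net, dataset.annotations,
                    dataset.positives, dataset.negatives)
model = mine_rules(cases, MiningParams(min_support=0.05,
                                       min_probability=0.8,
                                       consequent_filter="class"))
print(f"{len(cases)} cases, {len(model.rules)} rules")
top = model.rules[0]
print(f"top rule: {top.render()}")
print(f"  probability={top.probability:.3f} importance={top.importance:.3f}")

report = cross_validate(cases, "mram", k=10, seed=17,
                        params=MiningParams(min_support=0.05,
                                            min_probability=0.4,
                                            consequent_filter="class"))
for name in ("auc", "likelihood_lift", "rmse", "accuracy"):
    mean, sd = report.mean_sd[name]
    print(f"{name}: {mean:.3f} +/- {sd:.3f}")
```

prints

```
600 cases, 18 rules
top rule: go=GO:0000001, go=GO:0099002 => class=Y
  probability=1.000 importance=0.523
auc: 0.984 +/- 0.014
likelihood_lift: 0.079 +/- 0.007
rmse: 0.374 +/- 0.009
accuracy: 0.977 +/- 0.018
```

The top rule is one of the three planted implications recovered at
probability 1 (every protein carrying both terms is a target); its
importance 0.523 means carrying the antecedent raises the target odds
by half an order of magnitude. The cross-validated AUC of 0.98 sits
just under the generator's Bayes-optimal bound, and the positive
likelihood lift shows the rule model beats prior-only guessing.

The same workflow runs from the shell:

```bash
mram simulate --seed 17 --out data/
mram run --config config.yaml --out results/
```

where `config.yaml` points at the edge list, GAF, membership TSVs and
label lists (`mram run --help` lists the keys).

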