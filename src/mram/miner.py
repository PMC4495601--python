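"""Association-rule mining over labeled protein cases.

Level-wise (Apriori-style) frequent-itemset search with downward-closure
pruning, followed by rule induction ``X => y`` with single-item
consequents. Three statistics are attached to every rule:

* support  — fraction of cases containing X ∪ {y};
* probability (confidence) — support(X ∪ {y}) / support(X);
* importance — log10 of P(y | X) / P(y | ¬X), the log-likelihood shift
  the antecedent produces on the consequent. When no case outside X
  carries y, the 2x2 contingency is smoothed with an additive constant
  before the ratio so the statistic stays finite.

Support counting uses vertical case-ID sets per item; candidate
(k+1)-itemsets are generated by prefix join over sorted k-itemsets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .relstore import CaseSet, Item


@dataclass
class MiningParams:
    """Thresholds controlling the search.

    ``min_support`` may be given as a fraction (default 0.05) or an
    absolute case count via ``min_support_count``. ``max_itemset_size``
    defaults to 3 (rules with at most two antecedent items plus the
    consequent). ``consequent_filter`` restricts rule consequents to one
    attribute, typically ``class`` for target prediction.
    """

    min_support: float = 0.05
    min_probability: float = 0.4
    max_itemset_size: int = 3
    consequent_filter: str | None = None
    min_support_count: int | None = None
    importance_alpha: float = 0.5
    importance_base: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError("min_support must be in (0, 1]")
        if not (0 < self.min_probability <= 1):
            raise ValueError("min_probability must be in (0, 1]")
        if self.max_itemset_size < 2:
            raise ValueError("max_itemset_size must be >= 2")

    def support_count(self, n_cases: int) -> int:
        if self.min_support_count is not None:
            return max(1, self.min_support_count)
        return max(1, math.ceil(self.min_support * n_cases))


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[Item]
    support: float
    count: int

    def render(self) -> str:
        return ", ".join(sorted(it.render() for it in self.items))


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[Item]
    consequent: Item
    support: float
    probability: float
    importance: float

    def render(self) -> str:
        lhs = ", ".join(sorted(it.render() for it in self.antecedent))
        rhs = self.consequent.render()
        return f"{lhs} => {rhs}" if lhs else f"=> {rhs}"


@dataclass
class RuleModel:
    """An association model: ranked rules plus the training class priors."""

    rules: list[AssociationRule]
    priors: dict[str, float]
    params: MiningParams
    item_universe: set[Item] = field(default_factory=set)

    def class_rules(self) -> list[AssociationRule]:
        return [r for r in self.rules if r.consequent.attribute == "class"]

    # -- persistence ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "mram-rules/1",
            "priors": self.priors,
            "params": {
                "min_support": self.params.min_support,
                "min_probability": self.params.min_probability,
                "max_itemset_size": self.params.max_itemset_size,
                "consequent_filter": self.params.consequent_filter,
            },
            "item_universe": sorted(it.render() for it in self.item_universe),
            "rules": [
                {
                    "antecedent": sorted(it.render() for it in r.antecedent),
                    "consequent": r.consequent.render(),
                    "support": r.support,
                    "probability": r.probability,
                    "importance": r.importance,
                }
                for r in self.rules
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleModel":
        payload = json.loads(Path(path).read_text())
        rules = [
            AssociationRule(
                antecedent=frozenset(Item.parse(t) for t in r["antecedent"]),
                consequent=Item.parse(r["consequent"]),
                support=r["support"],
                probability=r["probability"],
                importance=r["importance"],
            )
            for r in payload["rules"]
        ]
        params = MiningParams(**payload["params"])
        model = cls(
            rules=rules,
            priors=payload["priors"],
            params=params,
            item_universe={Item.parse(t) for t in payload["item_universe"]},
        )
        model.rules = _sorted_rules(model.rules)
        return model


def _item_key(item: Item) -> tuple[str, str]:
    return (item.attribute, item.value)


def mine_frequent_itemsets(
    cases: CaseSet, params: MiningParams
) -> list[FrequentItemset]:
    """All itemsets of size 1..max_itemset_size with support >= threshold.

    Level-wise search: frequent k-itemsets are joined on their first k-1
    items (canonical order) to propose (k+1)-candidates, every k-subset
    of which must itself be frequent (downward closure) before its
    support is counted by intersecting per-item case-ID sets. Output is
    deterministic: itemsets sorted by (size, rendered form).
    """
    n = len(cases)
    if n == 0:
        raise ValueError("empty case set")
    min_count = params.support_count(n)

    tidsets: dict[Item, set[int]] = {}
    for idx, case in enumerate(cases.cases):
        for it in case.items:
            tidsets.setdefault(it, set()).add(idx)

    results: list[FrequentItemset] = []
    # level 1
    frequent: dict[tuple[Item, ...], set[int]] = {}
    for it in sorted(tidsets, key=_item_key):
        tids = tidsets[it]
        if len(tids) >= min_count:
            frequent[(it,)] = tids
            results.append(FrequentItemset(frozenset((it,)), len(tids) / n, len(tids)))

    k = 1
    while k < params.max_itemset_size and frequent:
        keys = sorted(frequent, key=lambda t: tuple(_item_key(i) for i in t))
        frequent_set = set(keys)
        nxt: dict[tuple[Item, ...], set[int]] = {}
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = keys[i], keys[j]
                if a[:-1] != b[:-1]:
                    break  # sorted order: no further shared prefix
                cand = a + (b[-1],)
                # downward closure: every k-subset must be frequent
                if any(
                    cand[:m] + cand[m + 1:] not in frequent_set
                    for m in range(len(cand) - 1)
                ):
                    continue
                tids = frequent[a] & tidsets[cand[-1]]
                if len(tids) >= min_count:
                    nxt[cand] = tids
        for cand in sorted(nxt, key=lambda t: tuple(_item_key(i) for i in t)):
            tids = nxt[cand]
            results.append(
                FrequentItemset(frozenset(cand), len(tids) / n, len(tids))
            )
        frequent = nxt
        k += 1
    return results


def rule_importance(
    antecedent: frozenset[Item],
    consequent: Item,
    cases: CaseSet,
    alpha: float = 0.5,
    base: float = 10.0,
) -> float:
    """log_base of P(Y|X) / P(Y|not-X) from the 2x2 case contingency.

    ``alpha`` is added to all four cells only when P(Y|not-X) would be
    zero (or no case falls outside X), keeping the score finite while
    leaving clean contingencies exact. Returns NaN with no matching-X
    cases (the rule is not evaluable).
    """
    a = b = c = d = 0  # X&Y, X&~Y, ~X&Y, ~X&~Y
    for case in cases.cases:
        items = case.items
        has_x = antecedent <= items
        has_y = consequent in items
        if has_x and has_y:
            a += 1
        elif has_x:
            b += 1
        elif has_y:
            c += 1
        else:
            d += 1
    if a + b == 0:
        return float("nan")
    if c == 0 or c + d == 0:
        if alpha <= 0:
            return float("inf") if a > 0 else float("nan")
        a, b, c, d = a + alpha, b + alpha, c + alpha, d + alpha
    p_given_x = a / (a + b)
    p_given_notx = c / (c + d)
    if p_given_x == 0:
        return float("-inf")
    return math.log(p_given_x / p_given_notx, base)


def _sorted_rules(rules: Iterable[AssociationRule]) -> list[AssociationRule]:
    # total, deterministic order: probability desc, importance desc,
    # antecedent size asc, lexicographic rendering
    return sorted(
        rules,
        key=lambda r: (
            -r.probability,
            -(r.importance if math.isfinite(r.importance) else -math.inf),
            len(r.antecedent),
            r.render(),
        ),
    )


def induce_rules(
    itemsets: Sequence[FrequentItemset], cases: CaseSet, params: MiningParams
) -> RuleModel:
    """Derive ranked rules X => y from the frequent itemsets.

    For every frequent itemset Z and every item y in Z (restricted to
    ``consequent_filter`` when set), the rule Z\\{y} => y is emitted when
    its probability support(Z)/support(Z\\{y}) reaches min_probability.
    Single-item consequents only.
    """
    support_by_set = {fs.items: fs.support for fs in itemsets}
    rules: list[AssociationRule] = []
    n = len(cases)
    for fs in itemsets:
        if len(fs.items) < 2:
            continue
        for y in fs.items:
            if (
                params.consequent_filter is not None
                and y.attribute != params.consequent_filter
            ):
                continue
            antecedent = fs.items - {y}
            ant_support = support_by_set.get(antecedent)
            if ant_support is None:
                # antecedent is a subset of a frequent set: always frequent
                count = sum(
                    1 for case in cases.cases if antecedent <= case.items
                )
                ant_support = count / n
            probability = fs.support / ant_support
            if probability + 1e-12 < params.min_probability:
                continue
            imp = rule_importance(
                antecedent, y, cases,
                alpha=params.importance_alpha, base=params.importance_base,
            )
            rules.append(
                AssociationRule(
                    antecedent=antecedent,
                    consequent=y,
                    support=fs.support,
                    probability=min(probability, 1.0),
                    importance=imp,
                )
            )
    return RuleModel(
        rules=_sorted_rules(rules),
        priors=cases.priors,
        params=params,
        item_universe=cases.item_universe,
    )


def mine_rules(cases: CaseSet, params: MiningParams) -> RuleModel:
    """Convenience: frequent itemsets + rule induction in one call."""
    return induce_rules(mine_frequent_itemsets(cases, params), cases, params)


def write_rule_report(model: RuleModel, path: str | Path,
                      term_labels: dict[str, str] | None = None) -> None:
    """Three-column TSV report: Probability, Importance, Rule.

    Rules render as ``attr=value, attr=value => DT = Y`` for class
    consequents; ``term_labels`` substitutes human-readable term names.
    """
    labels = term_labels or {}

    def _fmt_item(it: Item) -> str:
        value = labels.get(it.value, it.value)
        return f"{it.attribute}={value}" if it.attribute != "class" else ""

    lines = ["Probability\tImportance\tRule"]
    for r in model.rules:
        lhs = ", ".join(
            sorted(_fmt_item(it) for it in r.antecedent)
        )
        if r.consequent.attribute == "class":
            rhs = f"DT = {r.consequent.value}"
        else:
            rhs = _fmt_item(r.consequent)
        imp = f"{r.importance:.3f}" if math.isfinite(r.importance) else "NA"
        lines.append(f"{r.probability:.3f}\t{imp}\t{lhs} => {rhs}")
    Path(path).write_text("\n".join(lines) + "\n")
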