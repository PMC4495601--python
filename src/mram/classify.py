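"""Rule-based classification of proteins as drug targets.

Prediction follows a best-rule strategy: among the rules whose antecedent
is contained in the case's feature items, the top-ranked rule for each
class state supplies that state's probability estimate, and the two are
renormalized into P(target). A case matching no rule falls back to the
training prior, so every prediction is defined and every non-fallback
prediction is explainable by one printable rule. A weighted alternative
averages the top-k matching rules per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .miner import AssociationRule, RuleModel
from .relstore import Case, CaseSet

logger = logging.getLogger("mram.classify")


@dataclass
class Prediction:
    case_id: str
    p_positive: float
    predicted_class: str
    matched_rule: AssociationRule | None
    fallback_used: bool
    n_unseen_items: int = 0


def _best_per_class(
    model: RuleModel, features: frozenset
) -> dict[str, list[AssociationRule]]:
    matching: dict[str, list[AssociationRule]] = {}
    for rule in model.class_rules():  # already ranked
        if rule.antecedent <= features:
            matching.setdefault(rule.consequent.value, []).append(rule)
    return matching


def predict_proba(
    model: RuleModel,
    case: Case,
    aggregate: Literal["best", "weighted"] = "best",
    top_k: int = 3,
) -> Prediction:
    """Score one case against the rule model.

    With both class states matched, p = p(Y) / (p(Y) + p(N)); with only
    one state matched, that state's probability is used directly (its
    complement for N-only matches). With no match the training prior
    P(class=Y) is returned and ``fallback_used`` is set.
    """
    if not model.class_rules():
        raise ValueError("model contains no class-consequent rules")
    unseen = sum(1 for it in case.feature_items if it not in model.item_universe)
    features = frozenset(it for it in case.feature_items
                         if it in model.item_universe)
    matching = _best_per_class(model, features)

    def _state_p(rules: list[AssociationRule]) -> float:
        if aggregate == "weighted":
            chosen = rules[:top_k]
            return sum(r.probability for r in chosen) / len(chosen)
        return rules[0].probability

    prior_y = model.priors.get("Y", 0.0)
    if not matching:
        return Prediction(case.case_id, prior_y, "N" if prior_y < 0.5 else "Y",
                          None, True, unseen)
    p_y = _state_p(matching["Y"]) if "Y" in matching else None
    p_n = _state_p(matching["N"]) if "N" in matching else None
    if p_y is not None and p_n is not None:
        denom = p_y + p_n
        p_pos = p_y / denom if denom > 0 else prior_y
        best = matching["Y"][0]
    elif p_y is not None:
        p_pos = p_y
        best = matching["Y"][0]
    else:
        p_pos = 1.0 - p_n
        best = matching["N"][0]
    return Prediction(case.case_id, p_pos, "Y" if p_pos >= 0.5 else "N",
                      best, False, unseen)


def predict_batch(
    model: RuleModel,
    cases: CaseSet | Sequence[Case],
    threshold: float = 0.5,
    aggregate: Literal["best", "weighted"] = "best",
    top_k: int = 3,
) -> list[Prediction]:
    """Score a batch and rank by P(target) descending.

    Items unseen at training time are ignored per case (a count is kept
    on each prediction and logged in aggregate). The ranking is
    deterministic: ties broken by case ID.
    """
    case_list = cases.cases if isinstance(cases, CaseSet) else list(cases)
    if isinstance(cases, CaseSet) and cases.schemes and model.item_universe:
        _check_scheme_compatibility(cases, model)
    preds = []
    for case in case_list:
        p = predict_proba(model, case, aggregate=aggregate, top_k=top_k)
        p.predicted_class = "Y" if p.p_positive >= threshold else "N"
        preds.append(p)
    total_unseen = sum(p.n_unseen_items for p in preds)
    if total_unseen:
        logger.info("ignored %d feature items unseen at training time",
                    total_unseen)
    return sorted(preds, key=lambda p: (-p.p_positive, p.case_id))


def _check_scheme_compatibility(cases: CaseSet, model: RuleModel) -> None:
    model_buckets = {
        it.value for it in model.item_universe if it.attribute == "degree"
    }
    scheme = cases.schemes.get("degree")
    if scheme is not None and model_buckets:
        case_buckets = set(scheme.bucket_labels)
        if not (case_buckets & model_buckets):
            raise ValueError(
                "degree discretization mismatch between cases and model: "
                f"case buckets {sorted(case_buckets)} vs "
                f"model buckets {sorted(model_buckets)}"
            )


def write_predictions(preds: Iterable[Prediction], path: str | Path) -> None:
    lines = ["case_id\tp_positive\tpredicted_class\tmatched_rule\tfallback_used"]
    for p in preds:
        rule = p.matched_rule.render() if p.matched_rule else "NA"
        lines.append(
            f"{p.case_id}\t{p.p_positive:.6f}\t{p.predicted_class}\t"
            f"{rule}\t{str(p.fallback_used).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
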