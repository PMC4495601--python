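"""Evaluation battery: accuracy, AUC, lift charts, likelihood metrics.

Classifier quality is judged under stratified k-fold cross-validation by
four measures:

* accuracy at a fixed decision threshold;
* AUC as the tie-aware Mann-Whitney statistic P(score_pos > score_neg)
  + 0.5 P(tie), equal to the trapezoidal ROC area;
* likelihood log score — mean log10 of the probability the model
  assigned to each case's true class;
* likelihood lift — the excess of the log score over the prior-only
  score (0 means no better than guessing the class frequencies);
* likelihood RMSE — sqrt(mean (1 - p_true)^2).

Baseline learners (decision tree, Bernoulli naive Bayes, neural network
over one-hot item indicators, constant-prior dummy) run behind the same
learner interface as the rule miner so the comparison is like-for-like.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classify import predict_batch
from .miner import MiningParams, mine_rules
from .relstore import Case, CaseSet, Item

PROB_FLOOR = 1e-6  # rule models can emit 0; floor before logs
LOG_BASE = 10.0


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy(predicted: Sequence[str], labels: Sequence[str]) -> float:
    """Fraction of predictions equal to the true class label."""
    if len(predicted) != len(labels):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs "
            f"{len(labels)} labels"
        )
    if not labels:
        raise ValueError("empty prediction list")
    return sum(p == y for p, y in zip(predicted, labels)) / len(labels)


def auc(scores: Sequence[float], labels: Sequence[int | str]) -> float:
    """Mann-Whitney AUC with the half-credit tie convention."""
    y = np.asarray([1 if v in (1, "Y", True) else 0 for v in labels])
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and labels differ in length")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def likelihood_metrics(
    p_true: Sequence[float],
    prior_true: Sequence[float],
    base: float = LOG_BASE,
    floor: float = PROB_FLOOR,
) -> tuple[float, float, float]:
    """(log_score, likelihood_lift, rmse) from per-case true-class probabilities.

    ``p_true[i]`` is the model's probability for case i's actual class and
    ``prior_true[i]`` the class prior of that same class. Probabilities
    are floor-clipped before logs. The lift is computed as the exact
    difference of the two mean log scores, so the identity
    lift = log_score - prior_log_score holds to machine precision.
    """
    p = np.clip(np.asarray(p_true, dtype=float), floor, 1.0)
    q = np.clip(np.asarray(prior_true, dtype=float), floor, 1.0)
    if p.shape != q.shape:
        raise ValueError("p_true and prior_true differ in length")
    log_score = float(np.mean(np.log(p) / math.log(base)))
    prior_log_score = float(np.mean(np.log(q) / math.log(base)))
    lift = log_score - prior_log_score
    rmse = float(np.sqrt(np.mean((1.0 - p) ** 2)))
    return log_score, lift, rmse


@dataclass
class LiftCurve:
    """Cumulative-gains curve: positives captured vs fraction examined."""

    points: list[tuple[float, float]]
    ideal: list[tuple[float, float]]
    baseline: list[tuple[float, float]]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["population_fraction\tmodel\tideal\tbaseline"]
        for (x, m), (_, i), (_, b) in zip(self.points, self.ideal, self.baseline):
            lines.append(f"{x:.6f}\t{m:.6f}\t{i:.6f}\t{b:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def plot(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for curve, label in ((self.points, "model"), (self.ideal, "ideal"),
                             (self.baseline, "random")):
            xs, ys = zip(*curve)
            ax.plot(xs, ys, label=label)
        ax.set_xlabel("fraction of ranked population")
        ax.set_ylabel("fraction of positives captured")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def lift_chart(scores: Sequence[float], labels: Sequence[int | str]) -> LiftCurve:
    """Cumulative gains: cases ranked by score descending.

    Point k is (k/n, positives among the top k / all positives); the
    ideal curve ranks every positive first and reaches 1 at the positive
    prevalence; the baseline is the diagonal.
    """
    y = np.asarray([1 if v in (1, "Y", True) else 0 for v in labels])
    s = np.asarray(scores, dtype=float)
    n, n_pos = len(y), int(y.sum())
    if n_pos == 0 or n_pos == n:
        raise ValueError("lift chart needs both classes present")
    order = np.argsort(-s, kind="stable")
    captured = np.cumsum(y[order]) / n_pos
    xs = np.arange(1, n + 1) / n
    points = [(0.0, 0.0)] + list(zip(xs.tolist(), captured.tolist()))
    ideal = [(0.0, 0.0)] + [
        (k / n, min(k / n_pos, 1.0)) for k in range(1, n + 1)
    ]
    baseline = [(0.0, 0.0)] + [(k / n, k / n) for k in range(1, n + 1)]
    return LiftCurve(points, ideal, baseline)


# ---------------------------------------------------------------------------
# learner interface and implementations
# ---------------------------------------------------------------------------

class Learner(Protocol):
    def fit(self, cases: CaseSet) -> None: ...
    def predict_p_positive(self, cases: Sequence[Case]) -> np.ndarray: ...


class MramLearner:
    """The rule-mining classifier behind the common learner interface."""

    def __init__(self, params: MiningParams | None = None,
                 aggregate: str = "best"):
        self.params = params or MiningParams(consequent_filter="class")
        if self.params.consequent_filter is None:
            self.params.consequent_filter = "class"
        self.aggregate = aggregate
        self.model = None

    def fit(self, cases: CaseSet) -> None:
        self.model = mine_rules(cases, self.params)

    def predict_p_positive(self, cases: Sequence[Case]) -> np.ndarray:
        preds = predict_batch(self.model, list(cases), aggregate=self.aggregate)
        by_id = {p.case_id: p.p_positive for p in preds}
        return np.array([by_id[c.case_id] for c in cases])


class DummyPriorLearner:
    """Constant prediction at the training prior P(class=Y)."""

    def __init__(self) -> None:
        self.prior_y = 0.5

    def fit(self, cases: CaseSet) -> None:
        self.prior_y = cases.priors.get("Y", 0.0)

    def predict_p_positive(self, cases: Sequence[Case]) -> np.ndarray:
        return np.full(len(cases), self.prior_y)


class _Vectorizer:
    """One-hot item-indicator encoding over the training item universe."""

    def __init__(self) -> None:
        self.vocab: dict[Item, int] = {}

    def fit(self, cases: CaseSet) -> None:
        items = sorted(
            {it for c in cases.cases for it in c.feature_items},
            key=lambda it: (it.attribute, it.value),
        )
        self.vocab = {it: i for i, it in enumerate(items)}

    def transform(self, cases: Sequence[Case]) -> np.ndarray:
        X = np.zeros((len(cases), max(len(self.vocab), 1)))
        for row, case in enumerate(cases):
            for it in case.feature_items:
                col = self.vocab.get(it)
                if col is not None:
                    X[row, col] = 1.0
        return X


class BernoulliNaiveBayesLearner:
    """Bernoulli naive Bayes over item indicators, add-one smoothing.

    P(class) and P(item | class) are estimated from indicator counts with
    Laplace add-one smoothing; features are assumed conditionally
    independent given the class.
    """

    def __init__(self) -> None:
        self.vec = _Vectorizer()
        self.log_prior = np.zeros(2)
        self.log_p = self.log_q = None  # log P(x=1|c), log P(x=0|c)

    def fit(self, cases: CaseSet) -> None:
        self.vec.fit(cases)
        X = self.vec.transform(cases.cases)
        y = np.array([1 if c.class_item.value == "Y" else 0
                      for c in cases.cases])
        n = len(y)
        for cls in (0, 1):
            mask = y == cls
            n_c = int(mask.sum())
            self.log_prior[cls] = math.log((n_c + 1) / (n + 2))
            theta = (X[mask].sum(axis=0) + 1.0) / (n_c + 2.0)
            if cls == 0:
                self.log_p0, self.log_q0 = np.log(theta), np.log1p(-theta)
            else:
                self.log_p1, self.log_q1 = np.log(theta), np.log1p(-theta)

    def predict_p_positive(self, cases: Sequence[Case]) -> np.ndarray:
        X = self.vec.transform(cases)
        ll0 = self.log_prior[0] + X @ self.log_p0 + (1 - X) @ self.log_q0
        ll1 = self.log_prior[1] + X @ self.log_p1 + (1 - X) @ self.log_q1
        m = np.maximum(ll0, ll1)
        p1 = np.exp(ll1 - m)
        return p1 / (p1 + np.exp(ll0 - m))


class SklearnLearner:
    """Decision-tree / neural-net baselines delegating to scikit-learn."""

    def __init__(self, kind: str, seed: int = 0):
        self.kind = kind
        self.seed = seed
        self.vec = _Vectorizer()
        self.clf = None
        self.constant: float | None = None

    def _make(self):
        if self.kind == "dtree":
            from sklearn.tree import DecisionTreeClassifier
            return DecisionTreeClassifier(
                max_depth=6, min_samples_leaf=5, random_state=self.seed
            )
        if self.kind == "nnet":
            from sklearn.neural_network import MLPClassifier
            return MLPClassifier(
                hidden_layer_sizes=(16,), max_iter=300,
                random_state=self.seed,
            )
        raise ValueError(f"unknown sklearn learner kind: {self.kind}")

    def fit(self, cases: CaseSet) -> None:
        self.vec.fit(cases)
        X = self.vec.transform(cases.cases)
        y = np.array([1 if c.class_item.value == "Y" else 0
                      for c in cases.cases])
        if len(set(y)) < 2:
            self.constant = float(y[0])
            return
        self.clf = self._make()
        self.clf.fit(X, y)

    def predict_p_positive(self, cases: Sequence[Case]) -> np.ndarray:
        if self.constant is not None:
            return np.full(len(cases), self.constant)
        X = self.vec.transform(cases)
        proba = self.clf.predict_proba(X)
        pos_col = list(self.clf.classes_).index(1)
        return proba[:, pos_col]


LEARNERS: dict[str, Callable[..., Learner]] = {
    "mram": MramLearner,
    "dtree": lambda seed=0: SklearnLearner("dtree", seed),
    "nbayes": lambda seed=0: BernoulliNaiveBayesLearner(),
    "nnet": lambda seed=0: SklearnLearner("nnet", seed),
    "dummy": lambda seed=0: DummyPriorLearner(),
}


def make_learner(name: str, seed: int = 0, **kwargs) -> Learner:
    if name not in LEARNERS:
        raise ValueError(f"unknown learner {name!r}; choose from {sorted(LEARNERS)}")
    factory = LEARNERS[name]
    if name == "mram":
        return factory(**kwargs)
    return factory(seed=seed)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldMetrics:
    accuracy: float
    auc: float
    log_score: float
    likelihood_lift: float
    rmse: float


@dataclass
class EvaluationReport:
    per_fold: list[FoldMetrics]
    mean_sd: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean_sd:
            for name in ("accuracy", "auc", "log_score",
                         "likelihood_lift", "rmse"):
                vals = np.array([getattr(f, name) for f in self.per_fold])
                self.mean_sd[name] = (float(vals.mean()),
                                      float(vals.std(ddof=1)) if len(vals) > 1
                                      else 0.0)

    def __getattr__(self, name: str):
        if name in ("accuracy", "auc", "log_score", "likelihood_lift", "rmse"):
            return self.mean_sd[name][0]
        raise AttributeError(name)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_fold": [vars(f) for f in self.per_fold],
            "mean_sd": {k: {"mean": m, "sd": s}
                        for k, (m, s) in self.mean_sd.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _fold_metrics(
    learner: Learner,
    train: CaseSet,
    test: CaseSet,
    threshold: float,
) -> FoldMetrics:
    learner.fit(train)
    p_pos = learner.predict_p_positive(test.cases)
    labels = [c.class_item.value for c in test.cases]
    predicted = ["Y" if p >= threshold else "N" for p in p_pos]
    priors = train.priors
    p_true = [p if y == "Y" else 1.0 - p for p, y in zip(p_pos, labels)]
    prior_true = [priors.get(y, 0.0) for y in labels]
    log_score, lift, rmse = likelihood_metrics(p_true, prior_true)
    return FoldMetrics(
        accuracy=accuracy(predicted, labels),
        auc=auc(p_pos, labels),
        log_score=log_score,
        likelihood_lift=lift,
        rmse=rmse,
    )


def cross_validate(
    cases: CaseSet,
    learner_name: str = "mram",
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    params: MiningParams | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EvaluationReport:
    """Stratified k-fold CV; fully reproducible from the seed.

    ``folds`` allows sharing one fold assignment across experiments
    (the feature-ablation table uses this).
    """
    y = np.array([c.class_item.value for c in cases.cases])
    class_min = min(np.unique(y, return_counts=True)[1])
    if k > class_min:
        raise ValueError(
            f"k={k} exceeds the minority class count ({class_min})"
        )
    if folds is None:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(np.zeros(len(y)), y))
    per_fold = []
    for train_idx, test_idx in folds:
        if learner_name == "mram" and params is not None:
            learner = MramLearner(params=MiningParams(
                min_support=params.min_support,
                min_probability=params.min_probability,
                max_itemset_size=params.max_itemset_size,
                consequent_filter="class",
            ))
        else:
            learner = make_learner(learner_name, seed=seed)
        per_fold.append(
            _fold_metrics(learner, cases.subset(train_idx),
                          cases.subset(test_idx), threshold)
        )
    return EvaluationReport(per_fold=per_fold)


def make_folds(cases: CaseSet, k: int, seed: int):
    """Stratified fold assignment reusable across experiments."""
    y = np.array([c.class_item.value for c in cases.cases])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def ablation_study(
    case_builder: Callable[[Iterable[str]], CaseSet],
    feature_masks: Sequence[Iterable[str]],
    learner_name: str = "mram",
    k: int = 10,
    seed: int = 0,
    params: MiningParams | None = None,
) -> list[tuple[tuple[str, ...], float]]:
    """Likelihood lift per feature mask under shared CV folds.

    ``case_builder`` maps a feature mask to a CaseSet over the same
    proteins, so folds (assigned once from the labels) are identical
    across masks and differences are attributable to the features alone.
    """
    results = []
    shared_folds = None
    for mask in feature_masks:
        mask = tuple(mask)
        cases = case_builder(mask)
        if shared_folds is None:
            shared_folds = make_folds(cases, k, seed)
        report = cross_validate(
            cases, learner_name, k=k, seed=seed, params=params,
            folds=shared_folds,
        )
        results.append((mask, report.mean_sd["likelihood_lift"][0]))
    return results
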