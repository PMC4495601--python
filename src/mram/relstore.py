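"""Per-protein case assembly: the transactional view the miner consumes.

Each labeled protein becomes a :class:`Case` — one class item
(``class=Y`` for known drug targets, ``class=N`` for sampled negatives)
plus feature items drawn from five attributes: discretized degree
centrality, articulation-point status, GO terms, pathways and domains.
The multi-relational structure (one-to-many degree, many-to-many
annotations) is realized as typed in-memory relations.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .annotations import AnnotationTable
from .network import InteractionNetwork, articulation_points, degree_centrality

Attribute = Literal["class", "degree", "articulation", "go", "pathway", "domain"]

#: attributes that may appear as feature items (everything but the class)
FEATURE_ATTRIBUTES: tuple[str, ...] = (
    "degree", "articulation", "go", "pathway", "domain"
)


@dataclass(frozen=True, order=True)
class Item:
    """One attribute=value token; the atom of itemsets and rules."""

    attribute: str
    value: str

    def render(self) -> str:
        return f"{self.attribute}={self.value}"

    @classmethod
    def parse(cls, text: str) -> "Item":
        attr, _, value = text.partition("=")
        if not attr or not value:
            raise ValueError(f"cannot parse item: {text!r}")
        return cls(attr, value)


@dataclass
class DiscretizationScheme:
    """Bucketed encoding of an integer-valued attribute (degree).

    ``cut_points`` are ascending upper bounds (inclusive) of all buckets
    but the last; labels are inclusive integer ranges like ``"10-77"``.
    """

    attribute: str
    cut_points: list[int]
    bucket_labels: list[str]

    def bucket_of(self, value: int) -> str:
        for cut, label in zip(self.cut_points, self.bucket_labels):
            if value <= cut:
                return label
        return self.bucket_labels[-1]

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "cut_points": self.cut_points,
            "bucket_labels": self.bucket_labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationScheme":
        return cls(d["attribute"], list(d["cut_points"]), list(d["bucket_labels"]))


@dataclass
class Case:
    """One protein's nested item set: a class item plus feature items."""

    case_id: str
    class_item: Item
    feature_items: frozenset[Item]

    def __post_init__(self) -> None:
        if self.class_item.attribute != "class":
            raise ValueError("class_item must have attribute 'class'")
        if any(it.attribute == "class" for it in self.feature_items):
            raise ValueError("feature_items must not contain the class attribute")

    @property
    def items(self) -> frozenset[Item]:
        return self.feature_items | {self.class_item}


@dataclass
class CaseSet:
    """The miner's input dataset: S_pos union S_neg as labeled cases."""

    cases: list[Case]
    schemes: dict[str, DiscretizationScheme] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate case_ids in CaseSet")

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def item_universe(self) -> set[Item]:
        out: set[Item] = set()
        for c in self.cases:
            out |= c.items
        return out

    @property
    def priors(self) -> dict[str, float]:
        n = len(self.cases)
        counts: dict[str, int] = {}
        for c in self.cases:
            counts[c.class_item.value] = counts.get(c.class_item.value, 0) + 1
        return {k: v / n for k, v in counts.items()}

    def subset(self, indices: Sequence[int]) -> "CaseSet":
        return CaseSet([self.cases[i] for i in indices], dict(self.schemes))

    # -- on-disk format: TSV body + JSON sidecar with schemes ------------

    def to_files(self, tsv_path: str | Path, sidecar_path: str | Path) -> None:
        lines = []
        for c in self.cases:
            items = ";".join(sorted(it.render() for it in c.feature_items))
            lines.append(f"{c.case_id}\t{c.class_item.value}\t{items}")
        Path(tsv_path).write_text("\n".join(lines) + "\n")
        sidecar = {
            "schemes": {k: s.to_dict() for k, s in self.schemes.items()},
            "priors": self.priors,
            "n_cases": len(self.cases),
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_files(
        cls, tsv_path: str | Path, sidecar_path: str | Path | None = None
    ) -> "CaseSet":
        cases = []
        for line in Path(tsv_path).read_text().splitlines():
            if not line.strip():
                continue
            case_id, label, items_str = line.split("\t")
            feats = frozenset(
                Item.parse(tok) for tok in items_str.split(";") if tok
            )
            cases.append(Case(case_id, Item("class", label), feats))
        schemes = {}
        if sidecar_path is not None and Path(sidecar_path).exists():
            sidecar = json.loads(Path(sidecar_path).read_text())
            schemes = {
                k: DiscretizationScheme.from_dict(d)
                for k, d in sidecar.get("schemes", {}).items()
            }
        return cls(cases, schemes)


def discretize_degree(
    degrees: dict[str, int],
    n_buckets: int = 5,
    method: Literal["equal_frequency", "equal_width"] = "equal_frequency",
) -> DiscretizationScheme:
    """Bucket integer degrees into labeled ranges like ``"10-77"``.

    ``equal_frequency`` (default) places approximately equal numbers of
    proteins per bucket, keeping ties together — robust to the
    heavy-tailed degree distributions of interactomes, where it yields
    narrow low-degree buckets and a wide top bucket. ``equal_width``
    splits the min-max range evenly. If fewer distinct values than
    buckets are observed, buckets collapse to the distinct values.
    """
    if n_buckets < 1:
        raise ValueError("n_buckets must be >= 1")
    values = sorted(degrees.values())
    if not values:
        raise ValueError("no observed degree values")
    distinct = sorted(set(values))
    if n_buckets > len(distinct):
        n_buckets = len(distinct)

    if n_buckets == 1:
        cuts = [distinct[-1]]
    elif method == "equal_width":
        lo, hi = distinct[0], distinct[-1]
        width = (hi - lo) / n_buckets
        cuts = sorted({int(lo + width * (i + 1)) for i in range(n_buckets - 1)})
        cuts.append(hi)
    else:  # equal_frequency with ties kept together
        n = len(values)
        cuts = []
        for i in range(1, n_buckets):
            q = values[min(n - 1, (i * n) // n_buckets - 1)]
            # extend the cut to the last occurrence of the tied value
            if not cuts or q > cuts[-1]:
                cuts.append(q)
        if not cuts or cuts[-1] < distinct[-1]:
            cuts.append(distinct[-1])
        else:
            cuts[-1] = distinct[-1]

    # label each bucket by the observed values it contains; drop empty buckets
    labels, kept_cuts = [], []
    prev: int | None = None
    for cut in cuts:
        in_bucket = [
            v for v in distinct if (prev is None or v > prev) and v <= cut
        ]
        if not in_bucket:
            continue
        lo_v, hi_v = in_bucket[0], in_bucket[-1]
        labels.append(f"{lo_v}-{hi_v}" if lo_v != hi_v else str(lo_v))
        kept_cuts.append(cut)
        prev = cut
    return DiscretizationScheme("degree", kept_cuts, labels)


def build_cases(
    net: InteractionNetwork,
    annos: Iterable[AnnotationTable],
    positives: Iterable[str],
    negatives: Iterable[str],
    scheme: DiscretizationScheme | None = None,
    feature_mask: Iterable[str] = FEATURE_ATTRIBUTES,
    emit_negative_boolean_items: bool = False,
) -> CaseSet:
    """Assemble one labeled case per protein from topology + annotations.

    Items are emitted only for attributes in ``feature_mask``, enabling
    leave-one-feature-out ablation experiments. Articulation status is a
    presence-only item (``articulation=Y``) unless
    ``emit_negative_boolean_items`` restores the two-state encoding.
    Proteins lacking every annotation still yield a valid case carrying
    topology items only. When ``scheme`` is None an equal-frequency
    5-bucket scheme is fitted on the degrees of the labeled proteins.
    """
    positives, negatives = set(positives), set(negatives)
    overlap = positives & negatives
    if overlap:
        raise ValueError(
            "positive/negative label sets overlap: " + ", ".join(sorted(overlap))
        )
    labeled = positives | negatives
    outside = labeled - net.nodes
    if outside:
        raise ValueError(
            "labeled proteins absent from the network: "
            + ", ".join(sorted(outside)[:10])
        )
    mask = set(feature_mask)
    unknown = mask - set(FEATURE_ATTRIBUTES)
    if unknown:
        raise ValueError(f"unknown feature attributes in mask: {sorted(unknown)}")

    degrees = degree_centrality(net)
    if scheme is None:
        scheme = discretize_degree({p: degrees[p] for p in labeled})
    art = articulation_points(net) if "articulation" in mask else set()
    by_ns = {a.namespace: a.by_protein() for a in annos}

    cases = []
    for protein in sorted(labeled):
        feats: set[Item] = set()
        if "degree" in mask:
            feats.add(Item("degree", scheme.bucket_of(degrees[protein])))
        if "articulation" in mask:
            if protein in art:
                feats.add(Item("articulation", "Y"))
            elif emit_negative_boolean_items:
                feats.add(Item("articulation", "N"))
        for ns in ("go", "pathway", "domain"):
            if ns in mask:
                for term in by_ns.get(ns, {}).get(protein, ()):
                    feats.add(Item(ns, term))
        label = "Y" if protein in positives else "N"
        cases.append(Case(protein, Item("class", label), frozenset(feats)))
    return CaseSet(cases, {"degree": scheme})


def build_unlabeled_cases(
    net: InteractionNetwork,
    annos: Iterable[AnnotationTable],
    proteins: Iterable[str],
    scheme: DiscretizationScheme,
    feature_mask: Iterable[str] = FEATURE_ATTRIBUTES,
) -> list[Case]:
    """Feature-only cases for scoring unlabeled candidates (connector genes).

    The class item is a placeholder ``class=?`` ignored by the classifier;
    the training discretization scheme must be supplied so degree buckets
    match the rule vocabulary.
    """
    proteins = set(proteins)
    mask = set(feature_mask)
    degrees = degree_centrality(net)
    art = articulation_points(net) if "articulation" in mask else set()
    by_ns = {a.namespace: a.by_protein() for a in annos}
    out = []
    for protein in sorted(proteins):
        feats: set[Item] = set()
        if "degree" in mask and protein in degrees:
            feats.add(Item("degree", scheme.bucket_of(degrees[protein])))
        if "articulation" in mask and protein in art:
            feats.add(Item("articulation", "Y"))
        for ns in ("go", "pathway", "domain"):
            if ns in mask:
                for term in by_ns.get(ns, {}).get(protein, ()):
                    feats.add(Item(ns, term))
        out.append(Case(protein, Item("class", "?"), frozenset(feats)))
    return out


def sample_negatives(
    candidates: Iterable[str], n: int, seed: int
) -> set[str]:
    """Uniform sample of negative examples, without replacement, seeded."""
    pool = sorted(set(candidates))
    if n > len(pool):
        raise ValueError(f"requested {n} negatives from {len(pool)} candidates")
    rng = random.Random(seed)
    return set(rng.sample(pool, n))
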