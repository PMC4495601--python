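"""Self-contained synthetic benchmark: network, annotations, labels.

The generator emulates the statistical shape of the real inputs without
any download: a sparse undirected protein network with heavy-tailed
degrees (preferential attachment by default), Zipf-distributed
multi-valued GO/pathway/domain annotations per protein, a minority
positive class, and planted high-confidence antecedent => drug-target
rules whose recovery every pipeline stage can be tested against.

Planted rules work by reserving their antecedent terms: the reserved
terms are attached to a disjoint covered subset of proteins and never
drawn in background annotation sampling, so the empirical confidence of
``antecedent => class=Y`` concentrates at the configured q. A special
``("degree", "top")`` antecedent instead covers the highest-degree
fraction of proteins, planting signal carried purely by topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .annotations import AnnotationTable
from .network import EdgeList


@dataclass(frozen=True)
class PlantedRule:
    """Antecedent template, confidence q, and covered population fraction."""

    items: tuple[tuple[str, str], ...]  # (namespace, term) pairs
    confidence: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0 < self.confidence <= 1):
            raise ValueError("confidence must be in (0, 1]")
        if not (0 < self.coverage < 1):
            raise ValueError("coverage must be in (0, 1)")


@dataclass
class SyntheticConfig:
    n_proteins: int = 600
    edge_model: Literal["preferential_attachment", "erdos_renyi"] = (
        "preferential_attachment"
    )
    pa_m: int = 2
    er_p: float = 0.01
    n_go_terms: int = 150
    n_pathways: int = 60
    n_domains: int = 80
    annotations_per_protein: dict[str, float] = field(
        default_factory=lambda: {"go": 3.0, "pathway": 1.5, "domain": 1.0}
    )
    planted_rules: tuple[PlantedRule, ...] = (
        PlantedRule((("go", "GO:0099001"), ("pathway", "RP-00001")), 0.95, 0.12),
        PlantedRule((("go", "GO:0099002"),), 0.95, 0.12),
        PlantedRule((("domain", "IPR099001"), ("pathway", "RP-00002")), 0.95, 0.12),
    )
    positive_rate: float = 0.3
    noise_rate: float = 0.1
    zipf_exponent: float = 1.2
    seed: int = 17

    def __post_init__(self) -> None:
        if sum(r.coverage for r in self.planted_rules) > 1:
            raise ValueError("planted-rule coverage fractions sum beyond 1")
        if not (0 < self.positive_rate < 1):
            raise ValueError("positive_rate must be in (0, 1)")


def topology_signal_config(seed: int = 17, n_proteins: int = 600) -> SyntheticConfig:
    """Config whose only label signal is carried by network topology."""
    return SyntheticConfig(
        n_proteins=n_proteins,
        planted_rules=(PlantedRule((("degree", "top"),), 0.95, 0.2),),
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Everything needed to recompute every label from the seed."""

    planted: list[dict]
    generative_p: dict[str, float]  # per-protein P(label = Y)
    labels: dict[str, str]
    bayes_accuracy: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "planted_rules": self.planted,
            "generative_p": self.generative_p,
            "labels": self.labels,
            "bayes_accuracy": self.bayes_accuracy,
        }, indent=1))


@dataclass
class SyntheticDataset:
    edges: EdgeList
    annotations: list[AnnotationTable]
    positives: set[str]
    negatives: set[str]
    truth: SyntheticTruth

    @property
    def proteins(self) -> list[str]:
        return sorted(self.positives | self.negatives)


_GAF_ASPECTS = ("P", "F", "C")


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def _background_terms(prefixes: dict[str, str], config: SyntheticConfig,
                      reserved: set[str]) -> dict[str, list[str]]:
    counts = {"go": config.n_go_terms, "pathway": config.n_pathways,
              "domain": config.n_domains}
    pools = {}
    for ns, prefix in prefixes.items():
        pool = []
        i = 1
        while len(pool) < counts[ns]:
            term = f"{prefix}{i:05d}"
            if term not in reserved:
                pool.append(term)
            i += 1
        pools[ns] = pool
    return pools


def generate(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Build one benchmark dataset; identical seeds give identical output.

    When ``out_dir`` is given, writes every pipeline input format:
    ``edges.tsv``, ``annotations.gaf``, ``pathways.tsv``, ``domains.tsv``,
    ``positives.txt``, ``negatives.txt`` and a ``truth.json`` sufficient
    to recompute every label.
    """
    rng = np.random.default_rng(config.seed)
    proteins = _protein_ids(config.n_proteins)

    # --- network -------------------------------------------------------
    if config.edge_model == "preferential_attachment":
        g = nx.barabasi_albert_graph(config.n_proteins, config.pa_m,
                                     seed=int(rng.integers(2**31)))
    else:
        g = nx.gnp_random_graph(config.n_proteins, config.er_p,
                                seed=int(rng.integers(2**31)))
    edges = EdgeList(source_format="tsv")
    for a, b in g.edges():
        edges.add(proteins[a], proteins[b])

    # --- planted coverage sets (disjoint) ------------------------------
    reserved = {term for rule in config.planted_rules
                for ns, term in rule.items if ns != "degree"}
    degree = dict(g.degree())
    order_by_degree = sorted(range(config.n_proteins),
                             key=lambda i: (-degree[i], i))
    shuffled = list(rng.permutation(config.n_proteins))
    covered_by: dict[int, int] = {}  # protein index -> rule index
    cursor = 0
    for r_idx, rule in enumerate(config.planted_rules):
        n_cov = int(round(rule.coverage * config.n_proteins))
        if any(ns == "degree" for ns, _ in rule.items):
            pool = [i for i in order_by_degree if i not in covered_by]
        else:
            pool = [i for i in shuffled[cursor:] if i not in covered_by]
        chosen = pool[:n_cov]
        cursor += n_cov
        for i in chosen:
            covered_by[i] = r_idx

    # --- labels --------------------------------------------------------
    background_p = config.positive_rate * config.noise_rate
    gen_p: dict[str, float] = {}
    labels: dict[str, str] = {}
    draws = rng.random(config.n_proteins)
    for i, pid in enumerate(proteins):
        p = (config.planted_rules[covered_by[i]].confidence
             if i in covered_by else background_p)
        gen_p[pid] = p
        labels[pid] = "Y" if draws[i] < p else "N"

    # --- annotations ---------------------------------------------------
    pools = _background_terms(
        {"go": "GO:00", "pathway": "RP-", "domain": "IPR0"}, config, reserved
    )
    tables = {
        "go": AnnotationTable(namespace="go"),
        "pathway": AnnotationTable(namespace="pathway"),
        "domain": AnnotationTable(namespace="domain"),
    }
    # Zipf-weighted background popularity: real GAFs have very popular terms
    weights = {
        ns: (lambda w: w / w.sum())(
            np.arange(1, len(pool) + 1, dtype=float) ** -config.zipf_exponent
        )
        for ns, pool in pools.items()
    }
    for i, pid in enumerate(proteins):
        for ns, mean in config.annotations_per_protein.items():
            n_terms = int(rng.poisson(mean))
            if n_terms:
                picks = rng.choice(len(pools[ns]), size=n_terms,
                                   p=weights[ns])
                for t in picks:
                    tables[ns].pairs.add((pid, pools[ns][int(t)]))
        if i in covered_by:
            for ns, term in config.planted_rules[covered_by[i]].items:
                if ns != "degree":
                    tables[ns].pairs.add((pid, term))
    for ns, table in tables.items():
        for term in sorted(table.terms()):
            if ns == "go":
                aspect = _GAF_ASPECTS[int(term[-5:]) % 3]
                table.term_labels[term] = f"{aspect}:synthetic term {term}"
            else:
                table.term_labels[term] = f"synthetic {ns} {term}"

    positives = {p for p, y in labels.items() if y == "Y"}
    negatives = set(proteins) - positives
    bayes_acc = float(np.mean([max(p, 1 - p) for p in gen_p.values()]))
    truth = SyntheticTruth(
        planted=[{
            "items": [list(it) for it in rule.items],
            "confidence": rule.confidence,
            "coverage": rule.coverage,
        } for rule in config.planted_rules],
        generative_p=gen_p,
        labels=labels,
        bayes_accuracy=bayes_acc,
    )
    dataset = SyntheticDataset(
        edges=edges,
        annotations=[tables["go"], tables["pathway"], tables["domain"]],
        positives=positives,
        negatives=negatives,
        truth=truth,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(ds: SyntheticDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "edges.tsv").write_text(
        "#protein_a\tprotein_b\n"
        + "\n".join(f"{a}\t{b}" for a, b in sorted(ds.edges.edges)) + "\n"
    )
    go = next(t for t in ds.annotations if t.namespace == "go")
    gaf_lines = ["!gaf-version: 2.1"]
    for pid, term in sorted(go.pairs):
        label = go.term_labels.get(term, term)
        aspect, _, name = label.partition(":")
        gaf_lines.append("\t".join([
            "SYN", pid, pid, "", term, "SYN_REF:0000001", "IEA", "",
            aspect, name, "", "protein", "taxon:9606", "20150101", "SYN",
            "", "",
        ]))
    (out_dir / "annotations.gaf").write_text("\n".join(gaf_lines) + "\n")
    for ns, fname in (("pathway", "pathways.tsv"), ("domain", "domains.tsv")):
        table = next(t for t in ds.annotations if t.namespace == ns)
        lines = [
            f"{pid}\t{term}\t{table.term_labels.get(term, term)}"
            for pid, term in sorted(table.pairs)
        ]
        (out_dir / fname).write_text("\n".join(lines) + "\n")
    (out_dir / "positives.txt").write_text(
        "\n".join(sorted(ds.positives)) + "\n")
    (out_dir / "negatives.txt").write_text(
        "\n".join(sorted(ds.negatives)) + "\n")
    ds.truth.to_json(out_dir / "truth.json")


def planted_rule_items(config: SyntheticConfig) -> list[frozenset]:
    """The planted antecedents as miner Items (annotation-based rules only)."""
    from .relstore import Item

    out = []
    for rule in config.planted_rules:
        if any(ns == "degree" for ns, _ in rule.items):
            continue
        out.append(frozenset(Item(ns, term) for ns, term in rule.items))
    return out
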