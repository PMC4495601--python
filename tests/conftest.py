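"""Shared fixtures: tiny case sets, random graphs, brute-force oracles."""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from mram.miner import FrequentItemset
from mram.network import EdgeList, InteractionNetwork
from mram.relstore import Case, CaseSet, Item


def make_caseset(rows: list[tuple[str, str, list[str]]]) -> CaseSet:
    """Rows of (case_id, class value, ["attr=value", ...])."""
    cases = [
        Case(cid, Item("class", label),
             frozenset(Item.parse(tok) for tok in items))
        for cid, label, items in rows
    ]
    return CaseSet(cases)


def abc_caseset() -> CaseSet:
    """The canonical 4-case itemset example: {A,B,C},{A,B},{A,C},{B,C}."""
    return make_caseset([
        ("c1", "Y", ["go=A", "go=B", "go=C"]),
        ("c2", "Y", ["go=A", "go=B"]),
        ("c3", "Y", ["go=A", "go=C"]),
        ("c4", "Y", ["go=B", "go=C"]),
    ])


def random_caseset(rng: random.Random, n_items: int = 10,
                   n_cases: int = 20) -> CaseSet:
    tokens = [f"go=T{i}" for i in range(n_items)]
    rows = []
    for c in range(n_cases):
        k = rng.randint(1, max(1, n_items // 2))
        items = rng.sample(tokens, k)
        rows.append((f"c{c}", rng.choice("YN"), items))
    return make_caseset(rows)


def brute_force_frequent(cases: CaseSet, min_support: float,
                         max_size: int) -> dict[frozenset, float]:
    """Powerset enumeration oracle over the item universe (class included)."""
    import math
    universe = sorted(cases.item_universe, key=lambda it: (it.attribute, it.value))
    n = len(cases)
    min_count = max(1, math.ceil(min_support * n))
    out: dict[frozenset, float] = {}
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(universe, size):
            s = frozenset(combo)
            count = sum(1 for case in cases.cases if s <= case.items)
            if count >= min_count:
                out[s] = count / n
    return out


def brute_force_articulation(g: nx.Graph) -> set:
    """Remove each node in turn and recount connected components."""
    base = nx.number_connected_components(g)
    out = set()
    for node in g.nodes:
        h = g.copy()
        h.remove_node(node)
        if h.number_of_nodes() and nx.number_connected_components(h) > base:
            out.add(node)
    return out


def random_graph_net(seed: int, n: int = 30, p: float = 0.12
                     ) -> InteractionNetwork:
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes})
    return InteractionNetwork(graph=g, seed_set=set(g.nodes))


def edgelist_from_pairs(pairs) -> EdgeList:
    el = EdgeList()
    for a, b in pairs:
        el.add(a, b)
    return el


@pytest.fixture
def abc_cases() -> CaseSet:
    return abc_caseset()
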