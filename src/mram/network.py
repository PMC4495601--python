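"""Protein interaction network (PIN) construction and topology features.

The network layer turns raw interaction records into the undirected,
unweighted graph of a seed set (known drug targets) and its one-step
neighborhood, and computes the two topological features the rule miner
consumes: degree centrality and articulation-point status. It also
provides the connector-gene selection used to assemble the candidate
pool scored at prediction time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx

logger = logging.getLogger("mram.network")

EdgeFormat = Literal["tsv", "psimitab"]
PinMode = Literal["induced", "star"]


@dataclass
class EdgeList:
    """Deduplicated undirected interaction edges.

    ``edges`` holds unordered protein-ID pairs as sorted 2-tuples;
    self-loops are never stored.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)
    source_format: EdgeFormat = "tsv"

    def add(self, a: str, b: str) -> bool:
        """Add one undirected edge; returns False for self-loops/duplicates."""
        if not a or not b:
            raise ValueError("empty interactor ID")
        if a == b:
            return False
        pair = (a, b) if a < b else (b, a)
        if pair in self.edges:
            return False
        self.edges.add(pair)
        return True

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out


@dataclass
class InteractionNetwork:
    """Undirected simple graph of proteins with a flagged seed subset."""

    graph: nx.Graph
    seed_set: set[str]

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors(self, protein: str) -> set[str]:
        return set(self.graph.neighbors(protein))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_json(self, path: str | Path) -> None:
        """Serialize as a documented JSON adjacency file."""
        payload = {
            "format": "mram-network/1",
            "directed": False,
            "seeds": sorted(self.seed_set),
            "adjacency": {
                n: sorted(self.graph.neighbors(n)) for n in sorted(self.graph.nodes)
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "InteractionNetwork":
        payload = json.loads(Path(path).read_text())
        g = nx.Graph()
        g.add_nodes_from(payload["adjacency"])
        for node, nbrs in payload["adjacency"].items():
            g.add_edges_from((node, m) for m in nbrs)
        return cls(graph=g, seed_set=set(payload["seeds"]))


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    mean_degree: float
    mean_shortest_path: float
    n_components: int


def _strip_uniprot_prefix(token: str) -> str:
    if token.startswith("uniprotkb:"):
        return token[len("uniprotkb:"):]
    return token


def load_interactions(
    path: str | Path, format: EdgeFormat = "tsv", strict: bool = True
) -> EdgeList:
    """Read an interaction file into a deduplicated undirected edge list.

    ``tsv`` expects two tab-separated ID columns ('#' header/comment lines
    allowed); ``psimitab`` reads PSI-MI TAB 2.5 and uses columns 1-2 as
    interactor IDs, stripping ``uniprotkb:`` prefixes. Interaction-detection
    metadata is ignored: records are treated as binary, undirected and
    unweighted. Self-loops and duplicate unordered pairs are dropped and
    counted in the load report. In strict mode (default) a malformed row
    aborts with its line number; lenient mode downgrades it to a warning.
    """
    path = Path(path)
    edges = EdgeList(source_format=format)
    rows_read = self_loops = duplicates = malformed = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                if strict:
                    raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
                logger.warning("%s: skipping malformed row at line %d", path, lineno)
                malformed += 1
                continue
            a, b = fields[0].strip(), fields[1].strip()
            if format == "psimitab":
                a, b = _strip_uniprot_prefix(a), _strip_uniprot_prefix(b)
            rows_read += 1
            if a == b:
                self_loops += 1
                continue
            if not edges.add(a, b):
                duplicates += 1
    if rows_read == 0:
        logger.warning("%s: no interaction rows found", path)
    logger.info(
        "loaded %s: %d rows, %d edges kept, %d self-loops removed, "
        "%d duplicates removed, %d malformed skipped",
        path, rows_read, len(edges), self_loops, duplicates, malformed,
    )
    return edges


def build_pin(
    edges: EdgeList, seeds: Iterable[str], mode: PinMode = "induced"
) -> InteractionNetwork:
    """Build the one-step-neighbor PIN around a seed set.

    Nodes are the seeds plus every direct neighbor of a seed. ``induced``
    keeps all edges among included nodes (default: real interactomes are
    locally clustered, so neighbor-neighbor edges carry signal); ``star``
    keeps only seed-incident edges. Seeds absent from the edge list are
    retained as isolated nodes and reported via the log.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    if mode not in ("induced", "star"):
        raise ValueError(f"unknown PIN mode: {mode!r}")
    g_full = nx.Graph()
    g_full.add_edges_from(edges.edges)
    nodes = set(seeds)
    for s in seeds:
        if s in g_full:
            nodes.update(g_full.neighbors(s))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if mode == "induced":
        g.add_edges_from(
            (a, b) for a, b in edges.edges if a in nodes and b in nodes
        )
    else:  # star: only seed-incident edges
        g.add_edges_from(
            (a, b) for a, b in edges.edges if a in seeds or b in seeds
        )
    missing = sorted(s for s in seeds if s not in g_full)
    if missing:
        logger.warning(
            "%d seed(s) absent from the edge list kept as isolated nodes: %s",
            len(missing), ", ".join(missing[:10]),
        )
    return InteractionNetwork(graph=g, seed_set=seeds)


def degree_centrality(net: InteractionNetwork) -> dict[str, int]:
    """Degree centrality DC(p) = number of interaction partners of p."""
    return {n: d for n, d in net.graph.degree()}


def articulation_points(net: InteractionNetwork) -> set[str]:
    """Nodes whose removal disconnects their connected component."""
    return set(nx.articulation_points(net.graph))


def network_summary(net: InteractionNetwork) -> NetworkSummary:
    """Global summary: size, mean degree, mean shortest path, components.

    The mean shortest path is averaged over unordered node pairs within
    the largest connected component only; unreachable pairs are excluded.
    """
    g = net.graph
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    mean_degree = 2.0 * n_edges / n_nodes if n_nodes else 0.0
    components = list(nx.connected_components(g))
    if components:
        largest = max(components, key=len)
        sub = g.subgraph(largest)
        if len(largest) >= 2:
            msp = nx.average_shortest_path_length(sub)
        else:
            msp = 0.0
    else:
        msp = 0.0
    return NetworkSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        mean_degree=mean_degree,
        mean_shortest_path=msp,
        n_components=len(components),
    )


def select_connectors(
    net: InteractionNetwork,
    disease_genes: Iterable[str],
    drug_targets: Iterable[str],
) -> set[str]:
    """Connector genes: nodes directly linked to both input sets.

    Returns nodes outside both sets with at least one neighbor among the
    disease genes AND at least one among the drug targets — the candidate
    pool scored for putative drug-target status.
    """
    disease = set(disease_genes)
    targets = set(drug_targets)
    if not disease or not targets:
        raise ValueError("disease-gene and drug-target sets must be non-empty")
    out: set[str] = set()
    for node in net.graph.nodes:
        if node in disease or node in targets:
            continue
        nbrs = set(net.graph.neighbors(node))
        if nbrs & disease and nbrs & targets:
            out.add(node)
    return out


def read_id_list(path: str | Path) -> set[str]:
    """Read a seed list: one ID per line, '#' comments and blanks allowed."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line.split("#")[0].strip())
    return ids
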