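"""Hypergeometric over-representation testing of predicted targets.

For each term annotating at least one study protein, the upper-tail
hypergeometric probability P(X >= k) of drawing k annotated proteins in
a study set of size n from a population of N containing K annotated
proteins is computed. Benjamini-Hochberg q-values are reported
alongside, but significance is flagged on the raw p-value threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationTable


@dataclass
class EnrichmentRow:
    term: str
    label: str
    k: int      # study hits
    n: int      # study size
    K: int      # population hits
    N: int      # population size
    p_value: float
    bh_q: float
    significant: bool


def hypergeom_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    term_map: AnnotationTable,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Test each annotated term for over-representation in the study set.

    The default population should be the tested universe (e.g. all
    proteins in the interaction network). Rows are sorted by ascending
    p-value, ties broken by term ID.
    """
    study, population = set(study), set(population)
    if not population:
        raise ValueError("population is empty")
    violators = study - population
    if violators:
        raise ValueError(
            "study proteins outside the population: "
            + ", ".join(sorted(violators)[:10])
        )
    N, n = len(population), len(study)
    rows = []
    for term, proteins in sorted(term_map.by_term().items()):
        annotated = proteins & population
        K = len(annotated)
        k = len(annotated & study)
        if k == 0:
            continue
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        rows.append(EnrichmentRow(
            term=term,
            label=term_map.term_labels.get(term, term),
            k=k, n=n, K=K, N=N,
            p_value=p, bh_q=1.0,
            significant=p <= alpha,
        ))
    if rows:
        qvals = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, qvals):
            r.bh_q = float(q)
    rows.sort(key=lambda r: (r.p_value, r.term))
    return rows


def write_enrichment_tsv(rows: Iterable[EnrichmentRow], path: str | Path) -> None:
    lines = ["term\tlabel\tstudy_hits\tstudy_size\tpopulation_hits\t"
             "population_size\tp_value\tbh_q\tsignificant"]
    for r in rows:
        lines.append(
            f"{r.term}\t{r.label}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
            f"{r.p_value:.6g}\t{r.bh_q:.6g}\t{str(r.significant).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_revigo_export(rows: Iterable[EnrichmentRow], path: str | Path) -> None:
    """Two-column (term, p) export consumable by term-summarization tools."""
    lines = [f"{r.term}\t{r.p_value:.6g}" for r in rows]
    Path(path).write_text("\n".join(lines) + "\n")
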