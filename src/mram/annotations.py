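"""Functional annotation sources: GO (GAF 2.x), pathway and domain TSVs.

All three feature namespaces are normalized into one many-to-many
protein-term relation (:class:`AnnotationTable`) so the case builder can
treat GO terms, Reactome-style pathways and InterPro-style domains
uniformly. Gene-symbol to protein-accession translation is handled by
:func:`map_identifiers` with explicit ambiguity policies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

logger = logging.getLogger("mram.annotations")

Namespace = Literal["go", "pathway", "domain"]

#: GO aspect code (GAF column 9) -> item-label prefix, mirroring rule text
#: like "C:integral to plasma membrane".
_ASPECT_PREFIX = {"F": "F", "P": "P", "C": "C"}


@dataclass
class AnnotationTable:
    """Many-to-many protein-term relation for one feature namespace."""

    namespace: Namespace
    pairs: set[tuple[str, str]] = field(default_factory=set)
    term_labels: dict[str, str] = field(default_factory=dict)

    def proteins(self) -> set[str]:
        return {p for p, _ in self.pairs}

    def terms(self) -> set[str]:
        return {t for _, t in self.pairs}

    def terms_for(self, protein: str) -> set[str]:
        return {t for p, t in self.pairs if p == protein}

    def by_protein(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, t in self.pairs:
            out.setdefault(p, set()).add(t)
        return out

    def by_term(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, t in self.pairs:
            out.setdefault(t, set()).add(p)
        return out

    def restrict(self, proteins: set[str]) -> "AnnotationTable":
        kept = {(p, t) for p, t in self.pairs if p in proteins}
        return AnnotationTable(self.namespace, kept, dict(self.term_labels))


@dataclass
class IdMapping:
    """Source-ID to target-ID(s) mapping, e.g. gene symbol to UniProt."""

    forward: dict[str, set[str]] = field(default_factory=dict)
    provenance: str = ""


def load_gaf(
    path: str | Path, exclude_evidence: Iterable[str] = ()
) -> AnnotationTable:
    """Parse a GAF 2.x file into a GO annotation table.

    Pairs are (column 2 object ID, column 5 GO ID). The GO aspect
    (column 9: F/P/C) is kept as a prefix on the term label so rule items
    render like ``C:integral to plasma membrane``. Rows whose qualifier
    (column 4) contains NOT are dropped, as are '!' comment lines.
    ``exclude_evidence`` optionally drops rows by evidence code
    (column 7), e.g. ``{"IEA"}``; no codes are excluded by default.
    """
    path = Path(path)
    exclude = set(exclude_evidence)
    table = AnnotationTable(namespace="go")
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(
                    f"{path}: line {lineno} has {len(cols)} columns, "
                    "expected >= 9 (GAF 2.x)"
                )
            obj_id, qualifier, go_id = cols[1], cols[3], cols[4]
            evidence, aspect = cols[6], cols[8]
            if not obj_id or not go_id.startswith("GO:"):
                raise ValueError(f"{path}: line {lineno}: not a GAF annotation row")
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in exclude:
                continue
            table.pairs.add((obj_id, go_id))
            name = cols[9] if len(cols) > 9 and cols[9] else go_id
            prefix = _ASPECT_PREFIX.get(aspect, aspect or "?")
            table.term_labels[go_id] = f"{prefix}:{name}"
    return table


def load_membership_tsv(
    path: str | Path,
    namespace: Namespace,
    protein_col: int = 0,
    term_col: int = 1,
    label_col: int | None = None,
) -> AnnotationTable:
    """Read a generic protein-term membership TSV.

    Covers UniProt2Reactome-style pathway files and protein2ipr-style
    domain files via configurable 0-based column indices. Rows with an
    empty term field are skipped with a warning; a missing column is an
    error naming the row.
    """
    path = Path(path)
    table = AnnotationTable(namespace=namespace)
    needed = max(protein_col, term_col, label_col if label_col is not None else 0)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) <= needed:
                raise ValueError(
                    f"{path}: line {lineno} has {len(cols)} columns, "
                    f"need index {needed}"
                )
            protein, term = cols[protein_col].strip(), cols[term_col].strip()
            if not protein or not term:
                logger.warning("%s: line %d: empty protein/term field, skipped",
                               path, lineno)
                continue
            table.pairs.add((protein, term))
            if label_col is not None and cols[label_col].strip():
                table.term_labels[term] = cols[label_col].strip()
    return table


def load_mapping_tsv(path: str | Path, provenance: str = "") -> IdMapping:
    """Read a two-column source->target mapping TSV (one pair per row)."""
    forward: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
            raise ValueError(f"{path}: malformed mapping row at line {lineno}")
        forward.setdefault(cols[0].strip(), set()).add(cols[1].strip())
    return IdMapping(forward=forward, provenance=provenance or str(path))


def map_identifiers(
    ids: Iterable[str],
    mapping: IdMapping,
    policy: Literal["all", "first", "fail_ambiguous"] = "all",
) -> tuple[set[str], list[str]]:
    """Translate IDs through a mapping, reporting unmapped inputs.

    ``all`` expands one-to-many mappings; ``first`` takes the
    lexicographically smallest target; ``fail_ambiguous`` raises on any
    one-to-many entry. Unmapped IDs are returned, never silently dropped.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    ambiguous: list[str] = []
    for src in sorted(set(ids)):
        targets = mapping.forward.get(src)
        if not targets:
            unmapped.append(src)
            continue
        if len(targets) > 1 and policy == "fail_ambiguous":
            ambiguous.append(src)
            continue
        if policy == "first":
            mapped.add(min(targets))
        else:
            mapped.update(targets)
    if ambiguous:
        raise ValueError(
            "ambiguous mappings under fail_ambiguous policy: " + ", ".join(ambiguous)
        )
    if unmapped:
        logger.warning("%d unmapped identifier(s): %s",
                       len(unmapped), ", ".join(unmapped[:10]))
    return mapped, unmapped


def propagate_closure(
    table: AnnotationTable, parents: dict[str, set[str]]
) -> AnnotationTable:
    """Optional true-path closure over a flat term->parents relation.

    Off by default in the pipeline: annotation rows are used as-is, leaf
    terms only. Provided for sensitivity analyses with an external
    term-parent file.
    """
    closed = AnnotationTable(table.namespace, set(table.pairs),
                             dict(table.term_labels))
    for protein, term in table.pairs:
        stack = list(parents.get(term, ()))
        seen: set[str] = set()
        while stack:
            anc = stack.pop()
            if anc in seen:
                continue
            seen.add(anc)
            closed.pairs.add((protein, anc))
            stack.extend(parents.get(anc, ()))
    return closed
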