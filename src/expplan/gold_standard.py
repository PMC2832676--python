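"""Gold-standard construction from Gene Ontology annotations.

Two kinds of labels are produced:

* per-term gene labels — for a biological-process term, positives are the
  genes annotated to the term or any of its descendants (after propagating
  annotations up the is_a / part_of DAG); negatives are all other genes in
  the evaluated universe;
* per-gene-pair functional-relationship (FR) labels over a "functional slim"
  (a curated subset of high-level process terms): a pair is functionally
  related (fr=1) when the genes share at least one slim co-annotation,
  unrelated (fr=0) when both carry slim annotations but share none, and
  undefined otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "OntologyAnnotation",
    "GoldStandard",
    "FunctionalRelationLabels",
    "load_obo",
    "read_gaf",
    "read_annotation_table",
    "read_term_list",
    "propagate_annotations",
    "term_labels",
    "eligible_terms",
    "pair_fr_labels",
]

FR_TRUE = 1
FR_FALSE = 0
FR_UNDEFINED = -1

_PROPAGATING_RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyAnnotation:
    """An ontology DAG plus direct gene annotations and a slim-term subset."""

    term_ids: set[str]
    dag_parents: dict[str, set[str]]
    direct_annotations: dict[str, set[str]]
    slim_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.slim_terms <= self.term_ids:
            raise ValueError("slim_terms must be a subset of term_ids")
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        color: dict[str, int] = {}

        def visit(t: str) -> None:
            color[t] = 1
            for p in self.dag_parents.get(t, ()):
                c = color.get(p, 0)
                if c == 1:
                    raise ValueError(f"cycle in ontology DAG involving {t!r}")
                if c == 0:
                    visit(p)
            color[t] = 2

        for t in self.term_ids:
            if color.get(t, 0) == 0:
                visit(t)

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` via parent links (term excluded)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.dag_parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.dag_parents.get(p, ()))
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result


@dataclass
class GoldStandard:
    """Per-term labels and per-pair FR labels over a gene universe."""

    universe: list[str]
    propagated: dict[str, set[str]]
    slim_terms: set[str]
    fr: "FunctionalRelationLabels"

    def labels_for(self, term: str) -> tuple[set[str], set[str]]:
        return term_labels(term, self.propagated, set(self.universe))


@dataclass
class FunctionalRelationLabels:
    """Symmetric gene-pair FR labels as a compact int8 matrix.

    ``matrix[i, j]`` is 1, 0 or -1 (undefined) for genes ``genes[i]``,
    ``genes[j]``; the diagonal is undefined.
    """

    genes: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.genes), len(self.genes)):
            raise ValueError("FR matrix shape mismatch")

    def label(self, a: str, b: str) -> int:
        idx = {g: i for i, g in enumerate(self.genes)}
        return int(self.matrix[idx[a], idx[b]])


def load_obo(path: str | Path) -> tuple[set[str], dict[str, set[str]]]:
    """Parse an OBO ontology into (term ids, parent mapping).

    Only is_a and part_of edges are kept; obsolete terms are dropped.
    """
    import obonet

    graph = obonet.read_obo(str(path))
    term_ids = set(graph.nodes)
    parents: dict[str, set[str]] = {t: set() for t in term_ids}
    for child, parent, rel in graph.edges(keys=True):
        if rel in _PROPAGATING_RELATIONS:
            parents[child].add(parent)
    return term_ids, parents


def read_gaf(path: str | Path) -> dict[str, set[str]]:
    """Read gene -> direct GO terms from a GAF 2.x file.

    Column 2 (the stable DB object id) is the gene key and column 5 the GO
    id.  Rows whose qualifier contains NOT are dropped.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            gene, qualifier, term = cols[1], cols[3], cols[4]
            if "NOT" in qualifier.split("|"):
                continue
            out.setdefault(gene, set()).add(term)
    return out


def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (gene, term) TSV, e.g. a pre-propagated table."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


def read_term_list(path: str | Path) -> set[str]:
    """One term id per line (slim lists)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def propagate_annotations(
    direct: dict[str, set[str]], dag: OntologyAnnotation
) -> dict[str, set[str]]:
    """Close annotations over the ontology: a gene annotated to a term is
    annotated to every ancestor of that term.

    Annotations to terms unknown to the DAG are dropped with a warning.
    """
    unknown: set[str] = set()
    out: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set()
        for t in terms:
            if t not in dag.term_ids:
                unknown.add(t)
                continue
            closed.add(t)
            closed |= dag.ancestors(t)
        out[gene] = closed
    if unknown:
        warnings.warn(
            f"dropped annotations to {len(unknown)} unknown term(s): "
            + ", ".join(sorted(unknown)[:5]),
            stacklevel=2,
        )
    return out


def term_labels(
    term: str, annotations: dict[str, set[str]], universe: set[str]
) -> tuple[set[str], set[str]]:
    """Positive/negative gene partition of ``universe`` for one term.

    Positives are universe genes annotated (post-propagation) to the term;
    negatives are all other universe genes.
    """
    positives = {g for g in universe if term in annotations.get(g, ())}
    return positives, universe - positives


def eligible_terms(
    annotations: dict[str, set[str]],
    universe: set[str],
    terms: set[str] | None = None,
    min_genes: int = 10,
    max_genes: int = 500,
) -> list[str]:
    """Terms whose propagated positive count n satisfies min <= n <= max.

    Both boundaries are inclusive.  ``terms`` restricts the candidate set
    (e.g. to biological-process or slim terms); by default every annotated
    term is considered.
    """
    if min_genes > max_genes:
        raise ValueError("min_genes must be <= max_genes")
    counts: dict[str, int] = {}
    for g in universe:
        for t in annotations.get(g, ()):
            counts[t] = counts.get(t, 0) + 1
    candidates = set(counts) if terms is None else set(terms)
    return sorted(t for t in candidates if min_genes <= counts.get(t, 0) <= max_genes)


def pair_fr_labels(
    annotations: dict[str, set[str]],
    slim_terms: set[str],
    universe: list[str],
) -> FunctionalRelationLabels:
    """Functional-relationship labels for every unordered gene pair.

    fr=1 when the pair shares at least one slim co-annotation; fr=0 when both
    genes each carry at least one slim annotation but share none; undefined
    (-1) otherwise.  The returned matrix is symmetric with an undefined
    diagonal.
    """
    slim_list = sorted(slim_terms)
    slim_idx = {t: j for j, t in enumerate(slim_list)}
    M = np.zeros((len(universe), len(slim_list)), dtype=bool)
    for i, g in enumerate(universe):
        for t in annotations.get(g, ()):
            j = slim_idx.get(t)
            if j is not None:
                M[i, j] = True
    share = (M.astype(np.int32) @ M.T.astype(np.int32)) > 0
    has = M.any(axis=1)
    both = np.outer(has, has)
    fr = np.full((len(universe), len(universe)), FR_UNDEFINED, dtype=np.int8)
    fr[both] = FR_FALSE
    fr[share & both] = FR_TRUE
    np.fill_diagonal(fr, FR_UNDEFINED)
    return FunctionalRelationLabels(genes=list(universe), matrix=fr)


def build_gold_standard(
    direct: dict[str, set[str]],
    dag: OntologyAnnotation,
    universe: list[str],
) -> GoldStandard:
    """Propagate annotations and derive FR labels over ``universe``."""
    propagated = propagate_annotations(direct, dag)
    fr = pair_fr_labels(propagated, dag.slim_terms, universe)
    return GoldStandard(
        universe=list(universe),
        propagated=propagated,
        slim_terms=set(dag.slim_terms),
        fr=fr,
    )
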