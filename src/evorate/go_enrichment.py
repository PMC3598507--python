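"""Term-for-term GO over-representation of the slowest-evolving genes.

Direct annotations are first closed upward through the ontology (the
true-path rule, following is_a and part_of edges only), then each term is
tested for over-representation in the study set against the population with
a one-sided hypergeometric tail, P(X ≥ study_count).  Raw p-values are the
primary output; a Benjamini–Hochberg column is emitted alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PROPAGATION_RELATIONS = ("is_a", "part_of")


@dataclass
class GoDag:
    """GO terms and their is_a/part_of parent edges (child → parent)."""

    graph: nx.DiGraph
    _ancestor_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("is_a/part_of edge graph contains a cycle")

    @classmethod
    def from_obonet(cls, multigraph: nx.MultiDiGraph) -> "GoDag":
        graph = nx.DiGraph()
        for node, data in multigraph.nodes(data=True):
            graph.add_node(node,
                           name=data.get("name", ""),
                           namespace=data.get("namespace", ""))
        for child, parent, key in multigraph.edges(keys=True):
            if key in PROPAGATION_RELATIONS:
                graph.add_edge(child, parent, relation=key)
        return cls(graph)

    @classmethod
    def build(cls, terms: Mapping[str, tuple[str, str]],
              edges: Iterable[tuple[str, str, str]]) -> "GoDag":
        """Construct a DAG from ``{term: (name, namespace)}`` and
        ``(child, parent, relation)`` edges."""
        graph = nx.DiGraph()
        for term, (name, namespace) in terms.items():
            graph.add_node(term, name=name, namespace=namespace)
        for child, parent, relation in edges:
            if relation in PROPAGATION_RELATIONS:
                graph.add_edge(child, parent, relation=relation)
        return cls(graph)

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term))
            self._ancestor_cache[term] = cached
        return cached

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", "") \
            if term in self.graph else ""


def propagate_annotations(direct: Mapping[str, Iterable[str]],
                          dag: GoDag) -> dict[str, set[str]]:
    """Close annotations upward through the DAG (true-path rule).

    Each gene becomes annotated to every ancestor of each direct term.
    Terms absent from the DAG are skipped and tallied in a warning.
    Idempotent: propagating a propagated mapping changes nothing.
    """
    skipped = 0
    result: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set()
        for term in terms:
            if term not in dag.graph:
                skipped += 1
                continue
            closed.add(term)
            closed |= dag.ancestors(term)
        result[gene] = closed
    if skipped:
        logger.warning("propagation skipped %d annotations to unknown terms",
                       skipped)
    return result


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation in the study set."""

    term_id: str
    p_value: float
    study_count: int
    study_n: int
    pop_count: int
    pop_n: int
    study_fraction: float
    population_fraction: float
    description: str
    p_bh: float = float("nan")


def term_for_term(study: set[str], population: set[str],
                  annotations: Mapping[str, set[str]],
                  dag: Optional[GoDag] = None,
                  annotated_only: bool = False) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per GO term.

    For each term with at least one annotated population gene,
    p = P(X ≥ study_count) with X ~ Hypergeom(pop_n, pop_count, study_n).
    Results sort ascending by p (ties by term id).  With
    ``annotated_only`` genes lacking any annotation are removed from both
    denominators; by default they stay in, since a genome typically has GO
    coverage for only part of its genes.
    """
    if not population:
        raise ValueError("population set is empty")
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    if annotated_only:
        population = {g for g in population if annotations.get(g)}
        study = {g for g in study if annotations.get(g)}
        if not population:
            raise ValueError("no annotated genes in population")
    pop_n, study_n = len(population), len(study)
    pop_counts: dict[str, int] = {}
    study_counts: dict[str, int] = {}
    for gene in population:
        for term in annotations.get(gene, ()):
            pop_counts[term] = pop_counts.get(term, 0) + 1
            if gene in study:
                study_counts[term] = study_counts.get(term, 0) + 1
    results = []
    for term, pop_count in pop_counts.items():
        study_count = study_counts.get(term, 0)
        p = float(hypergeom.sf(study_count - 1, pop_n, pop_count, study_n))
        results.append(EnrichmentResult(
            term_id=term, p_value=min(p, 1.0),
            study_count=study_count, study_n=study_n,
            pop_count=pop_count, pop_n=pop_n,
            study_fraction=study_count / study_n if study_n else 0.0,
            population_fraction=pop_count / pop_n,
            description=dag.name(term) if dag is not None else ""))
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if results:
        bh = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [EnrichmentResult(**{**r.__dict__, "p_bh": float(q)})
                   for r, q in zip(results, bh)]
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term_id, r.p_value, r.p_bh, r.study_count, r.study_n,
          r.pop_count, r.pop_n, r.study_fraction, r.population_fraction,
          r.description) for r in results],
        columns=["term_id", "p_value", "p_bh", "study_count", "study_n",
                 "pop_count", "pop_n", "study_fraction",
                 "population_fraction", "description"])


__all__ = [
    "GoDag", "EnrichmentResult", "propagate_annotations", "term_for_term",
    "enrichment_to_frame", "PROPAGATION_RELATIONS",
]
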