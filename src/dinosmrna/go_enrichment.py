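"""GO enrichment: DAG handling, annotation propagation, per-term
Fisher's exact tests, and the elim decorrelation pass.

Per-term significance is the one-sided (over-representation)
hypergeometric tail of the 2x2 study/population table. The elim
variant processes terms from the leaves upward: when a term's classic P
falls below alpha, its study genes are removed from all ancestors
before those ancestors are tested, decorrelating the DAG-linked tests.
P values are reported uncorrected: the conditional tests are not
independent, so standard multiple-testing corrections do not apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class EnrichmentResult:
    term: str
    name: str
    study_in: int
    study_n: int
    pop_in: int
    pop_n: int
    p_value: float
    method: str   # "classic" | "elim"


class GoDag:
    """An acyclic is_a ontology with direct and propagated annotations."""

    def __init__(self, graph: nx.DiGraph, annotations: dict[str, set[str]]):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self.graph = graph  # edges point child -> parent
        self.direct = {g: set(t for t in terms if t in graph)
                       for g, terms in annotations.items()}
        self.propagated: dict[str, set[str]] = {}
        for gene, terms in self.direct.items():
            closed = set(terms)
            for t in terms:
                closed |= nx.descendants(graph, t)  # ancestors along is_a
            self.propagated[gene] = closed
        self.term_genes: dict[str, set[str]] = {t: set() for t in graph.nodes}
        for gene, terms in self.propagated.items():
            for t in terms:
                self.term_genes[t].add(gene)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)

    def depth(self, term: str) -> int:
        """Longest is_a path from a root (term with no parents)."""
        return self._depths()[term]

    def _depths(self) -> dict[str, int]:
        if not hasattr(self, "_depth_cache"):
            depths: dict[str, int] = {}
            for t in nx.topological_sort(self.graph.reverse(copy=False)):
                parents = list(self.graph.successors(t))
                depths[t] = 0 if not parents else 1 + max(depths[p] for p in parents)
            self._depth_cache = depths
        return self._depth_cache


def load_and_propagate(obo_path: str, annotation_path: str) -> GoDag:
    """Build a GoDag from an OBO file and a 2-column (gene, term) TSV.

    Only is_a edges are kept; obsolete terms are dropped by the OBO
    reader. Each gene's term set is closed under ancestors.
    """
    multigraph = obonet.read_obo(obo_path)
    graph = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        graph.add_node(node, **data)
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)

    annot = pd.read_csv(annotation_path, sep="\t", header=None,
                        names=["gene", "term"], dtype=str)
    if annot["gene"].isna().any() or (annot["gene"] == "").any():
        raise ValueError("annotation table contains empty gene ids")
    annotations: dict[str, set[str]] = {}
    for row in annot.itertuples():
        annotations.setdefault(row.gene, set()).add(row.term)
    return GoDag(graph, annotations)


def fisher_term(
    term: str,
    term_genes: set[str],
    study: set[str],
    population: set[str],
    name: str = "",
    method: str = "classic",
) -> EnrichmentResult:
    """One-sided over-representation P for one term.

    P = P(X >= study_in) with X ~ Hypergeom(pop_n, pop_in, study_n).
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    pop_in = len(term_genes & population)
    study_in = len(term_genes & study)
    p = float(hypergeom.sf(study_in - 1, len(population), pop_in, len(study)))
    return EnrichmentResult(
        term=term, name=name, study_in=study_in, study_n=len(study),
        pop_in=pop_in, pop_n=len(population), p_value=min(p, 1.0), method=method,
    )


def classic_enrichment(
    dag: GoDag, study: set[str], population: set[str]
) -> list[EnrichmentResult]:
    return [
        fisher_term(t, dag.term_genes[t], study, population, name=dag.name(t))
        for t in sorted(dag.graph.nodes)
    ]


def elim_enrichment(
    dag: GoDag, study: set[str], population: set[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Dependency-aware enrichment (elim variant).

    Terms are tested by decreasing depth; a term whose classic P < alpha
    has its study genes removed from all of its ancestors before they
    are tested. Returns one row per term with both classic and elim
    statistics; no multiple-testing correction is applied.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    depths = dag._depths()
    order = sorted(dag.graph.nodes, key=lambda t: (-depths[t], t))
    eliminated: dict[str, set[str]] = {t: set() for t in dag.graph.nodes}
    rows = []
    for term in order:
        genes = dag.term_genes[term]
        classic = fisher_term(term, genes, study, population, name=dag.name(term))
        elim_study_in = len((genes & study) - eliminated[term])
        elim_p = float(hypergeom.sf(
            elim_study_in - 1, classic.pop_n, classic.pop_in, classic.study_n))
        rows.append({
            "term": term,
            "name": dag.name(term),
            "namespace": dag.namespace(term),
            "depth": depths[term],
            "study_in": classic.study_in,
            "study_n": classic.study_n,
            "pop_in": classic.pop_in,
            "pop_n": classic.pop_n,
            "classic_p": classic.p_value,
            "elim_study_in": elim_study_in,
            "elim_p": min(elim_p, 1.0),
        })
        if classic.p_value < alpha:
            significant_study = genes & study
            for anc in dag.ancestors(term):
                eliminated[anc] |= significant_study
    df = pd.DataFrame(rows).sort_values("elim_p", kind="stable").reset_index(drop=True)
    df["method"] = "elim"
    return df
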