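"""Synthetic GO fixtures: a small is_a DAG, gene annotations, and a
study set with one term planted as over-represented.

The planted enrichment is a biased (Wallenius-type) draw of the study
set: genes annotated to the designated term carry ``odds_ratio`` times
the sampling weight of the rest of the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimulationConfig

#: Three-level default DAG (term -> parent); root has no parent.
_DEFAULT_EDGES = [
    ("GO:0000002", "GO:0000001"), ("GO:0000003", "GO:0000001"),
    ("GO:0000004", "GO:0000001"),
    ("GO:0000010", "GO:0000002"), ("GO:0000011", "GO:0000002"),
    ("GO:0000012", "GO:0000003"), ("GO:0000013", "GO:0000003"),
    ("GO:0000014", "GO:0000004"),
    ("GO:0000020", "GO:0000010"), ("GO:0000021", "GO:0000010"),
    ("GO:0000022", "GO:0000011"), ("GO:0000023", "GO:0000012"),
    ("GO:0000024", "GO:0000013"), ("GO:0000025", "GO:0000014"),
]


@dataclass
class GoFixture:
    obo_text: str
    annotations: pd.DataFrame           # columns gene, term (direct)
    study: set[str] = field(default_factory=set)
    population: set[str] = field(default_factory=set)
    enriched_term: str = ""
    odds_ratio: float = 1.0


def _obo_text(graph: nx.DiGraph) -> str:
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for term in sorted(graph.nodes):
        lines += [
            "[Term]",
            f"id: {term}",
            f"name: synthetic process {term[-4:]}",
            "namespace: biological_process",
        ]
        for parent in sorted(graph.successors(term)):
            lines.append(f"is_a: {parent} ! synthetic process {parent[-4:]}")
        lines.append("")
    return "\n".join(lines)


def generate_go_fixture(
    config: SimulationConfig,
    n_population: int = 1000,
    study_size: int = 50,
    odds_ratio: float = 10.0,
    enriched_term: str = "GO:0000020",
    edges: list[tuple[str, str]] | None = None,
    annotations_per_gene: tuple[int, int] = (1, 2),
) -> GoFixture:
    """Emit OBO text, direct gene->leaf annotations, and a study set in
    which ``enriched_term`` is over-represented at ``odds_ratio``."""
    rng = config.rng("go")
    graph = nx.DiGraph(edges if edges is not None else _DEFAULT_EDGES)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(f"requested ontology contains a cycle: {nx.find_cycle(graph)}")
    leaves = sorted(t for t in graph.nodes if graph.in_degree(t) == 0)
    if enriched_term not in graph.nodes:
        raise ValueError(f"enriched term {enriched_term} not in the DAG")

    genes = [f"gene-{i + 1:04d}" for i in range(n_population)]
    rows = []
    annotated_to_target: set[str] = set()
    lo, hi = annotations_per_gene
    for gene in genes:
        k = int(rng.integers(lo, hi + 1))
        for term in rng.choice(leaves, size=k, replace=False):
            rows.append({"gene": gene, "term": term})
            if term == enriched_term:
                annotated_to_target.add(gene)

    weights = np.array(
        [odds_ratio if g in annotated_to_target else 1.0 for g in genes])
    study: set[str] = set()
    pool = list(genes)
    w = weights.astype(float).copy()
    for _ in range(study_size):
        p = w / w.sum()
        pick = rng.choice(len(pool), p=p)
        study.add(pool[pick])
        pool.pop(pick)
        w = np.delete(w, pick)

    return GoFixture(
        obo_text=_obo_text(graph),
        annotations=pd.DataFrame(rows, columns=["gene", "term"]),
        study=study,
        population=set(genes),
        enriched_term=enriched_term,
        odds_ratio=odds_ratio,
    )
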