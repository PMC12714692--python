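"""Louvain modules, per-module topology, and hypergeometric enrichment.

Each topic network is partitioned into modules with the Louvain algorithm
(resolution 1, seeded). Modules are summarised topologically and tested for
annotation overrepresentation with the upper-tail hypergeometric test,
Benjamini-Hochberg corrected across the terms tested for that module.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .corpus_ingest import GeneSet
from .graph_build import TopicNetwork

__all__ = [
    "ModulePartition",
    "ModuleMetricsRecord",
    "EnrichmentRow",
    "louvain_partition",
    "module_metrics",
    "hypergeometric_ora",
    "bh_adjust",
]


@dataclass
class ModulePartition:
    topic: int
    assignment: dict[str, int]  # gene -> module id, ids contiguous from 0
    modularity: float
    seed: int

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for gene, mod in self.assignment.items():
            out.setdefault(mod, set()).add(gene)
        return out


@dataclass
class ModuleMetricsRecord:
    module: int
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    avg_path_length: float


@dataclass
class EnrichmentRow:
    module: int
    term_id: str
    term_name: str
    k: int  # module genes annotated to the term (within the universe)
    K: int  # term size within the universe
    n: int  # module size within the universe
    N: int  # universe size
    p: float
    p_adj: float


def louvain_partition(net: TopicNetwork, seed: int = 0) -> ModulePartition:
    """Seeded Louvain partition at resolution 1.

    Module ids are contiguous from 0, ordered by decreasing size with ties
    broken by the lexicographically smallest member, so the labelling is
    deterministic given the seed.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("louvain_partition requires a non-empty network")
    comms = nx.community.louvain_communities(g, resolution=1, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(map(str, c))))
    assignment = {gene: i for i, comm in enumerate(comms) for gene in comm}
    mod = nx.community.modularity(g, comms) if g.number_of_edges() else 0.0
    return ModulePartition(
        topic=net.topic, assignment=assignment, modularity=float(mod), seed=seed
    )


def module_metrics(
    net: TopicNetwork, partition: ModulePartition
) -> list[ModuleMetricsRecord]:
    """Topology of each module's induced subgraph.

    Singleton modules get density 0 and path length 0 by convention; path
    length is computed on the module's largest connected component.
    """
    missing = net.nodes - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    out: list[ModuleMetricsRecord] = []
    for mod, genes in sorted(partition.modules().items()):
        sub = net.graph.subgraph(genes)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        giant = sub.subgraph(max(nx.connected_components(sub), key=len))
        apl = (
            nx.average_shortest_path_length(giant)
            if giant.number_of_nodes() > 1
            else 0.0
        )
        out.append(
            ModuleMetricsRecord(
                module=mod,
                n_nodes=n,
                n_edges=e,
                avg_degree=2 * e / n,
                density=nx.density(sub) if n > 1 else 0.0,
                avg_path_length=float(apl),
            )
        )
    return out


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def hypergeometric_ora(
    module_genes: set[str],
    terms: list[GeneSet],
    universe: set[str],
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric overrepresentation of each term in a module.

    All gene lists are intersected with the universe first. p = P(X >= k)
    for X ~ Hypergeom(N, K, n); BH correction is applied across all terms
    tested for this module, and rows come back sorted by p (ties by term id).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    module = module_genes & universe
    n, N = len(module), len(universe)
    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    for term in terms:
        term_genes = term.gene_set & universe
        K = len(term_genes)
        k = len(module & term_genes)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        rows.append(
            EnrichmentRow(
                module=-1, term_id=term.set_id, term_name=term.name,
                k=k, K=K, n=n, N=N, p=p, p_adj=np.nan,
            )
        )
        pvals.append(p)
    if rows:
        for row, adj in zip(rows, bh_adjust(pvals)):
            row.p_adj = float(adj)
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows
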