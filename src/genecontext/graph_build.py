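"""Topic-specific gene co-occurrence networks from gene-set intersections.

Two genes are connected when they lie together in the intersection of at
least one pair of gene sets assigned to the same topic: every unordered pair
of distinct sets contributes a clique over its intersection, the union of
those cliques is taken, and multiple overlaying edges collapse to unique
connections. Genes that never co-occur in any pairwise intersection carry no
edge and are excluded from the network.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .corpus_ingest import GeneSet

__all__ = ["TopicNetwork", "build_topic_network", "write_network", "read_edgelist"]


@dataclass
class TopicNetwork:
    """Simple undirected unweighted graph over gene symbols for one topic."""

    topic: int
    graph: nx.Graph
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.graph.remove_edges_from(nx.selfloop_edges(self.graph))

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_topic_network(sets: list[GeneSet], topic: int = 0) -> TopicNetwork:
    """Union of intersection cliques over all distinct gene-set pairs.

    With fewer than two sets the network is empty. The result is invariant
    under permutation of the input list; edge multiplicity across set pairs
    is discarded.
    """
    g = nx.Graph()
    for s, t in itertools.combinations(sets, 2):
        common = sorted(s.gene_set & t.gene_set)
        g.add_edges_from(itertools.combinations(common, 2))
    return TopicNetwork(
        topic=topic, graph=g, provenance=sorted(s.set_id for s in sets)
    )


def write_network(net: TopicNetwork, outdir: str | Path, stem: str) -> dict[str, str]:
    """Write edge-list TSV and GraphML for one topic network."""
    outdir = Path(outdir)
    paths = {
        "edgelist": str(outdir / f"{stem}.edges.tsv"),
        "graphml": str(outdir / f"{stem}.graphml"),
        "provenance": str(outdir / f"{stem}.provenance.json"),
    }
    with open(paths["edgelist"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")
    nx.write_graphml(net.graph, paths["graphml"])
    with open(paths["provenance"], "w") as fh:
        json.dump({"topic": net.topic, "set_ids": net.provenance}, fh, indent=1)
    return paths


def read_edgelist(path: str | Path, topic: int = 0) -> TopicNetwork:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "gene_a\tgene_b":
            raise ValueError(f"{path}: unexpected edge-list header {header!r}")
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            g.add_edge(a, b)
    return TopicNetwork(topic=topic, graph=g)
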