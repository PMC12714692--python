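"""Network-level topology summaries and Laplacian spectral comparison.

Networks from different topics share few nodes, so structural similarity is
compared in spectral terms: each graph is summarised by the m largest
eigenvalues of its combinatorial Laplacian L = D - A (zero-padded when the
graph has fewer than m nodes) and networks are compared by the Euclidean
distance between those truncated spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_build import TopicNetwork

__all__ = [
    "GlobalMetricsRecord",
    "SpectralSignature",
    "global_metrics",
    "laplacian_spectrum",
    "spectral_distance_matrix",
    "DEFAULT_SPECTRUM_LENGTH",
]

DEFAULT_SPECTRUM_LENGTH = 20


@dataclass
class GlobalMetricsRecord:
    topic: int
    n_nodes: int
    n_edges: int
    avg_degree: float
    clustering: float
    density: float
    diameter: int
    avg_path_length: float
    modularity: float
    avg_betweenness: float
    avg_closeness: float


@dataclass
class SpectralSignature:
    topic: int
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if (np.diff(ev) > 1e-9).any():
            raise ValueError("eigenvalues must be non-increasing")
        self.eigenvalues = ev


def global_metrics(
    net: TopicNetwork, seed: int = 0, clustering: str = "global"
) -> GlobalMetricsRecord:
    """Global topological summary of one topic network.

    Clustering is the global transitivity (3 x triangles / connected triples)
    by default; ``clustering="average"`` switches to the mean local
    coefficient. Diameter and average path length are computed on the largest
    connected component; modularity is that of the Louvain partition at the
    given seed; closeness is the harmonic centrality normalised by n - 1.
    """
    from .community import louvain_partition
    from .node_topology import betweenness_centrality

    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("global_metrics requires a non-empty network")
    if clustering == "global":
        clust = nx.transitivity(g)
    elif clustering == "average":
        clust = nx.average_clustering(g)
    else:
        raise ValueError(f"unknown clustering mode {clustering!r}")
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    if giant.number_of_nodes() > 1:
        diameter = nx.diameter(giant)
        apl = nx.average_shortest_path_length(giant)
    else:
        diameter, apl = 0, 0.0
    part = louvain_partition(net, seed=seed)
    btw = betweenness_centrality(net)
    harm = nx.harmonic_centrality(g)
    denom = max(n - 1, 1)
    return GlobalMetricsRecord(
        topic=net.topic,
        n_nodes=n,
        n_edges=e,
        avg_degree=2 * e / n,
        clustering=float(clust),
        density=nx.density(g),
        diameter=int(diameter),
        avg_path_length=float(apl),
        modularity=part.modularity,
        avg_betweenness=float(np.mean(list(btw.values()))),
        avg_closeness=float(np.mean([v / denom for v in harm.values()])),
    )


def laplacian_spectrum(
    net: TopicNetwork, m: int = DEFAULT_SPECTRUM_LENGTH, largest: bool = True
) -> SpectralSignature:
    """The m largest (default) Laplacian eigenvalues, descending, zero-padded.

    ``largest=False`` keeps the m smallest instead (still reported in
    descending order) for sensitivity analyses.
    """
    if net.n_nodes == 0:
        raise ValueError("laplacian_spectrum requires a non-empty network")
    ev = nx.laplacian_spectrum(net.graph)  # ascending, real symmetric
    ev = np.clip(ev, 0.0, None)
    ev = np.sort(ev)[::-1] if largest else np.sort(ev)[:m][::-1]
    sig = np.zeros(m)
    take = min(m, ev.size)
    sig[:take] = ev[:take]
    sig = np.sort(sig)[::-1]
    return SpectralSignature(topic=net.topic, eigenvalues=sig)


def spectral_distance_matrix(sigs: list[SpectralSignature]) -> np.ndarray:
    """Pairwise Euclidean distances between truncated spectra (symmetric,
    zero diagonal)."""
    lengths = {s.eigenvalues.size for s in sigs}
    if len(lengths) > 1:
        raise ValueError(f"signature length mismatch: {sorted(lengths)}")
    mat = np.array([s.eigenvalues for s in sigs])
    diff = mat[:, None, :] - mat[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))
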