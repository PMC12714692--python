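"""Synthetic corpora, gene-set collections and benchmark graphs.

Generators with planted structure — disjoint per-topic vocabularies, planted
gene-set overlaps, and hub genes inserted into every set of their topic — so
each pipeline stage can be validated offline against known ground truth.
All generators draw from one explicit ``numpy`` Generator and are
bit-reproducible for a fixed seed.

Vocabulary tokens are built from a consonant-only alphabet (no vowels, no
``y``/``s``), which makes them invariant under Porter stemming and stopword
filtering: the preprocessing chain passes them through unchanged, so
planted-vocabulary recovery checks remain exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .corpus_ingest import DocumentRecord, GeneSet
from .graph_build import TopicNetwork
from .semantic_map import OntologyDag

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_genesets",
    "generate_study",
    "generate_ontology",
    "generate_benchmark_graph",
]

_TOKEN_ALPHABET = np.array(list("bcdfghjklmnpqrtvwz"))


@dataclass
class SyntheticConfig:
    """Planted-structure study conditions.

    Defaults encode the reference recovery setting: 4 planted topics with
    disjoint 50-token vocabularies, 60 documents per topic of 50 tokens
    each, 8 gene sets of 20 genes per topic with an expected pairwise
    overlap of half a set, and one hub gene per topic present in all of its
    topic's sets.
    """

    n_topics: int = 4
    vocab_per_topic: int = 50
    docs_per_topic: int = 60
    doc_length: int = 50
    sets_per_topic: int = 8
    genes_per_set: int = 20
    overlap_fraction: float = 0.5
    hub_genes_per_topic: int = 1
    background_vocab: int = 20
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_topics", "vocab_per_topic", "docs_per_topic", "doc_length",
            "sets_per_topic", "genes_per_set",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not (0 <= self.background_rate <= 1):
            raise ValueError("background_rate must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted labels: document -> topic, set -> topic, hubs per topic."""

    doc_topics: dict[str, int] = field(default_factory=dict)
    set_topics: dict[str, int] = field(default_factory=dict)
    hub_genes: dict[int, list[str]] = field(default_factory=dict)
    topic_vocabularies: dict[int, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["hub_genes"] = {str(k): v for k, v in self.hub_genes.items()}
        payload["topic_vocabularies"] = {
            str(k): v for k, v in self.topic_vocabularies.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            doc_topics={k: int(v) for k, v in payload["doc_topics"].items()},
            set_topics={k: int(v) for k, v in payload["set_topics"].items()},
            hub_genes={int(k): v for k, v in payload["hub_genes"].items()},
            topic_vocabularies={
                int(k): v for k, v in payload["topic_vocabularies"].items()
            },
        )


def _make_tokens(rng: np.random.Generator, count: int, length: int = 6) -> list[str]:
    tokens: list[str] = []
    seen: set[str] = set()
    while len(tokens) < count:
        t = "".join(rng.choice(_TOKEN_ALPHABET, size=length))
        if t not in seen:
            seen.add(t)
            tokens.append(t)
    return tokens


def _topic_vocabularies(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[int, list[str]], list[str]]:
    all_tokens = _make_tokens(
        rng, cfg.n_topics * cfg.vocab_per_topic + cfg.background_vocab
    )
    vocabs = {
        t: all_tokens[t * cfg.vocab_per_topic : (t + 1) * cfg.vocab_per_topic]
        for t in range(cfg.n_topics)
    }
    background = all_tokens[cfg.n_topics * cfg.vocab_per_topic :]
    return vocabs, background


def generate_corpus(
    cfg: SyntheticConfig,
) -> tuple[list[DocumentRecord], GroundTruth]:
    """Documents sampled from disjoint planted per-topic vocabularies.

    Each document draws ``doc_length`` tokens uniformly from its topic's
    vocabulary, with each position replaced by a background token at
    ``background_rate``. Document d of topic t carries set id ``T{t}S{j}``
    with j cycling over the topic's sets, so the corpus composes with
    :func:`generate_genesets` for end-to-end runs.
    """
    rng = np.random.default_rng(cfg.seed)
    vocabs, background = _topic_vocabularies(cfg, rng)
    docs: list[DocumentRecord] = []
    truth = GroundTruth(topic_vocabularies={t: list(v) for t, v in vocabs.items()})
    for t in range(cfg.n_topics):
        vocab = np.array(vocabs[t])
        bg = np.array(background) if background else vocab
        for i in range(cfg.docs_per_topic):
            tokens = rng.choice(vocab, size=cfg.doc_length)
            if cfg.background_rate > 0:
                mask = rng.random(cfg.doc_length) < cfg.background_rate
                tokens[mask] = rng.choice(bg, size=int(mask.sum()))
            doc_id = f"d{t}_{i:03d}"
            set_id = f"T{t}S{i % cfg.sets_per_topic}"
            docs.append(
                DocumentRecord(
                    doc_id=doc_id, set_id=set_id,
                    text=" ".join(tokens), source="abstract",
                )
            )
            truth.doc_topics[doc_id] = t
    return docs, truth


def generate_genesets(
    cfg: SyntheticConfig,
) -> tuple[list[GeneSet], GroundTruth]:
    """Gene sets with planted overlaps and hub genes.

    Per topic, sets sample ``genes_per_set`` genes without replacement from
    a pool sized so two sets share an expected ``overlap_fraction`` of a
    set; ``overlap_fraction = 0`` allocates disjoint slices instead. Every
    planted hub gene is inserted into all sets of its topic and therefore
    lies in every pairwise intersection.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    sets: list[GeneSet] = []
    truth = GroundTruth()
    for t in range(cfg.n_topics):
        hubs = [f"HUB{t}_{h}" for h in range(cfg.hub_genes_per_topic)]
        truth.hub_genes[t] = hubs
        if cfg.overlap_fraction > 0:
            pool_size = max(
                cfg.genes_per_set,
                int(round(cfg.genes_per_set / cfg.overlap_fraction)),
            )
        else:
            pool_size = cfg.genes_per_set * cfg.sets_per_topic
        pool = [f"G{t}_{i:03d}" for i in range(pool_size)]
        for j in range(cfg.sets_per_topic):
            if cfg.overlap_fraction > 0:
                picked = list(
                    rng.choice(pool, size=cfg.genes_per_set, replace=False)
                )
            else:
                picked = pool[j * cfg.genes_per_set : (j + 1) * cfg.genes_per_set]
            set_id = f"T{t}S{j}"
            sets.append(
                GeneSet(
                    set_id=set_id,
                    name=f"synthetic topic {t} set {j}",
                    genes=tuple(hubs + picked),
                )
            )
            truth.set_topics[set_id] = t
    return sets, truth


def generate_study(
    cfg: SyntheticConfig,
) -> tuple[list[GeneSet], list[DocumentRecord], GroundTruth]:
    """Consistent gene sets + documents + merged ground truth for a full run."""
    docs, doc_truth = generate_corpus(cfg)
    sets, set_truth = generate_genesets(cfg)
    by_set: dict[str, list[str]] = {}
    for d in docs:
        by_set.setdefault(d.set_id, []).append(d.doc_id)
    for s in sets:
        s.doc_ids = by_set.get(s.set_id, [])
    truth = GroundTruth(
        doc_topics=doc_truth.doc_topics,
        set_topics=set_truth.set_topics,
        hub_genes=set_truth.hub_genes,
        topic_vocabularies=doc_truth.topic_vocabularies,
    )
    return sets, docs, truth


def generate_ontology(
    sets: list[GeneSet], set_topics: dict[str, int]
) -> OntologyDag:
    """Toy annotation DAG: one leaf term per gene set, one inner term per
    topic, a single root; leaves carry their set's genes as annotations."""
    parents: dict[str, set[str]] = {}
    annotations: dict[str, set[str]] = {}
    terms: set[str] = {"ROOT"}
    for s in sets:
        topic_term = f"TOPIC{set_topics[s.set_id]}"
        leaf = f"TERM_{s.set_id}"
        parents[leaf] = {topic_term}
        parents.setdefault(topic_term, {"ROOT"})
        annotations[leaf] = set(s.genes)
        terms.update((leaf, topic_term))
    return OntologyDag(terms=terms, parents=parents, annotations=annotations)


_GRAPH_BUILDERS = {
    "path": lambda n=4: nx.path_graph(n),
    "cycle": lambda n=5: nx.cycle_graph(n),
    "star": lambda n=5: nx.star_graph(n - 1),  # n = total node count
    "complete": lambda n=5: nx.complete_graph(n),
    "grid": lambda rows=3, cols=3: nx.grid_2d_graph(rows, cols),
    "two_triangles": lambda bridged=False: _two_triangles(bridged),
    "k_ary_tree": lambda k=2, depth=3: nx.balanced_tree(k, depth),
}


def _two_triangles(bridged: bool) -> nx.Graph:
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    if bridged:
        g.add_edge(2, 3)
    return g


def generate_benchmark_graph(name: str, **params) -> TopicNetwork:
    """Named deterministic graph (nodes relabelled ``n0``, ``n1``, ...) used
    as an oracle fixture across modules."""
    try:
        builder = _GRAPH_BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown benchmark graph {name!r}; choose from {sorted(_GRAPH_BUILDERS)}"
        ) from None
    g = builder(**params)
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    return TopicNetwork(topic=0, graph=g)
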