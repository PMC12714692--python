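"""Semantic similarity map of topics over an annotation ontology.

The most significant enriched terms per topic are compared with the Lin
similarity over the ontology DAG (information content from cumulative
annotation frequencies), embedded in the plane with classical (Torgerson)
multidimensional scaling of 1 - similarity, and each topic is placed at the
centroid of its terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .community import EnrichmentRow
from .corpus_ingest import read_gmt

__all__ = [
    "OntologyDag",
    "TopicCentroid",
    "load_ontology",
    "select_top_terms",
    "term_similarity_matrix",
    "classical_mds",
    "topic_centroids",
    "DEFAULT_TOP_TERMS",
]

log = logging.getLogger("genecontext.semantic_map")

DEFAULT_TOP_TERMS = 100


@dataclass
class OntologyDag:
    """Term DAG (child -> parents) with direct term-to-gene annotations."""

    terms: set[str]
    parents: dict[str, set[str]]
    annotations: dict[str, set[str]]

    def __post_init__(self) -> None:
        for child, pars in self.parents.items():
            self.terms.add(child)
            self.terms.update(pars)
        for t in self.annotations:
            if t not in self.terms:
                raise ValueError(f"annotated term {t!r} not in DAG")
        self._check_acyclic()
        self._children: dict[str, set[str]] = {}
        for child, pars in self.parents.items():
            for p in pars:
                self._children.setdefault(p, set()).add(child)

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str, stack: list[str]) -> None:
            state[t] = 1
            for p in self.parents.get(t, ()):
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"ontology contains a cycle through {p!r}")
                if s == 0:
                    visit(p, stack)
            state[t] = 2

        for t in self.terms:
            if state.get(t, 0) == 0:
                visit(t, [])

    def ancestors(self, term: str) -> set[str]:
        """Ancestors of a term, including the term itself."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        out = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for p in self.parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return out

    def descendants(self, term: str) -> set[str]:
        """Descendants of a term, including the term itself."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        out = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for c in self._children.get(t, ()):
                if c not in out:
                    out.add(c)
                    frontier.append(c)
        return out

    def annotation_closure(self, term: str) -> set[str]:
        """Genes annotated to the term or any of its descendants."""
        genes: set[str] = set()
        for t in self.descendants(term):
            genes |= self.annotations.get(t, set())
        return genes


@dataclass
class TopicCentroid:
    topic: int
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)


def load_ontology(edges_path: str | Path, annotations_gmt: str | Path) -> OntologyDag:
    """Read a two-column child/parent TSV plus a term-to-gene GMT."""
    parents: dict[str, set[str]] = {}
    terms: set[str] = set()
    with open(edges_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line == "child_id\tparent_id":
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{edges_path}: line {lineno}: expected 2 columns")
            child, parent = fields
            parents.setdefault(child, set()).add(parent)
            terms.update((child, parent))
    annotations = {s.set_id: set(s.genes) for s in read_gmt(annotations_gmt)}
    return OntologyDag(terms=terms, parents=parents, annotations=annotations)


def select_top_terms(
    enrichment: list[EnrichmentRow], n: int = DEFAULT_TOP_TERMS
) -> list[str]:
    """Top-n most significant terms pooled over a topic's modules.

    A term appearing in several modules keeps its best (smallest p_adj) row;
    ordering is by p_adj, then p, then term id.
    """
    best: dict[str, EnrichmentRow] = {}
    for row in enrichment:
        prev = best.get(row.term_id)
        if prev is None or (row.p_adj, row.p) < (prev.p_adj, prev.p):
            best[row.term_id] = row
    ranked = sorted(best.values(), key=lambda r: (r.p_adj, r.p, r.term_id))
    return [r.term_id for r in ranked[:n]]


def term_similarity_matrix(
    terms: list[str], dag: OntologyDag
) -> np.ndarray:
    """Lin semantic similarity between annotation terms.

    IC(t) = -ln(|annotation closure of t| / |all annotated genes|);
    sim(a, b) = 2 IC(MICA) / (IC(a) + IC(b)) where the MICA is the common
    ancestor (self included) of maximal IC. Terms annotating every gene
    (IC 0) are maximally unspecific: sim is 1 on the diagonal, else 0.
    """
    for t in terms:
        if t not in dag.terms:
            raise KeyError(f"unknown term {t!r}")
    total_genes = set()
    for genes in dag.annotations.values():
        total_genes |= genes
    if not total_genes:
        raise ValueError("ontology carries no gene annotations")

    @lru_cache(maxsize=None)
    def ic(term: str) -> float:
        closure = dag.annotation_closure(term)
        if not closure:
            raise ValueError(f"term {term!r} has no annotated gene in its closure")
        return -math.log(len(closure) / len(total_genes))

    anc = {t: dag.ancestors(t) for t in terms}
    m = len(terms)
    sim = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            a, b = terms[i], terms[j]
            common = anc[a] & anc[b]
            denom = ic(a) + ic(b)
            if denom == 0 or not common:
                s = 0.0
            else:
                mica_ic = max(ic(t) for t in common)
                s = 2 * mica_ic / denom
            sim[i, j] = sim[j, i] = min(max(s, 0.0), 1.0)
    return sim


def classical_mds(similarity: np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson MDS of d = 1 - similarity.

    Double-centres the squared distance matrix, eigendecomposes, clips
    negative eigenvalues to 0, and scales the top eigenvectors by the square
    root of their eigenvalues. Each axis is sign-fixed so its first nonzero
    coordinate is positive, making the output bit-stable.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(s, s.T, atol=1e-12):
        raise ValueError("similarity must be symmetric")
    if not np.allclose(np.diag(s), 1.0, atol=1e-12):
        raise ValueError("similarity must have unit diagonal")
    if (s < -1e-12).any() or (s > 1 + 1e-12).any():
        raise ValueError("similarity values must lie in [0, 1]")
    d = 1.0 - s
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order][:dims], 0.0, None)
    evecs = evecs[:, order][:, :dims]
    coords = evecs * np.sqrt(evals)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords


def topic_centroids(
    coords: dict[str, np.ndarray], topic_terms: dict[int, list[str]]
) -> list[TopicCentroid]:
    """Arithmetic-mean coordinates of each topic's term list.

    Topics with no terms are omitted with a warning.
    """
    out: list[TopicCentroid] = []
    for topic in sorted(topic_terms):
        terms = topic_terms[topic]
        if not terms:
            log.warning("topic %d has no enriched terms; centroid omitted", topic)
            continue
        pts = np.array([coords[t] for t in terms], dtype=float)
        out.append(TopicCentroid(topic=topic, xy=pts.mean(axis=0)))
    return out
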