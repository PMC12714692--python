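"""LDA topic modelling of the gene-set document corpus.

Fits latent Dirichlet allocation on the pruned document-term matrix
(delegated to scikit-learn's batch variational Bayes, which is fully
deterministic for a fixed seed), selects the number of topics by maximising
the mean pairwise Jensen-Shannon divergence between topic-term distributions
(the Deveaud criterion), and assigns each document to its maximum-posterior
topic subject to a confidence threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numbers

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.utils._param_validation import Interval


class _LDA(LatentDirichletAllocation):
    """LDA with the Dirichlet priors allowed to exceed 1.

    The variational updates are valid for any positive prior, and the
    conventional document-topic default (50/k) is larger than 1 for small k;
    scikit-learn's declarative parameter check is simply wider here.
    """

    _parameter_constraints = {
        **LatentDirichletAllocation._parameter_constraints,
        "doc_topic_prior": [None, Interval(numbers.Real, 0, None, closed="neither")],
        "topic_word_prior": [None, Interval(numbers.Real, 0, None, closed="neither")],
    }

from .corpus_ingest import DocumentTermMatrix

__all__ = [
    "TopicModel",
    "TopicAssignment",
    "ModelSelectionReport",
    "fit_topic_model",
    "jensen_shannon_divergence",
    "deveaud_score",
    "select_k",
    "assign_documents",
    "DEFAULT_K_GRID",
    "DEFAULT_ASSIGN_THRESHOLD",
]

#: Default topic-count search grid.
DEFAULT_K_GRID = tuple(range(15, 31))
#: Default maximum-posterior confidence threshold for document assignment.
DEFAULT_ASSIGN_THRESHOLD = 0.2


@dataclass
class TopicModel:
    """Fitted LDA model: topic-term (beta) and document-topic (gamma) weights.

    beta is k x V with rows summing to 1; gamma is D x k with rows summing
    to 1. ``beta[t, j]`` is the probability of vocabulary token j under
    topic t; ``gamma[d, t]`` is document d's posterior weight on topic t.
    """

    k: int
    beta: np.ndarray
    gamma: np.ndarray
    seed: int
    hyperparams: dict[str, float]
    doc_ids: list[str] = field(default_factory=list)
    vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.shape[0] != self.k or self.gamma.shape[1] != self.k:
            raise ValueError("beta/gamma shapes inconsistent with k")
        for name, mat in (("beta", self.beta), ("gamma", self.gamma)):
            if (mat < 0).any():
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows do not sum to 1")


@dataclass
class TopicAssignment:
    doc_id: str
    topic: int | None
    confidence: float


@dataclass
class ModelSelectionReport:
    k_grid: list[int]
    scores: list[float]
    chosen_k: int
    seeds: list[int]


def fit_topic_model(
    dtm: DocumentTermMatrix,
    k: int,
    seed: int,
    alpha: float | None = None,
    eta: float = 0.1,
    max_iter: int = 100,
) -> TopicModel:
    """Fit a k-topic LDA model on a pruned document-term matrix.

    ``alpha`` (the symmetric Dirichlet prior on document-topic weights)
    defaults to 50/k; ``eta`` is the prior on topic-term weights. The same
    (dtm, k, seed, hyperparameters) always yields bit-identical beta and
    gamma.
    """
    n_docs = len(dtm.doc_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_docs:
        raise ValueError(f"k={k} exceeds the number of documents ({n_docs})")
    if alpha is None:
        alpha = 50.0 / k
    lda = _LDA(
        n_components=k,
        doc_topic_prior=alpha,
        topic_word_prior=eta,
        learning_method="batch",
        max_iter=max_iter,
        random_state=seed,
    )
    gamma = lda.fit_transform(dtm.counts)
    beta = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    gamma = gamma / gamma.sum(axis=1, keepdims=True)
    return TopicModel(
        k=k,
        beta=beta,
        gamma=gamma,
        seed=seed,
        hyperparams={"alpha": alpha, "eta": eta, "max_iter": max_iter},
        doc_ids=list(dtm.doc_ids),
        vocabulary=list(dtm.vocabulary),
    )


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD(p, q) = 1/2 KL(p||m) + 1/2 KL(q||m), m = (p+q)/2, natural log.

    Bounded by [0, ln 2]; 0*log(0) is treated as 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / m[mask])))

    return 0.5 * _kl(p) + 0.5 * _kl(q)


def deveaud_score(model: TopicModel) -> float:
    """Mean pairwise Jensen-Shannon divergence between topic-term rows.

    Higher means better-separated topics; the mean over ordered pairs equals
    the mean over unordered pairs by symmetry.
    """
    if model.k < 2:
        raise ValueError("deveaud_score requires k >= 2")
    pairs = list(itertools.combinations(range(model.k), 2))
    total = sum(
        jensen_shannon_divergence(model.beta[i], model.beta[j]) for i, j in pairs
    )
    return total / len(pairs)


def select_k(
    dtm: DocumentTermMatrix,
    k_grid: list[int] | tuple[int, ...] = DEFAULT_K_GRID,
    seeds: list[int] | tuple[int, ...] = (0,),
    **fit_kwargs,
) -> ModelSelectionReport:
    """Score each candidate k by the mean Deveaud score over seeds and pick
    the argmax (ties broken towards the smallest k)."""
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    k_grid = sorted(k_grid)
    scores = []
    for k in k_grid:
        per_seed = [
            deveaud_score(fit_topic_model(dtm, k, seed, **fit_kwargs))
            for seed in seeds
        ]
        scores.append(float(np.mean(per_seed)))
    chosen_k = k_grid[int(np.argmax(scores))]  # argmax returns first maximum
    return ModelSelectionReport(
        k_grid=list(k_grid), scores=scores, chosen_k=chosen_k, seeds=list(seeds)
    )


def assign_documents(
    model: TopicModel,
    threshold: float = DEFAULT_ASSIGN_THRESHOLD,
    multi_assign: bool = False,
) -> list[TopicAssignment]:
    """Assign each document to its maximum-posterior topic.

    A document is assigned iff its maximum gamma entry reaches ``threshold``;
    argmax ties break towards the smallest topic index. With
    ``multi_assign=True`` the document instead receives one assignment per
    topic whose gamma reaches the threshold (still at least one row per
    document: an unassigned row is emitted when none qualifies).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    out: list[TopicAssignment] = []
    for d, doc_id in enumerate(model.doc_ids):
        row = model.gamma[d]
        if multi_assign:
            hits = np.nonzero(row >= threshold)[0]
            if hits.size:
                out.extend(
                    TopicAssignment(doc_id, int(t), float(row[t])) for t in hits
                )
                continue
            out.append(TopicAssignment(doc_id, None, float(row.max())))
        else:
            conf = float(row.max())
            topic = int(np.argmax(row)) if conf >= threshold else None
            out.append(TopicAssignment(doc_id, topic, conf))
    return out
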