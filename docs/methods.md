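# Methods

## Overview

`genecontext` quantifies *contextual* gene importance: the same gene can be
peripheral in one biological context and a bottleneck in another. Contexts
are discovered from the literature attached to curated gene sets — each
gene set carries a document (its concatenated abstracts, or the curator's
description when no abstract exists) — and gene relationships inside each
context are derived purely from gene-set membership, not from any molecular
interaction source. The pipeline has three layers:

1. **Topic layer.** Documents are preprocessed and modelled with latent
   Dirichlet allocation (LDA); each document (hence each gene set) is
   assigned to its maximum-posterior topic when that posterior reaches a
   confidence threshold.
2. **Network layer.** Within one topic, every unordered pair of gene sets
   contributes a clique over its intersection; the union of these cliques,
   with duplicate edges collapsed, is the topic's simple undirected
   co-occurrence network. Genes that never appear in any pairwise
   intersection have no edge and are not nodes.
3. **Node/module layer.** Per network: betweenness and eigenvector
   centrality, local fractal dimension, betweenness variance under random
   edge rewiring (all min-max rescaled per network), Louvain modules with
   hypergeometric enrichment, Laplacian spectral comparison between
   networks, and a classical-MDS semantic map of enriched terms.

## Text preprocessing

Applied in order: Unicode compatibility (NFKD) normalisation; removal of
characters outside ASCII letters/digits/punctuation/whitespace (Greek and
other non-Latin residues are decomposed first, so accented Latin letters
keep their base form); lowercasing; replacement of punctuation and digits
by spaces; whitespace tokenisation; stopword removal; Porter stemming;
removal of tokens shorter than two characters. The Porter stemmer is
implemented in-package (the classic 1980 algorithm) and validated against
its canonical example pairs. Tokens with corpus-wide frequency below
`min_freq = 5` are removed iteratively together with the documents they
empty, to a fixpoint in which both invariants (no rare token, no empty
document) hold simultaneously.

Two conventions were genuinely open and are fixed as follows: rare-token
frequency is **corpus** frequency (summed over documents), the text-mining
convention, not document frequency; and when a set has both abstracts and a
description, abstracts win and the description is dropped. Note that Porter
stemming is not strictly idempotent (a handful of stems shorten again when
re-stemmed, e.g. *divis* → *divi*), so pipelines should tokenise raw text
exactly once.

## Topic model

LDA is fitted by batch variational Bayes (scikit-learn backend), which is
bit-deterministic for a fixed seed — the determinism contract every
downstream stage relies on. Symmetric priors default to `alpha = 50/k` on
document-topic weights and `eta = 0.1` on topic-term weights. The number of
topics is chosen by maximising the mean pairwise Jensen–Shannon divergence
between topic-term rows (natural log, so scores live in [0, ln 2]); the
default search grid is 15–30 and ties go to the smallest k. The original
weighting of this criterion is simplified to the plain mean over pairs,
which is monotone-equivalent for the argmax.

A document is assigned to `argmax` of its posterior topic weights iff that
maximum reaches the threshold (default **0.2**); argmax ties break to the
smallest topic index. A `multi_assign` flag instead assigns the document to
every topic whose weight reaches the threshold.

## Network construction

Edge semantics: an edge (g, h) requires g *and* h to lie together in the
intersection of at least one pair of same-topic sets. The weaker reading
(g ∈ S, h ∈ T, S ∩ T ≠ ∅) is rejected — it would connect genes that never
co-occur. Multiplicity across set pairs is discarded; provenance (the
contributing set ids) is kept as a sidecar. Topics with fewer than two
assigned sets, or whose sets have no pairwise intersection of size ≥ 2,
produce no network and are recorded as skipped.

## Network, module and node analytics

- **Global metrics**: clustering is global transitivity by default
  (mean-local available behind a switch); diameter and average path length
  are computed on the largest connected component, since infinite distances
  are unusable on disconnected graphs; closeness is harmonic centrality
  normalised by n − 1; modularity is that of the seeded Louvain partition.
- **Spectral comparison**: each network is summarised by the m = 20
  *largest* eigenvalues of L = D − A, descending, zero-padded when
  n < m; networks are compared by the Euclidean distance between these
  truncated spectra. Keeping the largest components preserves the dominant
  spectral content; a smallest-first ordering is available for sensitivity
  analyses. Log-transformed distances are a display option only.
- **Louvain modules**: resolution 1, explicit seed; module ids are relabelled
  contiguously from 0 ordered by decreasing size (ties by smallest member),
  so the labelling is deterministic.
- **Enrichment**: upper-tail hypergeometric test of each module against an
  annotation GMT, universe = network genes ∩ annotated genes (explicit and
  configurable; an external service's internal background cannot be
  replicated). Benjamini–Hochberg correction is applied per module — the
  per-query convention — and the significance filter (default
  p_adj < 0.05) is applied at report time; raw tables keep all rows.
- **Betweenness**: unnormalised Brandes, each unordered pair counted once.
  Any affine normalisation would be nullified by the later rescaling.
- **Eigenvector centrality**: power iteration on A + I (the shift makes the
  iteration converge on bipartite graphs), tolerance 1e-10, maximum entry
  scaled to 1.
- **Local fractal dimension (LFD)**: for node v let M(r) be the number of
  nodes within shortest-path distance r (v excluded), for
  r = 1 … min(eccentricity(v), 10). LFD is the least-squares slope of
  ln M(r) against ln r; fewer than two usable radii give 0, which keeps
  every node scored. Ball counts are cumulative.
- **Perturbation robustness**: each of `n_iter` (default 1000) iterations
  restarts from the observed graph and rewires
  max(1, round(0.001·|E|)) edges; a rewiring removes a uniformly chosen
  edge and inserts a uniformly chosen currently non-adjacent pair (the
  removed pair itself is eligible, so a complete graph is always restored
  and shows zero variance). Rewiring is *not* degree-preserving by design:
  the point is to let every node gain and lose edges. Iterations are
  independent, not cumulative — variance measures response to minimal
  structural change from the observed graph. The per-gene population
  variance (ddof 0) of raw betweenness across iterations is the robustness
  signal; like every node metric it is then min-max rescaled.
- **Rescaling**: (x − min)/(max − min) per network; constant columns map to
  0.5. A strictly-open variant is available behind a flag.
- **Semantic map**: per topic, the 100 most significant enriched terms
  (pooled over modules, duplicates keep their best row, ties broken by raw
  p then term id) are compared with Lin similarity,
  sim(a,b) = 2·IC(MICA)/(IC(a)+IC(b)), where IC(t) = −ln(fraction of all
  annotated genes in t's annotation closure) and the MICA is the common
  ancestor (self included) of maximal IC. Coordinates come from classical
  (Torgerson) MDS of d = 1 − sim: double-centre d², eigendecompose, clip
  negative eigenvalues to zero, scale eigenvectors by √eigenvalue, and fix
  each axis's sign so its first nonzero coordinate is positive (bit-stable
  output). Topic centroids are arithmetic means of their terms'
  coordinates.

## Synthetic study conditions

The generator plants known structure so every stage is testable offline:
per topic a disjoint vocabulary (default 50 consonant-only tokens, which
are invariant under stemming and stopword filtering, so recovery checks are
exact), 60 documents of 50 tokens, 8 gene sets of 20 genes drawn from a
per-topic pool sized for an expected pairwise overlap of half a set, and
one hub gene inserted into every set of its topic (hence into every
pairwise intersection — it must dominate degree). A configurable background
vocabulary and vocabulary-bleed rate emulate partially overlapping topics;
both default to off. All generators consume a single explicit NumPy
generator; no global random state.

What the generator does *not* emulate: real abstract length and token
frequency distributions, correlated (non-disjoint) topic vocabularies at
default settings, gene-set size heterogeneity, and annotation DAGs deeper
than three levels. Passing tests therefore demonstrate correctness of the
machinery and recoverability under clean planted structure, not performance
on noisy literature corpora.

## Determinism and problem sizes

One master seed derives per-stage seeds; stochastic stages (LDA, Louvain,
perturbation) are otherwise deterministic, so a rerun with the same config
is bit-identical, which the test suite checks by hashing every output file.
Tests and the acceptance script run the perturbation stage at 15–100
iterations and oracle comparisons at a few hundred random instances —
sizes chosen so the full suite completes in well under a minute per module
while still exercising every code path; the shipped defaults (1000
iterations, grid 15–30) are unchanged. The `--threads` flag is accepted and
recorded in the manifest but the current implementation is single-threaded.

## Known limitations

- LDA topic *identity* is stable only up to label permutation across seeds;
  all recovery metrics use optimal matching.
- The enrichment universe is explicit; results are universe-dependent by
  construction and will not numerically match services with proprietary
  backgrounds.
- The Lin-similarity map depends on the annotation corpus used for IC; the
  reproducible object is the map's topology, not exact coordinates.
- Spectral distances on zero-padded truncated spectra are a pseudo-metric:
  distinct graphs can be at distance 0.
- Laplacian spectra are computed densely; networks beyond ~10⁴ nodes would
  need a sparse truncated eigensolver.
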