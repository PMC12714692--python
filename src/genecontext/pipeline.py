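"""End-to-end pipeline orchestration with a stable on-disk layout.

Stages communicate through fixed file names inside one output directory, so
the CLI subcommands compose: ``ingest`` writes the pruned document-term
matrix, ``fit-topics``/``assign`` add the model and assignments,
``build-networks`` the per-topic graphs, and so on. ``run_pipeline`` chains
everything and records a JSON manifest (parameters, derived per-stage
seeds, row counts, output files). A rerun with the same config and master
seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus_ingest import (
    DEFAULT_STOPWORDS,
    build_dtm,
    merge_documents,
    preprocess_text,
    prune_rare_tokens,
    read_documents,
    read_dtm,
    read_gmt,
    read_stopwords,
    write_dtm,
    write_gmt,
)
from .topic_model import (
    DEFAULT_ASSIGN_THRESHOLD,
    TopicModel,
    assign_documents,
    fit_topic_model,
    select_k,
)
from .graph_build import TopicNetwork, build_topic_network, read_edgelist, write_network
from .graph_metrics import (
    DEFAULT_SPECTRUM_LENGTH,
    global_metrics,
    laplacian_spectrum,
    spectral_distance_matrix,
)
from .community import hypergeometric_ora, louvain_partition, module_metrics
from .node_topology import PerturbationConfig, compute_node_metrics, perturb_and_score
from .semantic_map import (
    DEFAULT_TOP_TERMS,
    classical_mds,
    load_ontology,
    select_top_terms,
    term_similarity_matrix,
    topic_centroids,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]

log = logging.getLogger("genecontext.pipeline")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults are the reference parameters
    (assignment threshold 0.2, 1000 perturbation iterations at rate 0.001,
    20 spectral components, 100 top terms, rare-token cutoff 5)."""

    gene_sets: str = ""
    documents: str = ""
    stopwords: str | None = None
    annotations: str | None = None
    ontology_edges: str | None = None
    ontology_annotations: str | None = None
    outdir: str = "genecontext_out"
    k: int | None = None
    k_grid: list[int] = field(default_factory=list)
    threshold: float = DEFAULT_ASSIGN_THRESHOLD
    multi_assign: bool = False
    min_freq: int = 5
    alpha: float | None = None
    eta: float = 0.1
    lda_max_iter: int = 100
    n_iter: int = 1000
    rewire_rate: float = 0.001
    spectrum_length: int = DEFAULT_SPECTRUM_LENGTH
    r_cap: int = 10
    top_terms: int = DEFAULT_TOP_TERMS
    seed: int = 0
    threads: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from one master seed (< 2^31)."""
    return (master_seed * 1_000_003 + stage_index * 7919) % (2**31)


# ---------------------------------------------------------------------------
# Stages (fixed file-name contract inside outdir)
# ---------------------------------------------------------------------------

def stage_ingest(cfg: PipelineConfig, outdir: Path) -> dict:
    sets = read_gmt(cfg.gene_sets)
    docs = read_documents(cfg.documents)
    if cfg.stopwords:
        stopwords = read_stopwords(cfg.stopwords)
    else:
        stopwords = DEFAULT_STOPWORDS
    merged = merge_documents(docs)
    tokenized = [preprocess_text(r.text, stopwords, doc_id=r.doc_id) for r in merged]
    dtm = prune_rare_tokens(build_dtm(tokenized), min_freq=cfg.min_freq)
    write_dtm(dtm, outdir / "dtm")
    write_gmt(sets, outdir / "genesets.gmt")
    return {
        "n_gene_sets": len(sets),
        "n_documents": len(docs),
        "n_merged_documents": len(merged),
        "dtm_shape": list(dtm.shape),
    }


def stage_fit_topics(cfg: PipelineConfig, outdir: Path) -> dict:
    dtm = read_dtm(outdir / "dtm")
    seed = stage_seed(cfg.seed, 1)
    info: dict = {}
    fit_kwargs = dict(alpha=cfg.alpha, eta=cfg.eta, max_iter=cfg.lda_max_iter)
    if cfg.k is None:
        grid = cfg.k_grid or list(range(15, 31))
        report = select_k(dtm, grid, seeds=[seed], **fit_kwargs)
        (outdir / "model_selection.json").write_text(
            json.dumps(asdict(report), indent=1)
        )
        k = report.chosen_k
        info["model_selection"] = {"chosen_k": k, "k_grid": report.k_grid}
    else:
        k = cfg.k
    model = fit_topic_model(dtm, k, seed, **fit_kwargs)
    topics = [f"topic_{t}" for t in range(model.k)]
    pd.DataFrame(model.beta, index=topics, columns=model.vocabulary).to_csv(
        outdir / "beta.tsv", sep="\t", index_label="topic"
    )
    pd.DataFrame(model.gamma, index=model.doc_ids, columns=topics).to_csv(
        outdir / "gamma.tsv", sep="\t", index_label="doc_id"
    )
    info.update({"k": model.k, "seed": seed, "hyperparams": model.hyperparams})
    return info


def _load_model(outdir: Path) -> TopicModel:
    beta = pd.read_csv(outdir / "beta.tsv", sep="\t", index_col=0)
    gamma = pd.read_csv(outdir / "gamma.tsv", sep="\t", index_col=0)
    return TopicModel(
        k=beta.shape[0],
        beta=beta.to_numpy(),
        gamma=gamma.to_numpy(),
        seed=-1,
        hyperparams={},
        doc_ids=[str(d) for d in gamma.index],
        vocabulary=list(beta.columns),
    )


def stage_assign(cfg: PipelineConfig, outdir: Path) -> dict:
    model = _load_model(outdir)
    assignments = assign_documents(model, cfg.threshold, cfg.multi_assign)
    df = pd.DataFrame(
        {
            "doc_id": [a.doc_id for a in assignments],
            "topic": [a.topic if a.topic is not None else "" for a in assignments],
            "confidence": [a.confidence for a in assignments],
        }
    )
    df.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    n_assigned = sum(a.topic is not None for a in assignments)
    return {"n_assigned": n_assigned, "n_unassigned": len(assignments) - n_assigned}


def _read_assignments(outdir: Path) -> dict[str, int]:
    df = pd.read_csv(
        outdir / "assignments.tsv", sep="\t", dtype={"doc_id": str}
    )
    out: dict[str, int] = {}
    for row in df.itertuples():
        if pd.notna(row.topic) and row.topic != "":
            out[row.doc_id] = int(row.topic)
    return out


def stage_build_networks(cfg: PipelineConfig, outdir: Path) -> dict:
    sets = {s.set_id: s for s in read_gmt(outdir / "genesets.gmt")}
    set_topic = _read_assignments(outdir)  # merged doc ids == set ids
    by_topic: dict[int, list] = {}
    for set_id, topic in set_topic.items():
        if set_id in sets:
            by_topic.setdefault(topic, []).append(sets[set_id])
    netdir = outdir / "networks"
    netdir.mkdir(exist_ok=True)
    manifest: dict[str, dict] = {}
    skipped: list[int] = []
    for topic in sorted(by_topic):
        members = by_topic[topic]
        if len(members) < 2:
            log.info("topic %d has <2 assigned gene sets; skipped", topic)
            skipped.append(topic)
            continue
        net = build_topic_network(members, topic=topic)
        if net.n_edges == 0:
            log.info("topic %d network has no co-occurrence edges; skipped", topic)
            skipped.append(topic)
            continue
        write_network(net, netdir, f"topic_{topic}")
        manifest[str(topic)] = {
            "set_ids": net.provenance,
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
        }
    (outdir / "networks.json").write_text(
        json.dumps({"topics": manifest, "skipped": skipped}, indent=1)
    )
    return {"n_networks": len(manifest), "skipped_topics": skipped}


def _load_networks(outdir: Path) -> list[TopicNetwork]:
    payload = json.loads((outdir / "networks.json").read_text())
    nets = []
    for topic in sorted(payload["topics"], key=int):
        path = outdir / "networks" / f"topic_{topic}.edges.tsv"
        nets.append(read_edgelist(path, topic=int(topic)))
    return nets


def stage_network_metrics(cfg: PipelineConfig, outdir: Path) -> dict:
    nets = _load_networks(outdir)
    seed = stage_seed(cfg.seed, 4)
    records = [asdict(global_metrics(net, seed=seed)) for net in nets]
    pd.DataFrame(records).to_csv(outdir / "global_metrics.tsv", sep="\t", index=False)
    sigs = [laplacian_spectrum(net, m=cfg.spectrum_length) for net in nets]
    spec = pd.DataFrame(
        [s.eigenvalues for s in sigs],
        index=[f"topic_{s.topic}" for s in sigs],
        columns=[f"lambda_{i+1}" for i in range(cfg.spectrum_length)],
    )
    spec.to_csv(outdir / "spectra.tsv", sep="\t", index_label="topic")
    dist = spectral_distance_matrix(sigs)
    labels = [f"topic_{s.topic}" for s in sigs]
    pd.DataFrame(dist, index=labels, columns=labels).to_csv(
        outdir / "spectral_distances.tsv", sep="\t", index_label="topic"
    )
    return {"n_networks": len(nets)}


def stage_modules(cfg: PipelineConfig, outdir: Path) -> dict:
    nets = _load_networks(outdir)
    seed = stage_seed(cfg.seed, 5)
    assign_rows = []
    metric_rows = []
    for net in nets:
        part = louvain_partition(net, seed=seed)
        for gene, mod in sorted(part.assignment.items()):
            assign_rows.append({"gene": gene, "topic": net.topic, "module": mod})
        for rec in module_metrics(net, part):
            metric_rows.append({"topic": net.topic, **asdict(rec)})
    pd.DataFrame(assign_rows).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    pd.DataFrame(metric_rows).to_csv(
        outdir / "module_metrics.tsv", sep="\t", index=False
    )
    return {"n_module_rows": len(metric_rows), "louvain_seed": seed}


def stage_enrich(cfg: PipelineConfig, outdir: Path) -> dict:
    if not cfg.annotations:
        log.info("no annotation collection configured; enrichment skipped")
        return {"skipped": True}
    terms = read_gmt(cfg.annotations)
    ann_genes = set().union(*(t.gene_set for t in terms))
    modules = pd.read_csv(outdir / "modules.tsv", sep="\t")
    rows = []
    for topic, topic_df in modules.groupby("topic"):
        universe = set(topic_df["gene"]) & ann_genes
        if not universe:
            log.warning("topic %s: universe empty after intersection; skipped", topic)
            continue
        for mod, mod_df in topic_df.groupby("module"):
            for row in hypergeometric_ora(set(mod_df["gene"]), terms, universe):
                row.module = int(mod)
                rows.append({"topic": int(topic), **asdict(row)})
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return {"n_enrichment_rows": len(rows)}


def stage_node_metrics(cfg: PipelineConfig, outdir: Path) -> dict:
    nets = _load_networks(outdir)
    seed = stage_seed(cfg.seed, 7)
    nodedir = outdir / "node_metrics"
    nodedir.mkdir(exist_ok=True)
    long_rows = []
    for net in nets:
        pcfg = PerturbationConfig(
            n_iter=cfg.n_iter, rewire_rate=cfg.rewire_rate,
            seed=stage_seed(seed, net.topic),
        )
        table = compute_node_metrics(net, pcfg, r_cap=cfg.r_cap)
        table.to_csv(nodedir / f"topic_{net.topic}.tsv", sep="\t")
        long = table.reset_index().melt(
            id_vars="gene", var_name="metric", value_name="value"
        )
        long.insert(1, "topic", net.topic)
        long_rows.append(long)
    pd.concat(long_rows, ignore_index=True).to_csv(
        outdir / "node_metrics_long.tsv", sep="\t", index=False
    )
    return {"n_networks": len(nets), "n_iter": cfg.n_iter}


def stage_perturb(cfg: PipelineConfig, outdir: Path) -> dict:
    """Variance-only rerun of the perturbation (diagnostic subcommand)."""
    nets = _load_networks(outdir)
    seed = stage_seed(cfg.seed, 7)
    rows = []
    for net in nets:
        pcfg = PerturbationConfig(
            n_iter=cfg.n_iter, rewire_rate=cfg.rewire_rate,
            seed=stage_seed(seed, net.topic),
        )
        for gene, var in sorted(perturb_and_score(net, pcfg).items()):
            rows.append({"gene": gene, "topic": net.topic, "btw_variance": var})
    pd.DataFrame(rows).to_csv(outdir / "perturbation.tsv", sep="\t", index=False)
    return {"n_rows": len(rows)}


def stage_semantic_map(cfg: PipelineConfig, outdir: Path) -> dict:
    if not (cfg.ontology_edges and cfg.ontology_annotations):
        log.info("no ontology configured; semantic map skipped")
        return {"skipped": True}
    enrich_path = outdir / "enrichment.tsv"
    if not enrich_path.exists():
        log.info("no enrichment table present; semantic map skipped")
        return {"skipped": True}
    from .community import EnrichmentRow

    dag = load_ontology(cfg.ontology_edges, cfg.ontology_annotations)
    df = pd.read_csv(enrich_path, sep="\t")
    topic_terms: dict[int, list[str]] = {}
    for topic, topic_df in df.groupby("topic"):
        rows = [
            EnrichmentRow(
                module=int(r.module), term_id=str(r.term_id),
                term_name=str(r.term_name), k=int(r.k), K=int(r.K),
                n=int(r.n), N=int(r.N), p=float(r.p), p_adj=float(r.p_adj),
            )
            for r in topic_df.itertuples()
        ]
        topic_terms[int(topic)] = select_top_terms(rows, n=cfg.top_terms)
    all_terms = sorted({t for terms in topic_terms.values() for t in terms})
    unknown = [t for t in all_terms if t not in dag.terms]
    if unknown:
        log.warning(
            "%d enriched terms absent from the ontology are dropped "
            "from the semantic map (e.g. %s)", len(unknown), unknown[:3],
        )
        all_terms = [t for t in all_terms if t in dag.terms]
        topic_terms = {
            k: [t for t in v if t in dag.terms] for k, v in topic_terms.items()
        }
    if not all_terms:
        log.warning("no enriched terms available; semantic map skipped")
        return {"skipped": True}
    sim = term_similarity_matrix(all_terms, dag)
    coords = classical_mds(sim, dims=2)
    coord_map = {t: coords[i] for i, t in enumerate(all_terms)}
    pd.DataFrame(coords, index=all_terms, columns=["x", "y"]).to_csv(
        outdir / "term_coordinates.tsv", sep="\t", index_label="term_id"
    )
    cents = topic_centroids(coord_map, topic_terms)
    pd.DataFrame(
        {
            "topic": [c.topic for c in cents],
            "x": [c.xy[0] for c in cents],
            "y": [c.xy[1] for c in cents],
        }
    ).to_csv(outdir / "topic_centroids.tsv", sep="\t", index=False)
    return {"n_terms": len(all_terms), "n_centroids": len(cents)}


_STAGES = [
    ("ingest", stage_ingest),
    ("fit_topics", stage_fit_topics),
    ("assign", stage_assign),
    ("build_networks", stage_build_networks),
    ("network_metrics", stage_network_metrics),
    ("modules", stage_modules),
    ("enrich", stage_enrich),
    ("node_metrics", stage_node_metrics),
    ("semantic_map", stage_semantic_map),
]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order and write the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "genecontext",
        "version": __version__,
        "config": asdict(cfg),
        "stages": {},
    }
    for name, fn in _STAGES:
        log.info("stage %s: starting", name)
        try:
            manifest["stages"][name] = fn(cfg, outdir)
        except Exception as exc:
            raise PipelineError(f"stage {name}: {exc}") from exc
        log.info("stage %s: done", name)
    manifest["outputs"] = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
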