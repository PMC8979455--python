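"""End-to-end orchestration: counts -> filters -> LSH -> Ccor graph -> GAE ->
clustering -> evaluation, with a manifest that makes a run reproducible.

One global seed fans out deterministically to per-stage seeds (seed + stage
index), so a single integer reproduces every artifact byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from . import gae, graph, lsh, metrics, preprocess, simulate

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "sample", "graph", "embed", "cluster", "evaluate")


@dataclass
class PipelineConfig:
    # input
    input: str | None = None
    format: str = "delimited"
    transpose: bool = False
    labels: str | None = None  # optional known labels TSV (cell_id<TAB>label)
    # preprocess
    min_genes: int = 1000
    min_count: int = 5
    min_cell_frac: float = 0.10
    norm: str = "size_factor"
    # lsh
    lsh_bits: int = 10
    lsh_neighbors: int = 5
    lsh_iters: int = 1
    target_genes: int | None = None
    # ccor graph
    ccor_mode: str = "empirical_tau"
    theta: float = -0.5
    graph_k: int = 5
    # gcn
    dims: tuple[int, int, int] = (256, 128, 128)
    epochs: int = 50
    lr: float = 0.001
    gcn_dropout: float = 0.1
    gcn_features: str = "expression"  # or "identity"
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    # clustering / evaluation
    k_clusters: int | None = None  # None -> silhouette sweep
    alpha: float = 0.05
    top_n: int = 50
    topo_k: int = 5
    epsilon: float = 1e-4
    # global
    seed: int = 0
    outdir: str = "copulagcn_run"

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGES.index(stage)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dims"] = list(self.dims)
        d["split"] = list(self.split)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "dims" in d:
            d["dims"] = tuple(d["dims"])
        if "split" in d:
            d["split"] = tuple(d["split"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_labels_tsv(path: str | Path, cell_ids: list[str]) -> metrics.LabelVector:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    mapping = dict(zip(df["cell_id"], df["label"]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"labels file missing {len(missing)} cell ids (e.g. {missing[:3]})")
    raw = [mapping[c] for c in cell_ids]
    uniq = {v: i for i, v in enumerate(sorted(set(raw)))}
    return metrics.LabelVector(labels=np.array([uniq[v] for v in raw]), cell_ids=cell_ids)


def write_labels_tsv(labels: metrics.LabelVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, lab in zip(labels.cell_ids, labels.labels):
            fh.write(f"{cid}\t{lab}\n")


def run_pipeline(
    cfg: PipelineConfig,
    counts: preprocess.CountMatrix | None = None,
    true_labels: metrics.LabelVector | None = None,
) -> Path:
    """Run every stage, writing artifacts and a manifest under ``cfg.outdir``.

    ``counts`` / ``true_labels`` may be passed in memory (e.g. straight from
    the simulator); otherwise they are read from ``cfg.input`` /
    ``cfg.labels``.  Returns the run directory.  A stage failure raises with
    the stage name; artifacts of completed stages remain on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "stage_seeds": {s: cfg.stage_seed(s) for s in STAGES},
        "stages": {},
    }
    if counts is None:
        if cfg.input is None:
            raise ValueError("no input: set cfg.input or pass counts")
        counts = preprocess.read_counts(cfg.input, cfg.format, transpose=cfg.transpose)
        manifest["input"] = {"path": cfg.input, "sha256": _sha256(Path(cfg.input))}
    else:
        manifest["input"] = {"path": "<in-memory>", "shape": list(counts.values.shape)}
    if true_labels is None and cfg.labels is not None:
        true_labels = read_labels_tsv(cfg.labels, counts.cell_ids)

    def _stage(name: str):
        t0 = time.time()
        logger.info("stage %s starting", name)
        return t0

    def _done(name: str, t0: float, outputs: list[str]) -> None:
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": outputs,
        }
        logger.info("stage %s done (%.1fs)", name, time.time() - t0)

    try:
        # ---- preprocess
        t0 = _stage("preprocess")
        norm = preprocess.preprocess(
            counts, cfg.min_genes, cfg.min_count, cfg.min_cell_frac, cfg.norm
        )
        if true_labels is not None:
            keep = [i for i, c in enumerate(true_labels.cell_ids) if c in set(norm.cell_ids)]
            true_labels = metrics.LabelVector(
                labels=true_labels.labels[keep],
                cell_ids=[true_labels.cell_ids[i] for i in keep],
            )
        norm_path = outdir / "normalized.tsv"
        pd.DataFrame(norm.values, index=norm.cell_ids, columns=norm.gene_ids).to_csv(
            norm_path, sep="\t", float_format="%.17g"
        )
        _done("preprocess", t0, [norm_path.name])

        # ---- LSH feature sampling
        t0 = _stage("sample")
        lsh_cfg = lsh.LSHConfig(
            n_bits=cfg.lsh_bits,
            n_neighbors=cfg.lsh_neighbors,
            iterations=cfg.lsh_iters,
            seed=cfg.stage_seed("sample"),
        )
        if cfg.target_genes is not None:
            subset = lsh.sample_to_target(norm, lsh_cfg, cfg.target_genes)
        else:
            subset = lsh.sample_features(norm, lsh_cfg)
        genes_path = outdir / "selected_genes.txt"
        genes_path.write_text("\n".join(norm.gene_ids[i] for i in subset.selected) + "\n")
        hist_path = outdir / "bucket_histogram.json"
        hist_path.write_text(
            json.dumps(
                {str(code): len(members) for code, members in sorted(subset.buckets.items())},
                indent=0,
            )
        )
        _done("sample", t0, [genes_path.name, hist_path.name])

        # ---- Ccor cell graph
        t0 = _stage("graph")
        ccor = graph.ccor_matrix(norm, subset, mode=cfg.ccor_mode, theta=cfg.theta)
        cell_graph = graph.build_knn_graph(ccor, k=cfg.graph_k)
        edges_path = outdir / "cell_graph_edges.tsv"
        graph.write_edge_list(cell_graph, norm.cell_ids, edges_path, ccor)
        adj_path = outdir / "cell_graph_adjacency.mtx"
        spio.mmwrite(adj_path, sparse.coo_matrix(cell_graph.adjacency()))
        _done("graph", t0, [edges_path.name, adj_path.name])

        # ---- GAE embedding
        t0 = _stage("embed")
        params = gae.GCNParams(
            layer_dims=tuple(cfg.dims),
            dropout=cfg.gcn_dropout,
            learning_rate=cfg.lr,
            epochs=cfg.epochs,
            seed=cfg.stage_seed("embed"),
        )
        split = gae.split_edges(cell_graph, tuple(cfg.split), seed=cfg.stage_seed("embed"))
        if cfg.gcn_features == "expression":
            X = norm.values[:, subset.selected]
        elif cfg.gcn_features == "identity":
            X = None
        else:
            raise ValueError(f"unknown gcn_features {cfg.gcn_features!r}")
        emb, linkpred, weights = gae.train_gae(
            cell_graph, params, split, cell_ids=norm.cell_ids, X=X
        )
        emb_path = outdir / "embedding.tsv"
        pd.DataFrame(
            emb.Z, index=emb.cell_ids,
            columns=[f"dim{i}" for i in range(emb.Z.shape[1])],
        ).to_csv(emb_path, sep="\t", float_format="%.8g")
        ckpt_path = outdir / "model_checkpoint.npz"
        np.savez(
            ckpt_path,
            **{f"W{i}": w for i, w in enumerate(weights)},
            layer_dims=np.array(params.layer_dims),
            seed=np.array(params.seed),
        )
        _done("embed", t0, [emb_path.name, ckpt_path.name])

        # ---- clustering
        t0 = _stage("cluster")
        if cfg.k_clusters is not None:
            k_used = cfg.k_clusters
        else:
            k_used, _ = metrics.silhouette_sweep(emb, seed=cfg.stage_seed("cluster"))
        labels = metrics.kmeans_cluster(emb, k_used, seed=cfg.stage_seed("cluster"))
        labels_path = outdir / "clusters.tsv"
        write_labels_tsv(labels, labels_path)
        _done("cluster", t0, [labels_path.name])

        # ---- evaluation
        t0 = _stage("evaluate")
        topo = metrics.topology_kl(
            norm.values, emb, k_ref=cfg.topo_k, epsilon=cfg.epsilon,
            seed=cfg.stage_seed("evaluate"),
        )
        report = {
            "n_cells": norm.n_cells,
            "n_genes_filtered": norm.n_genes,
            "n_genes_selected": len(subset),
            "graph_edges": cell_graph.n_edges,
            "k_clusters": int(k_used),
            "asw": metrics.silhouette(emb, labels),
            "topology_kl": topo.kl,
            "distance_tau": metrics.distance_preservation_tau(norm.values, emb),
            "linkpred": {
                "val_roc": linkpred.val_roc,
                "val_ap": linkpred.val_ap,
                "test_roc": linkpred.test_roc,
                "test_ap": linkpred.test_ap,
            },
        }
        outputs = ["report.json"]
        if true_labels is not None:
            report["ari"] = metrics.ari(labels, true_labels)
            markers = metrics.find_markers(norm, labels, alpha=cfg.alpha, top_n=cfg.top_n)
            markers_path = outdir / "markers.tsv"
            markers.to_csv(markers_path, sep="\t", index=False)
            outputs.append(markers_path.name)
        else:
            logger.info("no labels available: ARI and marker stages skipped")
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        _done("evaluate", t0, outputs)
    except Exception as exc:
        failed = next((s for s in STAGES if s not in manifest["stages"]), "?")
        manifest["failed_stage"] = failed
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage '{failed}': {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
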