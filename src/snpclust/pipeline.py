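"""End-to-end orchestration: filter -> encode -> reduce -> K scan ->
cluster at the selected K -> (optional) assignment evaluation -> 2-D views.

`run_pipeline` executes one (reduction, clustering) combination and writes a
run directory containing ``embedding.tsv``, ``clusters.tsv``,
``table1_validation.tsv``, ``table2_crosstab.tsv`` (when truth labels are
available), plots, and a ``manifest.json`` recording versions, seeds,
parameters, stage shapes and wall-clock — enough to reproduce the run.

`compare_methods` runs the {label, PCA, deep autoencoder} x {K-means,
hierarchical} grid and emits combined validation/cross-tab tables; a replay
helper recomputes %CA directly from printed confusion counts.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .autoencoder import ArchitectureSpec, Autoencoder
from .cluster import hierarchical, kmeans
from .encoding import label_encode, one_hot_encode, require_complete
from .evaluation import ConfusionTable, evaluate_assignment
from .io import SNPMatrix, filter_loci, read_genotype_table
from .pca import pca_fit, pca_transform
from .simulate import SimulationConfig, simulate_panel
from .validation import ValidationTable, scan_k, select_k, selection_report
from .viz import export_plot, pca_scatter, tsne_embed

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "compare_methods", "replay_crosstab"]

REDUCTIONS = ("deepae", "pca", "none")
CLUSTERINGS = ("kmeans", "hierarchical")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``input_path``/``input_format`` or ``simulation`` must be given.
    ``reduction="none"`` (the label-encoding baseline) clusters the
    label-encoded matrix directly and is only valid with
    ``encoding="label"``.
    """

    input_path: Optional[str] = None
    input_format: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    maf_min: float = 0.15
    max_missing: float = 0.0
    skip_filter: bool = False
    encoding: str = "one_hot"
    reduction: str = "deepae"
    encoder_widths: Sequence[int] = (2000, 700)
    bottleneck_dim: int = 40
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 32
    n_components: int = 40
    clustering: str = "hierarchical"
    linkage: str = "ward"
    n_restarts: int = 10
    k_range: Sequence[int] = tuple(range(2, 10))
    k_criterion: str = "sc_max"
    evaluate: bool = True
    make_plots: bool = True
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self):
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"reduction must be one of {REDUCTIONS}")
        if self.clustering not in CLUSTERINGS:
            raise ValueError(f"clustering must be one of {CLUSTERINGS}")
        if self.reduction == "none" and self.encoding != "label":
            raise ValueError("reduction 'none' is only valid with label encoding")
        if self.reduction in ("deepae", "pca") and self.encoding not in ("one_hot", "label"):
            raise ValueError("encoding must be 'one_hot' or 'label'")
        if self.reduction == "deepae" and self.encoding != "one_hot":
            raise ValueError("the autoencoder requires one_hot encoding")
        if self.input_path is None and self.simulation is None:
            raise ValueError("either an input file or a simulation config is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


def _load_panel(cfg: PipelineConfig) -> SNPMatrix:
    if cfg.simulation is not None:
        return simulate_panel(cfg.simulation)
    return read_genotype_table(cfg.input_path, cfg.input_format)


def _reduce(cfg: PipelineConfig, panel: SNPMatrix, record) -> np.ndarray:
    """Encode + reduce; returns the embedding used for clustering."""
    if cfg.reduction == "deepae":
        enc = one_hot_encode(panel)
        spec = ArchitectureSpec(
            input_dim=enc.values.shape[1],
            encoder_widths=cfg.encoder_widths,
            bottleneck_dim=cfg.bottleneck_dim,
            learning_rate=cfg.learning_rate,
        )
        model = Autoencoder.build(spec, seed=cfg.seed)
        model.train(enc, epochs=cfg.epochs, batch_size=cfg.batch_size, seed=cfg.seed)
        record["final_training_loss"] = model.loss_history[-1]
        return model.encode(enc)
    if cfg.reduction == "pca":
        enc = one_hot_encode(panel) if cfg.encoding == "one_hot" else label_encode(panel)
        n_comp = min(cfg.n_components, panel.n_samples - 1, enc.values.shape[1])
        model = pca_fit(enc, n_comp)
        record["n_components"] = n_comp
        return pca_transform(model, enc)
    # reduction "none": cluster the label-encoded matrix directly
    return require_complete(label_encode(panel))


def _cluster_at(cfg: PipelineConfig, emb: np.ndarray, K: int):
    if cfg.clustering == "kmeans":
        return kmeans(emb, K, n_restarts=cfg.n_restarts, seed=cfg.seed)
    return hierarchical(emb, K, linkage_method=cfg.linkage)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute one configuration end-to-end; see module docstring."""
    t0 = time.perf_counter()
    from . import __version__ as pkg_version

    manifest = {
        "package_version": pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "stages": {},
    }

    def stage(name, fn):
        t = time.perf_counter()
        out = fn()
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t, 3)}
        return out

    panel = stage("load", lambda: _load_panel(cfg))
    manifest["stages"]["load"]["shape"] = [panel.n_samples, panel.n_loci]
    logger.info("loaded panel: %d samples x %d loci", panel.n_samples, panel.n_loci)

    if not cfg.skip_filter:
        panel = stage("filter", lambda: filter_loci(panel, cfg.maf_min, cfg.max_missing))
        manifest["stages"]["filter"]["shape"] = [panel.n_samples, panel.n_loci]

    reduce_record: dict = {}
    emb = stage("reduce", lambda: _reduce(cfg, panel, reduce_record))
    manifest["stages"]["reduce"].update(reduce_record)
    manifest["stages"]["reduce"]["shape"] = list(emb.shape)

    table = stage("scan_k", lambda: scan_k(
        emb, cfg.clustering, cfg.k_range, seed=cfg.seed,
        reduction=cfg.reduction, linkage=cfg.linkage, n_restarts=cfg.n_restarts,
    ))
    sel = selection_report(table)
    K = select_k(table, cfg.k_criterion)
    manifest["selected_k"] = K
    manifest["k_selection"] = sel

    result = stage("cluster", lambda: _cluster_at(cfg, emb, K))

    confusion = None
    if cfg.evaluate and panel.true_labels is not None:
        confusion = stage("evaluate", lambda: evaluate_assignment(result.labels, panel.true_labels))
        manifest["percent_correct"] = confusion.percent_correct
        manifest["percent_correct_exact"] = confusion.percent_correct_exact

    out = {
        "panel": panel, "embedding": emb, "validation": table,
        "selected_k": K, "k_selection": sel, "clustering": result,
        "confusion": confusion, "manifest": manifest,
    }

    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(emb, index=panel.sample_ids).to_csv(
            outdir / "embedding.tsv", sep="\t", header=[f"dim{i+1}" for i in range(emb.shape[1])]
        )
        pd.DataFrame({
            "sample": panel.sample_ids, "method": cfg.clustering,
            "K": K, "cluster": result.labels,
        }).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        table.to_frame().to_csv(outdir / "table1_validation.tsv", sep="\t", index=False)
        if confusion is not None:
            _write_crosstab(outdir / "table2_crosstab.tsv", {_combo_name(cfg): confusion})
        if cfg.make_plots:
            _make_plots(cfg, panel, emb, outdir, manifest)
        manifest["stages"]["total"] = {"seconds": round(time.perf_counter() - t0, 3)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    if cfg.simulation is not None:
        d["simulation"] = asdict(cfg.simulation)
    return d


def _combo_name(cfg: PipelineConfig) -> str:
    red = {"deepae": "DeepAE", "pca": "PCA", "none": "LE"}[cfg.reduction]
    clu = {"kmeans": "KM", "hierarchical": "HC"}[cfg.clustering]
    return f"{red}-{clu}"


def _make_plots(cfg, panel, emb, outdir: Path, manifest: dict):
    labels = panel.true_labels if panel.true_labels is not None else ["all"] * panel.n_samples
    if cfg.reduction == "pca" and emb.shape[1] >= 2:
        export_plot(pca_scatter(emb, labels), outdir / "pca_scatter.png")
    if cfg.reduction == "deepae":
        n = emb.shape[0]
        perplexity = 30.0
        if perplexity < (n - 1) / 3:
            frame = tsne_embed(emb, labels, perplexity=perplexity, seed=cfg.seed)
            frame.to_frame(panel.sample_ids).to_csv(outdir / "tsne.tsv", sep="\t")
            export_plot(frame, outdir / "tsne_scatter.png")
        else:
            manifest["stages"].setdefault("viz", {})["tsne"] = (
                f"skipped: perplexity 30 infeasible for n={n}"
            )


def _write_crosstab(path, tables: dict):
    rows = []
    for name, t in tables.items():
        for i, cid in enumerate(t.cluster_ids):
            rows.append({
                "method": name, "cluster": f"Cluster {i + 1}",
                **{str(g): int(t.counts[i, j]) for j, g in enumerate(t.subpop_ids)},
                "pct_correct": t.percent_correct if i == 0 else "",
                "pct_correct_exact": round(t.percent_correct_exact, 3) if i == 0 else "",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compare_methods(
    base: PipelineConfig,
    reductions: Sequence[str] = ("none", "pca", "deepae"),
    clusterings: Sequence[str] = ("kmeans", "hierarchical"),
    outdir: Optional[str] = None,
) -> dict:
    """Run the reduction x clustering grid on one panel.

    Returns combined validation rows (one block per combination) and one
    confusion table per combination; writes combined TSVs when ``outdir`` is
    given. The panel is generated/loaded and filtered once so every
    combination sees identical data.
    """
    combos = [(r, c) for r in reductions for c in clusterings]
    if len(combos) < 2:
        raise ValueError("need at least 2 method combinations")
    panel = _load_panel(base)
    if not base.skip_filter:
        panel = filter_loci(panel, base.maf_min, base.max_missing)

    all_rows, confusions, results = ValidationTable(), {}, {}
    for red, clu in combos:
        cfg = PipelineConfig(**{
            **_config_dict(base),
            "reduction": red, "clustering": clu,
            "encoding": "label" if red == "none" else "one_hot",
            "simulation": base.simulation, "skip_filter": True,
            "outdir": None, "make_plots": False,
        })
        cfg.simulation = None
        cfg.input_path = None
        # reuse the already-prepared panel
        res = _run_on_panel(cfg, panel)
        name = _combo_name(cfg)
        results[name] = res
        for row in res["validation"].rows:
            all_rows.add(row["K"], name.split("-")[0], name.split("-")[1],
                         row["sc"], row["dbi"])
        if res["confusion"] is not None:
            confusions[name] = res["confusion"]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        all_rows.to_frame().to_csv(outdir / "table1_validation.tsv", sep="\t", index=False)
        if confusions:
            _write_crosstab(outdir / "table2_crosstab.tsv", confusions)
    return {"validation": all_rows, "confusions": confusions, "results": results}


def _run_on_panel(cfg: PipelineConfig, panel: SNPMatrix) -> dict:
    """run_pipeline body on an already-loaded, already-filtered panel."""
    reduce_record: dict = {}
    emb = _reduce(cfg, panel, reduce_record)
    table = scan_k(emb, cfg.clustering, cfg.k_range, seed=cfg.seed,
                   reduction=cfg.reduction, linkage=cfg.linkage,
                   n_restarts=cfg.n_restarts)
    K = select_k(table, cfg.k_criterion)
    result = _cluster_at(cfg, emb, K)
    confusion = None
    if cfg.evaluate and panel.true_labels is not None:
        confusion = evaluate_assignment(result.labels, panel.true_labels)
    return {"embedding": emb, "validation": table, "selected_k": K,
            "clustering": result, "confusion": confusion,
            "k_selection": selection_report(table)}


def replay_crosstab(counts, cluster_ids=None, subpop_ids=None) -> ConfusionTable:
    """Recompute matching and %CA from printed confusion counts (replay
    mode): verifies cross-tab arithmetic independently of any training."""
    counts = np.asarray(counts, dtype=np.int64)
    K, G = counts.shape
    t = ConfusionTable(
        counts,
        cluster_ids or [f"cluster{i + 1}" for i in range(K)],
        subpop_ids or [f"pop{j + 1}" for j in range(G)],
    )
    from .evaluation import match_clusters, percent_correct

    match_clusters(t)
    percent_correct(t)
    return t
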