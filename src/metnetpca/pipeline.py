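"""End-to-end orchestration: from data matrices to metabolic modules.

``run_pipeline`` chains the whole workflow — load, optional QC
preprocessing, unit-variance scaling, NetPCA, block influences, per-variable
explained variance, marker selection, identifier mapping, pathway ORA,
network preparation (compartment collapse, side-compound removal, carbon
filtering), subnetwork extraction, lightest-path distances, complete-linkage
clustering and the module report — writing every table plus a parameter
echo to the output directory.  The pipeline is a pure function of (inputs,
config, seed): re-running reproduces all outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import complete_linkage, cut_tree, module_report, silhouette_profile
from .data_network import read_manifest, uv_scale
from .enrichment import map_identifiers, neg_log10, ora
from .metnet import (
    carbon_filter,
    collapse_compartments,
    extract_subnetwork,
    load_network,
    path_distance_matrix,
    remove_side_compounds,
)
from .netpca import block_influence, fit_netpca, select_markers, variable_explained_variance

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_figures"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")

    def record(self) -> dict:
        return {"stage": self.stage, "error": str(self)}


@dataclass
class PipelineConfig:
    manifest: str
    nodes_file: str
    edges_file: str
    out_dir: str
    annotation: str | None = None       # TSV var_id -> identifier fields
    side_list: str | None = None        # one node id per line; default list otherwise
    qc_table: str | None = None         # optional long-format injection table
    n_components: int = 2
    tol: float = 1e-9
    max_iter: int = 500
    seed: int = 0
    marker_threshold: float = 20.0
    ora_alpha: float = 0.05
    ora_components: tuple[int, ...] = (1,)
    collapse: bool = True
    widen_seeds: bool = False           # seeds = all mapped markers, not only those in significant pathways
    clustering_k: int = 5
    drop_zero_variance: bool = True

    def validate(self) -> None:
        for name in ("manifest", "nodes_file", "edges_file"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("config", f"{name} path does not exist: {p}")
        for name in ("annotation", "side_list", "qc_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{name} path does not exist: {p}")
        if not 0 <= self.marker_threshold <= 100:
            raise PipelineError("config", f"marker_threshold must be in [0, 100], got {self.marker_threshold}")
        if not 0 < self.ora_alpha < 1:
            raise PipelineError("config", f"ora_alpha must be in (0, 1), got {self.ora_alpha}")
        if self.n_components < 1 or self.clustering_k < 1:
            raise PipelineError("config", "n_components and clustering_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ora_components" in raw:
            raw["ora_components"] = tuple(raw["ora_components"])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, str(e)) from e

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the report bundle (all objects +
    paths of the written tables)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    network = _stage("load")(read_manifest)(config.manifest)
    bundle["network_raw"] = network

    if config.qc_table is not None:
        from .preprocess import FeatureRun, loess_normalize, qc_ratio_filter

        def _preprocess():
            run = FeatureRun.from_table(pd.read_csv(config.qc_table, sep="\t"))
            filtered, removed = qc_ratio_filter(run)
            normalized = loess_normalize(filtered)
            normalized.to_table().to_csv(out / "qc_normalized.tsv", sep="\t", index=False)
            (out / "qc_removed_features.txt").write_text("\n".join(removed) + "\n")
            return normalized, removed

        bundle["qc_run"], bundle["qc_removed"] = _stage("preprocess_qc")(_preprocess)()

    scaled, scaling = _stage("uv_scale")(uv_scale)(network, config.drop_zero_variance)
    bundle["network"] = scaled
    bundle["scaling"] = scaling

    model = _stage("fit_netpca")(fit_netpca)(
        scaled, config.n_components, tol=config.tol, max_iter=config.max_iter, seed=config.seed
    )
    bundle["model"] = model
    model.export(out / "netpca")

    influences = _stage("block_influence")(block_influence)(model, scaled)
    bundle["influence"] = influences
    influences.export(out / "block_influence.tsv")

    var_table = _stage("variable_explained_variance")(variable_explained_variance)(model, scaled)
    bundle["variable_variance"] = var_table
    var_table.export(out / "variable_variance.tsv")

    markers = {
        a: _stage("select_markers")(select_markers)(var_table, a, config.marker_threshold)
        for a in range(1, config.n_components + 1)
    }
    bundle["markers"] = markers
    pd.DataFrame(
        [{"component": a, "var_id": v} for a, vs in markers.items() for v in vs]
    ).to_csv(out / "markers.tsv", sep="\t", index=False)

    def _load_graph():
        g = load_network(config.nodes_file, config.edges_file)
        return collapse_compartments(g) if config.collapse else g

    graph = _stage("load_metabolic_network")(_load_graph)()
    bundle["graph"] = graph

    def _map():
        all_vars = [v for b in scaled.col_classes for v in scaled.var_ids(b)]
        if config.annotation is not None:
            ann = pd.read_csv(config.annotation, sep="\t", dtype=str).fillna("")
            queries = []
            for _, row in ann.iterrows():
                q = {"query_id": row["var_id"]}
                q.update({k: v for k, v in row.items() if k != "var_id" and v})
                queries.append(q)
        else:
            queries = [{"query_id": v, "name": v} for v in all_vars]
        return map_identifiers(queries, graph)

    mapping = _stage("map_identifiers")(_map)()
    bundle["mapping"] = mapping
    pd.DataFrame(mapping.mapped, columns=["query_id", "node_id"]).to_csv(
        out / "mapped_identifiers.tsv", sep="\t", index=False
    )

    universe = set(graph.g.nodes)
    node_of = dict(mapping.mapped)
    ora_results = {}
    for a in config.ora_components:
        selected = {node_of[v] for v in markers.get(a, []) if v in node_of} & universe
        res = _stage("ora")(ora)(selected, universe, graph.pathway_members())
        ora_results[a] = res
        res.export(out / f"ora_component{a}.tsv")
    bundle["ora"] = ora_results

    def _prepare():
        side = None
        if config.side_list is not None:
            side = [l.strip() for l in Path(config.side_list).read_text().splitlines() if l.strip()]
        return carbon_filter(remove_side_compounds(graph, side))

    filtered = _stage("network_filter")(_prepare)()
    bundle["graph_filtered"] = filtered

    first = config.ora_components[0]
    significant = set(
        ora_results[first].significant(config.ora_alpha)["pathway"]
    ) if first in ora_results else set()
    mapped_markers = {node_of[v] for v in markers.get(first, []) if v in node_of}
    if config.widen_seeds:
        seeds = mapped_markers
    else:
        seeds = {
            n for n in mapped_markers
            if graph.node_pathways(n) & significant
        }
    seeds &= set(filtered.g.nodes)
    bundle["seeds"] = seeds

    if len(seeds) >= 2:
        sub = _stage("extract_subnetwork")(extract_subnetwork)(filtered, seeds)
        bundle["subnetwork"] = sub
        sub.export_tables(out / "subnetwork")
        dm = _stage("path_distance_matrix")(path_distance_matrix)(filtered, sorted(seeds))
        bundle["distance_matrix"] = dm
        dm.matrix.to_csv(out / "path_distances.tsv", sep="\t")
        tree = _stage("complete_linkage")(complete_linkage)(dm)
        bundle["tree"] = tree
        tree.merge_table().to_csv(out / "linkage_merges.tsv", sep="\t", index=False)
        k = min(config.clustering_k, len(tree.leaves))
        assignment = _stage("cut_tree")(cut_tree)(tree, k)
        bundle["assignment"] = assignment
        assignment.to_csv(out / "module_assignment.tsv", sep="\t", index_label="node_id")
        bundle["module_report"] = _stage("module_report")(module_report)(
            assignment, filtered, dm, tree
        )
        if len(tree.leaves) > 3:
            bundle["silhouette"] = silhouette_profile(dm, tree)
            bundle["silhouette"].to_csv(out / "silhouette_profile.tsv", sep="\t", index_label="k")
    else:
        logger.info("fewer than 2 subnetwork seeds; clustering skipped")

    log = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "n_matrices": len(network.matrices),
        "n_profiles": sum(len(network.obs_ids(g)) for g in network.row_classes),
        "n_variables": sum(len(scaled.var_ids(b)) for b in scaled.col_classes),
        "component_variance_pct": [float(x) for x in model.component_variance],
        "mapping_rate_pct": mapping.mapping_rate,
        "n_markers": {str(a): len(v) for a, v in markers.items()},
        "n_seeds": len(seeds),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    bundle["run_log"] = log
    bundle["out_dir"] = out
    return bundle


def make_figures(bundle: dict, out_dir: str | Path | None = None) -> list[Path]:
    """Score plot, ORA bar chart (with the -log10 alpha threshold line) and
    module-ordered distance heatmap from a report bundle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir) if out_dir is not None else Path(bundle["out_dir"]) / "figures"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for key in ("model", "ora", "config"):
        if key not in bundle:
            raise KeyError(f"bundle is missing element {key!r}")
    model = bundle["model"]
    config = bundle["config"]

    fig, ax = plt.subplots(figsize=(7, 6))
    cmap = plt.get_cmap("tab10")
    for i, g in enumerate(model.scores):
        s = model.scores[g]
        y = s[:, 1] if model.n_components > 1 else 0 * s[:, 0]
        ax.scatter(s[:, 0], y, s=14, color=cmap(i % 10), label=g, alpha=0.75)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    cv = model.component_variance
    ax.set_xlabel(f"Component 1 ({cv[0]:.1f}%)")
    ax.set_ylabel(f"Component 2 ({cv[1]:.1f}%)" if model.n_components > 1 else "")
    ax.legend(fontsize=8, ncol=2)
    ax.set_title("NetPCA global scores")
    p = out / "scores.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    first = config.ora_components[0]
    table = bundle["ora"][first].table
    fig, ax = plt.subplots(figsize=(7, max(2, 0.4 * len(table))))
    if len(table):
        t = table.iloc[::-1]
        ax.barh(t["pathway"], t["neg_log10_q"], color="#4878a8")
    thr = neg_log10(config.ora_alpha)
    ax.axvline(thr, color="red", ls="--", label=f"-log10({config.ora_alpha}) = {thr}")
    ax.set_xlabel("-log10 q-value")
    ax.legend(fontsize=8)
    ax.set_title("Pathway over-representation")
    p = out / "ora.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    if "module_report" in bundle and "ordered_matrix" in bundle["module_report"]:
        mat = bundle["module_report"]["ordered_matrix"]
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(mat.to_numpy(), cmap="Greys_r")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(mat)), mat.index, fontsize=6)
        fig.colorbar(im, label="lightest-path cost (darker = shorter)")
        ax.set_title("Reaction-path distances (dendrogram order)")
        p = out / "distance_heatmap.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    else:
        logger.info("no clustering in bundle; distance heatmap skipped")

    return written
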