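"""End-to-end orchestration: table → graph → metrics → communities →
null-model comparison → robustness → spatial report.

Every artifact the analysis produces is a plain text file (CSV/TSV/JSON/
GraphML) in the output directory, and the whole run is deterministic given
the configured seed: null models and robustness draw from independent,
logged sub-seeds.  Any stage failure aborts the run with a stage-named
error and removes the partial outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .community import walktrap
from .io import (
    aggregate_experiments,
    laterality_summary,
    read_area_catalog,
    read_projection_table,
)
from .metrics import (
    assortativity_degree,
    build_graph,
    clustering_coefficients,
    compute_metrics,
    reciprocity,
)
from .nullmodels import matched_null_models
from .robustness import robustness_curve
from .spatial import (
    mds_embed_2d,
    pairwise_distances,
    projection_profile_correlations,
    strength_distance_correlation,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration mirrored by the ``painnet run`` YAML file."""

    projections: str
    areas: str
    out_dir: str
    edge_threshold: float = 0.01
    detection_threshold: float = 1e-4
    hemisphere_rule: str = "sum"
    walktrap_steps: int = 4
    null_model_reps: int = 50
    robustness_fractions: list[float] = field(
        default_factory=lambda: [round(0.05 * k, 2) for k in range(11)]
    )
    robustness_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_threshold <= 0 or self.detection_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.null_model_reps < 1 or self.robustness_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.walktrap_steps < 1:
            raise ValueError("walktrap steps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _null_model_summary(n: int, m: int, reps: int, seed: int) -> dict:
    """Table-style reciprocity / clustering / assortativity per null model."""
    acc: dict[str, dict[str, list[float]]] = {}
    for r in range(reps):
        models = matched_null_models(n, m, seed=seed + r)
        for name, g in models.items():
            row = acc.setdefault(
                name, {"reciprocity": [], "clustering": [], "assortativity": []}
            )
            row["reciprocity"].append(reciprocity(g))
            row["clustering"].append(clustering_coefficients(g)[1])
            try:
                row["assortativity"].append(assortativity_degree(g))
            except ValueError:
                pass
    out = {}
    for name, vals in acc.items():
        out[name] = {
            k: (float(np.mean(v)) if v else math.nan) for k, v in vals.items()
        }
        out[name]["reps"] = reps
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a small dict of headline numbers."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def path(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    stage = "setup"
    log_lines = [f"painnet {__version__}", f"seed {cfg.seed}"]
    try:
        stage = "io"
        catalog = read_area_catalog(cfg.areas)
        table = read_projection_table(cfg.projections, catalog)
        agg = aggregate_experiments(table)
        agg.records.to_csv(path("aggregated.csv"), index=False, float_format="%.10g")
        lat = laterality_summary(agg, cfg.detection_threshold)
        log_lines.append(f"areas {len(catalog)} records {len(table)}")

        stage = "graph"
        g = build_graph(agg, cfg.edge_threshold, cfg.hemisphere_rule)
        g.to_graphml(path("graph.graphml"))
        g.to_edgelist_tsv(path("graph_edges.tsv"))

        stage = "metrics"
        report = compute_metrics(g)
        report.per_node_tsv(path("per_node.tsv"))
        top3 = report.top3()
        with open(path("centrality.tsv"), "w") as fh:
            fh.write("centrality\ttop1\ttop2\ttop3\n")
            for name, ranked in top3.items():
                fh.write(name + "\t" + "\t".join(ranked) + "\n")

        stage = "communities"
        part = walktrap(g, steps=cfg.walktrap_steps)
        part.to_json(path("communities.json"))
        with open(path("communities.tsv"), "w") as fh:
            fh.write("community\tsize\tmembers\n")
            for i, members in enumerate(part.communities()):
                fh.write(f"{i}\t{len(members)}\t{','.join(members)}\n")

        stage = "null_models"
        null_seed = cfg.seed + 10_000
        log_lines.append(f"null-model seed stream {null_seed}")
        nulls = _null_model_summary(
            g.n_nodes, g.n_edges, cfg.null_model_reps, null_seed
        )
        metrics_doc = {
            "pain_network": report.to_dict(),
            "laterality": {
                "ipsi_fraction": lat.ipsi_fraction,
                "contra_fraction": lat.contra_fraction,
                "ipsi_contra_volume_ratio": lat.ipsi_contra_volume_ratio,
                "detection_threshold": cfg.detection_threshold,
            },
            "null_models": nulls,
            "n_communities": part.n_communities,
            "config": asdict(cfg),
        }
        with open(path("metrics.json"), "w") as fh:
            json.dump(metrics_doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

        stage = "robustness"
        rob_seed = cfg.seed + 20_000
        log_lines.append(f"robustness seed stream {rob_seed}")
        frames = []
        for j, mode in enumerate(("random", "attack")):
            curve = robustness_curve(
                g,
                cfg.robustness_fractions,
                mode,
                n_reps=cfg.robustness_reps,
                seed=rob_seed + j,
            )
            frames.append(curve.to_frame())
        frames[0].to_csv(path("robustness.tsv"), sep="\t", index=False, mode="w")
        frames[1].to_csv(
            path("robustness.tsv"), sep="\t", index=False, mode="a", header=False
        )

        stage = "spatial"
        dm = pairwise_distances(catalog)
        dm.normalize().to_tsv(path("distance_matrix.tsv"))
        layout = mds_embed_2d(dm)
        with open(path("layout.tsv"), "w") as fh:
            fh.write("acronym\tx\ty\tgroup\n")
            for i, a in enumerate(dm.areas):
                fh.write(
                    f"{a}\t{layout[i, 0]:.10g}\t{layout[i, 1]:.10g}\t"
                    f"{catalog.group_of(a)}\n"
                )
        sd = strength_distance_correlation(agg, dm)
        sd.to_csv(path("strength_distance.tsv"), sep="\t", float_format="%.10g")
        corr = projection_profile_correlations(agg)
        for name, mat in (("source_corr", corr.source_corr), ("target_corr", corr.target_corr)):
            np.savetxt(
                path(f"{name}.tsv"),
                mat,
                delimiter="\t",
                fmt="%.10g",
                header="\t".join(corr.areas),
                comments="",
            )

        with open(path("run.log"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return {
        "n_nodes": g.n_nodes,
        "n_edges": g.n_edges,
        "density": report.density,
        "diameter": report.diameter,
        "reciprocity": report.reciprocity,
        "mean_clustering": report.mean_clustering,
        "assortativity": report.assortativity,
        "n_communities": part.n_communities,
        "ipsi_fraction": lat.ipsi_fraction,
        "ipsi_contra_volume_ratio": lat.ipsi_contra_volume_ratio,
    }
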