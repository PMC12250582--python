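"""End-to-end run: simulate/load -> cohorts -> networks -> variable
clustering -> cluster matching -> summary document.

Every run directory receives the serialized config (with its hash embedded
in the summary) so results are reproducible from the artifacts alone. All
randomness flows from ``RunConfig.seed`` (simulation) and
``RunConfig.community_seed`` (fast-unfolding), so identical configs produce
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from .cohorts import (COHORTS, assign_cohorts, baseline_table,
                      build_feature_matrix, filter_rare_features)
from .config import RunConfig
from .matching import cross_cohort_similarity, match_clusters
from .network import (build_network, compute_metrics, compute_oer_edges,
                      detect_communities, export_graph, top_clusters)
from .simulate import generate_cohort_events, read_event_tables, write_event_tables
from .varclust import cluster_variables, top_variable_clusters

logger = logging.getLogger(__name__)

DOMAINS = ("diagnosis", "procedure")


class PipelineError(RuntimeError):
    """A stage failed; partial artifacts are retained in the run directory."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def _write_matrix(matrix, outdir: Path, cohort: str, domain: str) -> None:
    """Sparse triplet CSV (patient_id, code, value=1) plus feature metadata."""
    trip = matrix.data.stack()
    trip = trip[trip > 0].rename("value").reset_index()
    trip.columns = ["patient_id", "code", "value"]
    trip.to_csv(outdir / f"{cohort}_{domain}_matrix.csv", index=False)
    meta = pd.DataFrame({"code": matrix.data.columns,
                         "count": matrix.counts.to_numpy(),
                         "prevalence": matrix.prevalence.round(6).to_numpy()})
    meta.to_csv(outdir / f"{cohort}_{domain}_features.csv", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full profiling pipeline; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("patientprofiler")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    try:
        stage = "input"
        if config.simulate:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            patients, events, truth = generate_cohort_events(sim)
            write_event_tables(patients, events, out, truth=truth)
            logger.info("simulated %d patients, %d events",
                        len(patients), len(events))
        else:
            if not (config.events_path and config.patients_path):
                raise PipelineError(stage, "events/patients paths required "
                                           "unless simulate is set")
            events, patients = read_event_tables(config.events_path,
                                                 config.patients_path)

        stage = "build-cohorts"
        assignments = assign_cohorts(
            events, patients, lookback_years=config.lookback_years,
            ha_window_days=config.ha_window_days)
        assignments.to_csv(out / "cohort_assignments.csv", index=False)
        counts = assignments["label"].value_counts()
        excl = assignments.loc[assignments["label"] == "EXCLUDED",
                               "exclusion_reason"].value_counts()
        summary["cohorts"] = {c: int(counts.get(c, 0)) for c in COHORTS}
        summary["excluded"] = {k: int(v) for k, v in excl.items()}
        summary["dropped_no_ckd"] = assignments.attrs.get("n_dropped_no_ckd", 0)
        logger.info("cohort sizes: %s; excluded: %s",
                    summary["cohorts"], summary["excluded"])

        stage = "features"
        feat_dir = out / "features"
        feat_dir.mkdir(exist_ok=True)
        matrices: dict[str, dict] = {}
        for domain in DOMAINS:
            raw = build_feature_matrix(events, assignments, domain,
                                       procedure_lookback_years=config.lookback_years)
            filtered, report = filter_rare_features(raw, config.min_prevalence)
            report.to_csv(feat_dir / f"{domain}_retention.csv")
            for cohort, m in filtered.items():
                _write_matrix(m, feat_dir, cohort, domain)
            matrices[domain] = filtered

        stage = "baseline"
        bt = baseline_table(assignments, patients,
                            comorbidity=matrices["diagnosis"])
        bt.to_tsv(out / "baseline_table.tsv")

        stage = "network"
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        summary["networks"] = {}
        net_results: dict[tuple[str, str], dict] = {}
        for domain in DOMAINS:
            summary["networks"][domain] = {}
            for cohort in COHORTS:
                m = matrices[domain][cohort]
                edges = compute_oer_edges(m)
                G = build_network(edges, mode=config.edge_mode,
                                  percentile=config.oer_percentile,
                                  node_counts=m.counts)
                if G.number_of_nodes() == 0:
                    raise PipelineError(stage, f"empty {domain} network for "
                                               f"{cohort}")
                metrics = compute_metrics(G)
                partition, modularity = detect_communities(
                    G, resolution=config.resolution,
                    seed=config.community_seed)
                top, dist = top_clusters(partition, k=config.n_clusters)
                export_graph(G, net_dir / f"{cohort}_{domain}.gexf",
                             metrics=metrics, partition=partition)
                export_graph(G, net_dir / f"{cohort}_{domain}_viz.gexf",
                             metrics=metrics, partition=partition, viz=True,
                             viz_percentile=config.viz_percentile)
                tsv = metrics.to_frame()
                tsv["community"] = pd.Series(partition)
                tsv.to_csv(net_dir / f"{cohort}_{domain}_metrics.tsv", sep="\t")
                summary["networks"][domain][cohort] = {
                    "nodes": G.number_of_nodes(),
                    "edges": G.number_of_edges(),
                    "oer_threshold": round(G.graph["oer_threshold"], 4),
                    "modularity": round(modularity, 4),
                    "resolution": config.resolution,
                    **{k: (round(v, 4) if isinstance(v, float) else v)
                       for k, v in metrics.summary().items()},
                    "cluster_distribution": dist.to_dict(orient="records"),
                }
                net_results[(domain, cohort)] = {
                    "top": top, "metrics": metrics, "partition": partition}

        stage = "varclust"
        vc_dir = out / "varclust"
        vc_dir.mkdir(exist_ok=True)
        summary["varclust"] = {}
        vc_results: dict[tuple[str, str], list[list[str]]] = {}
        for domain in DOMAINS:
            summary["varclust"][domain] = {}
            for cohort in COHORTS:
                tree = cluster_variables(matrices[domain][cohort].data)
                tree.to_json(vc_dir / f"{cohort}_{domain}_dendrogram.json")
                top = top_variable_clusters(tree, config.n_clusters)
                part = tree.cut(config.n_clusters)
                pd.Series(part, name="cluster").rename_axis("code").to_csv(
                    vc_dir / f"{cohort}_{domain}_clusters.tsv", sep="\t")
                summary["varclust"][domain][cohort] = {
                    "cluster_sizes": [len(c) for c in top]}
                vc_results[(domain, cohort)] = top

        stage = "match"
        match_dir = out / "match"
        match_dir.mkdir(exist_ok=True)
        summary["matches"] = {}
        for domain in DOMAINS:
            summary["matches"][domain] = {}
            matches = {}
            for cohort in COHORTS:
                match = match_clusters(net_results[(domain, cohort)]["top"],
                                       vc_results[(domain, cohort)])
                match.to_json(match_dir / f"{cohort}_{domain}_match.json")
                matches[cohort] = match
                summary["matches"][domain][cohort] = {
                    "similarity_pct": match.similarity_pct,
                    "mean_jaccard_pct": match.mean_jaccard_pct,
                }
            universes = {c: set(matrices[domain][c].data.columns)
                         for c in COHORTS}
            mets = {c: net_results[(domain, c)]["metrics"] for c in COHORTS}
            tables = cross_cohort_similarity(matches, universes, mets)
            tables.similar.to_csv(match_dir / f"{domain}_similar.tsv",
                                  sep="\t", index=False)
            tables.dissimilar.to_csv(match_dir / f"{domain}_dissimilar.tsv",
                                     sep="\t", index=False)
            tables.unique.to_csv(match_dir / f"{domain}_unique.tsv",
                                 sep="\t", index=False)

        stage = "summary"
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        render_summary(out)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def render_summary(run_dir: str | Path) -> Path:
    """Render summary.md from the artifacts in a run directory.

    Missing artifacts are listed as absent (with a warning) rather than
    failing the render.
    """
    run_dir = Path(run_dir)
    lines = ["# Patient profiling run summary", ""]
    missing: list[str] = []

    sj = run_dir / "summary.json"
    summary = json.loads(sj.read_text()) if sj.exists() else None
    if summary is None:
        missing.append("summary.json")
    else:
        lines += [f"Config hash: `{summary['config_hash']}`, "
                  f"seed {summary['seed']}", ""]
        lines += ["## Cohorts", ""]
        for c, n in summary.get("cohorts", {}).items():
            lines.append(f"- {c}: {n} patients")
        if summary.get("excluded"):
            lines.append(f"- excluded: {summary['excluded']}")
        lines.append("")

    bt = run_dir / "baseline_table.tsv"
    if bt.exists():
        lines += ["## Baseline characteristics", "",
                  f"See `{bt.name}`.", ""]
    else:
        missing.append("baseline_table.tsv")

    if summary is not None:
        lines += ["## Network metrics", ""]
        header = ("| domain | cohort | nodes | edges | diameter | avg degree "
                  "| avg path length | avg betweenness | avg closeness "
                  "| modularity | top-3 cluster % |")
        lines += [header, "|" + "---|" * 11]
        for domain, per in summary.get("networks", {}).items():
            for cohort, s in per.items():
                dist = "/".join(f"{d['pct_of_top']:.2f}"
                                for d in s["cluster_distribution"])
                lines.append(
                    f"| {domain} | {cohort} | {s['nodes']} | {s['edges']} "
                    f"| {s['diameter']} | {s['avg_degree']} "
                    f"| {s['avg_path_length']} | {s['avg_betweenness']} "
                    f"| {s['avg_closeness']} | {s['modularity']} | {dist} |")
        lines.append("")
        lines += ["## Cross-method cluster similarity", ""]
        for domain, per in summary.get("matches", {}).items():
            for cohort, s in per.items():
                lines.append(f"- {domain} / {cohort}: "
                             f"{s['similarity_pct']}% matched "
                             f"(mean Jaccard {s['mean_jaccard_pct']}%)")
        lines.append("")

    for domain in DOMAINS:
        for name in (f"{domain}_similar.tsv", f"{domain}_dissimilar.tsv",
                     f"{domain}_unique.tsv"):
            p = run_dir / "match" / name
            if not p.exists():
                missing.append(f"match/{name}")
    if missing:
        logger.warning("summary rendered with missing artifacts: %s", missing)
        lines += ["## Missing artifacts", ""]
        lines += [f"- {m}" for m in missing]
        lines.append("")

    path = run_dir / "summary.md"
    path.write_text("\n".join(lines))
    return path
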