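"""Configuration-driven pipeline runner and report writer.

One call executes the whole workflow — shortest-path module extraction,
superfamily composite reduction, initial model construction, ML fitting,
evidence-gated stepwise refinement and the two-group analysis — and writes
a report bundle: a machine-readable fit summary (JSON), the node/edge and
on/off test tables (TSV), the replayable refinement log (TSV), and the
final annotated model as 3-column TSV and DOT with nodes colored by
up/down expression and edges by up/down regulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import PathsemError
from .graph import (
    PathwayGraph,
    extract_module,
    graph_stats,
    read_pathway_table,
    to_dot,
    write_pathway_table,
)
from .io import (
    read_deg_list,
    read_evidence,
    read_expression,
    read_groups,
    read_superfamily,
)
from .model import build_composites, build_initial_model, classify_genes, collapse_graph
from .multigroup import GroupedData, two_group_analysis
from .refine import EvidenceSet, stepwise_refine
from .sem import FitConfig, fit_ml

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("pathsem")

_UP, _DOWN = "tomato", "skyblue"


@dataclass
class PipelineConfig:
    """File locations plus fitting options for one pipeline run."""

    expression: str
    groups: str
    pathway: str
    degs: str
    outdir: str
    superfamily: str | None = None
    evidence: str | None = None
    experimental_label: str | None = None
    dialect: str = "tsv3col"
    min_family_variance: float = 0.5
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self):
        for name in ("expression", "groups", "pathway", "degs"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("superfamily", "evidence"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration; a `fit:` block maps to FitConfig."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    base = Path(path).parent
    fit_block = raw.pop("fit", {}) or {}
    for key in ("expression", "groups", "pathway", "degs", "superfamily", "evidence", "outdir"):
        if key in raw and raw[key] is not None:
            raw[key] = str((base / raw[key]).resolve()) if not Path(raw[key]).is_absolute() else raw[key]
    return PipelineConfig(fit=FitConfig(**fit_block), **raw)


@dataclass
class PipelineResult:
    """In-memory handles plus the paths of everything written."""

    module: object
    collapsed: PathwayGraph
    composites: list
    initial_model: object
    initial_fit: object
    final_model: object
    final_fit: object
    refinement_log: object
    analysis: object
    files: dict


def _experimental_label(labels: pd.Series, requested: str | None) -> str:
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"group labels must have exactly two levels, got {levels}")
    if requested is not None:
        if requested not in levels:
            raise ValueError(f"experimental label {requested!r} not in {levels}")
        return requested
    for cand in ("experimental", "case", "disease", "mutant", "1"):
        if cand in levels:
            return cand
    if "control" in levels:
        return next(l for l in levels if l != "control")
    return levels[-1]  # deterministic fallback: lexicographically last


def _pooled_within_cov(gd: GroupedData, variables: list) -> tuple[np.ndarray, int]:
    """Pooled within-group ML covariance, so group mean shifts do not
    contaminate the covariance-structure fit."""
    mats = []
    n = 0
    for df in (gd.group1, gd.group2):
        X = df[variables].to_numpy(float)
        Xc = X - X.mean(axis=0)
        mats.append(Xc.T @ Xc)
        n += len(X)
    return (mats[0] + mats[1]) / n, n


def _fit_summary(fitres) -> dict:
    return {
        "chisq": round(float(fitres.chisq), 4),
        "df": int(fitres.df),
        "p_value": round(float(fitres.p_value), 6),
        "rmsea": None if np.isnan(fitres.rmsea) else round(float(fitres.rmsea), 4),
        "rmsea_pclose": None
        if np.isnan(fitres.rmsea_pclose)
        else round(float(fitres.rmsea_pclose), 6),
        "srmr": round(float(fitres.srmr), 4),
        "n": int(fitres.n),
        "t": int(fitres.model.n_free_beta + fitres.model.n_free_psi),
    }


def _stats_dict(g: PathwayGraph) -> dict:
    s = graph_stats(g)
    return {"n_nodes": s.n_nodes, "n_edges": s.n_edges, "mean_degree": round(s.mean_degree, 3)}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict = {}
    summary: dict = {"stages": {}}

    def _write_summary():
        files["summary"] = outdir / "summary.json"
        files["summary"].write_text(json.dumps(summary, indent=1))

    stage = "inputs"
    try:
        log.info("stage inputs: reading configuration files")
        # ---- inputs -------------------------------------------------
        pathway = read_pathway_table(config.pathway, dialect=config.dialect)
        expr = read_expression(config.expression)
        labels = read_groups(config.groups)
        degs = read_deg_list(config.degs)
        sfmap = read_superfamily(config.superfamily) if config.superfamily else {}
        evidence = (
            read_evidence(config.evidence, pathway=pathway)
            if config.evidence
            else EvidenceSet(pathway=pathway)
        )
        summary["stages"]["pathway"] = _stats_dict(pathway)

        # ---- module extraction --------------------------------------
        stage = "extract_module"
        log.info("stage extract_module")
        module = extract_module(pathway, degs)
        summary["stages"]["module"] = _stats_dict(module.subgraph)
        summary["stages"]["module"]["skipped_pairs"] = len(module.skipped_pairs)
        files["module"] = outdir / "module.tsv"
        write_pathway_table(module.subgraph, files["module"])
        _write_summary()

        # ---- composites + collapse ----------------------------------
        stage = "composites"
        log.info("stage composites")
        classify_genes(module.subgraph.nodes, degs)  # validates the partition
        composites = (
            build_composites(
                module, sfmap, expr, min_variance=config.min_family_variance
            )
            if sfmap
            else []
        )
        collapsed = collapse_graph(module, composites) if composites else module.subgraph
        summary["stages"]["collapsed"] = _stats_dict(collapsed)
        summary["stages"]["composites"] = [
            {
                "id": c.id,
                "members": list(c.members),
                "variance_explained": round(c.variance_explained, 4),
                "loadings": [round(float(x), 4) for x in c.loadings],
            }
            for c in composites
        ]
        files["composites"] = outdir / "composites.json"
        files["composites"].write_text(json.dumps(summary["stages"]["composites"], indent=1))

        # model-level data: genes plus composite scores
        data = expr.copy()
        for c in composites:
            data[c.id] = c.scores
        model_vars = sorted(collapsed.nodes)
        data = data[model_vars]

        # ---- initial model + fit ------------------------------------
        stage = "initial_model"
        log.info("stage initial_model")
        initial_model = build_initial_model(collapsed)
        exp_label = _experimental_label(labels, config.experimental_label)
        gd = GroupedData.from_frames(data, labels, exp_label)
        Sw, n_total = _pooled_within_cov(gd, list(initial_model.variables))
        initial_fit = fit_ml(initial_model, S=Sw, n=n_total, config=config.fit)
        summary["initial_fit"] = _fit_summary(initial_fit)
        _write_summary()

        # ---- refinement ---------------------------------------------
        stage = "refinement"
        log.info("stage refinement")
        final_model, rlog, final_fit = stepwise_refine(
            initial_model, S=Sw, n=n_total, evidence=evidence, config=config.fit
        )
        summary["final_fit"] = _fit_summary(final_fit)
        summary["refinement"] = {
            "n_added": len(rlog.accepted()),
            "stop_reason": rlog.stop_reason,
        }
        files["refinement_log"] = outdir / "refinement_log.tsv"
        rlog.to_frame().to_csv(files["refinement_log"], sep="\t", index=False)

        # ---- two-group analysis -------------------------------------
        stage = "two_group"
        log.info("stage two_group")
        analysis = two_group_analysis(final_model, gd, config.fit)
        summary["omnibus"] = {
            "mean": asdict(analysis.mean_test),
            "covariance": asdict(analysis.cov_test),
        }
        files["node_tests"] = outdir / "node_tests.tsv"
        files["edge_tests"] = outdir / "edge_tests.tsv"
        files["onoff_tests"] = outdir / "onoff_tests.tsv"
        analysis.node_table.to_csv(files["node_tests"], sep="\t", index=False)
        analysis.edge_table.to_csv(files["edge_tests"], sep="\t", index=False)
        analysis.onoff_table.to_csv(files["onoff_tests"], sep="\t", index=False)

        # ---- annotated final model ----------------------------------
        stage = "report"
        log.info("stage report")
        final_graph = PathwayGraph()
        for v in final_model.variables:
            final_graph.add_node(v)
        for tgt, src, prov in final_model.edges():
            kind = prov.split(":", 1)[1] if prov.startswith("kegg:") else prov
            final_graph.add_edge(src, tgt, kind)
        node_colors = {
            r.variable: (_DOWN if r.difference < 0 else _UP)
            for r in analysis.node_table.itertuples()
            if r.label
        }
        edge_colors = {
            (r.source, r.target): (_DOWN if r.difference < 0 else _UP)
            for r in analysis.edge_table.itertuples()
            if r.label
        }
        files["final_model"] = outdir / "final_model.tsv"
        write_pathway_table(final_graph, files["final_model"])
        files["final_dot"] = outdir / "final_model.dot"
        files["final_dot"].write_text(to_dot(final_graph, node_colors, edge_colors))
        _write_summary()
    except Exception as exc:
        _write_summary()  # preserve partial outputs for debugging
        raise PathsemError(f"stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        module=module,
        collapsed=collapsed,
        composites=composites,
        initial_model=initial_model,
        initial_fit=initial_fit,
        final_model=final_model,
        final_fit=final_fit,
        refinement_log=rlog,
        analysis=analysis,
        files={k: str(v) for k, v in files.items()},
    )
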