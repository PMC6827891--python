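"""File formats, run configuration and the end-to-end pipeline.

Expression matrices are plain TSV/CSV with a gene-id first column and
timepoint headers like ``0h, 6h, 12h, 24h, 48h`` (or bare numbers, hours).
Networks export as tab-separated edge lists, GraphML (for Cytoscape-style
visualization) or SIF.  ``run_pipeline`` wires the whole analysis:
TCG selection -> interpolation -> prior -> per-condition inference ->
BIC pruning -> differential network -> node metrics -> importance ->
temporal-pattern scores, persisting every intermediate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import __version__
from .preprocess import (
    DenseTrajectories,
    TCGCriteria,
    TimeCourseMatrix,
    hermite_interpolate,
    select_tcgs,
)
from .grn import GRN, build_prior_network, infer_grn
from .network import DifferentialNetwork, differential_network
from .patterns import pattern_scores
from .prioritize import importance_scores, node_metrics

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "write_trajectories",
    "write_network",
    "read_network_edgelist",
    "fit_diagnostics",
    "RunConfig",
    "PipelineResult",
    "analyze_pair",
    "run_pipeline",
]

log = logging.getLogger("drynet")

_TIME_RE = re.compile(r"^\s*[tT]?\s*([0-9]+(?:\.[0-9]*)?)\s*(?:h|hr|hrs|hour|hours)?\s*$")


def _parse_time(label: str, col: int) -> float:
    m = _TIME_RE.match(str(label))
    if not m:
        raise ValueError(f"unparseable time header {label!r} (column {col})")
    return float(m.group(1))


def read_expression_table(path: str | Path) -> TimeCourseMatrix:
    """Read a genes x timepoints TSV/CSV into a validated matrix.

    Errors name the offending (row, column): duplicate gene ids are
    listed, negative or non-numeric cells located.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    times = [_parse_time(c, k + 1) for k, c in enumerate(df.columns)]
    values = np.empty(df.shape)
    for r in range(df.shape[0]):
        for c in range(df.shape[1]):
            try:
                v = float(df.iat[r, c])
            except (TypeError, ValueError):
                raise ValueError(
                    f"malformed cell at row {df.index[r]!r}, column {df.columns[c]!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"invalid expression {df.iat[r, c]!r} at row {df.index[r]!r}, "
                    f"column {df.columns[c]!r}"
                )
            values[r, c] = v
    return TimeCourseMatrix([str(g) for g in df.index], np.asarray(times), values)


def _time_header(times: np.ndarray) -> list[str]:
    return [f"{t:g}h" for t in times]


def write_expression_table(expr: TimeCourseMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids,
                      columns=_time_header(expr.times))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def write_trajectories(traj: DenseTrajectories, path: str | Path) -> None:
    """Wide TSV of the dense interpolated trajectories."""
    df = pd.DataFrame(traj.X, index=traj.gene_ids,
                      columns=[f"{t:.6g}" for t in traj.grid_times])
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def write_network(net: GRN | DifferentialNetwork, fmt: str, path: str | Path) -> None:
    """Export a network as 'edgelist', 'graphml' or 'sif'.

    Rows are ordered by (source, target); weights carry 6 significant
    digits, so repeated exports are byte-identical.
    """
    edges = net.edges()
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\tsign\n")
            for row in edges.itertuples(index=False):
                fh.write(f"{row.source}\t{row.target}\t{row.weight:.6g}\t{row.sign}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for row in edges.itertuples(index=False):
                rel = "activates" if row.sign > 0 else "represses"
                fh.write(f"{row.source}\t{rel}\t{row.target}\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from(net.gene_ids)
        for row in edges.itertuples(index=False):
            g.add_edge(row.source, row.target,
                       weight=float(f"{row.weight:.6g}"), sign=int(row.sign))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_edgelist(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def fit_diagnostics(grn: GRN) -> dict:
    """Per-gene JSON-ready fit report (penalty, CV error, residual variance)."""
    return {
        "theta": grn.theta,
        "n_edges": grn.n_edges,
        "genes": {
            g: {
                "lambda": _none_if_nan(grn.lam[i]),
                "cv_error": _none_if_nan(grn.cv_error[i]),
                "sigma": _none_if_nan(grn.sigma[i]),
            }
            for i, g in enumerate(grn.gene_ids)
        },
    }


def _none_if_nan(x: float) -> float | None:
    return None if np.isnan(x) else float(x)


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run.

    Defaults follow the motivating study: zeta=10, delta=5, n=100 grid
    points, 10 CV folds, theta picked by BIC (0.01 is the study's
    operating value), k=9 clusters, 1000 bootstrap iterations.
    """

    sensitive: str | None = None
    resistant: str | None = None
    test: str | None = None
    zeta: float = 10.0
    delta: float = 5.0
    pseudocount: float = 0.5
    n_grid: int = 100
    rho0: float = 0.6
    folds: int = 10
    theta: float | None = None
    k_clusters: int = 9
    alpha: float = 0.05
    dtw_normalize: bool = True
    distance_metric: str = "dtw"
    n_bootstrap: int = 1000
    n_markers: int = 5
    select_tcg: bool = True
    seed: int = 0
    outdir: str = "drynet_out"

    def __post_init__(self) -> None:
        TCGCriteria(self.zeta, self.delta, self.pseudocount)  # validates
        if self.n_grid < 2:
            raise ValueError("n_grid must be >= 2")
        if not 0 <= self.rho0 <= 1:
            raise ValueError("rho0 must lie in [0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.theta is not None and self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """All primary artifacts of one sensitive-vs-resistant analysis."""

    genes: list[str]
    sens_expr: TimeCourseMatrix
    res_expr: TimeCourseMatrix
    sens_traj: DenseTrajectories
    res_traj: DenseTrajectories
    sens_grn: GRN
    res_grn: GRN
    diff: DifferentialNetwork
    metrics: pd.DataFrame | None
    importance: pd.DataFrame | None
    patterns_sensitive: pd.DataFrame
    patterns_resistant: pd.DataFrame

    def top_genes(self, n: int = 5) -> list[str]:
        if self.importance is None:
            return []
        return list(self.importance.index[:n])


def analyze_pair(
    sens: TimeCourseMatrix,
    res: TimeCourseMatrix,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full differential-network analysis on two conditions.

    Temporally changing genes are selected on the union over the two
    conditions (both networks need one shared gene universe for the
    differential step), each arm is interpolated and inferred
    independently, and the importance table is computed over the
    differential-network genes.
    """
    cfg = config or RunConfig()
    common = [g for g in sens.gene_ids if g in set(res.gene_ids)]
    if not common:
        raise ValueError("the two conditions share no genes")
    sens = sens.subset(common)
    res = res.subset(common)

    if cfg.select_tcg:
        crit = TCGCriteria(cfg.zeta, cfg.delta, cfg.pseudocount)
        tcg = sorted(set(select_tcgs(sens, crit)) | set(select_tcgs(res, crit)),
                     key=common.index)
        if len(tcg) < 2:
            raise ValueError(
                f"only {len(tcg)} temporally changing genes; nothing to model"
            )
        sens, res = sens.subset(tcg), res.subset(tcg)
    genes = list(sens.gene_ids)

    sens_traj = hermite_interpolate(sens, cfg.n_grid)
    res_traj = hermite_interpolate(res, cfg.n_grid)
    sens_grn = infer_grn(sens_traj, rho0=cfg.rho0, folds=cfg.folds,
                         seed=cfg.seed, theta=cfg.theta)
    res_grn = infer_grn(res_traj, rho0=cfg.rho0, folds=cfg.folds,
                        seed=cfg.seed + 10_000, theta=cfg.theta)
    diff = differential_network(res_grn, sens_grn)

    metrics = importance = None
    if diff.n_edges > 0 and diff.n_genes >= 2:
        metrics = node_metrics(diff, res_grn, sens_grn, sens_traj, res_traj)
        importance = importance_scores(metrics)

    return PipelineResult(
        genes=genes,
        sens_expr=sens,
        res_expr=res,
        sens_traj=sens_traj,
        res_traj=res_traj,
        sens_grn=sens_grn,
        res_grn=res_grn,
        diff=diff,
        metrics=metrics,
        importance=importance,
        patterns_sensitive=pattern_scores(sens),
        patterns_resistant=pattern_scores(res),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-to-file pipeline run: read inputs, analyze, persist everything."""
    if not config.sensitive or not config.resistant:
        raise ValueError("config must name sensitive and resistant matrices")
    for label, p in (("sensitive", config.sensitive), ("resistant", config.resistant)):
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} matrix not found: {p}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("drynet %s | seed=%d", __version__, config.seed)
    sens = read_expression_table(config.sensitive)
    res = read_expression_table(config.resistant)
    result = analyze_pair(sens, res, config)

    write_expression_table(result.sens_expr, out / "tcg_sensitive.tsv")
    write_expression_table(result.res_expr, out / "tcg_resistant.tsv")
    write_trajectories(result.sens_traj, out / "trajectories_sensitive.tsv")
    write_trajectories(result.res_traj, out / "trajectories_resistant.tsv")
    for label, net in (("sensitive", result.sens_grn), ("resistant", result.res_grn),
                       ("differential", result.diff)):
        write_network(net, "edgelist", out / f"network_{label}.tsv")
        write_network(net, "graphml", out / f"network_{label}.graphml")
    for label, grn in (("sensitive", result.sens_grn), ("resistant", result.res_grn)):
        with open(out / f"fit_{label}.json", "w") as fh:
            json.dump(fit_diagnostics(grn), fh, indent=1, sort_keys=True)
    if result.importance is not None:
        result.importance.to_csv(out / "importance.tsv", sep="\t")
    result.patterns_sensitive.to_csv(out / "patterns_sensitive.tsv", sep="\t")
    result.patterns_resistant.to_csv(out / "patterns_resistant.tsv", sep="\t")
    config.to_yaml(out / "config.yaml")
    log.info("pipeline finished: %d genes, %d differential edges",
             len(result.genes), result.diff.n_edges)
    return result
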