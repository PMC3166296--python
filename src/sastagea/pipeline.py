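"""End-to-end orchestration: filter -> detect -> associate -> 4D -> report.

A :class:`PipelineConfig` names the input files, the change criterion and the
association thresholds; :func:`run_pipeline` executes the stages, writes the
change-set tables, per-phase edge lists, the 4D edge list, GraphML exports,
a plain-text summary and a machine-readable run manifest, and returns the
in-memory results.  Re-running on identical inputs and config is
bit-reproducible; every output names the threshold and universe size used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationNetwork,
    NetworkSummary,
    build_phase_network,
    edge_table,
    summarize_network,
    write_graphml,
)
from .change_detection import ChangeCriterion, PhaseChangeSet, build_change_sets
from .expression_io import (
    ExpressionDataset,
    collapse_duplicate_probes,
    filter_missing_probes,
    load_expression,
)
from .four_d import build_4d_network, node_category_table

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_summary"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable and echoed into the output dir."""

    matrix: str
    annotations: str
    outdir: str
    scale: str = "log2"
    detection: str | None = None
    gene_map: str | None = None  # two-column TSV probe_id -> gene_id
    max_missing_fraction: float = 0.80
    criterion: ChangeCriterion = field(default_factory=ChangeCriterion)
    association_threshold: float = 0.005
    fourd_threshold: float = 0.0001
    universe: str = "post_filter"  # or "pre_filter"
    tissue_codes: dict[str, str] = field(default_factory=dict)
    include_endpoint: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        crit = ChangeCriterion(**raw.pop("criterion", {}))
        return cls(criterion=crit, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunReport:
    config: PipelineConfig
    universe_size: int
    change_sets: list[PhaseChangeSet]
    phase_networks: list[AssociationNetwork]
    fourd_network: AssociationNetwork
    summaries: list[NetworkSummary]
    outdir: Path


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_change_sets(sets: list[PhaseChangeSet], outdir: Path) -> None:
    rows = [
        {
            "node_name": s.node_name,
            "tissue": s.code,
            "phase": s.phase.label,
            "direction": s.direction,
            "n_genes": len(s.genes),
        }
        for s in sets
    ]
    pd.DataFrame(rows).to_csv(outdir / "change_sets.tsv", sep="\t", index=False)
    with open(outdir / "change_set_members.tsv", "w") as fh:
        fh.write("node_name\tgene_id\n")
        for s in sets:
            for g in sorted(s.genes):
                fh.write(f"{s.node_name}\t{g}\n")


def run_pipeline(cfg: PipelineConfig, ds: ExpressionDataset | None = None) -> RunReport:
    """Execute the full analysis and write all artefacts under ``cfg.outdir``.

    ``ds`` may be passed directly (e.g. a freshly simulated dataset) to skip
    file loading; the config's input paths are then ignored.
    """
    outdir = Path(cfg.outdir)
    if ds is None:
        for label, path in (("matrix", cfg.matrix), ("annotations", cfg.annotations)):
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"pipeline input {label!r} not found: {path}")
        ds = load_expression(cfg.matrix, cfg.annotations, cfg.scale, cfg.detection)
    outdir.mkdir(parents=True, exist_ok=True)

    n_pre = ds.n_genes
    ds = filter_missing_probes(ds, cfg.max_missing_fraction)
    if cfg.gene_map:
        gm = pd.read_csv(cfg.gene_map, sep="\t", index_col=0).iloc[:, 0].to_dict()
        ds = collapse_duplicate_probes(ds, gm)
    N = n_pre if cfg.universe == "pre_filter" else ds.n_genes

    sets = build_change_sets(
        ds, cfg.criterion, tissue_codes=cfg.tissue_codes,
        include_endpoint=cfg.include_endpoint,
    )
    _write_change_sets(sets, outdir)

    by_window: dict[tuple[float, float], list[PhaseChangeSet]] = {}
    for s in sets:
        by_window.setdefault(s.phase.window, []).append(s)

    phase_nets: list[AssociationNetwork] = []
    summaries: list[NetworkSummary] = []
    for window in sorted(by_window):
        net = build_phase_network(by_window[window], N, cfg.association_threshold)
        phase_nets.append(net)
        summaries.append(summarize_network(net))
        stem = f"edges_{net.phase_scope}"
        edge_table(net).to_csv(outdir / f"{stem}.tsv", sep="\t", index=False)
        write_graphml(net, outdir / f"{stem}.graphml")

    net4d = build_4d_network(sets, N, cfg.fourd_threshold)
    summaries.append(summarize_network(net4d))
    edge_table(net4d).to_csv(outdir / "edges_4D.tsv", sep="\t", index=False)
    write_graphml(net4d, outdir / "edges_4D.graphml")
    node_category_table(net4d).to_csv(outdir / "node_categories_4D.tsv", sep="\t", index=False)

    report = RunReport(
        config=cfg, universe_size=N, change_sets=sets,
        phase_networks=phase_nets, fourd_network=net4d,
        summaries=summaries, outdir=outdir,
    )
    (outdir / "summary.txt").write_text(render_summary(report))
    manifest = {
        "sastagea_version": __version__,
        "config": cfg.to_dict(),
        "universe_N": N,
        "n_probes_input": n_pre,
        "n_genes_analyzed": ds.n_genes,
        "inputs_sha256": {
            p: _sha256(p)
            for p in (cfg.matrix, cfg.annotations, cfg.detection, cfg.gene_map)
            if p and Path(p).exists()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report


def render_summary(report: RunReport) -> str:
    """Plain-text per-phase table: sync/async edges, connected/stochastic nodes."""
    lines = [
        f"universe N = {report.universe_size}; "
        f"phase threshold p < {report.config.association_threshold}; "
        f"4D threshold p < {report.config.fourd_threshold}",
        "",
        f"{'phase':>10} {'nodes':>6} {'sync':>6} {'async':>6} {'connected':>10} {'stochastic':>11}",
    ]
    for s in report.summaries:
        lines.append(
            f"{s.phase_scope:>10} {s.n_nodes:>6} {s.synchronous_edges:>6} "
            f"{s.asynchronous_edges:>6} {s.connected_nodes:>10} {s.stochastic_nodes:>11}"
        )
    return "\n".join(lines) + "\n"
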