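"""Pipeline orchestration, run manifests, and figure rendering.

The pipeline ties the modules into the end-to-end workflow: read the RA,
simulate the integrated process model, attribute criticality by
leave-one-out, classify against the per-CQA threshold, block/escalate by
detectability when available, and compare against the classical RPN
ranking.  Every run emits a JSON manifest sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import blocking, criticality, rpn_compare
from .ipm_engine import SimulationConfig, run_ipm
from .ra_model import (Direction, RiskAssessment, ScoreScale,
                       read_risk_assessment, write_criticality_table)

__all__ = ["RunManifest", "load_config", "run_pipeline", "render_reports"]

log = logging.getLogger("ipmrisk")


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted with every pipeline run."""

    tool_version: str
    command: str
    seed: int
    n_cycles: int
    input_digest: str | None
    config: dict
    parameters: dict
    timestamp: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True, default=str) + "\n")


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    """Read a YAML config into plain keyword arguments."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def config_from_mapping(cfg: dict) -> tuple[SimulationConfig, dict]:
    """Split a config mapping into a SimulationConfig and RA-level options."""
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    sim_kwargs = {k: v for k, v in cfg.items() if k in sim_fields}
    ra_keys = ("cqa_name", "direction", "starting_cqa_pct", "s_max", "o_max",
               "d_max", "threshold")
    ra_opts = {k: v for k, v in cfg.items() if k in ra_keys}
    unknown = set(cfg) - sim_fields - set(ra_keys)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return SimulationConfig(**sim_kwargs), ra_opts


def run_pipeline(
    ra_path: str | Path,
    out_dir: str | Path,
    config_path: str | Path | None = None,
    *,
    threshold: float = 10.0,
    figures: bool = False,
    **overrides,
) -> dict:
    """Full workflow on an RA CSV; writes all outputs under ``out_dir``.

    Returns a dict with the criticality table, block warnings, the IPM
    result, and the paths written.  Detectability-based blocking is
    skipped with a warning when the RA carries no detectability scores.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_map = load_config(config_path) if config_path else {}
    cfg_map.update({k: v for k, v in overrides.items() if v is not None})
    threshold = float(cfg_map.pop("threshold", threshold))
    sim_config, ra_opts = config_from_mapping(cfg_map)

    scale = ScoreScale(s_max=int(ra_opts.get("s_max", 5)),
                       o_max=int(ra_opts.get("o_max", 5)),
                       d_max=int(ra_opts.get("d_max", 5)))
    ra = read_risk_assessment(
        str(ra_path),
        cqa_name=str(ra_opts.get("cqa_name", "CQA")),
        direction=Direction(ra_opts.get("direction", "higher_is_better")),
        scale=scale,
        starting_cqa_pct=float(ra_opts.get("starting_cqa_pct", 100.0)),
    )
    log.info("simulating %d PPs / %d UOs: mode=%s cycles=%d seed=%d loo=%s",
             ra.n_pps, len(ra.uos), sim_config.propagation_mode,
             sim_config.n_cycles, sim_config.seed, sim_config.loo_mode)

    ipm = run_ipm(ra, sim_config)
    table = criticality.leave_one_out(ra, sim_config)
    table = criticality.classify(table, threshold)

    warnings: list[str] = []
    has_d = table["detectability"].notna().all() and len(table) > 0
    if has_d:
        table = blocking.assign_blocks(table)
        table, warnings = blocking.escalate(table)
        for w in warnings:
            log.warning("%s", w)
    else:
        log.warning("no detectability scores; blocking step skipped")

    comparison = rpn_compare.compare_rankings(table)

    paths = {"criticality": out_dir / "criticality.csv",
             "rpn_compare": out_dir / "rpn_compare.csv",
             "manifest": out_dir / "manifest.json"}
    write_criticality_table(table, paths["criticality"])
    comparison.to_csv(paths["rpn_compare"], index=False)
    if has_d:
        paths["blocks"] = out_dir / "blocks.csv"
        block_cols = ["uo", "pp", "detectability", "mean_cqa_reduction_pct",
                      "block_id", "is_block_most_critical", "block_escalated",
                      "is_critical"]
        table[block_cols].to_csv(paths["blocks"], index=False)

    manifest = RunManifest(
        tool_version=_version(),
        command="pipeline",
        seed=sim_config.seed,
        n_cycles=sim_config.n_cycles,
        input_digest=_digest(ra_path),
        config=dataclasses.asdict(sim_config),
        parameters={"threshold": threshold, "cqa_name": ra.cqa_name,
                    "direction": ra.direction.value,
                    "starting_cqa_pct": ra.starting_cqa_pct,
                    "oos_probability": ipm.oos_probability,
                    "mean_ds_cqa_pct": ipm.mean_ds,
                    "spec_limit_pct": ipm.spec_limit},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.to_json(paths["manifest"])

    if figures:
        paths.update(render_reports(table, out_dir))

    return {"table": table, "comparison": comparison, "ipm": ipm,
            "warnings": warnings, "paths": paths, "manifest": manifest}


def _version() -> str:
    from . import __version__

    return __version__


def render_reports(table: pd.DataFrame, out_dir: str | Path) -> dict:
    """Render the standard report figures from a criticality table.

    Bar chart of ascending CQA reductions (highest-impact PP rightmost);
    severity-by-occurrence contour (only when the table covers a complete
    score grid); reduction-vs-RPN scatter.  Figure bytes are deterministic
    for fixed inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    if table.empty:
        log.warning("empty criticality table; no figures rendered")
        return paths
    meta = {"Date": None}  # drop the embedded timestamp for reproducible bytes

    ordered = table.sort_values("mean_cqa_reduction_pct", kind="mergesort")
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(ordered)), 4))
    labels = ordered["uo"].astype(str) + "_" + ordered["pp"].astype(str)
    ax.bar(range(len(ordered)), ordered["mean_cqa_reduction_pct"], color="#4878a8")
    ax.set_xticks(range(len(ordered)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("CQA reduction (%)")
    ax.set_title("PP contribution to CQA reduction (ascending)")
    fig.tight_layout()
    paths["fig_reduction"] = out_dir / "reduction_bar.png"
    fig.savefig(paths["fig_reduction"], metadata=meta)
    plt.close(fig)

    pivot = table.pivot_table(index="severity", columns="occurrence",
                              values="mean_cqa_reduction_pct", aggfunc="mean")
    if pivot.notna().all().all() and pivot.size >= 4:
        fig, ax = plt.subplots(figsize=(5, 4))
        cs = ax.contourf(pivot.columns, pivot.index, pivot.values, levels=12,
                         cmap="viridis")
        fig.colorbar(cs, ax=ax, label="CQA reduction (%)")
        ax.set_xlabel("occurrence")
        ax.set_ylabel("severity")
        ax.set_title("S and O contribution to CQA reduction")
        fig.tight_layout()
        paths["fig_contour"] = out_dir / "so_contour.png"
        fig.savefig(paths["fig_contour"], metadata=meta)
        plt.close(fig)
    else:
        log.warning("criticality table does not cover a full S x O grid; "
                    "contour figure skipped")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["rpn"], table["mean_cqa_reduction_pct"], s=18, color="#a84848")
    ax.set_xlabel("RPN")
    ax.set_ylabel("CQA reduction (%)")
    ax.set_title("Simulated reduction vs classical RPN")
    fig.tight_layout()
    paths["fig_rpn"] = out_dir / "reduction_vs_rpn.png"
    fig.savefig(paths["fig_rpn"], metadata=meta)
    plt.close(fig)
    return paths
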