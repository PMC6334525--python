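"""Readers and writers for the package's tidy text formats.

Flow samples travel as tidy CSV (one row per cell:
``condition,duration,day,replicate,cell_id,intensity``); expression
matrices as TSV with cells in rows, metadata columns ``condition`` /
``culture`` first, then gene and spike-in columns (undetected entries
empty); proportion series as TSV; networks as canonical edge-list TSV and
GraphML with node attributes.  Floats round-trip at 1e-9.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .kinetics import ProportionSeries
from .mixture import FlowSample
from .noise import ExpressionMatrix
from .network import GeneNetwork

__all__ = [
    "write_flow_csv",
    "read_flow_csv",
    "write_expression_table",
    "read_expression_table",
    "write_proportions_tsv",
    "read_proportions_tsv",
    "write_network_tsv",
    "write_network_graphml",
    "read_network_graphml",
    "PipelineConfig",
    "load_config",
    "save_config",
]

FLOW_COLUMNS = ["condition", "duration", "day", "replicate", "cell_id", "intensity"]
_META_COLS = ["condition", "culture"]


def write_flow_csv(samples, path) -> None:
    """Write a collection (dict or iterable) of FlowSample as tidy CSV."""
    if isinstance(samples, dict):
        samples = samples.values()
    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    "condition": s.condition,
                    "duration": s.duration_days,
                    "day": s.day,
                    "replicate": s.replicate,
                    "cell_id": np.arange(1, len(s.intensities) + 1),
                    "intensity": s.intensities,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.10g")


def read_flow_csv(path) -> dict[tuple, FlowSample]:
    """Read tidy flow CSV into samples keyed (condition, duration, day,
    replicate).  Missing columns and non-numeric intensities are reported
    by name / line number."""
    df = pd.read_csv(path, dtype={"condition": str})
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"flow CSV {path} is missing required column(s): {', '.join(missing)}")
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = intensity.isna() & df["intensity"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"non-numeric intensity in {path} at line {line}")
    out = {}
    for (cond, dur, day, rep), grp in df.groupby(
        ["condition", "duration", "day", "replicate"], sort=False
    ):
        s = FlowSample(
            condition=cond,
            duration_days=float(dur),
            day=float(day),
            replicate=rep if isinstance(rep, str) else int(rep),
            intensities=grp["intensity"].to_numpy(dtype=float),
        )
        out[s.key] = s
    return out


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """TSV with cells in rows: condition, culture, then gene columns;
    undetected entries written empty (log2 mode)."""
    vals = matrix.values.where(matrix.detected)
    df = pd.concat([matrix.cell_meta[
        [c for c in _META_COLS if c in matrix.cell_meta.columns]
    ], vals], axis=1)
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_table(
    path,
    mode: str = "log2",
    lod: float = 28.0,
    annotations: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV.

    ``mode="ct"`` converts via log2-expression = LOD − Ct, with Ct ≥ LOD
    (or missing) undetected; ``mode="log2"`` passes values through, with
    empty entries as the undetected sentinel.  ``annotations`` (indexed by
    gene, boolean columns ``is_spikein`` / ``is_h3k9ac_target``) overrides
    the default spike-in detection by column-name prefix ``spike``.
    """
    if mode not in ("ct", "log2"):
        raise ValueError(f"unknown expression mode {mode!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicated gene column(s): {', '.join(dupes)}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = [c for c in _META_COLS if c in df.columns]
    if "condition" not in meta_cols:
        raise ValueError(f"expression table {path} is missing the 'condition' column")
    gene_cols = [c for c in df.columns if c not in meta_cols]
    if len(set(gene_cols)) != len(gene_cols):
        dupes = sorted({c for c in gene_cols if gene_cols.count(c) > 1})
        raise ValueError(f"duplicated gene column(s): {', '.join(dupes)}")
    vals = df[gene_cols].apply(pd.to_numeric, errors="raise")
    if mode == "ct":
        detected = vals.notna() & (vals < lod)
        vals = (lod - vals).where(detected)
    else:
        detected = vals.notna()
    cell_meta = df[meta_cols].copy()
    if "culture" not in cell_meta.columns:
        cell_meta["culture"] = "unknown"
    if annotations is not None:
        gene_meta = annotations.reindex(gene_cols)
        gene_meta["is_spikein"] = gene_meta.get("is_spikein", False).fillna(False).astype(bool)
        if "is_h3k9ac_target" in gene_meta.columns:
            gene_meta["is_h3k9ac_target"] = gene_meta["is_h3k9ac_target"].fillna(False).astype(bool)
        else:
            gene_meta["is_h3k9ac_target"] = False
    else:
        gene_meta = pd.DataFrame(
            {
                "is_spikein": [c.lower().startswith("spike") for c in gene_cols],
                "is_h3k9ac_target": False,
            },
            index=gene_cols,
        )
    return ExpressionMatrix(
        values=vals.astype(float), detected=detected, cell_meta=cell_meta, gene_meta=gene_meta
    )


def write_proportions_tsv(series_map: dict[tuple, ProportionSeries], path) -> None:
    rows = []
    for (cond, dur, rep), s in series_map.items():
        for i, t in enumerate(s.times):
            rows.append(
                {
                    "condition": cond,
                    "duration": dur,
                    "replicate": rep,
                    "day": t,
                    "p_hn": s.proportions[i, 0],
                    "p_mn": s.proportions[i, 1],
                    "p_ln": s.proportions[i, 2],
                    "n_cells": None if s.n_cells is None else int(s.n_cells[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_proportions_tsv(path) -> dict[tuple, ProportionSeries]:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str})
    out = {}
    for (cond, dur, rep), grp in df.groupby(["condition", "duration", "replicate"], sort=False):
        grp = grp.sort_values("day")
        out[(cond, float(dur), rep if isinstance(rep, str) else int(rep))] = ProportionSeries(
            condition=cond,
            times=grp["day"].to_numpy(dtype=float),
            proportions=grp[["p_hn", "p_mn", "p_ln"]].to_numpy(dtype=float),
            replicate=rep,
            n_cells=grp["n_cells"].to_numpy() if grp["n_cells"].notna().all() else None,
        )
    return out


def write_network_tsv(net: GeneNetwork, path) -> None:
    net.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_network_graphml(net: GeneNetwork, path, cv_gains: pd.Series | None = None) -> None:
    """GraphML with is_h3k9ac_target (and optional cv_gain) node
    attributes and the full statistics on each edge."""
    g = nx.Graph(condition=net.condition)
    for gene, row in net.nodes.iterrows():
        attrs = {"is_h3k9ac_target": bool(row["is_h3k9ac_target"])}
        if cv_gains is not None and gene in cv_gains.index and np.isfinite(cv_gains[gene]):
            attrs["cv_gain"] = float(cv_gains[gene])
        g.add_node(gene, **attrs)
    for e in net.edges:
        g.add_edge(
            e.gene_a,
            e.gene_b,
            spearman_rho=_g(e.spearman_rho),
            spearman_p=_g(e.spearman_p),
            odds_ratio=_g(e.odds_ratio),
            or_p=_g(e.or_p),
            n_codetected=int(e.n_codetected),
            significant_by=",".join(e.significant_by),
        )
    nx.write_graphml(g, path)


def _g(x: float) -> float:
    return float(x) if np.isfinite(x) else -1.0


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run configuration; all stage options in one place."""

    outdir: str = "pluristate_out"
    seed: int = 17
    simulate: bool = True
    flow_path: str | None = None
    expression_path: str | None = None
    annotations_path: str | None = None
    # simulation sizes
    n_cells_per_sample: int = 10_000
    n_replicates: int = 4
    n_cells_expression: int = 35
    # mixture options
    mixture_k: int = 3
    mixture_n_init: int = 10
    subsample_per_sample: int = 1000
    # kinetics options
    p0_mode: str = "measured"
    n_starts: int = 25
    n_boot: int = 200
    reference_condition: str = "DMSO"
    # noise options
    expression_mode: str = "log2"
    lod: float = 28.0
    min_detected: int = 5
    qc_mad_threshold: float = 3.0
    # network options
    alpha: float = 0.05
    min_codetect: int = 10
    edge_rule: str = "either"
    gain_mode: str = "mean"

    def validate(self) -> None:
        if self.mixture_k < 1 or self.n_starts < 1:
            raise ValueError("mixture_k and n_starts must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.p0_mode not in ("measured", "free"):
            raise ValueError(f"unknown p0_mode {self.p0_mode!r}")
        if self.edge_rule not in ("either", "both"):
            raise ValueError(f"unknown edge_rule {self.edge_rule!r}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
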