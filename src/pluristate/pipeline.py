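"""End-to-end orchestration: simulate -> gate -> kinetics -> noise ->
network -> compare, with a JSON run manifest.

Each stage writes its outputs under the configured directory; a failing
stage aborts the run naming the stage, and the partial manifest is kept
with a ``.partial`` suffix.  Runs are idempotent under a fixed seed.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np

from . import __version__, io, mixture, network, noise, simulate
from .kinetics import KineticParams, fit_kinetics, compare_conditions

__all__ = ["run_pipeline", "default_simulation_config"]

STAGES = ("simulate", "gate", "kinetics", "noise", "network", "compare")


def default_simulation_config(cfg: io.PipelineConfig) -> simulate.SimulationConfig:
    """Wash-off design emulated by default: a control condition that
    favors the high-reporter state and a treatment condition with slowed,
    less reversible transitions out of the mid state."""
    return simulate.SimulationConfig(
        seed=cfg.seed,
        n_cells_per_sample=cfg.n_cells_per_sample,
        n_replicates=cfg.n_replicates,
        conditions=[
            simulate.ConditionTruth(
                label="DMSO", params=KineticParams(0.3, 0.5, 0.1, 0.05), p0=(0.8, 0.15, 0.05)
            ),
            simulate.ConditionTruth(
                label="MB3", params=KineticParams(0.15, 0.1, 0.12, 0.02), p0=(0.3, 0.55, 0.15)
            ),
        ],
    )


def run_pipeline(cfg: io.PipelineConfig) -> dict:
    """Run all stages per the config and return the manifest dict."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in vars(cfg).items()},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    partial = outdir / "manifest.partial.json"
    current = "simulate"
    try:
        # --- simulate ------------------------------------------------
        if cfg.simulate:
            sim_cfg = default_simulation_config(cfg)
            flow = simulate.make_washoff_dataset(sim_cfg)
            panel = simulate.default_panel(seed=cfg.seed)
            rng = np.random.default_rng(cfg.seed)
            mats = [
                simulate.simulate_expression_matrix(
                    panel, cfg.n_cells_expression, cond, seed=int(rng.integers(2**31 - 1))
                )
                for cond in ("DMSO", "MB3")
            ]
            expr = simulate.concat_conditions(mats)
            io.write_flow_csv(flow, outdir / "flow.csv")
            io.write_expression_table(expr, outdir / "expression.tsv")
            manifest["stages"]["simulate"] = {
                "n_flow_samples": len(flow),
                "n_cells_expression": int(len(expr.values)),
            }
        else:
            if cfg.flow_path is None or not Path(cfg.flow_path).exists():
                raise FileNotFoundError(f"flow input not found: {cfg.flow_path}")
            flow = io.read_flow_csv(cfg.flow_path)
            expr = io.read_expression_table(
                cfg.expression_path, mode=cfg.expression_mode, lod=cfg.lod
            )
            manifest["stages"]["simulate"] = {"skipped": True, "n_flow_samples": len(flow)}

        # --- gate ----------------------------------------------------
        current = "gate"
        pooled = mixture.pool_virtual_ensemble(
            flow.values(), per_sample_n=cfg.subsample_per_sample, seed=cfg.seed
        )
        model = mixture.fit_mixture(pooled, k=cfg.mixture_k, seed=cfg.seed,
                                    n_init=cfg.mixture_n_init)
        props = mixture.state_proportions(model, flow.values())
        io.write_proportions_tsv(props, outdir / "proportions.tsv")
        manifest["stages"]["gate"] = {
            "pooled_n": int(model.n_fit),
            "means": list(map(float, model.means)),
            "weights": list(map(float, model.weights)),
            "bic": model.bic,
        }

        # --- kinetics ------------------------------------------------
        current = "kinetics"
        by_condition: dict[str, list] = {}
        for (cond, _dur, _rep), series in props.items():
            by_condition.setdefault(cond, []).append(series)
        fits = {
            cond: fit_kinetics(
                series_list, p0_mode=cfg.p0_mode, n_starts=cfg.n_starts,
                n_boot=cfg.n_boot, seed=cfg.seed,
            )
            for cond, series_list in by_condition.items()
        }
        manifest["stages"]["kinetics"] = {
            cond: {
                "rates": list(f.params.as_array()),
                "reversibility_index": f.reversibility,
                "residual_ss": f.residual_ss,
            }
            for cond, f in fits.items()
        }

        # --- noise ---------------------------------------------------
        current = "noise"
        expr_qc = noise.qc_filter_cells(expr, mad_threshold=cfg.qc_mad_threshold)
        conds = expr_qc.conditions
        if len(conds) < 2:
            raise ValueError("noise comparison needs two conditions in the expression data")
        ref = cfg.reference_condition if cfg.reference_condition in conds else conds[0]
        alt = next(c for c in conds if c != ref)
        cmp_noise = noise.compare_noise(expr_qc, ref, alt, min_detected=cfg.min_detected)
        cmp_noise.per_gene.to_csv(outdir / "noise_comparison.tsv", sep="\t")
        manifest["stages"]["noise"] = {
            "reference": ref,
            "alternative": alt,
            "cv_p": cmp_noise.cv_p,
            "mean_p": cmp_noise.mean_p,
            "median_cv_gain": float(np.nanmedian(cmp_noise.per_gene["cv_gain"])),
            "n_genes_used": cmp_noise.n_genes_used,
        }

        # --- network -------------------------------------------------
        current = "network"
        nets = {}
        for cond in (ref, alt):
            net = network.build_network(
                expr_qc, cond, alpha=cfg.alpha, min_codetect=cfg.min_codetect,
                edge_rule=cfg.edge_rule,
            )
            nets[cond] = net
            io.write_network_tsv(net, outdir / f"network_{cond}.tsv")
            io.write_network_graphml(
                net, outdir / f"network_{cond}.graphml",
                cv_gains=cmp_noise.per_gene["cv_gain"],
            )
        manifest["stages"]["network"] = {c: {"n_edges": len(n.edges)} for c, n in nets.items()}

        # --- compare -------------------------------------------------
        current = "compare"
        comparison = network.classify_edges(nets[ref], nets[alt])
        degrees = network.target_subnetwork_degrees(
            comparison, expr_qc.gene_meta.loc[list(nets[ref].nodes.index), "is_h3k9ac_target"]
        )
        degrees.to_csv(outdir / "edge_degrees.tsv", sep="\t")
        gain_cmp = network.edge_cv_gain_comparison(comparison, cmp_noise, mode=cfg.gain_mode)
        gain_cmp.tests.to_csv(outdir / "edge_gain_tests.tsv", sep="\t", index=False)
        kin_table = compare_conditions(fits, reference=ref) if len(fits) >= 2 else None
        if kin_table is not None:
            kin_table.to_csv(outdir / "kinetics_comparison.tsv", sep="\t")
        manifest["stages"]["compare"] = {
            "common_edges": len(comparison.common),
            "only_ref_edges": len(comparison.only_a),
            "only_alt_edges": len(comparison.only_b),
        }
    except Exception as exc:
        io.write_manifest(manifest, partial)
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["checksums"] = _checksums(outdir)
    io.write_manifest(manifest, outdir / "manifest.json")
    if partial.exists():
        partial.unlink()
    return manifest


def _checksums(outdir: Path) -> dict[str, str]:
    out = {}
    for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.csv")):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
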