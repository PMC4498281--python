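"""End-to-end orchestration: data -> QC -> DEGs -> network -> SOM -> enrichment.

``run_pipeline`` executes the stages in order (floor, PCA screening,
contrasts, DEG calling, correlation, network construction, degrees/hubs/
components, SOM binning, region partition, overlays, enrichment) and
writes every artifact plus a machine-readable JSON run report.  The run
is deterministic: one master seed fans out to per-stage seeds through a
``numpy`` SeedSequence, all writers sort their output, and the report
carries no volatile fields (stage timings go to the log only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import io as aio
from . import network as net_mod
from . import qc_deg, som, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]


@dataclass
class PipelineConfig:
    # input: either synthetic simulation or user files
    synthetic: synthetic.SyntheticConfig | None = None
    matrix_path: str | None = None
    design_path: str | None = None
    gene_sets_path: str | None = None  # GMT to overlay / test in hubs
    annotation_path: str | None = None  # gene -> category TSV for ORA

    # stage parameters (defaults follow the reference workflow)
    floor: float = 4.0
    qc_n_pcs: int = 2
    qc_z_cut: float = 3.0
    drop_outliers: bool = True
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    moderated: bool = False
    corr_threshold: float = 0.97
    corr_mode: str = "positive"
    corr_basis: str = "replicate_means"
    hub_k: int = 100
    som_rows: int = 2
    som_cols: int = 3
    som_epochs: int = 200
    earliness_cut: float = 0.5
    hub_alpha: float = 0.01
    ora_alpha: float = 0.05

    out_dir: str = "results/run"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            sd = dataclasses.asdict(self.synthetic)
            sd["class_fractions"] = dict(self.synthetic.class_fractions)
            sd["planted_sets"] = {
                k: list(v) for k, v in self.synthetic.planted_sets.items()
            }
            sd["time_points_h"] = list(self.synthetic.time_points_h)
            d["synthetic"] = sd
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "time_points_h" in syn:
                syn["time_points_h"] = tuple(syn["time_points_h"])
            if "planted_sets" in syn:
                syn["planted_sets"] = {k: tuple(v) for k, v in syn["planted_sets"].items()}
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        return cfg


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Fan a master seed out to per-stage seeds (documented derivation)."""
    state = np.random.SeedSequence(master_seed).generate_state(2)
    return {"synthetic": int(state[0] % 2**31), "som": int(state[1] % 2**31)}


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2f s", self.name, time.perf_counter() - self.t0)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and return the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    config_echo = config.to_dict()
    config_echo.pop("out_dir")  # a location, not a parameter: keeps reports
    # byte-identical across output directories
    report: dict[str, Any] = {
        "version": _version(),
        "config": config_echo,
        "stage_seeds": seeds,
    }

    truth: synthetic.SyntheticTruth | None = None
    with _Stage("input"):
        if config.synthetic is not None:
            syn_cfg = dataclasses.replace(config.synthetic, seed=seeds["synthetic"])
            matrix, design, truth = synthetic.generate_dataset(syn_cfg)
            aio.write_matrix(matrix, out / "matrix.tsv")
            aio.write_design(design, out / "design.tsv")
            synthetic.write_truth(truth, out / "truth_classes.tsv", out / "planted_sets.gmt")
            report["input"] = {"mode": "synthetic", "n_genes": matrix.n_genes,
                               "n_samples": matrix.n_samples}
        else:
            if not config.matrix_path or not config.design_path:
                raise ValueError("matrix_path and design_path required without synthetic config")
            matrix = aio.read_matrix(config.matrix_path)
            design = aio.read_design(config.design_path)
            design.validate_against(matrix)
            report["input"] = {"mode": "files", "n_genes": matrix.n_genes,
                               "n_samples": matrix.n_samples}

    with _Stage("floor"):
        matrix = qc_deg.floor_transform(matrix, config.floor)

    with _Stage("qc"):
        qc = qc_deg.detect_outlier_samples(
            matrix, design, config.qc_n_pcs, config.qc_z_cut, floor_value=config.floor
        )
        dropped = qc.flagged_samples if config.drop_outliers else []
        if dropped:
            matrix = matrix.drop_samples(dropped)
            design = design.drop_samples(dropped)
        qc.to_frame().to_csv(out / "qc_outliers.tsv", sep="\t", index=False)
        report["qc"] = {
            "pc_variance_fractions": [round(float(v), 6) for v in qc.pc_variance_fractions[:5]],
            "flagged_samples": qc.flagged_samples,
            "dropped_samples": dropped,
        }

    with _Stage("deg"):
        contrasts = qc_deg.fit_timepoint_contrasts(matrix, design, moderated=config.moderated)
        deg = qc_deg.call_degs(contrasts, config.fc_threshold, config.p_threshold)
        summary = qc_deg.summarize_degs(deg)
        qc_deg.write_deg_table(deg, out / "deg_table.tsv")
        summary.table.to_csv(out / "deg_summary.tsv", sep="\t")
        report["deg"] = {
            "per_time": {
                f"{t:g}": row.to_dict() for t, row in summary.table.iterrows()
            },
            "union": summary.union,
        }
        deg_genes = deg.deg_genes
        if len(deg_genes) < 2:
            raise RuntimeError(f"only {len(deg_genes)} DEGs; cannot build a network")

    with _Stage("network"):
        corr = net_mod.correlation_matrix(matrix, design, deg_genes, config.corr_basis)
        net = net_mod.build_network(corr.r, config.corr_threshold, config.corr_mode)
        net.basis = config.corr_basis
        net.excluded_genes = corr.excluded
        hubs = net_mod.identify_hubs(net, config.hub_k)
        components, single = net_mod.connected_components(net)
        pd.DataFrame(
            {"gene": hubs.hubs, "degree": [net.graph.degree(g) for g in hubs.hubs]}
        ).to_csv(out / "hubs.tsv", sep="\t", index=False)
        report["network"] = {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "zero_variance_excluded": len(corr.excluded),
            "n_components": len(components),
            "single_component": single,
            "hub_degree_min": hubs.degree_range[0],
            "hub_degree_max": hubs.degree_range[1],
        }

    with _Stage("som"):
        node_matrix = matrix.subset_genes(net.nodes)
        z = som.standardize_profiles(node_matrix, design)
        model = som.train_som(
            z, config.som_rows, config.som_cols, config.som_epochs, seed=seeds["som"]
        )
        assignment = som.assign_som_bins(model, z)
        assignment.to_frame(model).to_csv(out / "som_assignment.tsv", sep="\t", index=False)
        times = design.times
        pd.DataFrame(
            model.codebook, columns=[f"t{t:g}h" for t in times]
        ).to_csv(out / "som_codebook.tsv", sep="\t", index_label="unit", float_format="%.10g")
        unit_summary = pd.DataFrame(
            {
                "unit": range(model.n_units),
                "count": assignment.counts,
                **{
                    f"mean_t{t:g}h": assignment.mean_profiles[:, i]
                    for i, t in enumerate(times)
                },
                **{
                    f"sd_t{t:g}h": assignment.sd_profiles[:, i]
                    for i, t in enumerate(times)
                },
            }
        )
        unit_summary.to_csv(out / "som_units.tsv", sep="\t", index=False, float_format="%.10g")
        report["som"] = {
            "bin_sizes": [int(c) for c in assignment.counts],
            "initial_quantization_error": round(model.initial_quantization_error, 6),
            "final_quantization_error": round(model.final_quantization_error, 6),
        }

    with _Stage("regions"):
        regions, bin_label, bin_e = net_mod.partition_regions(
            net, assignment.unit_of(), matrix, design, config.earliness_cut
        )
        pd.DataFrame(
            sorted(regions.items()), columns=["gene", "region"]
        ).to_csv(out / "regions.tsv", sep="\t", index=False)
        region_sizes = {r: sum(1 for v in regions.values() if v == r) for r in ("ER", "LR", "none")}
        report["regions"] = {
            "bin_labels": {str(u): bin_label[u] for u in sorted(bin_label)},
            "bin_earliness": {str(u): round(bin_e[u], 4) for u in sorted(bin_e)},
            "region_sizes": region_sizes,
        }

    with _Stage("overlay_enrichment"):
        if config.gene_sets_path:
            sets = aio.read_gmt(config.gene_sets_path)
        elif truth is not None:
            sets = [
                aio.GeneSet(name=name, description="planted", members=list(members))
                for name, members in truth.set_membership.items()
            ]
        else:
            sets = []
        if sets:
            overlays = enr.project_gene_sets(net, sets)
            pd.DataFrame([o.as_dict() for o in overlays.values()]).sort_values("set").to_csv(
                out / "overlays.tsv", sep="\t", index=False, float_format="%.10g"
            )
            hub_rows = enr.hub_set_enrichment(net, sets, alpha=config.hub_alpha)
            enr.enrichment_frame(hub_rows).to_csv(
                out / "hub_enrichment.tsv", sep="\t", index=False, float_format="%.10g"
            )
            report["overlays"] = {
                name: {"nodes_hit": o.nodes_hit, "fraction": round(o.fraction, 4)}
                for name, o in sorted(overlays.items())
            }
            report["hub_enrichment"] = {
                r.category: {"k": r.k, "K": r.K, "p": float(f"{r.p:.6g}"),
                             "significant": r.significant}
                for r in hub_rows
            }

        if config.annotation_path:
            annotation = aio.read_annotation(config.annotation_path)
        elif truth is not None:
            annotation = pd.DataFrame(
                sorted(truth.gene_class.items()), columns=["gene", "category"]
            )
        else:
            annotation = None
        if annotation is not None:
            ora_rows = enr.run_ora(
                deg_genes, matrix.gene_ids, annotation, alpha=config.ora_alpha
            )
            enr.enrichment_frame(ora_rows).to_csv(
                out / "ora.tsv", sep="\t", index=False, float_format="%.10g"
            )
            report["ora"] = {
                r.category: {"k": r.k, "p_adj": float(f"{r.p_adj:.6g}"),
                             "significant": r.significant}
                for r in ora_rows
            }

    with _Stage("export"):
        aio.write_network(net, out / "network_edges.tsv", "edge_tsv")
        aio.write_network(net, out / "network.sif", "sif")
        aio.write_network(net, out / "network.graphml", "graphml")
        with open(out / "run_report.json", "w", encoding="utf-8") as handle:
            json.dump(report, handle, indent=2, sort_keys=True)
            handle.write("\n")

    return report


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("abanet")
    except Exception:  # pragma: no cover - editable installs always resolve
        return "unknown"
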