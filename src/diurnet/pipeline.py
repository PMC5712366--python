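"""End-to-end orchestration: counts → RPM → filter → periodicity → networks.

A single :class:`PipelineConfig` (YAML-compatible) drives the run.  Every
stage writes its outputs into the run directory and registers them, with
SHA-256 checksums, in ``manifest.json``; excluded genes are listed with a
reason (unexpressed, constant, failed fit) so nothing is dropped
silently.  Stage outputs are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coexpression import build_gcn, gcn_stats, pcc_matrix
from .ensemble import (call_edges, confidence_matrix, degree_distribution_fit,
                       ensemble_infer, network_summary)
from .expression import (CountMatrix, DesignGrid, ExpressionTensor,
                         compute_rpm, filter_expressed, replicate_mean,
                         zscore_genes)
from .periodicity import (consensus_periodicity, peak_time_bins,
                          records_to_frame)
from .synthetic_data import (generate_arx_tensor, generate_counts,
                             generate_nonperiodic_tensor,
                             generate_periodic_tensor)

logger = logging.getLogger("diurnet")

__all__ = ["PipelineConfig", "simulate", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults mirror the study design."""

    # I/O
    counts_tsv: str | None = None
    metadata_tsv: str | None = None
    out_dir: str = "diurnet_run"
    library_from_column_sums: bool = False
    # expression
    min_rpm: float = 1.0
    log2_transform: bool = False
    # periodicity
    alpha: float = 0.01
    n_perm: int = 30
    n_surrogates: int = 1000
    omega0: float = 6.0
    dark_window: tuple[float, float] = (22.0, 2.0)
    # co-expression
    gcn_cutoffs: tuple[float, ...] = (0.7, 0.8)
    gcn_absolute: bool = False
    # GRN / ensemble
    arx_orders: tuple[int, ...] = (1, 2, 3)
    M: int = 30
    confidence_threshold: int = 20
    hub_min_children: int = 50
    n_lambda: int = 40
    # randomness
    seed: int = 0
    # simulation block
    sim_n_periodic: int = 100
    sim_n_background: int = 170
    sim_n_arx: int = 30
    sim_n_parents: int = 6
    sim_children_per_parent: int = 3
    sim_arx_order: int = 1
    sim_noise_sd: float = 0.5
    sim_innovation_sd: float = 0.1
    sim_arx_scale: float = 20.0
    sim_arx_baseline: float = 30.0
    sim_library_size: float = 2e7

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not set(self.arx_orders) <= {1, 2, 3}:
            raise ValueError("arx_orders must be a subset of {1, 2, 3}")
        if not 0 < self.confidence_threshold <= self.M:
            raise ValueError("confidence threshold must lie in (0, M]")
        for c in self.gcn_cutoffs:
            if not 0 < c <= 1:
                raise ValueError("GCN cutoffs must lie in (0, 1]")
        if self.min_rpm < 0 or self.n_perm < 1 or self.M < 1:
            raise ValueError("min_rpm, n_perm and M must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dark_window", "gcn_cutoffs", "arx_orders"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("dark_window", "gcn_cutoffs", "arx_orders"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.data = {
            "diurnet_version": __version__,
            "numpy_version": np.__version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
            "seed": config.seed,
            "stages": {},
            "excluded_genes": [],
            "outputs": {},
        }

    def stage(self, name: str, seconds: float, **info) -> None:
        self.data["stages"][name] = {"wall_seconds": round(seconds, 3), **info}
        logger.info("stage %-12s done in %.2fs %s", name, seconds, info or "")

    def exclude(self, genes, reason: str) -> None:
        self.data["excluded_genes"].extend(
            {"gene": g, "reason": reason} for g in genes)

    def register(self, label: str, path: Path) -> None:
        self.data["outputs"][label] = {
            "path": path.name, "sha256": _sha256(path)}

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# simulation entry point
# ---------------------------------------------------------------------------

def simulate(config: PipelineConfig, out_dir: str | Path | None = None
             ) -> dict:
    """Write a synthetic count dataset with ground-truth files.

    The tensor stacks three gene classes on the default two-day design:
    24 h sinusoids, autocorrelated background noise, and a sparse
    ARX-coupled block (shifted/scaled onto the RPM scale).  Counts are
    Poisson draws at the configured library size; negative expression
    values are clipped at zero only here, at count generation.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = DesignGrid()
    seed = config.seed

    periodic, truth_phases = generate_periodic_tensor(
        config.sim_n_periodic, grid, noise_sd=config.sim_noise_sd,
        seed=seed + 1, gene_prefix="per")
    background = generate_nonperiodic_tensor(
        config.sim_n_background, grid, ar_coefficient=0.3,
        noise_sd=config.sim_noise_sd, seed=seed + 2, gene_prefix="bg")
    arx, truth_net = generate_arx_tensor(
        config.sim_n_arx, config.sim_n_parents, config.sim_children_per_parent,
        order=config.sim_arx_order, innovation_sd=config.sim_innovation_sd,
        grid_or_length=grid, seed=seed + 3,
        measurement_sd=config.sim_noise_sd / config.sim_arx_scale
        if config.sim_noise_sd > 0 else 0.0, gene_prefix="arx")
    arx_values = config.sim_arx_baseline + config.sim_arx_scale * arx.values

    genes = list(periodic.genes) + list(background.genes) + list(arx.genes)
    values = np.concatenate([periodic.values, background.values, arx_values])
    tensor = ExpressionTensor(genes, grid, np.clip(values, 0.0, None))

    counts = generate_counts(tensor, config.sim_library_size, seed=seed + 4)
    counts.to_tsv(out / "counts.tsv", out / "metadata.tsv")
    truth_phases.to_tsv(out / "truth_phases.tsv")
    truth_net.to_tsv(out / "truth_network.tsv")
    tensor.to_tsv(out / "truth_expression.tsv")
    logger.info("simulate: wrote %d genes × %d samples to %s",
                len(genes), grid.n_timepoints * grid.n_reps, out)
    return {"counts": counts, "tensor": tensor, "truth_phases": truth_phases,
            "truth_network": truth_net, "out_dir": out,
            "periodic_genes": list(periodic.genes)}


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig,
                 counts: CountMatrix | None = None) -> dict:
    """Run all stages and write outputs plus a checksummed manifest.

    ``counts`` may be passed in-memory; otherwise ``config.counts_tsv`` /
    ``config.metadata_tsv`` are read.  Returns a dict of in-memory stage
    results and output paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    results: dict = {"out_dir": out}

    # ---- expression ------------------------------------------------------
    t0 = time.perf_counter()
    if counts is None:
        if not config.counts_tsv or not config.metadata_tsv:
            raise ValueError("config must provide counts_tsv and metadata_tsv")
        counts = CountMatrix.from_tsv(
            config.counts_tsv, config.metadata_tsv,
            library_from_column_sums=config.library_from_column_sums)
    tensor = compute_rpm(counts)
    expressed = filter_expressed(tensor, config.min_rpm)
    manifest.exclude(sorted(set(tensor.genes) - set(expressed)), "unexpressed")
    tensor = tensor.subset(expressed)
    if config.log2_transform:
        tensor = ExpressionTensor(tensor.genes, tensor.grid,
                                  np.log2(tensor.values + 1.0))
        logger.info("run_pipeline: applied log2(RPM+1) transform")
    tensor.to_tsv(out / "expression_rpm.tsv")
    manifest.register("expression_rpm", out / "expression_rpm.tsv")
    manifest.stage("expression", time.perf_counter() - t0,
                   n_genes_in=len(counts.genes), n_expressed=len(expressed),
                   min_rpm=config.min_rpm, log2_transform=config.log2_transform)
    results["tensor"] = tensor

    # ---- periodicity -----------------------------------------------------
    t0 = time.perf_counter()
    records = consensus_periodicity(
        tensor, n_perm=config.n_perm, alpha=config.alpha,
        n_surrogates=config.n_surrogates, seed=config.seed + 10,
        omega0=config.omega0)
    frame = records_to_frame(records)
    frame.to_csv(out / "periodicity.tsv", sep="\t")
    manifest.register("periodicity", out / "periodicity.tsv")
    periodic_genes = [r.gene for r in records if r.is_periodic]
    peak_times = {r.gene: r.peak_time for r in records
                  if r.is_periodic and r.peak_time is not None}
    try:
        dark_fraction = peak_time_bins(records, config.dark_window)
    except ValueError:
        dark_fraction = None
    manifest.stage("periodicity", time.perf_counter() - t0,
                   n_periodic=len(periodic_genes),
                   dark_peak_fraction=dark_fraction,
                   n_perm=config.n_perm, alpha=config.alpha,
                   n_surrogates=config.n_surrogates, seed=config.seed + 10)
    results.update(records=records, periodic_genes=periodic_genes,
                   peak_times=peak_times, dark_peak_fraction=dark_fraction)

    if not periodic_genes:
        logger.warning("run_pipeline: no periodic genes; skipping network stages")
        results["manifest_path"] = manifest.write()
        return results

    periodic_tensor = tensor.subset(periodic_genes)

    # ---- co-expression ---------------------------------------------------
    t0 = time.perf_counter()
    series, constant = zscore_genes(replicate_mean(periodic_tensor))
    manifest.exclude(constant, "constant")
    gcn_results = {}
    if series.n_genes >= 2:
        r = pcc_matrix(series)
        for cutoff in config.gcn_cutoffs:
            net = build_gcn(r, series.genes, cutoff,
                            absolute=config.gcn_absolute)
            stats = gcn_stats(net)
            path = out / f"gcn_edges_pcc{cutoff:g}.tsv"
            net.to_tsv(path)
            manifest.register(f"gcn_pcc{cutoff:g}", path)
            gcn_results[cutoff] = {"network": net, "stats": stats}
    manifest.stage("coexpression", time.perf_counter() - t0,
                   cutoffs=list(config.gcn_cutoffs),
                   **{f"pcc{c:g}": {"n_nodes": v["stats"]["n_nodes"],
                                    "n_edges": v["stats"]["n_edges"]}
                      for c, v in gcn_results.items()})
    results["gcn"] = gcn_results

    # ---- GRN ensemble ----------------------------------------------------
    grn_results = {}
    for order in config.arx_orders:
        t0 = time.perf_counter()
        base_seed = config.seed + 1000 * order
        networks = ensemble_infer(periodic_tensor, order, M=config.M,
                                  base_seed=base_seed,
                                  n_lambda=config.n_lambda)
        conf = confidence_matrix(networks)
        called = call_edges(conf, config.confidence_threshold)
        summary = network_summary(called, peak_times,
                                  config.hub_min_children)
        hist, slope = degree_distribution_fit(called)
        summary["out_degree_loglog_slope"] = slope
        failed = sorted({g for net in networks for g in net.failed_targets})
        manifest.exclude(failed, f"failed_fit_arx{order}")
        conf_path = out / f"grn_confidence_arx{order}.tsv"
        net_path = out / f"grn_network_arx{order}.tsv"
        conf.to_tsv(conf_path)
        called.to_tsv(net_path)
        manifest.register(f"grn_confidence_arx{order}", conf_path)
        manifest.register(f"grn_network_arx{order}", net_path)
        manifest.stage(f"grn_arx{order}", time.perf_counter() - t0,
                       M=len(networks), base_seed=base_seed,
                       threshold=config.confidence_threshold,
                       n_edges=summary["n_edges"],
                       n_parents=summary["n_parents"],
                       n_children=summary["n_children"])
        grn_results[order] = {"networks": networks, "confidence": conf,
                              "called": called, "summary": summary,
                              "degree_histogram": hist,
                              "loglog_slope": slope}
    results["grn"] = grn_results

    summary_json = {
        "n_expressed": len(tensor.genes),
        "n_periodic": len(periodic_genes),
        "dark_peak_fraction": dark_fraction,
        "gcn": {f"pcc{c:g}": v["stats"] for c, v in gcn_results.items()},
        "grn": {f"arx{o}": v["summary"] for o, v in grn_results.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary_json, indent=2,
                                                 sort_keys=True, default=str))
    manifest.register("summary", out / "summary.json")
    results["summary"] = summary_json
    results["manifest_path"] = manifest.write()
    return results
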