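"""End-to-end orchestration: intersect -> fit_all -> assemble -> extract ->
refine -> survival, with a run manifest for reproducibility.

Every stage writes its artifact under the output directory; the manifest
records parameters, input/output paths, SHA-256 checksums and wall times so a
re-run under the same seed can be verified bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import network_assembly, subnetwork_extraction
from .bayesian_refinement import BNConfig, refine
from .io_formats import (intersect_samples, read_layer, read_prior_edges,
                         read_seed_genes, write_network)
from .survival_analysis import (median_split_logrank, read_survival_table)
from .vif_regression import VIFConfig, fit_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mrna: str
    mirna: str
    methylation: str
    cnv: str
    seed_genes: str
    prior_edges: str
    survival: str | None = None
    out_dir: str = "omicsnet_out"
    cutoff: float = network_assembly.DEFAULT_CUTOFF
    seed: int = 0
    n_jobs: int = 1
    vif: VIFConfig = field(default_factory=VIFConfig)
    bn: BNConfig = field(default_factory=BNConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        vif = VIFConfig(**raw.pop("vif", {}))
        bn = BNConfig(**raw.pop("bn", {}))
        cfg = cls(vif=vif, bn=bn, **raw)
        return cfg

    def validate_paths(self) -> None:
        required = [self.mrna, self.mirna, self.methylation, self.cnv,
                    self.seed_genes, self.prior_edges]
        if self.survival:
            required.append(self.survival)
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # share the global seed with the stage configs
    cfg.vif.seed = cfg.seed
    cfg.bn.seed = cfg.seed
    manifest: dict = {"seed": cfg.seed, "stages": {}}

    def stage(name):
        logger.info("=== stage %s ===", name)
        return time.perf_counter()

    try:
        t0 = stage("intersect")
        dataset = intersect_samples(
            read_layer(cfg.mrna, "mrna"),
            read_layer(cfg.mirna, "mirna"),
            read_layer(cfg.methylation, "methylation"),
            read_layer(cfg.cnv, "cnv"))
        manifest["stages"]["intersect"] = {
            "n_samples": dataset.n_samples,
            "seconds": round(time.perf_counter() - t0, 3)}

        t0 = stage("fit")
        results = fit_all(dataset, cfg.vif, n_jobs=cfg.n_jobs)
        models_path = out / "models.tsv"
        with open(models_path, "w") as fh:
            fh.write("gene\tn_used\tadj_r2\tregulator\tcoefficient\n")
            for res in results:
                if not res.selected:
                    fh.write(f"{res.target_gene}\t{res.n_used}\t"
                             f"{res.adj_r2:.6f}\t\t\n")
                for node, coef in res.selected:
                    fh.write(f"{res.target_gene}\t{res.n_used}\t"
                             f"{res.adj_r2:.6f}\t{node}\t{coef:.6g}\n")
        manifest["stages"]["fit"] = {
            "n_models": len(results),
            "n_usable": sum(r.usable for r in results),
            "out": str(models_path), "sha256": _sha256(models_path),
            "seconds": round(time.perf_counter() - t0, 3)}

        t0 = stage("assemble")
        net = network_assembly.assemble(results, cutoff=cfg.cutoff)
        net_path = out / "network.tsv"
        write_network(net, net_path, "edge_tsv")
        stats = network_assembly.network_stats(net)
        manifest["stages"]["assemble"] = {
            "cutoff": cfg.cutoff, "n_nodes": stats.n_nodes,
            "n_edges": stats.n_edges,
            "by_layer": {"mrna": stats.n_mrna, "mirna": stats.n_mirna,
                         "methylation": stats.n_methylation,
                         "cnv": stats.n_cnv},
            "out": str(net_path), "sha256": _sha256(net_path),
            "seconds": round(time.perf_counter() - t0, 3)}

        t0 = stage("subnet")
        seeds = read_seed_genes(cfg.seed_genes)
        prior = read_prior_edges(cfg.prior_edges, seed_genes=seeds)
        spec = subnetwork_extraction.SubnetworkSpec(seed_genes=seeds)
        subnet = subnetwork_extraction.extract(net, spec, prior)
        subnet_path = out / "subnetwork.tsv"
        write_network(subnet, subnet_path, "edge_tsv")
        manifest["stages"]["subnet"] = {
            "n_seeds": len(seeds), "n_nodes": subnet.n_nodes,
            "n_edges": subnet.n_edges,
            "out": str(subnet_path), "sha256": _sha256(subnet_path),
            "seconds": round(time.perf_counter() - t0, 3)}

        t0 = stage("refine")
        refined = refine(subnet, dataset, prior, cfg.bn)
        refined_path = out / "refined.graphml"
        write_network(refined, refined_path, "graphml")
        write_network(refined, out / "refined.tsv", "edge_tsv")
        manifest["stages"]["refine"] = {
            "score": refined.score,
            "n_directed": len(refined.directed_edges),
            "n_undirected": len(refined.undirected_edges),
            "out": str(refined_path), "sha256": _sha256(refined_path),
            "seconds": round(time.perf_counter() - t0, 3)}

        if cfg.survival:
            t0 = stage("survival")
            table = read_survival_table(cfg.survival)
            lr = median_split_logrank(table)
            surv_path = out / "survival_logrank.json"
            surv_path.write_text(json.dumps({
                "statistic": lr.statistic, "p_value": lr.p_value,
                "n_low": lr.n_per_group[0], "n_high": lr.n_per_group[1]},
                indent=2))
            manifest["stages"]["survival"] = {
                "statistic": lr.statistic, "p_value": lr.p_value,
                "out": str(surv_path), "sha256": _sha256(surv_path),
                "seconds": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        failed = len(manifest["stages"])
        names = ["intersect", "fit", "assemble", "subnet", "refine",
                 "survival"]
        raise RuntimeError(
            f"pipeline failed at stage "
            f"{names[min(failed, len(names) - 1)]!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
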