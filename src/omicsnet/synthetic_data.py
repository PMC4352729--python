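"""Synthetic multi-omics benchmark generator with known ground truth.

The generator emulates the structure of a TCGA-style integrated cohort at desk
scale: a log2 gene-expression matrix whose regulated genes are sparse linear
functions of a few miRNA / methylation / copy-number features, plus matched
survival data whose hazard depends on one designated driver gene.  Because the
generative model is linear-Gaussian, structure recovery by VIF regression and
Gaussian Bayesian-network scoring is a fair test of the downstream stages.

Conventions (overridable): miRNA and methylation effects on expression are
drawn negative, copy-number effects positive.  Effect sizes are drawn on the
standardized-regulator scale so every regulator contributes a comparable share
of signal variance regardless of its layer's native units; the Gaussian noise
SD is then set from the realized signal variance so the population R^2 of each
regulated gene equals ``target_r2`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (MultiOmicsDataset, OmicsLayer, write_layer)
from .networks import node_id
from .survival_analysis import SurvivalTable, write_survival_table


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults give 650 candidate regulators against 150 samples (p >> n, as in
    the motivating application) while running in seconds.
    """

    n_samples: int = 150
    n_genes: int = 200
    n_mirna: int = 50
    n_meth: int = 200
    n_cnv: int = 200
    k_min: int = 2
    k_max: int = 5
    target_r2: float = 0.6
    frac_regulated: float = 0.5
    effect_low: float = 0.8            # |effect| on the standardized scale
    effect_high: float = 1.2
    sign_conventions: bool = True      # mirna/meth negative, cnv positive
    baseline_hazard: float = 0.1       # events per unit time at mean expression
    log_hr_per_sd: float = 1.0         # log hazard ratio per SD of the driver
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_mirna", "n_meth", "n_cnv"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 < self.target_r2 < 1.0:
            raise ConfigError("target_r2 must lie strictly inside (0, 1)")
        if not 0.0 <= self.frac_regulated <= 1.0:
            raise ConfigError("frac_regulated must lie in [0, 1]")
        if not 1 <= self.k_min <= self.k_max:
            raise ConfigError("need 1 <= k_min <= k_max")
        if self.k_max > self.n_mirna + self.n_meth + self.n_cnv:
            raise ConfigError("k_max exceeds the available regulator pool")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigError("censoring_rate must lie in [0, 1)")


@dataclass
class GroundTruth:
    """True regulator->gene edges, per-target noise, and the survival driver."""

    true_edges: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: dict[str, float] = field(default_factory=dict)
    driver_gene: str = ""
    seed: int = 0

    def edges_of(self, gene: str) -> set[str]:
        return {reg for reg, tgt, _ in self.true_edges if tgt == gene}

    def regulated_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, tgt, _ in self.true_edges:
            seen.setdefault(tgt)
        return list(seen)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(reg, tgt) for reg, tgt, _ in self.true_edges}


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _feature_names(prefix: str, n: int, genes: list[str]) -> list[str]:
    """Per-gene layers reuse gene symbols; overflow features get fresh names."""
    names = genes[:n]
    names += [f"{prefix}{i:04d}" for i in range(1, n - len(names) + 1)]
    return names


def generate_dataset(cfg: SimConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw one cohort: four omics layers plus the true regulatory edges."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]
    genes = _gene_symbols(cfg.n_genes)
    mirna_ids = [f"miR-{i}" for i in range(1, cfg.n_mirna + 1)]
    meth_ids = _feature_names("MX", cfg.n_meth, genes)
    cnv_ids = _feature_names("CX", cfg.n_cnv, genes)

    mirna = rng.normal(6.0, 1.5, size=(cfg.n_mirna, cfg.n_samples))
    a = rng.uniform(0.8, 4.0, size=cfg.n_meth)
    b = rng.uniform(0.8, 4.0, size=cfg.n_meth)
    meth = rng.beta(a[:, None], b[:, None],
                    size=(cfg.n_meth, cfg.n_samples))
    cnv = rng.choice(np.arange(-2, 3),
                     p=[0.05, 0.15, 0.60, 0.15, 0.05],
                     size=(cfg.n_cnv, cfg.n_samples)).astype(float)

    pool = ([(node_id("mirna", f), mirna[i]) for i, f in enumerate(mirna_ids)]
            + [(node_id("methylation", f), meth[i]) for i, f in enumerate(meth_ids)]
            + [(node_id("cnv", f), cnv[i]) for i, f in enumerate(cnv_ids)])

    n_regulated = int(round(cfg.frac_regulated * cfg.n_genes))
    regulated = list(rng.choice(cfg.n_genes, size=n_regulated, replace=False))

    expr = rng.normal(8.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    truth = GroundTruth(seed=cfg.seed)
    for gi in regulated:
        gene = genes[gi]
        k = int(rng.integers(cfg.k_min, cfg.k_max + 1))
        idx = rng.choice(len(pool), size=k, replace=False)
        signal = np.zeros(cfg.n_samples)
        pending = []
        for j in idx:
            reg_node, x = pool[j]
            sd = x.std()
            if sd < 1e-12:      # a flat regulator carries no signal
                continue
            z = (x - x.mean()) / sd
            mag = rng.uniform(cfg.effect_low, cfg.effect_high)
            if cfg.sign_conventions:
                sign = 1.0 if reg_node.startswith("cnv:") else -1.0
            else:
                sign = rng.choice([-1.0, 1.0])
            signal += sign * mag * z
            pending.append((reg_node, gene, sign * mag / sd))
        var_signal = float(signal.var())
        if var_signal < 1e-12:
            continue
        noise_sd = float(np.sqrt(var_signal * (1.0 - cfg.target_r2)
                                 / cfg.target_r2))
        expr[gi] = 8.0 + signal + rng.normal(0.0, noise_sd, cfg.n_samples)
        truth.true_edges.extend(pending)
        truth.noise_sd[gene] = noise_sd

    truth.driver_gene = (truth.regulated_genes()[0]
                         if truth.true_edges else genes[0])

    def _layer(tag, ids, arr):
        return OmicsLayer(tag, pd.DataFrame(arr, index=ids, columns=samples))

    dataset = MultiOmicsDataset(
        mrna=_layer("mrna", genes, expr),
        mirna=_layer("mirna", mirna_ids, mirna),
        methylation=_layer("methylation", meth_ids, meth),
        cnv=_layer("cnv", cnv_ids, cnv),
        sample_ids=samples,
    )
    return dataset, truth


def generate_survival(dataset: MultiOmicsDataset, truth: GroundTruth,
                      cfg: SimConfig) -> SurvivalTable:
    """Exponential event times whose log hazard is linear in the driver
    gene's standardized expression, with independent exponential censoring."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    if truth.driver_gene not in dataset.mrna.values.index:
        raise ConfigError(f"driver gene {truth.driver_gene!r} not in the "
                          "expression layer")
    x = dataset.mrna.values.loc[truth.driver_gene].to_numpy()
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    hazard = cfg.baseline_hazard * np.exp(cfg.log_hr_per_sd * z)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        rate_c = (cfg.baseline_hazard * cfg.censoring_rate
                  / (1.0 - cfg.censoring_rate))
        t_cens = rng.exponential(1.0 / rate_c, size=len(x))
    else:
        t_cens = np.full(len(x), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return SurvivalTable(sample_ids=list(dataset.sample_ids), time=time,
                         event=event, covariate=x)


def write_dataset(dataset: MultiOmicsDataset, truth: GroundTruth,
                  out_dir: str | Path,
                  survival: SurvivalTable | None = None) -> None:
    """Write the four layer TSVs, the truth edge TSV, and (optionally) the
    survival TSV into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for layer in dataset.layers():
        write_layer(layer, out / f"{layer.layer_tag}.tsv")
    with open(out / "truth_edges.tsv", "w") as fh:
        fh.write("regulator\ttarget\teffect\n")
        for reg, tgt, eff in truth.true_edges:
            fh.write(f"{reg}\t{tgt}\t{eff}\n")
    if survival is not None:
        write_survival_table(survival, out / "survival.tsv")
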