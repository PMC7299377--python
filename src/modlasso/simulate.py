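"""Synthetic trans-omic benchmark generator.

Real cohorts with matched genotype, brain gene-expression and proteomic data
are access-restricted, so the package ships a generator that reproduces the
*statistical structure* the modularity-constrained model assumes:

* a modular tripartite prior network — genes partitioned into modules,
  each SNP attached upstream of exactly one gene (emulating a promoter/TFBS
  relation), gene--gene and gene--protein edges drawn densely within modules
  and sparsely between them;
* a biological cascade in the data — genotypes are minor-allele dosages
  ``Binomial(2, MAF)``, gene expression responds linearly to its upstream
  SNPs, protein abundance to the mean of its interacting genes, each layer
  with Gaussian noise;
* an outcome driven by a *planted module*: a fixed fraction of one module's
  features carry true weights of constant magnitude and random sign, and
  ``y`` is their standardized-feature linear combination plus noise.

Diagnosis labels (CN/MCI/AD) are assigned by outcome tertiles purely so the
stratified cross-validation machinery can be exercised; no disease model is
claimed.  See docs/methods.md for what the generator does and does not
emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .network import TransOmicNetwork, build_network

__all__ = [
    "SimConfig",
    "MultiOmicDataset",
    "Benchmark",
    "generate_network",
    "generate_dataset",
    "simulate",
    "make_benchmark",
    "BENCHMARK_PRESETS",
]


@dataclass
class SimConfig:
    """Generator settings; defaults are the `default` benchmark conditions."""

    n_subjects: int = 200
    n_snps: int = 100
    n_genes: int = 150
    n_proteins: int = 50
    n_modules: int = 5
    planted_module_genes: int | None = 15
    within_module_edge_prob: float = 0.15
    between_module_edge_prob: float = 0.005
    maf_range: tuple[float, float] = (0.05, 0.5)
    eqtl_effect: float = 0.8
    gene_to_protein_effect: float = 0.8
    noise_sd_expr: float = 1.0
    noise_sd_protein: float = 1.0
    noise_sd_y: float = 2.0
    planted_module_index: int = 0
    causal_fraction: float = 1.0
    true_weight_scale: float = 1.0
    peptides_per_gene: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_snps, self.n_genes, self.n_proteins,
               self.n_modules) < 1:
            raise ValueError("all counts must be >= 1")
        for p in (self.within_module_edge_prob, self.between_module_edge_prob,
                  self.causal_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if not self.within_module_edge_prob > self.between_module_edge_prob:
            raise ValueError("within-module edge probability must exceed between-module")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.planted_module_index < self.n_modules:
            raise ValueError("planted_module_index out of range")
        if self.planted_module_genes is not None and not (
                1 <= self.planted_module_genes <= self.n_genes):
            raise ValueError("planted_module_genes out of range")
        if min(self.noise_sd_expr, self.noise_sd_protein, self.noise_sd_y) < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class MultiOmicDataset:
    """Feature matrix, outcome and ground truth for one simulated cohort.

    ``X`` holds raw features (SNP columns are 0/1/2 dosages), ``X_std``
    their z-scored copies (constant columns kept at 0).  The truth weights
    ``w_star`` are defined on the standardized scale: ``y = X_std @ w_star
    + noise``.
    """

    X: pd.DataFrame
    y: pd.Series
    layers: dict[str, str]
    X_std: pd.DataFrame = field(repr=False)
    diagnosis: pd.Series | None = None
    w_star: pd.Series | None = None
    support: tuple[str, ...] = ()
    modules: dict[str, int] = field(default_factory=dict)
    config: SimConfig | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class Benchmark:
    dataset: MultiOmicDataset
    network: TransOmicNetwork
    modules: dict[str, int]
    config: SimConfig


def _ids(cfg: SimConfig):
    snps = [f"rs{10000 + i}" for i in range(cfg.n_snps)]
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    prots = [f"PROT{i:04d}" for i in range(cfg.n_proteins)]
    return snps, genes, prots


def generate_network(cfg: SimConfig) -> tuple[TransOmicNetwork, dict[str, int]]:
    """Draw the modular SNP->gene->protein prior network.

    Genes are split evenly into ``n_modules`` modules.  Each SNP is assigned
    upstream of exactly one gene (inheriting its module); gene--gene and
    gene--protein edges are Bernoulli draws with the within/between module
    probabilities, and every protein is guaranteed at least one gene partner
    inside its module.  Reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    snps, genes, prots = _ids(cfg)
    modules: dict[str, int] = {}
    # gene partition: the planted module may be smaller than the others
    # (planted_module_genes genes), the rest cycle over the other modules
    if cfg.planted_module_genes is None or cfg.n_modules == 1:
        for i, g in enumerate(genes):
            modules[g] = i % cfg.n_modules
    else:
        others = [m for m in range(cfg.n_modules) if m != cfg.planted_module_index]
        for i, g in enumerate(genes):
            if i < cfg.planted_module_genes:
                modules[g] = cfg.planted_module_index
            else:
                modules[g] = others[(i - cfg.planted_module_genes) % len(others)]
    edges: list[tuple[str, str, str]] = []

    # each SNP sits upstream of exactly one gene
    snp_gene = rng.integers(0, cfg.n_genes, size=cfg.n_snps)
    for s, gi in zip(snps, snp_gene):
        modules[s] = modules[genes[gi]]
        edges.append((s, genes[gi], "tfbs"))

    # gene--gene functional interactions
    for i in range(cfg.n_genes):
        for j in range(i + 1, cfg.n_genes):
            same = modules[genes[i]] == modules[genes[j]]
            p = cfg.within_module_edge_prob if same else cfg.between_module_edge_prob
            if rng.random() < p:
                edges.append((genes[i], genes[j], "interacts"))

    # proteins: a primary "encoded-by" gene drawn uniformly over genes
    # (shared within a peptide group when peptides_per_gene > 1) plus random
    # module-structured partner edges; module membership follows the primary
    group_primary: dict[int, str] = {}
    for q_i, q in enumerate(prots):
        group = q_i // max(1, cfg.peptides_per_gene)
        if group not in group_primary:
            group_primary[group] = genes[int(rng.integers(0, cfg.n_genes))]
        primary = group_primary[group]
        modules[q] = modules[primary]
        partners = {primary}
        for g in genes:
            same = modules[g] == modules[q]
            p = cfg.within_module_edge_prob if same else cfg.between_module_edge_prob
            if rng.random() < p:
                partners.add(g)
        for g in sorted(partners):
            edges.append((g, q, "regulates"))

    layers = {s: "SNP" for s in snps}
    layers.update({g: "gene" for g in genes})
    layers.update({q: "protein" for q in prots})
    return build_network(edges, layers), modules


def generate_dataset(cfg: SimConfig, net: TransOmicNetwork,
                     modules: Mapping[str, int]) -> MultiOmicDataset:
    """Draw the genotype/expression/protein cascade and the planted outcome."""
    rng = np.random.default_rng([cfg.seed, 1])
    snps, genes, prots = _ids(cfg)
    n = cfg.n_subjects

    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    geno = rng.binomial(2, mafs, size=(n, cfg.n_snps)).astype(float)

    snp_idx = {s: i for i, s in enumerate(snps)}
    expr = np.zeros((n, cfg.n_genes))
    for j, g in enumerate(genes):
        parents = [snp_idx[s] for s in net.graph.neighbors(g)
                   if net.layers[s] == "SNP"]
        signal = cfg.eqtl_effect * geno[:, parents].sum(axis=1) if parents else 0.0
        expr[:, j] = signal + rng.normal(0.0, cfg.noise_sd_expr, size=n)

    gene_idx = {g: j for j, g in enumerate(genes)}
    prot = np.zeros((n, cfg.n_proteins))
    for q_i, q in enumerate(prots):
        parents = [gene_idx[g] for g in net.graph.neighbors(q)
                   if net.layers[g] == "gene"]
        if not parents:
            raise ValueError(f"protein {q} has no gene partner in the network")
        signal = cfg.gene_to_protein_effect * expr[:, parents].mean(axis=1)
        prot[:, q_i] = signal + rng.normal(0.0, cfg.noise_sd_protein, size=n)

    feature_ids = snps + genes + prots
    X = pd.DataFrame(np.hstack([geno, expr, prot]), columns=feature_ids,
                     index=[f"S{i:04d}" for i in range(n)])
    sd = X.std(axis=0, ddof=0)
    scale = sd.where(sd > 0, 1.0)
    X_std = (X - X.mean(axis=0)) / scale

    planted = sorted(f for f in feature_ids if modules[f] == cfg.planted_module_index)
    if not planted:
        raise ValueError("planted module is empty")
    n_causal = max(1, int(round(cfg.causal_fraction * len(planted))))
    support = sorted(rng.choice(planted, size=n_causal, replace=False).tolist())
    w_star = pd.Series(0.0, index=feature_ids, name="w_star")
    signs = rng.choice([-1.0, 1.0], size=n_causal)
    w_star.loc[support] = signs * cfg.true_weight_scale
    if cfg.true_weight_scale == 0.0:
        support = []  # no-signal (null) condition: empty true support

    y = pd.Series(
        X_std.to_numpy() @ w_star.to_numpy()
        + rng.normal(0.0, cfg.noise_sd_y, size=n),
        index=X.index, name="y",
    )

    # outcome tertiles stand in for diagnosis strata (low score -> AD)
    t1, t2 = np.quantile(y, [1 / 3, 2 / 3])
    diagnosis = pd.Series(
        np.where(y <= t1, "AD", np.where(y <= t2, "MCI", "CN")),
        index=X.index, name="diagnosis",
    )
    return MultiOmicDataset(
        X=X, y=y, layers=dict(net.layers), X_std=X_std, diagnosis=diagnosis,
        w_star=w_star, support=tuple(support), modules=dict(modules), config=cfg,
    )


def simulate(cfg: SimConfig) -> Benchmark:
    """Convenience wrapper: network + dataset from one config."""
    net, modules = generate_network(cfg)
    data = generate_dataset(cfg, net, modules)
    return Benchmark(dataset=data, network=net, modules=modules, config=cfg)


BENCHMARK_PRESETS: dict[str, dict] = {
    # n=200, p=300 (100 SNPs / 150 genes / 50 proteins), 5 modules; the
    # planted module holds 15 genes plus its attached SNPs/proteins
    # (~30 features), all causal
    "default": {},
    "small": {"n_subjects": 40, "n_snps": 10, "n_genes": 15, "n_proteins": 5,
              "n_modules": 3, "planted_module_genes": 5,
              "within_module_edge_prob": 0.5,
              "between_module_edge_prob": 0.05},
    "null": {"true_weight_scale": 0.0},
}


def make_benchmark(name: str = "default", seed: int = 0) -> Benchmark:
    """Named fixture bundles: ``default``, ``small`` and ``null`` (no signal)."""
    if name not in BENCHMARK_PRESETS:
        raise ValueError(
            f"unknown benchmark {name!r}; expected one of {sorted(BENCHMARK_PRESETS)}"
        )
    cfg = SimConfig(seed=seed, **BENCHMARK_PRESETS[name])
    return simulate(cfg)
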