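"""Synthetic hypermutator-evolution datasets for end-to-end testing.

The generator emulates a long-term evolution experiment observed through
metagenomic time series: a bacterial genome of ~4,200 protein-coding genes,
a panel of hypermutator and nonmutator populations evolving for 60,000
generations, per-gene mRNA/protein abundances, and a protein-protein
interaction network.

Model
-----
Rather than forward population-genetic simulation, mutations are generated
under an *observable-mutation thinning* model. Candidate point mutations
arise in each hypermutator population as a Poisson process proportional to
gene length (rate ``mu_h`` per nucleotide over the horizon). Each candidate
is synonymous with probability ``frac_syn``, otherwise nonsynonymous
(missense:nonsense 9:1). Purifying selection is abundance-coupled: a
nonsynonymous candidate in gene g is removed — never reaches an observable
allele frequency — with probability

    pi_g = expit(beta * z_g),

where ``z_g`` is the gene's standardized log-abundance and ``beta >= 0`` the
selection coupling. ``beta = 0`` thins uniformly (pi = 1/2 everywhere);
larger ``beta`` removes nonsynonymous mutations preferentially from highly
expressed genes, producing the expression-rate anticorrelation. Synonymous
candidates are retained at a rate multiplied by ``1 + gamma * max(z_g, 0)``
and renormalized so the genome-wide expected synonymous total is independent
of ``gamma`` — the bias is purely distributional. Surviving mutations get a
first-observation generation uniform on (0, horizon].

Nonmutator populations arise at rate ``mu_n`` (two orders of magnitude
lower) with no selection thinning, plus an optional positive-selection
channel concentrating extra mutations in a small random target-gene set,
mimicking the parallel adaptive targets of real evolution experiments.

Abundances are log-normal (spanning several orders of magnitude) and
correlated across growth conditions through a shared Gaussian factor; PPI
degrees have expectation increasing in abundance with coupling ``delta``
(``delta = 0`` decouples them), realized by configuration-model stub
pairing with self-loops and multi-edges rejected.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml
from scipy.special import expit

from .io import (
    write_abundance_tables,
    write_gene_annotations,
    write_mutation_table,
    write_ppi_edgelist,
)
from .ppi import DegreeMap, degree
from .types import (
    AbundanceTable,
    ConfigError,
    GeneAnnotation,
    MutationClass,
    MutationRecord,
    PPINetwork,
    PopulationClass,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedDataset",
    "generate_genome",
    "generate_covariates",
    "simulate_mutation_tables",
    "simulate_dataset",
    "write_dataset",
]

# RNG substream tags so each stage draws from an independent, reproducible
# stream of the configured seed.
_STAGE_GENOME = 1
_STAGE_COVARIATES = 2
_STAGE_MUTATIONS = 3


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic experiment.

    Rates are per nucleotide per population integrated over the full
    horizon, so ``mu_h * L_g`` is the expected number of candidate point
    mutations arising in gene g in one hypermutator population over the
    whole experiment.
    """

    n_genes: int = 4200
    #: log-normal gene length parameters (natural log of nucleotides);
    #: median ~800 nt with a realistic right tail.
    length_meanlog: float = math.log(800.0)
    length_sdlog: float = 0.55
    #: log-normal abundance parameters (arbitrary units, ~3 orders of
    #: magnitude of spread) and the growth conditions measured.
    abundance_meanlog: float = 5.0
    abundance_sdlog: float = 1.6
    conditions: Tuple[str, ...] = ("exponential", "stationary")
    #: correlation of log-abundance between conditions (Gaussian scale).
    condition_corr: float = 0.8
    n_hypermutator: int = 6
    n_nonmutator: int = 6
    horizon: int = 60_000
    #: observable-candidate arrival rates per nt per population over the
    #: horizon; hypermutator ~100x the nonmutator rate.
    mu_h: float = 6e-4
    mu_n: float = 6e-6
    #: fraction of arising point mutations that are synonymous.
    frac_syn: float = 0.25
    #: missense fraction within nonsynonymous candidates.
    missense_fraction: float = 0.9
    #: selection coupling: strength of abundance-dependent removal of
    #: nonsynonymous candidates.
    beta: float = 2.0
    #: expression-coupled synonymous rate bias.
    gamma: float = 1.0
    #: abundance-PPI-degree coupling.
    delta: float = 1.0
    mean_degree: float = 8.0
    #: nonmutator positive-selection channel: number of target genes and
    #: their candidate-rate multiplier (0 targets disables the channel).
    n_target_genes: int = 20
    target_boost: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_hypermutator < 1 or self.n_nonmutator < 1:
            raise ConfigError("population counts must be >= 1")
        for name in ("mu_h", "mu_n", "beta", "gamma", "delta", "target_boost"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not 0.0 <= self.frac_syn <= 1.0:
            raise ConfigError("frac_syn must be in [0, 1]")
        if not 0.0 <= self.missense_fraction <= 1.0:
            raise ConfigError("missense_fraction must be in [0, 1]")
        if not -1.0 <= self.condition_corr <= 1.0:
            raise ConfigError("condition_corr must be in [-1, 1]")
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["conditions"] = list(self.conditions)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown simulation option(s): {sorted(unknown)}")
        if "conditions" in data:
            data = dict(data)
            data["conditions"] = tuple(data["conditions"])
        return cls(**data)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth latent state of one simulated dataset.

    Used by parameter-recovery tests: ``pi`` holds the per-gene removal
    probabilities of nonsynonymous candidates (monotone nondecreasing in
    abundance when ``beta > 0``) and ``z`` the standardized log-abundances
    they derive from.
    """

    config: SimulationConfig
    z: Dict[str, float]
    pi: Dict[str, float]
    degrees: DegreeMap
    n_pairing_retries: int = 0

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [
            {
                "gene_id": g,
                "z": self.z[g],
                "pi": self.pi[g],
                "degree": self.degrees.values.get(g, 0),
            }
            for g in sorted(self.z)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SimulatedDataset:
    """A complete synthetic input bundle."""

    config: SimulationConfig
    annotations: List[GeneAnnotation]
    abundances: List[AbundanceTable]
    network: PPINetwork
    truth: SyntheticTruth
    records: List[MutationRecord]


def generate_genome(config: SimulationConfig) -> List[GeneAnnotation]:
    """Draw ``n_genes`` non-overlapping genes on a single circular reference.

    Lengths are log-normal, rounded to a positive multiple of 3 (whole
    codons); genes are laid end to end with short intergenic gaps.
    """
    rng = np.random.default_rng([_STAGE_GENOME, config.seed])
    raw = rng.lognormal(config.length_meanlog, config.length_sdlog, config.n_genes)
    lengths = np.maximum(3, (np.round(raw / 3).astype(np.int64)) * 3)
    gaps = rng.geometric(1.0 / 100.0, config.n_genes)  # mean ~100 nt
    strands = rng.choice(["+", "-"], config.n_genes)
    width = len(str(config.n_genes))
    annotations = []
    pos = 0
    for i in range(config.n_genes):
        start = pos
        end = start + int(lengths[i])
        annotations.append(
            GeneAnnotation(
                gene_id=f"SYN_{i + 1:0{width}d}",
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        pos = end + int(gaps[i])
    return annotations


def _abundance_logs(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n_genes, n_conditions) correlated log-abundances via a shared factor."""
    n, k = config.n_genes, len(config.conditions)
    rho = config.condition_corr
    shared = rng.standard_normal(n)
    if rho >= 0:
        noise = rng.standard_normal((n, k))
        u = math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * noise
    else:  # anti-correlated pair support (k=2 only makes strict sense)
        noise = rng.standard_normal((n, k))
        signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        u = math.sqrt(-rho) * shared[:, None] * signs + math.sqrt(1.0 + rho) * noise
    return config.abundance_meanlog + config.abundance_sdlog * u


def generate_covariates(
    config: SimulationConfig, annotations: Sequence[GeneAnnotation]
) -> Tuple[List[AbundanceTable], PPINetwork, SyntheticTruth]:
    """Generate abundances, a PPI network and the latent truth.

    Expected PPI degree increases in abundance with coupling ``delta``
    (delta = 0 makes degree independent of abundance); the network is
    realized by configuration-model stub pairing with self-loops and
    multi-edges rejected, resampling the degree sequence if it is
    infeasible (all-zero).
    """
    import networkx as nx

    rng = np.random.default_rng([_STAGE_COVARIATES, config.seed])
    gene_ids = [a.gene_id for a in annotations]
    n = len(gene_ids)
    if n != config.n_genes:
        raise ConfigError(
            f"annotation set has {n} genes but config.n_genes = {config.n_genes}"
        )

    logs = _abundance_logs(config, rng)
    abundances = [
        AbundanceTable(
            condition_id=cond,
            values=dict(zip(gene_ids, np.exp(logs[:, j]))),
        )
        for j, cond in enumerate(config.conditions)
    ]

    mean_log = logs.mean(axis=1)
    sd = mean_log.std()
    z = (mean_log - mean_log.mean()) / sd if sd > 0 else np.zeros(n)
    pi = expit(config.beta * z)

    lam = np.exp(config.delta * z)
    lam *= config.mean_degree / lam.mean()
    retries = 0
    while True:
        target_degrees = rng.poisson(lam)
        if target_degrees.sum() > 0:
            break
        retries += 1
        if retries > 100:
            raise ConfigError("could not draw a feasible PPI degree sequence")
    if target_degrees.sum() % 2 == 1:  # stub pairing needs an even stub count
        target_degrees[int(rng.integers(n))] += 1
    multigraph = nx.configuration_model(
        list(target_degrees), seed=int(rng.integers(2**31 - 1))
    )
    edges = set()
    for a, b in multigraph.edges():
        if a == b:
            continue  # rejected self-loop
        edges.add((gene_ids[a], gene_ids[b]) if a < b else (gene_ids[b], gene_ids[a]))
    network = PPINetwork.from_edges(edges, network_id="synthetic_ppi")

    truth = SyntheticTruth(
        config=config,
        z=dict(zip(gene_ids, z)),
        pi=dict(zip(gene_ids, pi)),
        degrees=degree(network),
        n_pairing_retries=retries,
    )
    return abundances, network, truth


def _expand_records(
    population_id: str,
    population_class: PopulationClass,
    gene_ids: Sequence[str],
    counts_by_class: Dict[MutationClass, np.ndarray],
    horizon: int,
    rng: np.random.Generator,
) -> List[MutationRecord]:
    records: List[MutationRecord] = []
    gene_arr = np.asarray(gene_ids, dtype=object)
    for mut_class, counts in counts_by_class.items():
        total = int(counts.sum())
        if total == 0:
            continue
        genes = np.repeat(gene_arr, counts)
        gens = rng.integers(1, horizon + 1, size=total)
        records.extend(
            MutationRecord(
                population_id=population_id,
                population_class=population_class,
                gene_id=g,
                mutation_class=mut_class,
                generation_observed=int(t),
            )
            for g, t in zip(genes, gens)
        )
    return records


def simulate_mutation_tables(
    config: SimulationConfig,
    annotations: Sequence[GeneAnnotation],
    truth: SyntheticTruth,
    seed: int | None = None,
) -> List[MutationRecord]:
    """Draw the ever-observed mutation table for every population.

    ``seed`` overrides the mutation-stage seed (the genome and covariates
    stay fixed), which is how replicate mutation tables are drawn over a
    shared synthetic genome.
    """
    rng = np.random.default_rng(
        [_STAGE_MUTATIONS, config.seed if seed is None else seed]
    )
    gene_ids = [a.gene_id for a in annotations]
    lengths = np.array([a.length_nt for a in annotations], dtype=float)
    z = np.array([truth.z[g] for g in gene_ids])
    pi = np.array([truth.pi[g] for g in gene_ids])

    # Synonymous rate multiplier, renormalized so the expected genome-wide
    # synonymous total does not depend on gamma.
    w = 1.0 + config.gamma * np.maximum(z, 0.0)
    w_norm = w * (lengths.sum() / (lengths * w).sum())

    records: List[MutationRecord] = []

    for p in range(config.n_hypermutator):
        pop_id = f"H{p + 1}"
        n_syn = rng.poisson(config.frac_syn * config.mu_h * lengths * w_norm)
        n_nonsyn_cand = rng.poisson((1.0 - config.frac_syn) * config.mu_h * lengths)
        n_nonsyn = rng.binomial(n_nonsyn_cand, 1.0 - pi)  # selection thinning
        n_missense = rng.binomial(n_nonsyn, config.missense_fraction)
        n_nonsense = n_nonsyn - n_missense
        records.extend(
            _expand_records(
                pop_id,
                PopulationClass.HYPERMUTATOR,
                gene_ids,
                {
                    MutationClass.SYNONYMOUS: n_syn,
                    MutationClass.MISSENSE: n_missense,
                    MutationClass.NONSENSE: n_nonsense,
                },
                config.horizon,
                rng,
            )
        )

    # Positive-selection channel for nonmutators: a small shared random
    # target set accrues candidates at target_boost times the base rate.
    boost = np.ones(len(gene_ids))
    if config.n_target_genes > 0 and config.target_boost > 0:
        targets = rng.choice(
            len(gene_ids), size=min(config.n_target_genes, len(gene_ids)), replace=False
        )
        boost[targets] = config.target_boost

    for p in range(config.n_nonmutator):
        pop_id = f"N{p + 1}"
        rate = config.mu_n * lengths * boost
        n_syn = rng.poisson(config.frac_syn * rate)
        n_nonsyn = rng.poisson((1.0 - config.frac_syn) * rate)  # no thinning
        n_missense = rng.binomial(n_nonsyn, config.missense_fraction)
        n_nonsense = n_nonsyn - n_missense
        records.extend(
            _expand_records(
                pop_id,
                PopulationClass.NONMUTATOR,
                gene_ids,
                {
                    MutationClass.SYNONYMOUS: n_syn,
                    MutationClass.MISSENSE: n_missense,
                    MutationClass.NONSENSE: n_nonsense,
                },
                config.horizon,
                rng,
            )
        )
    return records


def simulate_dataset(
    config: SimulationConfig | None = None, **overrides
) -> SimulatedDataset:
    """Generate a full synthetic dataset (genome, covariates, mutations)."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    annotations = generate_genome(config)
    abundances, network, truth = generate_covariates(config, annotations)
    records = simulate_mutation_tables(config, annotations, truth)
    return SimulatedDataset(
        config=config,
        annotations=annotations,
        abundances=abundances,
        network=network,
        truth=truth,
        records=records,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> Dict[str, Path]:
    """Write a dataset in exactly the file dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "mutations": outdir / "mutations.csv",
        "abundances": outdir / "abundances.tsv",
        "ppi": outdir / "ppi.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "simulation_config.yaml",
    }
    write_gene_annotations(dataset.annotations, paths["annotations"])
    write_mutation_table(dataset.records, paths["mutations"])
    write_abundance_tables(dataset.abundances, paths["abundances"])
    write_ppi_edgelist(dataset.network, paths["ppi"])
    dataset.truth.to_tsv(paths["truth"])
    dataset.config.to_yaml(paths["config"])
    return paths
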