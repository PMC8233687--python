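"""Shared fixtures and scipy-free reference implementations (oracles)."""

from __future__ import annotations

import math
from typing import List, Sequence

import pytest

from mutdens import (
    GeneAnnotation,
    MutationClass,
    MutationRecord,
    PopulationClass,
    SimulationConfig,
    simulate_dataset,
)
from mutdens.types import INTERGENIC

# ---------------------------------------------------------------------------
# Brute-force oracles, deliberately independent of the package internals
# (plain-Python ranks and Pearson, no numpy/scipy).
# ---------------------------------------------------------------------------


def manual_average_ranks(values: Sequence[float]) -> List[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # ranks are 1-based; tied values share the mean
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def manual_pearson(a: Sequence[float], b: Sequence[float]) -> float:
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def brute_force_spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Explicit ranks-then-Pearson reference for Spearman's rho."""
    return manual_pearson(manual_average_ranks(x), manual_average_ranks(y))


def brute_force_counts(records, gene_ids, populations, scheme, cutoff):
    """Reference per-gene counting: a plain loop over records."""
    counts = {g: 0 for g in gene_ids}
    for r in records:
        if r.gene_id == INTERGENIC:
            continue
        if populations is not None:
            if isinstance(populations, str):
                if r.population_class.value != populations:
                    continue
            elif r.population_id not in populations:
                continue
        if scheme == "nonsynonymous":
            if r.mutation_class not in (MutationClass.MISSENSE, MutationClass.NONSENSE):
                continue
        elif scheme == "synonymous":
            if r.mutation_class is not MutationClass.SYNONYMOUS:
                continue
        if r.generation_observed > cutoff:
            continue
        counts[r.gene_id] += 1
    return counts


# ---------------------------------------------------------------------------
# Small fixed fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def small_annotations() -> List[GeneAnnotation]:
    return [
        GeneAnnotation("geneA", 0, 1500),
        GeneAnnotation("geneB", 1600, 2600, strand="-"),
        GeneAnnotation("geneC", 2700, 3000, name="yfgX"),
    ]


@pytest.fixture
def small_records() -> List[MutationRecord]:
    H, N = PopulationClass.HYPERMUTATOR, PopulationClass.NONMUTATOR
    return [
        MutationRecord("H1", H, "geneA", MutationClass.MISSENSE, 5_000),
        MutationRecord("H1", H, "geneA", MutationClass.MISSENSE, 25_000),
        MutationRecord("H2", H, "geneA", MutationClass.SYNONYMOUS, 40_000),
        MutationRecord("H2", H, "geneB", MutationClass.NONSENSE, 12_000),
        MutationRecord("H1", H, "geneB", MutationClass.INDEL, 55_000),
        MutationRecord("N1", N, "geneC", MutationClass.SYNONYMOUS, 30_000),
        MutationRecord("H1", H, INTERGENIC, MutationClass.NONCODING, 10_000),
    ]


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size dataset under the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick, reduced dataset for pipeline-level tests."""
    return simulate_dataset(SimulationConfig(n_genes=400, seed=3))
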