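"""Domain types shared across the package.

The unit of observation throughout is the *ever-observed mutation*: a
distinct allele detected at any frequency at any sequenced timepoint of a
population's metagenomic time series, recorded once with the generation at
which it was first seen. Gene-level statistics are built on top of these
records together with a gene annotation set that supplies the length
normalizer for each locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, Mapping, Set, Tuple

__all__ = [
    "MutdensError",
    "ConfigError",
    "DataError",
    "AssociationError",
    "MutationClass",
    "PopulationClass",
    "POINT_CLASSES",
    "NONSYNONYMOUS_CLASSES",
    "INTERGENIC",
    "GeneAnnotation",
    "MutationRecord",
    "AbundanceTable",
    "PPINetwork",
]


class MutdensError(Exception):
    """Base class for all package errors."""


class ConfigError(MutdensError):
    """Invalid configuration (bad schema, contradictory options)."""


class DataError(MutdensError):
    """Invalid or inconsistent input data."""


class AssociationError(MutdensError):
    """A correlation test cannot be computed (too few genes, constant input)."""


class MutationClass(str, Enum):
    """Mutation categories carried by the processed metagenomic tables."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"
    INDEL = "indel"
    SV = "sv"


class PopulationClass(str, Enum):
    """Mutation-rate phenotype of an evolving population.

    Hypermutator lineages carry broken DNA repair and accumulate nearly
    neutral mutations at ~100x the ancestral rate; their observed mutation
    spectrum is the signal the density statistic is designed for.
    """

    HYPERMUTATOR = "hypermutator"
    NONMUTATOR = "nonmutator"


#: Point-mutation classes (single-nucleotide changes within a gene).
POINT_CLASSES: frozenset = frozenset(
    {MutationClass.MISSENSE, MutationClass.NONSENSE, MutationClass.SYNONYMOUS}
)

#: The nonsynonymous scheme: missense + nonsense point mutations.
NONSYNONYMOUS_CLASSES: frozenset = frozenset(
    {MutationClass.MISSENSE, MutationClass.NONSENSE}
)

#: Sentinel gene_id for mutations that fall outside annotated genes.
INTERGENIC = "INTERGENIC"


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's identity and coordinates on the reference.

    Coordinates are stored 0-based half-open, so ``length_nt == end - start``
    with no off-by-one bookkeeping. ``length_nt`` is the per-gene normalizer
    used to turn mutation counts into densities.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(
                f"gene {self.gene_id!r}: end ({self.end}) must exceed start "
                f"({self.start}); zero/negative length is not a gene"
            )
        if self.start < 0:
            raise DataError(f"gene {self.gene_id!r}: negative start {self.start}")
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length_nt(self) -> int:
        """Gene length in nucleotides."""
        return self.end - self.start


@dataclass(frozen=True)
class MutationRecord:
    """One ever-observed allele in one population.

    ``generation_observed`` is the first timepoint (in generations) at which
    the allele was detected; the record is never re-counted at later
    timepoints. ``gene_id`` is :data:`INTERGENIC` for mutations outside
    annotated genes; such records are retained on read but excluded from all
    gene-level statistics.
    """

    population_id: str
    population_class: PopulationClass
    gene_id: str
    mutation_class: MutationClass
    generation_observed: int

    def __post_init__(self) -> None:
        if self.generation_observed < 0:
            raise DataError(
                f"record ({self.population_id}, {self.gene_id}): negative "
                f"generation {self.generation_observed}"
            )

    @property
    def is_intergenic(self) -> bool:
        return self.gene_id == INTERGENIC


@dataclass(frozen=True)
class AbundanceTable:
    """Per-gene abundance (mRNA or protein) under one growth condition.

    Missing genes are absent from ``values``, never imputed as zero: an
    abundance assay not covering a gene is different from measuring nothing.
    """

    condition_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for gene_id, v in self.values.items():
            if v < 0:
                raise DataError(
                    f"abundance table {self.condition_id!r}: negative abundance "
                    f"{v} for gene {gene_id!r}"
                )

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def __getitem__(self, gene_id: str) -> float:
        return self.values[gene_id]


def _canon_edge(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPINetwork:
    """An undirected protein-protein interaction network.

    Edges are unordered gene-id pairs stored once in canonical (sorted)
    orientation; self-loops are never stored. ``network_id`` labels the
    source edge set (e.g. a curated interaction database).
    """

    edges: frozenset  # of (gene_id_a, gene_id_b) canonical tuples
    network_id: str = "ppi"

    @classmethod
    def from_edges(
        cls, pairs: Iterable[Tuple[str, str]], network_id: str = "ppi"
    ) -> "PPINetwork":
        """Build a network from raw pairs, collapsing reciprocal duplicates
        and dropping self-loops."""
        edges = {_canon_edge(a, b) for a, b in pairs if a != b}
        return cls(edges=frozenset(edges), network_id=network_id)

    @property
    def nodes(self) -> Set[str]:
        out: Set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return iter(self.edges)


def annotations_by_id(
    annotations: Iterable[GeneAnnotation],
) -> Dict[str, GeneAnnotation]:
    """Index annotations by gene_id, enforcing uniqueness."""
    out: Dict[str, GeneAnnotation] = {}
    for ann in annotations:
        if ann.gene_id in out:
            raise DataError(f"duplicate gene_id {ann.gene_id!r} in annotation set")
        out[ann.gene_id] = ann
    return out
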