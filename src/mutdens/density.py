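"""Per-gene observed-mutation counts and length-normalized densities.

The core statistic: for a chosen set of populations, a mutation-class scheme
and a generation cutoff, count the ever-observed mutations per gene
(``m_g``) and normalize by gene length (``d_g = m_g / L_g``). Every gene in
the annotation set appears in the result, including genes with no observed
mutations — whether those zeros enter a downstream correlation is a
separate, explicit policy choice.

This deliberately ignores phylogenetic structure, clonal interference and
frequency-dependent selection: a mutation counts once if it was ever seen,
regardless of its subsequent trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import records_to_frame
from .types import (
    INTERGENIC,
    NONSYNONYMOUS_CLASSES,
    POINT_CLASSES,
    DataError,
    GeneAnnotation,
    MutationClass,
    MutationRecord,
    PopulationClass,
    annotations_by_id,
)

__all__ = [
    "SubsetDescriptor",
    "DensityTable",
    "classify",
    "count_per_gene",
    "densify",
    "mutation_density",
    "cumulative_series",
]

SCHEMES = ("all", "nonsynonymous", "synonymous")


@dataclass(frozen=True)
class SubsetDescriptor:
    """Which slice of the data a density table summarizes.

    ``populations`` is either None (every population), a population-class
    name ("hypermutator"/"nonmutator"), or an explicit tuple of population
    ids. ``point_mutations_only`` restricts scheme="all" to point mutations
    (missense, nonsense, synonymous) instead of every class.
    """

    populations: str | tuple | None = None
    scheme: str = "all"
    cutoff: int = 60_000
    point_mutations_only: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise DataError(f"unknown scheme {self.scheme!r}; expected {SCHEMES}")
        if self.cutoff < 0:
            raise DataError(f"negative generation cutoff {self.cutoff}")

    @property
    def populations_label(self) -> str:
        if self.populations is None:
            return "all_populations"
        if isinstance(self.populations, str):
            return self.populations
        return "+".join(self.populations)


@dataclass(frozen=True)
class DensityTable:
    """Per-gene mutation counts and densities for one data subset.

    ``frame`` is indexed by gene_id with columns ``length_nt`` (int),
    ``count`` (int) and, after :func:`densify`, ``density`` (float,
    mutations per nucleotide).
    """

    subset: SubsetDescriptor
    frame: pd.DataFrame

    @property
    def counts(self) -> pd.Series:
        return self.frame["count"]

    @property
    def densities(self) -> pd.Series:
        if "density" not in self.frame.columns:
            raise DataError("densities not computed yet; call densify() first")
        return self.frame["density"]

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "gene_id", out.index)
        out["populations"] = self.subset.populations_label
        out["scheme"] = self.subset.scheme
        out["cutoff"] = self.subset.cutoff
        out["point_mutations_only"] = self.subset.point_mutations_only
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DensityTable":
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "length_nt", "count", "populations", "scheme", "cutoff"}
        if required - set(df.columns):
            raise DataError(f"{path}: not a density TSV (missing columns)")
        populations = df["populations"].iloc[0] if len(df) else None
        if populations == "all_populations":
            populations = None
        elif isinstance(populations, str) and "+" in populations:
            populations = tuple(populations.split("+"))
        subset = SubsetDescriptor(
            populations=populations,
            scheme=str(df["scheme"].iloc[0]) if len(df) else "all",
            cutoff=int(df["cutoff"].iloc[0]) if len(df) else 60_000,
            point_mutations_only=bool(df["point_mutations_only"].iloc[0])
            if "point_mutations_only" in df.columns and len(df)
            else False,
        )
        frame = df.set_index("gene_id")[
            ["length_nt", "count"] + (["density"] if "density" in df.columns else [])
        ]
        return cls(subset=subset, frame=frame)


def classify(
    mutation_class: MutationClass,
    scheme: str = "all",
    point_mutations_only: bool = False,
) -> bool:
    """Does a mutation of this class enter the given counting scheme?

    scheme="nonsynonymous" includes exactly missense and nonsense;
    scheme="synonymous" includes exactly synonymous; scheme="all" includes
    every class assigned to a gene (restricted to point mutations when
    ``point_mutations_only`` is set).
    """
    mutation_class = MutationClass(mutation_class)
    if scheme == "all":
        return (mutation_class in POINT_CLASSES) if point_mutations_only else True
    if scheme == "nonsynonymous":
        return mutation_class in NONSYNONYMOUS_CLASSES
    if scheme == "synonymous":
        return mutation_class is MutationClass.SYNONYMOUS
    raise DataError(f"unknown scheme {scheme!r}; expected {SCHEMES}")


def _population_mask(frame: pd.DataFrame, populations) -> pd.Series:
    if populations is None:
        return pd.Series(True, index=frame.index)
    if isinstance(populations, str):
        try:
            pop_class = PopulationClass(populations)
        except ValueError:
            raise DataError(
                f"population selector {populations!r} is neither a population "
                f"class nor a sequence of population ids"
            ) from None
        return frame["population_class"] == pop_class.value
    return frame["population_id"].isin(list(populations))


def _scheme_mask(frame: pd.DataFrame, scheme: str, point_only: bool) -> pd.Series:
    if scheme == "all":
        if point_only:
            return frame["mutation_class"].isin([c.value for c in POINT_CLASSES])
        return pd.Series(True, index=frame.index)
    if scheme == "nonsynonymous":
        return frame["mutation_class"].isin([c.value for c in NONSYNONYMOUS_CLASSES])
    if scheme == "synonymous":
        return frame["mutation_class"] == MutationClass.SYNONYMOUS.value
    raise DataError(f"unknown scheme {scheme!r}; expected {SCHEMES}")


def count_per_gene(
    records: Sequence[MutationRecord] | pd.DataFrame,
    annotations: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
    populations: str | Sequence[str] | None = None,
    scheme: str = "all",
    cutoff: int = 60_000,
    point_mutations_only: bool = False,
) -> DensityTable:
    """Count ever-observed mutations per gene over a data subset.

    A gene's count is the number of records with that gene_id, a selected
    population, a class included by the scheme, and
    ``generation_observed <= cutoff`` (inclusive). Genes with no matching
    records get count 0; INTERGENIC records are skipped. A record naming a
    gene absent from the annotation set is a hard error.
    """
    if isinstance(annotations, Mapping):
        ann_map = dict(annotations)
    else:
        ann_map = annotations_by_id(annotations)
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)

    subset = SubsetDescriptor(
        populations=tuple(populations)
        if populations is not None and not isinstance(populations, str)
        else populations,
        scheme=scheme,
        cutoff=cutoff,
        point_mutations_only=point_mutations_only,
    )

    gene_index = pd.Index(list(ann_map), name="gene_id")
    lengths = pd.Series(
        [ann_map[g].length_nt for g in gene_index], index=gene_index, name="length_nt"
    )

    if len(frame):
        genic = frame[frame["gene_id"] != INTERGENIC]
        unknown = set(genic["gene_id"]) - set(ann_map)
        if unknown:
            raise DataError(
                f"mutation record(s) reference unknown gene_id(s): "
                f"{sorted(unknown)[:5]}"
            )
        mask = (
            _population_mask(genic, subset.populations)
            & _scheme_mask(genic, scheme, point_mutations_only)
            & (genic["generation_observed"] <= cutoff)
        )
        counts = (
            genic.loc[mask]
            .groupby("gene_id")
            .size()
            .reindex(gene_index, fill_value=0)
            .astype(np.int64)
        )
    else:
        counts = pd.Series(0, index=gene_index, dtype=np.int64)

    out = pd.DataFrame({"length_nt": lengths, "count": counts})
    return DensityTable(subset=subset, frame=out)


def densify(
    counts: DensityTable,
    annotations: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation] | None = None,
) -> DensityTable:
    """Compute ``d_g = m_g / L_g`` for every counted gene.

    ``annotations`` may re-supply lengths (they must cover every counted
    gene); by default the lengths carried in the count table are used.
    """
    frame = counts.frame.copy()
    if annotations is not None:
        ann_map = (
            dict(annotations)
            if isinstance(annotations, Mapping)
            else annotations_by_id(annotations)
        )
        missing = [g for g in frame.index if g not in ann_map]
        if missing:
            raise DataError(f"no annotation (gene length) for gene(s) {missing[:5]}")
        frame["length_nt"] = [ann_map[g].length_nt for g in frame.index]
    if (frame["length_nt"] <= 0).any():
        bad = frame.index[frame["length_nt"] <= 0][0]
        raise DataError(f"gene {bad!r} has non-positive length")
    frame["density"] = frame["count"] / frame["length_nt"]
    return DensityTable(subset=counts.subset, frame=frame)


def mutation_density(
    records: Sequence[MutationRecord] | pd.DataFrame,
    annotations: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
    populations: str | Sequence[str] | None = None,
    scheme: str = "all",
    cutoff: int = 60_000,
    point_mutations_only: bool = False,
) -> DensityTable:
    """Count and normalize in one step (count_per_gene followed by densify)."""
    if not isinstance(annotations, Mapping):
        annotations = annotations_by_id(annotations)
    counts = count_per_gene(
        records,
        annotations,
        populations=populations,
        scheme=scheme,
        cutoff=cutoff,
        point_mutations_only=point_mutations_only,
    )
    return densify(counts)


def cumulative_series(
    records: Sequence[MutationRecord] | pd.DataFrame,
    annotations: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
    populations: str | Sequence[str] | None = None,
    scheme: str = "all",
    cutoffs: Sequence[int] = (10_000, 20_000, 30_000, 40_000, 50_000, 60_000),
    point_mutations_only: bool = False,
) -> List[DensityTable]:
    """Density tables at each successive generation cutoff.

    The table at cutoff ``c`` counts mutations first observed by generation
    ``c`` (inclusive), so per-gene counts are nondecreasing along the series
    and the final table equals the plain full-horizon computation.
    """
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise DataError(f"cutoffs must be strictly ascending, got {cutoffs}")
    if not isinstance(annotations, Mapping):
        annotations = annotations_by_id(annotations)
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    return [
        mutation_density(
            frame,
            annotations,
            populations=populations,
            scheme=scheme,
            cutoff=c,
            point_mutations_only=point_mutations_only,
        )
        for c in cutoffs
    ]
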