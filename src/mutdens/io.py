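"""Readers and writers for annotations, mutation tables, abundances and PPI
edge lists.

File dialects
-------------
* Annotations: GFF3 (gene features with ID attributes; 1-based inclusive
  coordinates, converted to 0-based half-open on read) or a TSV dialect with
  columns ``gene_id, name, start_1based, end_1based, strand``.
* Mutations: CSV with header ``population_id, population_class, gene_id,
  mutation_class, generation_observed`` — one row per ever-observed allele.
* Abundances: long TSV with header ``gene_id, condition_id, abundance``.
* PPI: two-column TSV of gene-id pairs (an optional third confidence column
  is thresholded at load time).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .types import (
    INTERGENIC,
    AbundanceTable,
    DataError,
    GeneAnnotation,
    MutationClass,
    MutationRecord,
    PPINetwork,
    PopulationClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_annotations",
    "write_gene_annotations",
    "read_mutation_table",
    "write_mutation_table",
    "read_abundance_tables",
    "write_abundance_tables",
    "read_ppi_edgelist",
    "write_ppi_edgelist",
    "first_observation_from_trajectories",
]

_ANNOTATION_COLUMNS = ["gene_id", "name", "start_1based", "end_1based", "strand"]
_MUTATION_COLUMNS = [
    "population_id",
    "population_class",
    "gene_id",
    "mutation_class",
    "generation_observed",
]


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def read_gene_annotations(
    path: str | Path, format: str = "tsv"
) -> List[GeneAnnotation]:
    """Read a gene annotation set from GFF3 or the TSV dialect.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention, so a record spanning 101..400 yields
    ``start=100, end=400, length_nt=300``.

    Raises
    ------
    DataError
        On duplicate gene ids or non-positive gene lengths.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")
    if format == "gff3":
        annotations = _read_gff3(path)
    elif format == "tsv":
        annotations = _read_annotation_tsv(path)
    else:
        raise DataError(f"unknown annotation format {format!r} (use gff3 or tsv)")
    seen: set = set()
    for ann in annotations:
        if ann.gene_id in seen:
            raise DataError(f"duplicate gene_id {ann.gene_id!r} in {path}")
        seen.add(ann.gene_id)
    return annotations


def _read_gff3(path: Path) -> List[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    annotations: List[GeneAnnotation] = []
    feature_types = set(db.featuretypes())
    # Prefer explicit gene features; fall back to CDS records.
    ftype = "gene" if "gene" in feature_types else "CDS"
    for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
        ids = feat.attributes.get("ID") or feat.attributes.get("locus_tag")
        if not ids:
            raise DataError(f"{path}: {ftype} feature without ID attribute: {feat}")
        name_attr = feat.attributes.get("Name")
        annotations.append(
            GeneAnnotation(
                gene_id=ids[0],
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                name=name_attr[0] if name_attr else None,
            )
        )
    return annotations


def _read_annotation_tsv(path: Path) -> List[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing annotation columns {sorted(missing)}")
    annotations = []
    for row in df.itertuples(index=False):
        try:
            start_1b = int(row.start_1based)
            end_1b = int(row.end_1based)
        except (TypeError, ValueError) as exc:
            raise DataError(
                f"{path}: non-integer coordinates for gene {row.gene_id!r}"
            ) from exc
        name = None if pd.isna(row.name) or row.name == "" else str(row.name)
        annotations.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                start=start_1b - 1,
                end=end_1b,
                strand=str(row.strand),
                name=name,
            )
        )
    return annotations


def write_gene_annotations(
    annotations: Iterable[GeneAnnotation], path: str | Path
) -> None:
    """Write annotations in the TSV dialect (1-based inclusive coordinates)."""
    rows = [
        {
            "gene_id": a.gene_id,
            "name": a.name or "",
            "start_1based": a.start + 1,
            "end_1based": a.end,
            "strand": a.strand,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutation tables
# ---------------------------------------------------------------------------

def read_mutation_table(path: str | Path) -> List[MutationRecord]:
    """Read the flat one-row-per-ever-observed-allele CSV dialect.

    Unknown population or mutation classes are hard errors naming the
    offending row; INTERGENIC records are retained (flagged via
    ``MutationRecord.is_intergenic``) for downstream exclusion.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"mutation table not found: {path}")
    records: List[MutationRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_MUTATION_COLUMNS) - set(
            reader.fieldnames
        ):
            raise DataError(
                f"{path}: mutation CSV must have columns {_MUTATION_COLUMNS}"
            )
        for i, row in enumerate(reader, start=2):  # 1-based, after header
            try:
                pop_class = PopulationClass(row["population_class"])
            except ValueError:
                raise DataError(
                    f"{path} row {i}: unknown population_class "
                    f"{row['population_class']!r}"
                ) from None
            try:
                mut_class = MutationClass(row["mutation_class"])
            except ValueError:
                raise DataError(
                    f"{path} row {i}: unknown mutation_class "
                    f"{row['mutation_class']!r}"
                ) from None
            try:
                gen = int(row["generation_observed"])
            except ValueError:
                raise DataError(
                    f"{path} row {i}: non-integer generation "
                    f"{row['generation_observed']!r}"
                ) from None
            records.append(
                MutationRecord(
                    population_id=row["population_id"],
                    population_class=pop_class,
                    gene_id=row["gene_id"],
                    mutation_class=mut_class,
                    generation_observed=gen,
                )
            )
    if not records:
        logger.warning("mutation table %s contains no records", path)
    return records


def write_mutation_table(
    records: Iterable[MutationRecord], path: str | Path
) -> None:
    """Write records in the mutation CSV dialect (round-trips with
    :func:`read_mutation_table`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MUTATION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.population_id,
                    r.population_class.value,
                    r.gene_id,
                    r.mutation_class.value,
                    r.generation_observed,
                ]
            )


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Represent mutation records as a DataFrame (one row per record)."""
    return pd.DataFrame(
        {
            "population_id": [r.population_id for r in records],
            "population_class": [r.population_class.value for r in records],
            "gene_id": [r.gene_id for r in records],
            "mutation_class": [r.mutation_class.value for r in records],
            "generation_observed": [r.generation_observed for r in records],
        }
    )


def first_observation_from_trajectories(
    trajectories: Mapping[Tuple[str, str], Tuple[Sequence[int], Sequence[float]]],
) -> Dict[Tuple[str, str], int]:
    """Convenience converter from allele-frequency trajectories.

    Maps ``(population_id, allele_key) -> (times, frequencies)`` to the first
    generation with frequency > 0, i.e. the ``generation_observed`` of the
    flat dialect. Alleles never observed (all-zero trajectories) are omitted.
    """
    out: Dict[Tuple[str, str], int] = {}
    for key, (times, freqs) in trajectories.items():
        if len(times) != len(freqs):
            raise DataError(f"trajectory {key}: times/frequencies length mismatch")
        for t, f in sorted(zip(times, freqs)):
            if f > 0:
                out[key] = int(t)
                break
    return out


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

def read_abundance_tables(path: str | Path) -> List[AbundanceTable]:
    """Read a long-format abundance TSV into one table per condition."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"abundance table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "condition_id", "abundance"}
    if required - set(df.columns):
        raise DataError(f"{path}: abundance TSV must have columns {sorted(required)}")
    tables = []
    for condition_id, sub in df.groupby("condition_id", sort=True):
        dupes = sub["gene_id"][sub["gene_id"].duplicated()]
        if not dupes.empty:
            raise DataError(
                f"{path}: duplicate gene_id {dupes.iloc[0]!r} in condition "
                f"{condition_id!r}"
            )
        tables.append(
            AbundanceTable(
                condition_id=str(condition_id),
                values=dict(zip(sub["gene_id"].astype(str), sub["abundance"].astype(float))),
            )
        )
    return tables


def write_abundance_tables(
    tables: Iterable[AbundanceTable], path: str | Path
) -> None:
    rows = []
    for t in tables:
        for gene_id in sorted(t.values):
            rows.append(
                {
                    "gene_id": gene_id,
                    "condition_id": t.condition_id,
                    "abundance": t.values[gene_id],
                }
            )
    pd.DataFrame(rows, columns=["gene_id", "condition_id", "abundance"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

def read_ppi_edgelist(
    path: str | Path,
    network_id: str | None = None,
    min_confidence: float | None = None,
) -> PPINetwork:
    """Read a two-column TSV of interacting gene pairs.

    Reciprocal duplicates collapse to one undirected edge; self-loops are
    dropped with a logged count. If a third numeric confidence column is
    present and ``min_confidence`` is given, edges below the threshold are
    discarded (default keeps every edge, as for pre-curated sets).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"PPI edge list not found: {path}")
    pairs: List[Tuple[str, str]] = []
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if i == 1 and fields[0] in ("gene_id_a", "protein_a", "source"):
                continue  # optional header
            if len(fields) not in (2, 3):
                raise DataError(
                    f"{path} row {i}: expected 2 (or 3) tab-separated columns, "
                    f"got {len(fields)}"
                )
            a, b = fields[0], fields[1]
            if len(fields) == 3 and min_confidence is not None:
                try:
                    conf = float(fields[2])
                except ValueError:
                    raise DataError(
                        f"{path} row {i}: non-numeric confidence {fields[2]!r}"
                    ) from None
                if conf < min_confidence:
                    continue
            if a == b:
                n_self += 1
                continue
            pairs.append((a, b))
    if n_self:
        logger.info("dropped %d self-loop(s) while reading %s", n_self, path)
    return PPINetwork.from_edges(pairs, network_id=network_id or path.stem)


def write_ppi_edgelist(network: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id_a\tgene_id_b\n")
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")
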