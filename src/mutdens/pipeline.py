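"""Configuration-driven end-to-end pipeline.

A run takes either real input files (annotations, mutation table, abundance
tables, PPI edge lists) or a simulation block, sweeps an analysis grid of
population selectors x mutation-class schemes x zeros policies x generation
cutoffs against every covariate, and writes:

* ``associations.tsv`` — one Spearman test per grid cell per covariate;
* ``densities/`` — the full-horizon density table per population selector
  and scheme;
* ``degrees/`` — the degree map per PPI network;
* ``manifest.json`` — config hash, seed and library versions, enough to
  re-run bit-exactly;
* optional diagnostic plots.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .density import SCHEMES, cumulative_series, mutation_density
from .io import (
    read_abundance_tables,
    read_gene_annotations,
    read_mutation_table,
    read_ppi_edgelist,
    records_to_frame,
)
from .ppi import DegreeMap, degree
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .stats import AssociationResult, associate, results_to_frame
from .types import AssociationError, ConfigError, DataError


def _covariate_id(covariate) -> str:
    return getattr(covariate, "condition_id", None) or getattr(
        covariate, "network_id", "covariate"
    )

logger = logging.getLogger(__name__)

__all__ = ["GridSpec", "RunConfig", "load_run_config", "run"]

DEFAULT_CUTOFFS = (10_000, 20_000, 30_000, 40_000, 50_000, 60_000)


@dataclass(frozen=True)
class GridSpec:
    """The analysis grid swept by a run."""

    population_selectors: Tuple[str, ...] = ("hypermutator", "nonmutator")
    schemes: Tuple[str, ...] = ("all", "nonsynonymous", "synonymous")
    zeros_policies: Tuple[str, ...] = ("include", "exclude")
    cutoffs: Tuple[int, ...] = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        if not (
            self.population_selectors
            and self.schemes
            and self.zeros_policies
            and self.cutoffs
        ):
            raise ConfigError("analysis grid must be non-empty in every dimension")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ConfigError(f"unknown scheme {s!r} in grid")
        for z in self.zeros_policies:
            if z not in ("include", "exclude"):
                raise ConfigError(f"unknown zeros policy {z!r} in grid")


@dataclass(frozen=True)
class InputPaths:
    annotations: Path
    mutations: Path
    abundances: Optional[Path] = None
    ppi: Tuple[Path, ...] = ()
    annotation_format: str = "tsv"


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: inputs XOR a simulation block, plus the grid."""

    output_dir: Path
    inputs: Optional[InputPaths] = None
    simulation: Optional[SimulationConfig] = None
    grid: GridSpec = field(default_factory=GridSpec)
    seed: int = 0
    log_level: str = "INFO"
    plots: bool = False
    point_mutations_only: bool = False

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one of an inputs section or a simulation block is required"
            )


def load_run_config(path: str | Path) -> RunConfig:
    """Parse the YAML run-configuration schema."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")

    inputs = None
    if "inputs" in data:
        section = data["inputs"]
        try:
            ppi = section.get("ppi", [])
            if isinstance(ppi, (str, Path)):
                ppi = [ppi]
            inputs = InputPaths(
                annotations=Path(section["annotations"]),
                mutations=Path(section["mutations"]),
                abundances=Path(section["abundances"])
                if "abundances" in section
                else None,
                ppi=tuple(Path(p) for p in ppi),
                annotation_format=section.get("annotation_format", "tsv"),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: inputs section missing {exc}") from None

    simulation = None
    if "simulation" in data:
        sim_data = dict(data["simulation"] or {})
        if "seed" not in sim_data and "seed" in data:
            sim_data["seed"] = int(data["seed"])
        simulation = SimulationConfig.from_dict(sim_data)

    grid_data = data.get("grid", {})
    grid = GridSpec(
        population_selectors=tuple(
            grid_data.get("population_selectors", ("hypermutator", "nonmutator"))
        ),
        schemes=tuple(grid_data.get("schemes", ("all", "nonsynonymous", "synonymous"))),
        zeros_policies=tuple(grid_data.get("zeros", ("include", "exclude"))),
        cutoffs=tuple(int(c) for c in grid_data.get("cutoffs", DEFAULT_CUTOFFS)),
    )

    if "output_dir" not in data:
        raise ConfigError(f"{path}: output_dir is required")
    return RunConfig(
        output_dir=Path(data["output_dir"]),
        inputs=inputs,
        simulation=simulation,
        grid=grid,
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
        plots=bool(data.get("plots", False)),
        point_mutations_only=bool(data.get("point_mutations_only", False)),
    )


def _config_digest(config: RunConfig) -> str:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    canonical = json.dumps(encode(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _load_inputs(config: RunConfig):
    inputs = config.inputs
    annotations = read_gene_annotations(
        inputs.annotations, format=inputs.annotation_format
    )
    records = read_mutation_table(inputs.mutations)
    abundances = (
        read_abundance_tables(inputs.abundances) if inputs.abundances else []
    )
    networks = [read_ppi_edgelist(p) for p in inputs.ppi]
    return annotations, records, abundances, networks


def run(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline; returns the association table it wrote."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "densities").mkdir(exist_ok=True)
    (outdir / "degrees").mkdir(exist_ok=True)

    t0 = time.perf_counter()
    if config.simulation is not None:
        logger.info("stage simulate: generating synthetic dataset")
        dataset = simulate_dataset(config.simulation)
        write_dataset(dataset, outdir / "simulated_inputs")
        annotations = dataset.annotations
        records = dataset.records
        abundances = dataset.abundances
        networks = [dataset.network]
    else:
        logger.info("stage load: reading input files")
        annotations, records, abundances, networks = _load_inputs(config)
    logger.info("stage load/simulate done in %.2fs", time.perf_counter() - t0)

    degree_maps = [degree(net) for net in networks]
    for dm in degree_maps:
        dm.to_tsv(outdir / "degrees" / f"{dm.network_id}.tsv")

    covariates = list(abundances) + list(degree_maps)
    if not covariates:
        raise DataError("no covariates: provide abundances and/or PPI edge lists")

    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    results: List[AssociationResult] = []
    t1 = time.perf_counter()
    for selector in config.grid.population_selectors:
        for scheme in config.grid.schemes:
            series = cumulative_series(
                frame,
                annotations,
                populations=selector,
                scheme=scheme,
                cutoffs=config.grid.cutoffs,
                point_mutations_only=config.point_mutations_only,
            )
            series[-1].to_tsv(outdir / "densities" / f"{selector}_{scheme}.tsv")
            for covariate in covariates:
                for zeros in config.grid.zeros_policies:
                    for table in series:
                        try:
                            results.append(
                                associate(table, covariate, zeros=zeros)
                            )
                        except AssociationError as exc:
                            # a cell whose test is undefined (too few genes
                            # after filtering, constant covariate) keeps its
                            # row in the report with NaN statistics
                            logger.warning(
                                "undefined association for %s/%s/%s cutoff %d: %s",
                                selector, scheme, zeros, table.subset.cutoff, exc,
                            )
                            results.append(
                                AssociationResult(
                                    rho=float("nan"),
                                    p_value=float("nan"),
                                    n=0,
                                    covariate_id=_covariate_id(covariate),
                                    zeros=zeros,
                                    subset=table.subset,
                                )
                            )
    logger.info("stage correlate done in %.2fs", time.perf_counter() - t1)

    report = results_to_frame(results)
    report.to_csv(outdir / "associations.tsv", sep="\t", index=False)

    manifest = {
        "mutdens_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_digest(config),
        "n_genes": len(annotations),
        "n_records": len(frame),
        "n_association_rows": len(report),
        "versions": _library_versions(),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if config.plots:
        from .plots import plot_density_vs_covariate, plot_rho_time_course

        plotdir = outdir / "plots"
        plotdir.mkdir(exist_ok=True)
        plot_rho_time_course(report, plotdir / "rho_time_course.png")
        if abundances:
            table = mutation_density(
                frame, annotations, populations="hypermutator", scheme="all",
                cutoff=max(config.grid.cutoffs),
            )
            plot_density_vs_covariate(
                table, abundances[0], plotdir / "density_vs_abundance.png"
            )
    return report


def _library_versions() -> Dict[str, str]:
    import numpy
    import scipy

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
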