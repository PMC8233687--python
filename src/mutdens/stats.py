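"""Rank-based association between mutation density and gene-level covariates.

Spearman's rank correlation with two-sided tests against rho = 0, matching
standard statistical practice for expression-rate (E-R) correlation
analyses: ties share average ranks, and the p-value uses the t-distribution
approximation with n - 2 degrees of freedom. For very small samples
(n < 10), where that approximation degrades, an exact permutation p-value is
computed instead by full enumeration.

A test's gene universe is always the *intersection* of the density table and
the covariate — genes without a covariate measurement are dropped, never
imputed as zero, because "not measured" cannot be distinguished from "not
expressed" in the inputs. Genes with zero observed mutations are kept by
default (``zeros="include"``) and dropped under ``zeros="exclude"``, the
standard sensitivity analysis for count-based densities.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .density import DensityTable, SubsetDescriptor
from .types import AbundanceTable, AssociationError

__all__ = [
    "AssociationResult",
    "spearman_two_sided",
    "associate",
    "correlation_time_course",
    "results_to_frame",
    "EXACT_PERMUTATION_MAX_N",
]

#: below this sample size the two-sided p-value is computed by exact
#: enumeration of all n! permutations instead of the t approximation.
EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class AssociationResult:
    """One Spearman test: rho, two-sided p, sample size, and provenance."""

    rho: float
    p_value: float
    n: int
    covariate_id: str = ""
    zeros: str = "include"
    subset: SubsetDescriptor | None = None

    def to_row(self) -> dict:
        subset = self.subset or SubsetDescriptor()
        return {
            "covariate_id": self.covariate_id,
            "populations": subset.populations_label,
            "scheme": subset.scheme,
            "cutoff": subset.cutoff,
            "zeros": self.zeros,
            "n": self.n,
            "rho": self.rho,
            "p_value": self.p_value,
        }


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise AssociationError("correlation undefined: constant input vector")
    return float(rx @ ry) / denom


@functools.lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating every permutation of one rank vector."""
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    perms = _all_permutations(len(rx))
    rhos = (ryc[perms] @ rxc) / denom
    count = int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
    return count / len(perms)


def spearman_two_sided(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Spearman rho and two-sided p-value for rho != 0.

    Ties receive average ranks. For n >= 10 the p-value uses the
    t-approximation with n - 2 degrees of freedom (the conventional
    large-sample test); for n < 10 it is exact by permutation enumeration.

    Raises
    ------
    AssociationError
        If the vectors differ in length, n < 3, or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AssociationError(
            f"x and y must be 1-D vectors of equal length, got {x.shape} vs {y.shape}"
        )
    n = len(x)
    if n < 3:
        raise AssociationError(f"need at least 3 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise AssociationError("correlation undefined: constant input vector")
    if n < EXACT_PERMUTATION_MAX_N:
        rx, ry = _average_ranks(x), _average_ranks(y)
        rho = _rho_from_ranks(rx, ry)
        p = _exact_permutation_p(rx, ry, rho)
        return rho, p
    res = sps.spearmanr(x, y, alternative="two-sided")
    rho = float(res.statistic)
    p = float(res.pvalue)
    # |rho| == 1 gives an infinite t statistic; the approximation returns 0,
    # clamp into the open-closed interval (0, 1].
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return rho, p


def _covariate_values(
    covariate: AbundanceTable | Mapping[str, float],
) -> Tuple[str, Mapping[str, float]]:
    if isinstance(covariate, AbundanceTable):
        return covariate.condition_id, covariate.values
    if isinstance(covariate, Mapping):
        return "covariate", covariate
    network_id = getattr(covariate, "network_id", None)
    values = getattr(covariate, "values", None)
    if not isinstance(values, Mapping):
        raise AssociationError(
            "covariate must be an AbundanceTable, DegreeMap or mapping "
            "gene_id -> value"
        )
    return network_id or "covariate", values


def associate(
    density: DensityTable,
    covariate: AbundanceTable | Mapping[str, float],
    zeros: str = "include",
    covariate_id: str | None = None,
) -> AssociationResult:
    """Spearman test of per-gene mutation density against a covariate.

    The gene set is the intersection of the density table and the covariate;
    ``zeros="exclude"`` additionally drops genes with zero observed
    mutations before testing. The reported ``n`` is the post-filter size.
    """
    if zeros not in ("include", "exclude"):
        raise AssociationError(f"zeros policy must be include/exclude, got {zeros!r}")
    default_id, values = _covariate_values(covariate)
    frame = density.frame
    if "density" not in frame.columns:
        raise AssociationError("density table has no densities; call densify() first")
    genes = [g for g in frame.index if g in values]
    sub = frame.loc[genes]
    if zeros == "exclude":
        sub = sub[sub["count"] > 0]
    n = len(sub)
    if n < 3:
        raise AssociationError(
            f"only {n} gene(s) shared between density table and covariate "
            f"after filtering; need at least 3"
        )
    x = np.array([values[g] for g in sub.index], dtype=float)
    y = sub["density"].to_numpy()
    rho, p = spearman_two_sided(x, y)
    return AssociationResult(
        rho=rho,
        p_value=p,
        n=n,
        covariate_id=covariate_id or default_id,
        zeros=zeros,
        subset=density.subset,
    )


def correlation_time_course(
    series: Sequence[DensityTable],
    covariate: AbundanceTable | Mapping[str, float],
    zeros: str = "include",
    covariate_id: str | None = None,
) -> List[AssociationResult]:
    """One association per cumulative cutoff.

    Applied to the output of :func:`mutdens.density.cumulative_series`; the
    final element equals a direct full-horizon :func:`associate`.
    """
    return [
        associate(table, covariate, zeros=zeros, covariate_id=covariate_id)
        for table in series
    ]


def results_to_frame(
    results: Iterable[AssociationResult], bh_adjust: bool = False
) -> pd.DataFrame:
    """Tabulate association results, one row per panel.

    ``bh_adjust=True`` appends a Benjamini-Hochberg adjusted q-value column
    across the collected rows (off by default: per-panel p-values are the
    primary report).
    """
    df = pd.DataFrame([r.to_row() for r in results])
    if bh_adjust and len(df):
        df["q_value"] = sps.false_discovery_control(
            df["p_value"].to_numpy(), method="bh"
        )
    return df
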