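"""Per-gene interaction degree from protein-protein interaction networks."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping

import networkx as nx
import pandas as pd

from .types import DataError, PPINetwork

__all__ = ["DegreeMap", "degree", "to_networkx"]


@dataclass(frozen=True)
class DegreeMap:
    """gene_id -> number of distinct interaction partners in one network.

    Only genes appearing in the network carry an entry; genes absent from
    the edge set are absent from the map (the association layer intersects
    gene sets, so they simply drop out of a degree-based test). Use
    :meth:`with_zero_imputed` to instead treat such genes as degree 0.
    """

    values: Mapping[str, int]
    network_id: str = "ppi"

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, gene_id: str) -> int:
        return self.values[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def with_zero_imputed(self, gene_ids) -> "DegreeMap":
        """Extend the map with degree 0 for the listed genes not in it."""
        values = dict(self.values)
        for g in gene_ids:
            values.setdefault(g, 0)
        return DegreeMap(values=values, network_id=self.network_id)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene_id": g, "degree": d, "network_id": self.network_id}
            for g, d in sorted(self.values.items())
        ]
        pd.DataFrame(rows, columns=["gene_id", "degree", "network_id"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DegreeMap":
        df = pd.read_csv(path, sep="\t")
        if {"gene_id", "degree"} - set(df.columns):
            raise DataError(f"{path}: not a degree TSV")
        network_id = (
            str(df["network_id"].iloc[0])
            if "network_id" in df.columns and len(df)
            else "ppi"
        )
        return cls(
            values=dict(zip(df["gene_id"].astype(str), df["degree"].astype(int))),
            network_id=network_id,
        )


def to_networkx(network: PPINetwork) -> nx.Graph:
    """The network as an undirected simple :class:`networkx.Graph`."""
    g = nx.Graph()
    g.add_edges_from(network.edges)
    return g


def degree(network: PPINetwork) -> DegreeMap:
    """Unweighted, undirected, distinct-partner degree of every node.

    The sum of degrees equals twice the edge count (handshake identity),
    guaranteed by construction since the network stores each unordered pair
    once and never stores self-loops.
    """
    g = to_networkx(network)
    return DegreeMap(
        values={node: int(d) for node, d in g.degree()},
        network_id=network.network_id,
    )
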