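"""Pearson co-expression network over periodic genes.

Edges connect gene pairs whose replicate-mean series correlate at or
above a signed cutoff (the default 0.7 keeps positively co-expressed
pairs only; absolute-value mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .expression import SeriesMatrix

__all__ = ["CoexpressionNetwork", "pcc_matrix", "build_gcn", "gcn_stats"]


@dataclass
class CoexpressionNetwork:
    """Undirected correlation network: nodes are genes with ≥ 1 passing edge."""

    graph: nx.Graph
    cutoff: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_frame(self) -> pd.DataFrame:
        rows = [(u, v, d["pcc"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc"])

    def to_tsv(self, path) -> None:
        self.edges_frame().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def pcc_matrix(series: SeriesMatrix) -> np.ndarray:
    """All-pairs Pearson correlation matrix of the gene series.

    Requires ≥ 3 timepoints and no constant genes (their correlation is
    undefined); symmetric with unit diagonal.
    """
    if series.hours.size < 3:
        raise ValueError("need >= 3 timepoints for correlation")
    sd = series.values.std(axis=1, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant gene(s) have undefined correlation: "
                         f"{[series.genes[i] for i in bad[:5]]}")
    r = np.corrcoef(series.values)
    np.fill_diagonal(r, 1.0)
    return r


def build_gcn(pcc: np.ndarray, genes: list[str], cutoff: float = 0.7,
              absolute: bool = False) -> CoexpressionNetwork:
    """Threshold the correlation matrix into an undirected network.

    Edge (i, j), i < j, iff r(i, j) ≥ cutoff (or |r| ≥ cutoff with
    ``absolute``); self-edges never included; nodes are genes incident to
    at least one edge.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    score = np.abs(pcc) if absolute else pcc
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = score[iu, ju] >= cutoff
    g = nx.Graph()
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(genes[i], genes[j], pcc=float(pcc[i, j]))
    return CoexpressionNetwork(g, cutoff)


def gcn_stats(network: CoexpressionNetwork) -> dict:
    """Node/edge counts and the degree distribution of the stored network."""
    degrees = sorted(d for _, d in network.graph.degree())
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return {"n_nodes": network.n_nodes, "n_edges": network.n_edges,
            "degree_histogram": hist}
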