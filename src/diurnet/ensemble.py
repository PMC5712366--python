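"""Replicate-resampling ensemble of network estimates and edge confidence.

With few timepoints and noisy replicates, a single penalized regression
is unstable.  The ensemble draws M series matrices by picking one
replicate per timepoint (time order preserved — a bootstrap-like scheme
that keeps the temporal structure intact), infers one binary network per
draw, sums them into an integer confidence matrix B, and calls the edges
whose confidence strictly exceeds a threshold (default 20 of 30).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionTensor, SeriesMatrix
from .grn import BinaryNetwork, infer_network_single

logger = logging.getLogger("diurnet")

__all__ = [
    "ConfidenceMatrix",
    "DirectedNetwork",
    "resample_series",
    "ensemble_infer",
    "confidence_matrix",
    "call_edges",
    "network_summary",
    "degree_distribution_fit",
]


@dataclass
class ConfidenceMatrix:
    """Integer gene × gene matrix counting, over M trials, how often each
    directed edge (source row → target column) was selected."""

    genes: list[str]
    B: np.ndarray
    M: int

    def __post_init__(self) -> None:
        if np.any(self.B < 0) or np.any(self.B > self.M):
            raise ValueError("confidence counts must lie in [0, M]")

    def to_tsv(self, path) -> None:
        i, j = np.nonzero(self.B)
        pd.DataFrame({"source": [self.genes[a] for a in i],
                      "target": [self.genes[b] for b in j],
                      "confidence": self.B[i, j]}).to_csv(path, sep="\t", index=False)


@dataclass
class DirectedNetwork:
    """Called directed edges with confidences, plus self-loop report."""

    genes: list[str]
    graph: nx.DiGraph
    threshold: int
    M: int
    self_loops: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def parents(self) -> list[str]:
        return sorted(n for n, d in self.graph.out_degree() if d > 0)

    @property
    def children(self) -> list[str]:
        return sorted(n for n, d in self.graph.in_degree() if d > 0)

    def edges_frame(self) -> pd.DataFrame:
        rows = [(u, v, d["confidence"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "confidence"])

    def to_tsv(self, path) -> None:
        self.edges_frame().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path, peak_times: dict[str, float] | None = None) -> None:
        g = self.graph.copy()
        if peak_times:
            for node in g.nodes:
                if node in peak_times:
                    g.nodes[node]["peak_time"] = float(peak_times[node])
        nx.write_graphml(g, path)


def resample_series(tensor: ExpressionTensor,
                    seed: int | np.random.Generator = 0) -> SeriesMatrix:
    """Draw one replicate per timepoint, uniformly, shared across genes.

    A replicate is one sequencing library, so the same draw applies to all
    genes at a timepoint; time order is untouched.
    """
    grid = tensor.grid
    if grid.n_reps < 2:
        logger.warning("resample_series: single replicate, returning identity")
        return SeriesMatrix(list(tensor.genes), grid.hours, tensor.values[:, :, 0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sel = rng.integers(0, grid.n_reps, size=grid.n_timepoints)
    return SeriesMatrix(list(tensor.genes), grid.hours,
                        tensor.values[:, np.arange(grid.n_timepoints), sel])


def ensemble_infer(tensor: ExpressionTensor, order: int, M: int = 30,
                   base_seed: int = 0, max_failed_fraction: float = 0.1,
                   **infer_kwargs) -> list[BinaryNetwork]:
    """Infer M binary networks from M replicate-resampled series.

    Trial m uses seed ``base_seed + m`` (m = 1..M).  A trial is dropped
    only when more than ``max_failed_fraction`` of its targets failed.
    """
    networks: list[BinaryNetwork] = []
    for m in range(1, M + 1):
        series = resample_series(tensor, seed=base_seed + m)
        net = infer_network_single(series, order, **infer_kwargs)
        if len(net.failed_targets) > max_failed_fraction * len(net.genes):
            logger.warning("ensemble_infer: trial %d dropped "
                           "(%d failed targets)", m, len(net.failed_targets))
            continue
        networks.append(net)
    return networks


def confidence_matrix(networks: list[BinaryNetwork]) -> ConfidenceMatrix:
    """Elementwise sum of the trial adjacencies."""
    if not networks:
        raise ValueError("no networks to aggregate")
    genes = networks[0].genes
    shape = networks[0].matrix.shape
    for net in networks[1:]:
        if net.genes != genes or net.matrix.shape != shape:
            raise ValueError("networks must share gene order and shape")
    B = np.sum([net.matrix for net in networks], axis=0)
    return ConfidenceMatrix(list(genes), B, M=len(networks))


def call_edges(conf: ConfidenceMatrix, threshold: int = 20) -> DirectedNetwork:
    """Call edges whose confidence strictly exceeds the threshold.

    Boundary semantics follow "exceed": B = threshold is *not* called.
    Self-loops (a gene explained by its own lags) are excluded from the
    edge set and reported separately.
    """
    if not 0 < threshold <= conf.M:
        raise ValueError("threshold must lie in (0, M]")
    graph = nx.DiGraph()
    off = conf.B.copy()
    diag = np.diag(off).copy()
    np.fill_diagonal(off, 0)
    for i, j in zip(*np.nonzero(off > threshold)):
        graph.add_edge(conf.genes[i], conf.genes[j], confidence=int(off[i, j]))
    self_loops = [(g, int(c)) for g, c in zip(conf.genes, diag) if c > threshold]
    return DirectedNetwork(list(conf.genes), graph, threshold, conf.M, self_loops)


def network_summary(net: DirectedNetwork,
                    peak_times: dict[str, float] | None = None,
                    hub_min_children: int = 50) -> dict:
    """Edge/parent/child counts, hubs and degree distributions.

    A hub is a parent with out-degree strictly greater than
    ``hub_min_children``.
    """
    out_deg = dict(net.graph.out_degree())
    in_deg = dict(net.graph.in_degree())
    parents = net.parents
    children = net.children
    hubs = sorted((g for g, d in out_deg.items() if d > hub_min_children),
                  key=lambda g: -out_deg[g])
    summary = {
        "n_edges": net.n_edges,
        "n_parents": len(parents),
        "n_children": len(children),
        "n_genes_in_network": net.graph.number_of_nodes(),
        "hubs": [{"gene": g, "out_degree": out_deg[g]} for g in hubs],
        "out_degree_distribution": _histogram(out_deg.values()),
        "in_degree_distribution": _histogram(in_deg.values()),
        "n_self_loops": len(net.self_loops),
    }
    if peak_times is not None:
        summary["parent_peak_times"] = {
            g: float(peak_times[g]) for g in parents if g in peak_times}
    return summary


def _histogram(degrees) -> dict[int, int]:
    hist: dict[int, int] = {}
    for d in degrees:
        if d > 0:
            hist[int(d)] = hist.get(int(d), 0) + 1
    return dict(sorted(hist.items()))


def degree_distribution_fit(net: DirectedNetwork | nx.DiGraph,
                            min_support: int = 5) -> tuple[dict[int, int], float | None]:
    """Out-degree histogram with a descriptive log-log slope.

    The slope is the least-squares fit of log(frequency) on log(degree)
    over positive out-degrees; it is reported descriptively (a heavy tail
    shows as a clearly negative slope) and left undefined when fewer than
    ``min_support`` distinct positive degrees exist.
    """
    graph = net.graph if isinstance(net, DirectedNetwork) else net
    hist = _histogram(d for _, d in graph.out_degree())
    if len(hist) < min_support:
        return hist, None
    deg = np.array(list(hist.keys()), dtype=float)
    freq = np.array(list(hist.values()), dtype=float)
    slope = float(np.polyfit(np.log(deg), np.log(freq), 1)[0])
    return hist, slope
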