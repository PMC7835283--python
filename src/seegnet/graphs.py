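"""Baseline-thresholded directed event graphs.

Significance thresholds for coupling are derived once from the mean and
standard deviation of all h² values in a pre-ictal baseline window (20 s
before seizure onset by convention) and applied to every event:

    t1 = mu_b + 1 * sigma_b   (weak edge:   t1 < h² <= t2, drawn dashed)
    t2 = mu_b + 2 * sigma_b   (strong edge: h² > t2, drawn solid)

Nodes are electrode contacts; an edge src→dst exists when h²(dst|src) clears
t1.  Direction handling is configurable (see :func:`build_event_graph`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coupling import CouplingMatrix
from .signal_io import EventAnnotation

WEAK = "weak"
STRONG = "strong"


@dataclass
class ThresholdModel:
    mu_b: float
    sigma_b: float
    t1: float
    t2: float
    baseline_window: EventAnnotation | None = None

    def classify(self, h2: float) -> str | None:
        if h2 > self.t2:
            return STRONG
        if h2 > self.t1:
            return WEAK
        return None


@dataclass(frozen=True)
class GraphEdge:
    src: str
    dst: str
    cls: str  # WEAK or STRONG
    h2: float
    lag_samples: int


@dataclass
class DirectedEventGraph:
    nodes: list
    edges: list  # of GraphEdge
    event: EventAnnotation | None = None

    def __post_init__(self):
        for e in self.edges:
            if e.src == e.dst:
                raise ValueError("self-loops are not allowed")

    def edge_set(self, classes=(WEAK, STRONG)) -> set:
        return {(e.src, e.dst) for e in self.edges if e.cls in classes}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.src, e.dst, cls=e.cls, h2=float(e.h2),
                       lag_samples=int(e.lag_samples))
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def to_edge_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"src": e.src, "dst": e.dst, "class": e.cls, "h2": e.h2,
              "lag_samples": e.lag_samples} for e in self.edges],
            columns=["src", "dst", "class", "h2", "lag_samples"],
        )


@dataclass
class AdjacencyMatrix:
    labels: list
    M: np.ndarray
    mode: str  # "binary" or "weighted"


def fit_baseline(baseline_matrix: CouplingMatrix, min_window_s: float = 20.0) -> ThresholdModel:
    """Pool all off-diagonal baseline h² values into mean/SD thresholds.

    Uses the sample (n-1) standard deviation.  Computed once per study and
    reused for every event of every seizure.
    """
    ev = baseline_matrix.event
    if ev is not None and ev.duration_s < min_window_s:
        warnings.warn(
            f"baseline window of {ev.duration_s:.1f} s is shorter than the "
            f"recommended {min_window_s:.0f} s")
    vals = baseline_matrix.offdiag_values()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 baseline h2 values")
    mu = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=1))
    return ThresholdModel(mu_b=mu, sigma_b=sigma, t1=mu + sigma, t2=mu + 2 * sigma,
                          baseline_window=ev)


def _winner_direction(cands: list) -> "GraphEdge":
    """Pick one direction for a pair: prefer a positive optimal lag (the
    target trails the source, i.e. activity propagates src→dst); when the lag
    signs do not discriminate, take the larger h²; final ties go to the
    lexicographically smaller source label."""
    pos = [e for e in cands if e.lag_samples > 0]
    pool = pos if len(pos) == 1 else cands
    return sorted(pool, key=lambda e: (-e.h2, e.src, e.dst))[0]


def build_event_graph(cm: CouplingMatrix, thr: ThresholdModel,
                      rule: str = "independent") -> DirectedEventGraph:
    """Emit thresholded directed edges from a coupling matrix.

    rule="independent" (default): each ordered pair is tested on its own, so
    both directions may coexist.  rule="winner": at most one direction per
    unordered pair is kept, chosen by lag sign then h² (see module docstring).
    """
    if rule not in ("independent", "winner"):
        raise ValueError("rule must be 'independent' or 'winner'")
    n = len(cm.labels)
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if rule == "winner" and i > j:
                continue
            cand = []
            pairs = [(i, j)] if rule == "independent" else [(i, j), (j, i)]
            for a, b in pairs:
                v = cm.values[a, b]
                cls = thr.classify(v) if np.isfinite(v) else None
                if cls is not None:
                    cand.append(GraphEdge(cm.labels[a], cm.labels[b], cls,
                                          float(v), int(cm.lags[a, b])))
            if not cand:
                continue
            if rule == "independent":
                edges.extend(cand)
            else:
                edges.append(_winner_direction(cand))
    return DirectedEventGraph(nodes=list(cm.labels), edges=edges, event=cm.event)


def to_adjacency(g: DirectedEventGraph, mode: str = "binary") -> AdjacencyMatrix:
    """Adjacency view of the graph: binary (0/1) or weighted (weak=1, strong=2)."""
    if mode not in ("binary", "weighted"):
        raise ValueError("mode must be 'binary' or 'weighted'")
    n = len(g.nodes)
    idx = {lab: k for k, lab in enumerate(g.nodes)}
    M = np.zeros((n, n))
    for e in g.edges:
        w = 1.0 if mode == "binary" else (2.0 if e.cls == STRONG else 1.0)
        M[idx[e.src], idx[e.dst]] = w
    return AdjacencyMatrix(labels=list(g.nodes), M=M, mode=mode)


def from_adjacency(adj: AdjacencyMatrix, event: EventAnnotation | None = None
                   ) -> DirectedEventGraph:
    """Rebuild a graph from an adjacency matrix (class from weights when weighted)."""
    edges = []
    n = len(adj.labels)
    for i in range(n):
        for j in range(n):
            if i == j or adj.M[i, j] == 0:
                continue
            cls = STRONG if (adj.mode == "weighted" and adj.M[i, j] >= 2) else WEAK
            edges.append(GraphEdge(adj.labels[i], adj.labels[j], cls, np.nan, 0))
    return DirectedEventGraph(nodes=list(adj.labels), edges=edges, event=event)
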